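"""Deterministic seed derivation.

Every stage of the pipeline draws its randomness from a seed derived from the
run's base seed and a short stage label, so stages can be reproduced in
isolation and reruns are bit-identical.
"""

from __future__ import annotations

import zlib

_MOD = 2**31


def derive_seed(base: int, label: str) -> int:
    """Derive a stage seed (< 2**31) from a base seed and a stage label."""
    return (int(base) * 1_000_003 + zlib.crc32(label.encode("utf-8"))) % _MOD
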