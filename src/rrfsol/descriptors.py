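"""0-2D molecular descriptors and shuffled decoy augmentation.

The descriptor table is the numeric interface between chemistry and
modelling: one row per molecule, columns of constitutional/topological/
fragment-count descriptors computable without 3D geometry. For the decoy
null used by variable selection, every column is duplicated with its values
permuted across molecules — a per-descriptor negative control carrying the
same marginal distribution but no relation to the response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorMatrix",
    "DescriptorError",
    "compute_descriptors",
    "clean_matrix",
    "add_shuffled_decoys",
    "DECOY_SUFFIX",
]

DECOY_SUFFIX = "__shuffled"


class DescriptorError(ValueError):
    pass


@dataclass
class DescriptorMatrix:
    """Molecules x named numeric descriptors, optionally with decoys.

    ``decoy_map`` maps each decoy column name to its parent descriptor name;
    decoy columns are exact permutations of their parent's values.
    """

    data: pd.DataFrame
    decoy_map: dict = field(default_factory=dict)
    descriptor_set: str = "rdkit-2d"
    dropped_columns: dict = field(default_factory=dict)   # name -> reason
    failed_molecules: dict = field(default_factory=dict)  # id -> reason

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise DescriptorError(f"duplicated descriptor names: {dupes}")
        for decoy, parent in self.decoy_map.items():
            if parent not in self.data.columns:
                raise DescriptorError(f"decoy {decoy!r} maps to missing parent {parent!r}")

    @property
    def molecule_ids(self) -> list:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list:
        return list(self.data.columns)

    @property
    def parent_columns(self) -> list:
        return [c for c in self.data.columns if c not in self.decoy_map]

    def save(self, csv_path, sidecar_path=None) -> None:
        csv_path = Path(csv_path)
        self.data.rename_axis("molecule_id").to_csv(csv_path)
        sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"descriptor_set": self.descriptor_set, "decoy_map": self.decoy_map},
                indent=2,
            )
        )

    @classmethod
    def load(cls, csv_path, sidecar_path=None) -> "DescriptorMatrix":
        csv_path = Path(csv_path)
        data = pd.read_csv(csv_path, index_col="molecule_id").rename_axis(None)
        sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            data=data,
            decoy_map=meta.get("decoy_map", {}),
            descriptor_set=meta.get("descriptor_set", "unknown"),
        )


def compute_descriptors(molecules, descriptor_set: str = "rdkit-2d") -> DescriptorMatrix:
    """Compute the open 0-2D descriptor table for curated molecules.

    ``molecules`` is a list of :class:`~rrfsol.curation.CuratedMolecule` (or
    anything with ``inchi_key`` and ``standardized_smiles``). Molecules whose
    descriptor computation fails are excluded and recorded in
    ``failed_molecules`` with a reason — never silently dropped.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    if descriptor_set != "rdkit-2d":
        raise DescriptorError(f"unknown descriptor set {descriptor_set!r}")

    rows, index, failed = [], [], {}
    for mol_rec in molecules:
        mol = Chem.MolFromSmiles(mol_rec.standardized_smiles)
        if mol is None:
            failed[mol_rec.inchi_key] = "standardized SMILES failed to re-parse"
            continue
        try:
            values = Descriptors.CalcMolDescriptors(mol)
        except Exception as exc:  # descriptor backends can raise on exotica
            failed[mol_rec.inchi_key] = f"descriptor computation failed: {exc}"
            continue
        rows.append(values)
        index.append(mol_rec.inchi_key)
    if not rows:
        raise DescriptorError("descriptor computation failed for every molecule")
    data = pd.DataFrame(rows, index=index).astype(float)
    return DescriptorMatrix(data=data, descriptor_set=descriptor_set, failed_molecules=failed)


def clean_matrix(m: DescriptorMatrix) -> DescriptorMatrix:
    """Drop constant columns and columns with missing/non-finite entries.

    Idempotent. Raises when nothing usable remains.
    """
    dropped = dict(m.dropped_columns)
    keep = []
    for col in m.data.columns:
        vals = m.data[col].to_numpy()
        if not np.isfinite(vals).all():
            dropped[col] = "non-finite or missing values"
        elif np.all(vals == vals[0]):
            dropped[col] = "constant column"
        else:
            keep.append(col)
    if not keep:
        raise DescriptorError("no usable descriptors: all columns dropped")
    decoy_map = {d: p for d, p in m.decoy_map.items() if d in keep and p in keep}
    return DescriptorMatrix(
        data=m.data[keep].copy(),
        decoy_map=decoy_map,
        descriptor_set=m.descriptor_set,
        dropped_columns=dropped,
        failed_molecules=dict(m.failed_molecules),
    )


def add_shuffled_decoys(m: DescriptorMatrix, seed: int) -> DescriptorMatrix:
    """Append a shuffled decoy ``X__shuffled`` for every column of ``m``.

    Each decoy is an *independent* row-permutation of its parent (one shared
    permutation would preserve inter-column correlations among decoys and
    distort the null). Column count doubles; moments of each decoy equal its
    parent's exactly.
    """
    if m.decoy_map:
        raise DescriptorError("matrix already contains decoys")
    rng = np.random.default_rng(seed)
    n = len(m.data)
    decoys = {}
    for col in m.data.columns:
        decoys[col + DECOY_SUFFIX] = m.data[col].to_numpy()[rng.permutation(n)]
    data = pd.concat([m.data, pd.DataFrame(decoys, index=m.data.index)], axis=1)
    return DescriptorMatrix(
        data=data,
        decoy_map={col + DECOY_SUFFIX: col for col in m.data.columns},
        descriptor_set=m.descriptor_set,
        dropped_columns=dict(m.dropped_columns),
        failed_molecules=dict(m.failed_molecules),
    )
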