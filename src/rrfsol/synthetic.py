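"""Synthetic descriptor datasets with the statistical structure the
modelling procedure assumes.

The generator emulates a curated solubility table: a numeric descriptor
matrix whose response (logS, log10 mol/L) is a sparse linear function of a
few informative columns plus residual noise, with multi-source replicate
measurements of controllable inter-source scatter, a controllable fraction
of grossly shifted (mislabelled) molecules, and redundant
correlated-duplicate descriptor columns. Descriptors are abstract numeric
columns, not computed from simulated structures: the selection, cleaning and
consensus stages consume numeric matrices, and real-descriptor behaviour is
covered by the SMILES fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .curation import RawRecord

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_descriptor_dataset",
    "standard_benchmarks",
    "generate_toy_smiles_fixture",
    "TOY_FIXTURE_N_MOLECULES",
    "TOY_FIXTURE_N_REJECTED",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset draw.

    ``beta`` are the coefficients of the informative columns; descriptor
    columns are i.i.d. standard normal, so ``|beta_j|`` is the per-column
    signal SD in log units. ``intercept`` places the bulk of the response
    around the logS = -2 solubility-class cut-off. When
    ``bimodal_offset > 0`` half the molecules are shifted up and half down
    by that amount, straddling the cut-off.
    """

    n_molecules: int = 500
    n_informative: int = 10
    n_noise: int = 200
    n_correlated_duplicates: int = 0
    beta: tuple = (2.0, -1.75, 1.5, -1.4, 1.25, -1.1, 1.0, -0.95, 0.9, -0.8)
    noise_sd: float = 0.5
    replicated_fraction: float = 0.0
    replicates_min: int = 2
    replicates_max: int = 3
    inter_source_sd: float = 0.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 3.0
    outliers_single_source: bool = True
    duplicate_jitter_sd: float = 0.3
    intercept: float = -2.0
    bimodal_offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.beta) != self.n_informative:
            raise ValueError("beta must have n_informative entries")
        if not (0 <= self.outlier_fraction < 1):
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.n_correlated_duplicates > self.n_informative:
            raise ValueError("cannot duplicate more columns than are informative")
        for name in ("noise_sd", "inter_source_sd", "duplicate_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticDataset:
    """One draw: descriptor matrix, replicate measurements, ground truth."""

    X: pd.DataFrame                      # molecules x descriptors
    measurements: pd.DataFrame           # long: molecule_id, logS, source
    y_true: pd.Series                    # noiseless-label value (no shift)
    y_label: pd.Series                   # underlying value incl. outlier shift
    informative_columns: list
    duplicate_map: dict                  # duplicate column -> parent column
    outlier: pd.Series                   # bool per molecule
    replicated: pd.Series                # bool per molecule (>1 source)
    spec: SyntheticSpec

    def mean_logs(self) -> pd.Series:
        """Per-molecule arithmetic mean of the replicate measurements."""
        return self.measurements.groupby("molecule_id", sort=False)["logS"].mean().reindex(self.X.index)

    def inter_source_sd(self) -> pd.Series:
        """Per-molecule (n-1)-denominator SD; 0 for single measurements."""
        sd = self.measurements.groupby("molecule_id", sort=False)["logS"].std(ddof=1)
        return sd.reindex(self.X.index).fillna(0.0)


def generate_descriptor_dataset(spec: SyntheticSpec, seed: int | None = None) -> SyntheticDataset:
    """Draw one dataset. A pure function of ``spec`` and ``seed``."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_molecules
    ids = [f"m{i:05d}" for i in range(n)]

    p_real = spec.n_informative + spec.n_noise
    X = rng.standard_normal((n, p_real))
    names = [f"x{j:03d}" for j in range(p_real)]
    informative = names[: spec.n_informative]

    duplicate_map = {}
    dup_cols = []
    for d in range(spec.n_correlated_duplicates):
        parent_idx = d % spec.n_informative
        col = X[:, parent_idx] + rng.normal(0.0, spec.duplicate_jitter_sd, n)
        name = f"{names[parent_idx]}_dup{d}"
        duplicate_map[name] = names[parent_idx]
        dup_cols.append(col)
        names.append(name)
    if dup_cols:
        X = np.column_stack([X] + dup_cols)

    intercepts = np.full(n, spec.intercept)
    if spec.bimodal_offset > 0:
        lower = rng.permutation(n) < n // 2
        intercepts = intercepts + np.where(lower, -spec.bimodal_offset, spec.bimodal_offset)

    beta = np.asarray(spec.beta, dtype=float)
    y_true = intercepts + X[:, : spec.n_informative] @ beta + rng.normal(0.0, spec.noise_sd, n)

    n_rep = int(round(spec.replicated_fraction * n))
    replicated = np.zeros(n, dtype=bool)
    if n_rep:
        replicated[rng.choice(n, n_rep, replace=False)] = True

    outlier = np.zeros(n, dtype=bool)
    n_out = int(round(spec.outlier_fraction * n))
    if n_out:
        pool = np.where(~replicated)[0] if spec.outliers_single_source else np.arange(n)
        if n_out > pool.size:
            raise ValueError("outlier_fraction too large for the single-source pool")
        outlier[rng.choice(pool, n_out, replace=False)] = True

    y_label = y_true.copy()
    y_label[outlier] += rng.choice([-1.0, 1.0], n_out) * spec.outlier_shift

    rows = []
    for i in range(n):
        k = int(rng.integers(spec.replicates_min, spec.replicates_max + 1)) if replicated[i] else 1
        vals = y_label[i] + rng.normal(0.0, spec.inter_source_sd, k)
        for s, v in enumerate(vals):
            rows.append((ids[i], float(v), f"src{s}"))
    measurements = pd.DataFrame(rows, columns=["molecule_id", "logS", "source"])

    return SyntheticDataset(
        X=pd.DataFrame(X, index=ids, columns=names),
        measurements=measurements,
        y_true=pd.Series(y_true, index=ids, name="logS_true"),
        y_label=pd.Series(y_label, index=ids, name="logS_label"),
        informative_columns=informative,
        duplicate_map=duplicate_map,
        outlier=pd.Series(outlier, index=ids, name="outlier"),
        replicated=pd.Series(replicated, index=ids, name="replicated"),
        spec=spec,
    )


def standard_benchmarks() -> dict:
    """Named dataset presets used throughout the test battery.

    SELECTION: variable-recovery conditions (500 molecules, 10 informative of
    215 columns incl. 5 jittered duplicates, residual SD 0.5).
    CLEANING: contamination conditions (800 molecules, 15 % of labels shifted
    by +-3 log units among single-source molecules; 35 % of molecules carry
    2-3 replicate sources with 0.3 log inter-source SD, so both RELIABLE and
    UNRELIABLE partitions are populated).
    CONSENSUS: bimodal response straddling the logS = -2 class cut-off.
    """
    return {
        "SELECTION": SyntheticSpec(
            n_molecules=500,
            n_informative=10,
            n_noise=200,
            n_correlated_duplicates=5,
            beta=(2.0, -1.75, 1.5, -1.4, 1.25, -1.1, 1.0, -0.95, 0.9, -0.8),
            noise_sd=0.5,
            intercept=-2.0,
        ),
        "CLEANING": SyntheticSpec(
            n_molecules=800,
            n_informative=3,
            n_noise=30,
            n_correlated_duplicates=2,
            beta=(1.0, -0.8, 0.6),
            noise_sd=0.5,
            replicated_fraction=0.35,
            inter_source_sd=0.3,
            outlier_fraction=0.15,
            outlier_shift=3.0,
            outliers_single_source=True,
            intercept=-2.5,
        ),
        "CONSENSUS": SyntheticSpec(
            n_molecules=600,
            n_informative=5,
            n_noise=20,
            n_correlated_duplicates=0,
            beta=(0.8, -0.7, 0.7, -0.6, 0.6),
            noise_sd=0.5,
            replicated_fraction=0.3,
            inter_source_sd=0.3,
            intercept=-2.0,
            bimodal_offset=1.5,
        ),
    }


# -- toy SMILES fixture -------------------------------------------------

#: Distinct standardized structures in the toy fixture (the salt collapses
#: onto acetic acid, the malformed record is rejected).
TOY_FIXTURE_N_MOLECULES = 10
#: Records of the fixture that fail structure standardization.
TOY_FIXTURE_N_REJECTED = 1

_CAFFEINE = "Cn1cnc2c1c(=O)n(C)c(=O)n2C"
_ASPIRIN = "CC(=O)Oc1ccccc1C(=O)O"
_IBUPROFEN = "CC(C)Cc1ccc(cc1)C(C)C(=O)O"

_TOY_ROWS = [
    # record_id, smiles, logS, source
    ("r01", "CCO", -0.10, "A"),                    # ethanol
    ("r02", "OCC", -0.30, "B"),                    # ethanol, alternate spelling
    ("r03", "c1ccccc1", -1.00, "A"),               # benzene
    ("r04", "C1=CC=CC=C1", -2.64, "B"),            # benzene, kekulized; SD > 1
    ("r05", _CAFFEINE, -0.90, "A"),
    ("r06", _CAFFEINE, -1.10, "B"),
    ("r07", _ASPIRIN, -1.55, "A"),                 # single measurement
    ("r08", "c1ccc2ccccc2c1", -3.60, "A"),         # naphthalene
    ("r09", "c1ccc2ccccc2c1", -3.00, "B"),
    ("r10", "c1ccc2ccccc2c1", -3.10, "C"),
    ("r11", "Oc1ccccc1", 0.00, "A"),               # phenol
    ("r12", "Cc1ccccc1", -2.21, "A"),              # toluene
    ("r13", "CC(=O)O", 1.00, "A"),                 # acetic acid
    ("r14", "CC(=O)[O-].[Na+]", 0.80, "B"),        # sodium acetate -> acetic acid
    ("r15", "c1ccncc1", 1.00, "A"),                # pyridine, single measurement
    ("r16", _IBUPROFEN, -3.97, "A"),               # single measurement
    ("r17", "C1CC", -1.00, "A"),                   # malformed: unclosed ring
    ("r18", "CCO", -0.20, "C"),
    ("r19", "c1ccc(O)cc1", -0.10, "B"),            # phenol, alternate spelling
    ("r20", "Cc1ccccc1", -2.31, "B"),
]


def generate_toy_smiles_fixture() -> list:
    """Hand-written records over 10 real small molecules.

    Exercises every curation path: aromatic/kekulized duplicate spellings,
    a salt form that collapses onto its parent acid, single-measurement and
    multi-measurement molecules, one pair with inter-source SD above 1 log
    unit, and one malformed SMILES.
    """
    return [RawRecord(record_id=r, smiles=s, logS=v, source=src) for r, s, v, src in _TOY_ROWS]
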