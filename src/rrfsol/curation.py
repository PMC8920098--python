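"""Structure curation: parsing, standardization, deduplication and
reliability partitioning of solubility records.

Records arrive as SMILES with optional experimental logS (log10 mol/L) and a
source tag. Standardization keeps the largest covalently bonded organic
fragment, neutralizes charges where chemically valid and canonicalizes; the
InChIKey of the standardized structure is the deduplication key. Replicate
measurements of one structure are aggregated to a mean and an inter-source
standard deviation, and each molecule is labelled RELIABLE when it has more
than one measurement with 0 < SD < 1 log unit — the moderately scattered,
replicated molecules that later serve as the optimization yardstick — and
UNRELIABLE otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "RawRecord",
    "CuratedMolecule",
    "CurationError",
    "StructureParseError",
    "InorganicStructureError",
    "RELIABLE",
    "UNRELIABLE",
    "standardize_structure",
    "deduplicate",
    "curate_records",
    "partition_reliability",
    "remove_overlap",
    "read_records",
    "write_curated_csv",
    "write_rejections_csv",
    "read_curated_csv",
]

RELIABLE = "RELIABLE"
UNRELIABLE = "UNRELIABLE"


class CurationError(ValueError):
    """Base class for curation failures."""


class StructureParseError(CurationError):
    """SMILES could not be parsed into a molecule."""


class InorganicStructureError(CurationError):
    """No covalently bonded organic (carbon-containing) fragment."""


@dataclass(frozen=True)
class RawRecord:
    """One input measurement: a structure and (optionally) its logS."""

    record_id: str
    smiles: str
    logS: float | None = None
    source: str | None = None

    def __post_init__(self):
        if not self.smiles:
            raise ValueError(f"record {self.record_id}: empty SMILES")
        if self.logS is not None and not math.isfinite(self.logS):
            raise ValueError(f"record {self.record_id}: non-finite logS")


@dataclass(frozen=True)
class CuratedMolecule:
    """A standardized structure with aggregated measurements.

    ``inter_source_sd`` uses the (n-1) denominator for n >= 2 and is defined
    as 0 for a single measurement, so single-valued molecules fall into the
    "SD equal to 0" UNRELIABLE bucket.
    """

    inchi_key: str
    standardized_smiles: str
    measurements: tuple = ()          # tuple of (logS, source)
    mean_logS: float | None = None
    inter_source_sd: float = 0.0
    n_measurements: int = 0

    @property
    def reliability(self) -> str:
        if self.n_measurements > 1 and 0.0 < self.inter_source_sd < 1.0:
            return RELIABLE
        return UNRELIABLE


_fragment_chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_uncharger = rdMolStandardize.Uncharger()


def standardize_structure(smiles: str) -> tuple:
    """Standardize one SMILES; return ``(standardized_smiles, inchi_key)``.

    Pipeline: parse -> cleanup -> keep largest organic fragment -> neutralize
    charges -> canonicalize -> InChIKey. Idempotent: standardizing the output
    reproduces it. Tautomer canonicalization is deliberately not applied;
    the InChI standard layer already normalizes mobile hydrogens.

    Raises
    ------
    StructureParseError
        for unparseable SMILES.
    InorganicStructureError
        when no carbon-containing fragment remains.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(f"unparseable SMILES: {smiles!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = _fragment_chooser.choose(mol)
    if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
        raise InorganicStructureError(f"no organic fragment in {smiles!r}")
    mol = _uncharger.uncharge(mol)
    std_smiles = Chem.MolToSmiles(mol)
    key = Chem.MolToInchiKey(mol)
    if not key:
        raise CurationError(f"InChI generation failed for {smiles!r}")
    return std_smiles, key


def deduplicate(records: list) -> list:
    """Group standardizable records by InChIKey and aggregate measurements.

    Precondition: every record standardizes (use :func:`curate_records` for
    tolerant processing). Duplicate measurements with identical value and
    source are kept. Output order follows first appearance, so the result is
    independent of measurement order within groups; the molecule *set* is
    permutation-invariant.
    """
    groups: dict = {}
    order: list = []
    for rec in records:
        std_smiles, key = standardize_structure(rec.smiles)
        if key not in groups:
            groups[key] = (std_smiles, [])
            order.append(key)
        if rec.logS is not None:
            groups[key][1].append((float(rec.logS), rec.source))
    out = []
    for key in order:
        std_smiles, meas = groups[key]
        meas = sorted(meas, key=lambda m: (m[0], m[1] or ""))
        values = np.array([m[0] for m in meas])
        n = len(values)
        mean = float(values.mean()) if n else None
        sd = float(values.std(ddof=1)) if n >= 2 else 0.0
        out.append(
            CuratedMolecule(
                inchi_key=key,
                standardized_smiles=std_smiles,
                measurements=tuple(meas),
                mean_logS=mean,
                inter_source_sd=sd,
                n_measurements=n,
            )
        )
    return out


def curate_records(records: list) -> tuple:
    """Standardize + deduplicate, tolerating bad records.

    Returns ``(molecules, rejections)`` where rejections is a list of
    ``(record_id, reason)``. Records are never silently dropped.
    """
    good, rejections = [], []
    for rec in records:
        try:
            standardize_structure(rec.smiles)
        except CurationError as exc:
            rejections.append((rec.record_id, str(exc)))
        else:
            good.append(rec)
    return deduplicate(good), rejections


def partition_reliability(molecules: list) -> tuple:
    """Split molecules into (reliable, unreliable) lists.

    RELIABLE iff more than one measurement and 0 < inter-source SD < 1 log
    unit; the two lists partition the input.
    """
    reliable = [m for m in molecules if m.reliability == RELIABLE]
    unreliable = [m for m in molecules if m.reliability == UNRELIABLE]
    return reliable, unreliable


def remove_overlap(training: list, external: list) -> tuple:
    """Drop training molecules whose InChIKey appears in ``external``.

    Returns ``(filtered_training, overlap_count)``.
    """
    ext_keys = {m.inchi_key for m in external}
    kept = [m for m in training if m.inchi_key not in ext_keys]
    return kept, len(training) - len(kept)


# -- file IO ------------------------------------------------------------


def read_records(
    path,
    smiles_col: str = "smiles",
    logs_col: str = "logS",
    source_col: str = "source",
    sdf_logs_property: str = "logS",
) -> list:
    """Read raw records from CSV, ``.smi`` or SDF.

    CSV column names are configurable; ``.smi`` is whitespace-delimited
    ``SMILES [id]``; SDF takes logS from a named property field.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    records = []
    if suffix == ".smi":
        for i, line in enumerate(path.read_text().splitlines()):
            parts = line.split()
            if not parts:
                continue
            rid = parts[1] if len(parts) > 1 else f"smi{i:05d}"
            records.append(RawRecord(record_id=rid, smiles=parts[0]))
    elif suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                records.append(RawRecord(record_id=f"sdf{i:05d}", smiles="*"))
                continue
            try:
                Chem.SanitizeMol(mol)
                smiles = Chem.MolToSmiles(mol)
            except Exception:
                smiles = "*"
            logs = None
            if mol.HasProp(sdf_logs_property):
                try:
                    logs = float(mol.GetProp(sdf_logs_property))
                except ValueError:
                    logs = None
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            records.append(
                RawRecord(record_id=name or f"sdf{i:05d}", smiles=smiles, logS=logs)
            )
    else:
        frame = pd.read_csv(path)
        if smiles_col not in frame.columns:
            raise CurationError(
                f"column {smiles_col!r} not found in {path.name}; "
                f"available: {list(frame.columns)}"
            )
        has_logs = logs_col in frame.columns
        has_src = source_col in frame.columns
        id_col = "record_id" if "record_id" in frame.columns else None
        for i, row in frame.iterrows():
            logs = row[logs_col] if has_logs else None
            if logs is not None and (isinstance(logs, float) and math.isnan(logs)):
                logs = None
            records.append(
                RawRecord(
                    record_id=str(row[id_col]) if id_col else f"csv{i:05d}",
                    smiles=str(row[smiles_col]),
                    logS=None if logs is None else float(logs),
                    source=str(row[source_col]) if has_src and not pd.isna(row[source_col]) else None,
                )
            )
    return records


def molecules_to_frame(molecules: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "inchi_key": [m.inchi_key for m in molecules],
            "smiles": [m.standardized_smiles for m in molecules],
            "mean_logS": [m.mean_logS for m in molecules],
            "sd": [m.inter_source_sd for m in molecules],
            "n": [m.n_measurements for m in molecules],
            "reliability": [m.reliability for m in molecules],
        }
    )


def write_curated_csv(molecules: list, path) -> None:
    molecules_to_frame(molecules).to_csv(path, index=False)


def read_curated_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_rejections_csv(rejections: list, path) -> None:
    pd.DataFrame(rejections, columns=["record_id", "reason"]).to_csv(path, index=False)
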