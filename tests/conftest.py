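import numpy as np
import pandas as pd
import pytest

from rrfsol.curation import RawRecord
from rrfsol.synthetic import SyntheticSpec, generate_descriptor_dataset, generate_toy_smiles_fixture


@pytest.fixture(scope="session")
def toy_records():
    return generate_toy_smiles_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """A small contaminated dataset for fast pipeline-level tests."""
    spec = SyntheticSpec(
        n_molecules=240,
        n_informative=3,
        n_noise=8,
        n_correlated_duplicates=0,
        beta=(1.0, -0.8, 0.6),
        noise_sd=0.5,
        replicated_fraction=0.35,
        inter_source_sd=0.3,
        outlier_fraction=0.15,
        outlier_shift=3.0,
        intercept=-2.5,
        seed=11,
    )
    return generate_descriptor_dataset(spec)


def reliability_mask(dataset) -> np.ndarray:
    """RELIABLE rule (n > 1 and 0 < sd < 1) applied to generated replicates."""
    sd = dataset.inter_source_sd()
    n = dataset.measurements.groupby("molecule_id", sort=False).size().reindex(dataset.X.index)
    return ((n > 1) & (sd > 0) & (sd < 1)).to_numpy()


@pytest.fixture(scope="session")
def alkane_series_csv(tmp_path_factory):
    """A small real-molecule training table written to CSV.

    Simple organic series (alkanes, alcohols, acids, aromatics) with
    fabricated logS values spanning the -2 class cut-off; used by CLI
    end-to-end tests so descriptor computation runs on genuine structures.
    """
    rng = np.random.default_rng(5)
    rows = []
    frames = {
        "alkane": "C" * 1,
        "alcohol": "OC",
    }
    smiles_list = []
    for k in range(1, 13):
        smiles_list.append("C" * k)                    # alkanes C1..C12
    for k in range(1, 9):
        smiles_list.append("OC" + "C" * k)             # primary alcohols
    for k in range(0, 6):
        smiles_list.append("OC(=O)" + "C" * (k + 1))   # carboxylic acids
    smiles_list += [
        "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1",
        "c1ccncc1", "CC(C)O", "CC(C)CO", "CCOCC",
    ]
    for i, smi in enumerate(smiles_list):
        n_heavy = sum(c.isalpha() and c.upper() != "H" for c in smi)
        logs = 0.8 - 0.55 * n_heavy + float(rng.normal(0, 0.2))
        rows.append((f"mol{i:03d}", smi, round(logs, 3), "labA"))
    frame = pd.DataFrame(rows, columns=["record_id", "smiles", "logS", "source"])
    path = tmp_path_factory.mktemp("cli-data") / "training.csv"
    frame.to_csv(path, index=False)
    return path
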