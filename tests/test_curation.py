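"""Structure standardization, deduplication and reliability partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from rrfsol.curation import (
    RELIABLE,
    UNRELIABLE,
    CuratedMolecule,
    InorganicStructureError,
    RawRecord,
    StructureParseError,
    curate_records,
    deduplicate,
    partition_reliability,
    read_records,
    remove_overlap,
    standardize_structure,
    write_curated_csv,
)
from rrfsol.synthetic import TOY_FIXTURE_N_MOLECULES, TOY_FIXTURE_N_REJECTED


class TestStandardize:
    def test_idempotent_on_clean_structure(self):
        smiles1, key1 = standardize_structure("CCO")
        smiles2, key2 = standardize_structure(smiles1)
        assert (smiles1, key1) == (smiles2, key2)

    def test_counter_ion_stripped_matches_independent_inchi(self):
        # independent oracle: InChIKey of the bare ethanol fragment via RDKit
        expected = Chem.MolToInchiKey(Chem.MolFromSmiles("CCO"))
        _, key = standardize_structure("CCO.Cl")
        assert key == expected

    def test_unclosed_ring_is_parse_error(self):
        with pytest.raises(StructureParseError):
            standardize_structure("C1CC")

    def test_purely_inorganic_rejected(self):
        with pytest.raises(InorganicStructureError):
            standardize_structure("[Na+].[Cl-]")

    def test_charge_neutralized(self):
        _, key_anion = standardize_structure("CC(=O)[O-]")
        _, key_acid = standardize_structure("CC(=O)O")
        assert key_anion == key_acid

    @pytest.mark.parametrize(
        "a,b",
        [("c1ccccc1", "C1=CC=CC=C1"), ("CCO", "OCC"), ("Oc1ccccc1", "c1ccc(O)cc1")],
    )
    def test_spelling_variants_share_key(self, a, b):
        assert standardize_structure(a)[1] == standardize_structure(b)[1]


class TestDeduplicate:
    def test_two_measurements_mean_and_sd(self):
        records = [
            RawRecord("a", "CCO", -2.0, "s1"),
            RawRecord("b", "OCC", -3.0, "s2"),
        ]
        (mol,) = deduplicate(records)
        assert mol.n_measurements == 2
        assert mol.mean_logS == pytest.approx(-2.5)
        assert mol.inter_source_sd == pytest.approx(0.7071067811865476, abs=1e-12)

    def test_single_measurement_sd_zero(self):
        (mol,) = deduplicate([RawRecord("a", "CCO", -2.0, None)])
        assert mol.mean_logS == -2.0
        assert mol.inter_source_sd == 0.0
        assert mol.n_measurements == 1

    def test_three_records_two_sharing_key(self):
        records = [
            RawRecord("a", "CCO", -2.0, None),
            RawRecord("b", "OCC", -3.0, None),
            RawRecord("c", "c1ccccc1", -1.6, None),
        ]
        assert len(deduplicate(records)) == 2

    def test_empty_input(self):
        assert deduplicate([]) == []

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(perm=st.permutations(list(range(5))))
    def test_order_invariant(self, perm):
        base = [
            RawRecord("a", "CCO", -2.0, "s1"),
            RawRecord("b", "OCC", -3.0, "s2"),
            RawRecord("c", "c1ccccc1", -1.6, "s1"),
            RawRecord("d", "C1=CC=CC=C1", -1.8, "s2"),
            RawRecord("e", "Cc1ccccc1", -2.2, "s1"),
        ]
        expected = {
            (m.inchi_key, m.mean_logS, m.inter_source_sd, m.n_measurements)
            for m in deduplicate(base)
        }
        shuffled = {
            (m.inchi_key, m.mean_logS, m.inter_source_sd, m.n_measurements)
            for m in deduplicate([base[i] for i in perm])
        }
        assert shuffled == expected


def _mol(key, n, sd):
    return CuratedMolecule(
        inchi_key=key, standardized_smiles="C", measurements=(),
        mean_logS=-2.0, inter_source_sd=sd, n_measurements=n,
    )


class TestReliability:
    @pytest.mark.parametrize(
        "n,sd,expected",
        [
            (2, 0.5, RELIABLE),
            (2, 0.0, UNRELIABLE),
            (1, 0.0, UNRELIABLE),
            (2, 1.0, UNRELIABLE),   # boundary: strictly less than 1
            (2, 1.5, UNRELIABLE),
            (3, 0.999, RELIABLE),
        ],
    )
    def test_rule(self, n, sd, expected):
        assert _mol("K", n, sd).reliability == expected

    def test_partition_property(self):
        mols = [_mol(f"K{i}", n, sd) for i, (n, sd) in enumerate([(1, 0), (2, 0.5), (3, 2.0), (2, 0)])]
        rel, unrel = partition_reliability(mols)
        assert len(rel) + len(unrel) == len(mols)
        assert set(m.inchi_key for m in rel).isdisjoint(m.inchi_key for m in unrel)


class TestRemoveOverlap:
    def test_partial_overlap(self):
        train = [_mol(f"K{i}", 1, 0) for i in range(5)]
        ext = [_mol("K1", 1, 0), _mol("K3", 1, 0)]
        kept, n_overlap = remove_overlap(train, ext)
        assert n_overlap == 2 and len(kept) == 3
        assert {m.inchi_key for m in kept}.isdisjoint({m.inchi_key for m in ext})

    def test_disjoint(self):
        train = [_mol("A", 1, 0)]
        kept, n = remove_overlap(train, [_mol("B", 1, 0)])
        assert kept == train and n == 0

    def test_full_overlap(self):
        train = [_mol("A", 1, 0)]
        kept, n = remove_overlap(train, [_mol("A", 1, 0), _mol("B", 1, 0)])
        assert kept == [] and n == 1


class TestToyFixture:
    def test_counts_and_salt_collapse(self, toy_records):
        mols, rejections = curate_records(toy_records)
        assert len(mols) == TOY_FIXTURE_N_MOLECULES
        assert len(rejections) == TOY_FIXTURE_N_REJECTED
        assert rejections[0][0] == "r17"
        # the sodium acetate record merged into acetic acid
        acetic_key = standardize_structure("CC(=O)O")[1]
        (acetic,) = [m for m in mols if m.inchi_key == acetic_key]
        assert acetic.n_measurements == 2

    def test_standardization_idempotent_across_fixture(self, toy_records):
        mols, _ = curate_records(toy_records)
        for m in mols:
            assert standardize_structure(m.standardized_smiles)[0] == m.standardized_smiles

    def test_reliability_split(self, toy_records):
        mols, _ = curate_records(toy_records)
        rel, unrel = partition_reliability(mols)
        assert len(rel) == 6 and len(unrel) == 4
        # the wide-scatter benzene pair (sd > 1) is UNRELIABLE despite n=2
        benzene_key = standardize_structure("c1ccccc1")[1]
        assert benzene_key in {m.inchi_key for m in unrel}


class TestIO:
    def test_csv_round_trip(self, toy_records, tmp_path):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "record_id": [r.record_id for r in toy_records],
                "smiles": [r.smiles for r in toy_records],
                "logS": [r.logS for r in toy_records],
                "source": [r.source for r in toy_records],
            }
        )
        path = tmp_path / "records.csv"
        frame.to_csv(path, index=False)
        records = read_records(path)
        assert len(records) == len(toy_records)
        mols, rej = curate_records(records)
        assert len(mols) == TOY_FIXTURE_N_MOLECULES and len(rej) == 1
        out = tmp_path / "curated.csv"
        write_curated_csv(mols, out)
        back = pd.read_csv(out)
        assert list(back.columns) == ["inchi_key", "smiles", "mean_logS", "sd", "n", "reliability"]
        assert len(back) == TOY_FIXTURE_N_MOLECULES

    def test_smi_format(self, tmp_path):
        path = tmp_path / "input.smi"
        path.write_text("CCO mol1\nc1ccccc1 mol2\n")
        records = read_records(path)
        assert [r.record_id for r in records] == ["mol1", "mol2"]
        assert records[0].logS is None

    def test_missing_column_error_names_it(self, tmp_path):
        import pandas as pd

        path = tmp_path / "bad.csv"
        pd.DataFrame({"structure": ["CCO"]}).to_csv(path, index=False)
        with pytest.raises(Exception, match="smiles"):
            read_records(path)
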