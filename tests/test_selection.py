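"""Recursive shuffle-decoy variable selection."""

import numpy as np
import pandas as pd
import pytest

from rrfsol.descriptors import DECOY_SUFFIX, DescriptorMatrix, add_shuffled_decoys
from rrfsol.selection import (
    EmptySelectionError,
    InsufficientDataError,
    OccurrenceProfile,
    SelectionParams,
    audit_frame,
    correlation_prune,
    count_occurrences,
    decoy_filter,
    select_variables,
)

FAST = SelectionParams(occurrence_threshold=40, n_trees=150, seed=0)


def _profile(counts):
    return OccurrenceProfile(counts=counts, n_trees=100)


class TestCountOccurrences:
    def test_constant_response_all_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd"))
        profile = count_occurrences(X, np.zeros(60), FAST)
        assert all(v == 0 for v in profile.counts.values())

    def test_exact_dependence_dominates(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            rng.standard_normal((200, 20)), columns=[f"x{i}" for i in range(20)]
        )
        y = X["x7"].to_numpy()
        profile = count_occurrences(X, y, FAST)
        assert max(profile.counts, key=profile.counts.get) == "x7"

    def test_insufficient_rows(self):
        X = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        with pytest.raises(InsufficientDataError, match="insufficient data"):
            count_occurrences(X, np.zeros(5), FAST)

    def test_covers_every_offered_column(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((60, 5)), columns=list("abcde"))
        profile = count_occurrences(X, X["a"].to_numpy(), FAST)
        assert set(profile.counts) == set("abcde")


class TestDecoyFilter:
    PARAMS = SelectionParams(occurrence_threshold=110)
    DECOY_MAP = {"X" + DECOY_SUFFIX: "X"}

    @pytest.mark.parametrize(
        "count,shuffled,kept",
        [
            (200, 30, True),    # clears threshold and decoy
            (150, 180, False),  # decoy outranks
            (110, 0, False),    # boundary: strictly greater than threshold
            (111, 111, True),   # ties with decoy survive (>=)
        ],
    )
    def test_rules(self, count, shuffled, kept):
        profile = _profile({"X": count, "X" + DECOY_SUFFIX: shuffled})
        retained = decoy_filter(profile, self.DECOY_MAP, self.PARAMS)
        assert ("X" in retained) is kept

    def test_decoys_always_discarded(self):
        profile = _profile({"X": 500, "X" + DECOY_SUFFIX: 400})
        retained = decoy_filter(profile, self.DECOY_MAP, self.PARAMS)
        assert "X" + DECOY_SUFFIX not in retained


class TestCorrelationPrune:
    PARAMS = SelectionParams()

    def test_exact_copy_pruned_keeping_higher_count(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        X = pd.DataFrame({"x1": x, "x2": x})
        profile = _profile({"x1": 50, "x2": 30})
        assert correlation_prune(X, ["x1", "x2"], profile, self.PARAMS) == ["x1"]

    def test_independent_columns_both_kept(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((1000, 2)), columns=["a", "b"])
        profile = _profile({"a": 50, "b": 40})
        assert abs(np.corrcoef(X["a"], X["b"])[0, 1]) < 0.51
        assert set(correlation_prune(X, ["a", "b"], profile, self.PARAMS)) == {"a", "b"}

    def test_single_survivor_unchanged(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        assert correlation_prune(X, ["a"], _profile({"a": 5}), self.PARAMS) == ["a"]

    def test_tie_breaks_lexicographically(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        X = pd.DataFrame({"b": x, "a": x})
        profile = _profile({"a": 10, "b": 10})
        assert correlation_prune(X, ["b", "a"], profile, self.PARAMS) == ["a"]


class TestSelectVariables:
    def _dataset(self, seed=0, n=300, noise_cols=30):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.standard_normal((n, 2 + noise_cols)),
            columns=["x1", "x2"] + [f"n{i}" for i in range(noise_cols)],
        )
        y = 2 * X["x1"].to_numpy() - X["x2"].to_numpy() + rng.normal(0, 0.3, n)
        return X, y

    def test_recovers_informative_no_decoys(self):
        X, y = self._dataset()
        selected, rounds = select_variables(X, y, FAST)
        assert {"x1", "x2"} <= set(selected)
        assert not any(DECOY_SUFFIX in name for name in selected)

    def test_monotone_shrinkage_and_termination(self):
        X, y = self._dataset(seed=1)
        selected, rounds = select_variables(X, y, FAST)
        assert len(rounds) <= FAST.max_rounds
        for rnd in rounds:
            assert set(rnd.selected) <= set(rnd.offered)
        for prev, cur in zip(rounds, rounds[1:]):
            assert set(cur.offered) == set(prev.selected)

    def test_no_selected_pair_above_correlation_threshold(self):
        X, y = self._dataset(seed=2)
        selected, _ = select_variables(X, y, FAST)
        if len(selected) > 1:
            corr = np.corrcoef(X[selected].to_numpy(), rowvar=False)
            off_diag = corr[~np.eye(len(selected), dtype=bool)]
            assert np.all(np.abs(off_diag) <= FAST.correlation_threshold)

    def test_fixed_point_on_reduced_dataset(self):
        # already reduced to the informative variables: one round suffices
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"x1": rng.standard_normal(200), "x2": rng.standard_normal(200)})
        y = X["x1"].to_numpy() - X["x2"].to_numpy()
        selected, rounds = select_variables(X, y, FAST)
        assert set(selected) == {"x1", "x2"}
        assert len(rounds) <= 2

    def test_impossible_threshold_raises_with_advice(self):
        X, y = self._dataset(seed=3)
        params = SelectionParams(occurrence_threshold=10**7, n_trees=50, seed=0)
        with pytest.raises(EmptySelectionError, match="threshold"):
            select_variables(X, y, params)

    def test_determinism(self):
        X, y = self._dataset(seed=4)
        a, _ = select_variables(X, y, FAST)
        b, _ = select_variables(X, y, FAST)
        assert a == b

    def test_audit_frame_structure(self):
        X, y = self._dataset(seed=5)
        _, rounds = select_variables(X, y, FAST)
        frame = audit_frame(rounds, FAST)
        assert list(frame.columns) == [
            "round", "variable", "occurrences", "shuffled_occurrences", "decision", "reason",
        ]
        kept = frame[(frame["round"] == rounds[-1].round_index) & (frame.decision == "keep")]
        assert set(kept.variable) == set(rounds[-1].selected)

    def test_rejects_matrix_with_decoys(self):
        X, y = self._dataset(seed=7, noise_cols=3)
        m = add_shuffled_decoys(DescriptorMatrix(data=X), seed=0)
        with pytest.raises(ValueError, match="decoys"):
            select_variables(m, y, FAST)
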