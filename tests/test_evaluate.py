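"""Binning performance measures: hand-checked fixtures and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from duobin.evaluate import (
    ConfusionMatrix,
    confusion_matrix,
    f1,
    precision,
    recall,
    species_discovered,
)
from duobin.io import UNCLASSIFIED


def cm(R, unclassified=0):
    R = np.asarray(R, dtype=float)
    return ConfusionMatrix(
        R=R,
        bins=list(range(R.shape[0])),
        genomes=[f"g{j}" for j in range(R.shape[1])],
        unclassified=unclassified,
    )


class TestConfusionMatrix:
    def test_hand_tally(self):
        predicted = {f"c{i}": 0 for i in range(1, 10)}  # c1..c9 -> bin0
        predicted["c10"] = 0
        predicted.update({f"c{i}": 1 for i in range(11, 21)})
        truth = {f"c{i}": "gA" for i in range(1, 10)}
        truth.update({f"c{i}": "gB" for i in range(10, 21)})
        m = confusion_matrix(predicted, truth)
        np.testing.assert_array_equal(m.R, [[9, 1], [0, 10]])
        assert m.unclassified == 0

    def test_all_unclassified(self):
        predicted = {"a": UNCLASSIFIED, "b": UNCLASSIFIED}
        truth = {"a": "g1", "b": "g2"}
        m = confusion_matrix(predicted, truth)
        assert m.R.size == 0 and m.unclassified == 2

    def test_missing_truth_raises(self):
        with pytest.raises(KeyError, match="mystery"):
            confusion_matrix({"mystery": 0}, {"other": "g"})


class TestMetrics:
    def test_worked_example(self):
        m = cm([[9, 1], [0, 10]])
        assert precision(m) == pytest.approx(95.0)
        assert recall(m) == pytest.approx(95.0)

    def test_unclassified_lowers_recall(self):
        m = cm([[9, 1], [0, 10]], unclassified=5)
        assert recall(m) == pytest.approx(76.0)
        assert precision(m) == pytest.approx(95.0)  # unchanged

    def test_diagonal_is_perfect(self):
        m = cm(np.diag([4, 6, 2]))
        assert precision(m) == 100.0
        assert recall(m) == 100.0

    def test_single_mixed_bin(self):
        assert precision(cm([[5, 5]])) == pytest.approx(50.0)

    def test_precision_undefined_when_nothing_classified(self):
        assert math.isnan(precision(cm(np.zeros((0, 0)), unclassified=3)))

    def test_f1_values(self):
        assert f1(80.0, 80.0) == pytest.approx(80.0)
        assert f1(100.0, 50.0) == pytest.approx(66.6667, abs=1e-3)
        assert f1(0.0, 0.0) == 0.0

    def test_recall_monotone_in_unclassified(self):
        R = [[7, 2], [1, 5]]
        vals = [recall(cm(R, unclassified=u)) for u in range(0, 20, 3)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    @given(
        st.integers(1, 4),
        st.integers(1, 4),
        st.integers(0, 10),
        st.integers(0, 100),
    )
    def test_harmonic_leq_arithmetic(self, M, N, unclassified, seed):
        rng = np.random.default_rng(seed)
        R = rng.integers(0, 6, size=(M, N))
        if R.sum() == 0:
            return
        m = cm(R, unclassified=unclassified)
        p, r = precision(m), recall(m)
        assert 0 <= p <= 100 and 0 <= r <= 100
        assert f1(p, r) <= (p + r) / 2 + 1e-9


class TestSpeciesDiscovery:
    def make(self, bin_counts, totals):
        """bin_counts: {bin: {genome: n}}; totals: genome -> |S|."""
        predicted, truth = {}, {}
        i = 0
        for b, per_genome in bin_counts.items():
            for g, n in per_genome.items():
                for _ in range(n):
                    predicted[f"c{i}"] = b
                    truth[f"c{i}"] = g
                    i += 1
        for g, total in totals.items():
            have = sum(1 for c, gg in truth.items() if gg == g)
            for _ in range(total - have):
                predicted[f"c{i}"] = UNCLASSIFIED
                truth[f"c{i}"] = g
                i += 1
        return predicted, truth

    def test_discovered_with_per_species_report(self):
        predicted, truth = self.make({0: {"S": 6, "X": 4}}, {"S": 10, "X": 4})
        m = confusion_matrix(predicted, truth)
        disc = species_discovered(m, predicted, truth)
        assert "S" in disc
        prec, binned = disc["S"]
        assert prec == pytest.approx(60.0)
        assert binned == pytest.approx(60.0)

    def test_exactly_half_is_not_discovered(self):
        # bin is exactly 50% S, and holds exactly 50% of S: both strict
        predicted, truth = self.make({0: {"S": 5, "X": 5}}, {"S": 10, "X": 5})
        m = confusion_matrix(predicted, truth)
        assert "S" not in species_discovered(m, predicted, truth)

    def test_genome_split_across_bins_not_discovered(self):
        predicted, truth = self.make({0: {"S": 5}, 1: {"S": 5}}, {"S": 10})
        m = confusion_matrix(predicted, truth)
        assert species_discovered(m, predicted, truth) == {}

    def test_each_genome_discovered_by_at_most_one_bin(self):
        predicted, truth = self.make(
            {0: {"A": 8, "B": 1}, 1: {"B": 7, "C": 2}, 2: {"C": 9}},
            {"A": 9, "B": 9, "C": 12},
        )
        m = confusion_matrix(predicted, truth)
        disc = species_discovered(m, predicted, truth)
        assert set(disc) == {"A", "B", "C"}
        assert len(disc) <= min(len(m.bins), len(m.genomes))

    def test_filtered_contigs_penalise_discovery(self):
        # 6 of 20 contigs binned; the other 14 were filtered out before
        # binning (present in truth, absent from the prediction)
        predicted, truth = self.make({0: {"S": 6}}, {"S": 6})
        for i in range(14):
            truth[f"extra{i}"] = "S"
        m = confusion_matrix(predicted, truth)
        assert species_discovered(m, predicted, truth) == {}
        assert "S" in species_discovered(
            m, predicted, truth, include_filtered=False
        )
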