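import math

import numpy as np
import pytest

from samplex.core import (
    Atom,
    ClassificationResult,
    ConfidenceVector,
    Label,
    PerResidueData,
    Residue,
    ResidueKey,
    Status,
    StructureEnsemble,
)
from samplex.evaluation import (
    ConfusionCounts,
    interface_residues,
    mcc,
    method_a,
    method_b,
    score_prediction,
    score_selection,
)


def data_from(values):
    return PerResidueData(values={ResidueKey("A", i + 1): float(v) for i, v in enumerate(values)})


def residue(chain, num, atoms):
    return Residue(
        key=ResidueKey(chain, num),
        name="ALA",
        atoms=[Atom(name=n, element=e, coords=c) for n, e, c in atoms],
    )


class TestMcc:
    def test_perfect_prediction(self):
        assert mcc(ConfusionCounts(tp=10, fp=0, tn=20, fn=0)) == pytest.approx(1.0)

    def test_balanced_random_is_zero(self):
        assert mcc(ConfusionCounts(tp=10, fp=10, tn=10, fn=10)) == 0.0

    def test_integer_oracle(self):
        got = mcc(ConfusionCounts(tp=5, tn=80, fp=2, fn=3))
        assert got == pytest.approx(394 / math.sqrt(7 * 8 * 83 * 82), abs=1e-12)

    def test_degenerate_denominator_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert mcc(ConfusionCounts(tp=0, fp=0, tn=5, fn=0)) == 0.0

    def test_matches_pearson_correlation_on_random_tables(self, rng):
        # MCC is the Pearson correlation of the two binary indicators
        for _ in range(1000):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 30, size=4))
            pred = np.r_[np.ones(tp), np.ones(fp), np.zeros(tn), np.zeros(fn)]
            true = np.r_[np.ones(tp), np.zeros(fp), np.zeros(tn), np.ones(fn)]
            expected = np.corrcoef(pred, true)[0, 1]
            assert mcc(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(expected, abs=1e-9)


class TestInterface:
    def two_chain_structure(self, gap):
        a = residue("A", 1, [("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.5, 0.0, 0.0))])
        b = residue("B", 1, [("CA", "C", (0.0, gap, 0.0))])
        return StructureEnsemble([[a, b]])

    def test_distant_chains_have_empty_interface(self):
        ia, ib = interface_residues(self.two_chain_structure(100.0), {"A"}, {"B"})
        assert ia == set() and ib == set()

    @pytest.mark.parametrize("gap, expected", [(4.9, True), (5.1, False)])
    def test_five_angstrom_backbone_criterion(self, gap, expected):
        ia, _ = interface_residues(self.two_chain_structure(gap), {"A"}, {"B"})
        assert (ResidueKey("A", 1) in ia) is expected

    def test_contact_in_any_model_counts(self):
        near = [
            residue("A", 1, [("N", "N", (0.0, 0.0, 0.0))]),
            residue("B", 1, [("CA", "C", (0.0, 4.0, 0.0))]),
        ]
        far = [
            residue("A", 1, [("N", "N", (0.0, 0.0, 0.0))]),
            residue("B", 1, [("CA", "C", (0.0, 50.0, 0.0))]),
        ]
        ens = StructureEnsemble([far, near])
        ia, ib = interface_residues(ens, {"A"}, {"B"})
        assert ResidueKey("A", 1) in ia and ResidueKey("B", 1) in ib

    def test_hydrogens_do_not_create_contacts(self):
        a = residue("A", 1, [("N", "N", (0.0, 0.0, 0.0))])
        b = residue("B", 1, [("H", "H", (0.0, 3.0, 0.0)), ("CA", "C", (0.0, 50.0, 0.0))])
        ia, _ = interface_residues(StructureEnsemble([[a, b]]), {"A"}, {"B"})
        assert ia == set()

    def test_symmetric_under_label_swap(self):
        ens = self.two_chain_structure(4.0)
        ia, ib = interface_residues(ens, {"A"}, {"B"})
        ib2, ia2 = interface_residues(ens, {"B"}, {"A"})
        assert (ia, ib) == (ia2, ib2)

    def test_unknown_chain_raises(self):
        with pytest.raises(KeyError):
            interface_residues(self.two_chain_structure(4.0), {"A"}, {"C"})


class TestThresholdBaselines:
    def test_method_a_single_outlier(self):
        data = data_from([0] * 9 + [10])  # mu = 1, sigma = 3 -> cut at 4
        assert method_a(data, n_sigma=1) == {ResidueKey("A", 10)}

    def test_method_a_uniform_selects_nothing(self):
        assert method_a(data_from([2] * 5), n_sigma=1) == set()

    def test_method_a_two_sigma_is_subset_of_one_sigma(self, rng):
        for _ in range(20):
            data = data_from(np.abs(rng.normal(0.3, 0.3, size=30)))
            assert method_a(data, 2) <= method_a(data, 1)

    def test_method_b_iterated_rejection_oracle(self):
        # round 1: mu = 1.5, sigma = 3.2016, cut = 4.70 -> rejects 5 and 10;
        # round 2: all zeros -> no rejection
        data = data_from([0] * 8 + [5, 10])
        assert method_b(data, n_sigma=1) == {ResidueKey("A", 9), ResidueKey("A", 10)}

    def test_method_b_contains_method_a(self, rng):
        for _ in range(30):
            data = data_from(np.abs(rng.normal(0.3, 0.3, size=25)))
            for n in (1, 2):
                assert method_b(data, n) >= method_a(data, n)


class TestScoring:
    def result_with(self, labels):
        keys = [ResidueKey("A", i + 1) for i in range(len(labels))]
        conf = ConfidenceVector(
            rho={k: 0.0 for k, l in zip(keys, labels) if l != Label.NO_DECISION},
            status={
                k: (Status.EXCLUDED if l == Label.NO_DECISION else Status.MEASURED)
                for k, l in zip(keys, labels)
            },
        )
        return ClassificationResult(
            labels=dict(zip(keys, labels)), rho_start=conf, rho_final=conf, sigma_r=1.0
        )

    def test_exact_prediction_has_no_errors(self):
        res = self.result_with([Label.PERTURBED, Label.UNPERTURBED, Label.UNPERTURBED])
        counts = score_prediction(res, {ResidueKey("A", 1)})
        assert (counts.fp, counts.fn) == (0, 0)

    def test_ambiguous_policies(self):
        res = self.result_with([Label.PERTURBED, Label.AMBIGUOUS, Label.UNPERTURBED])
        truth = {ResidueKey("A", 1)}
        assert score_prediction(res, truth, "negative").total == 3
        assert score_prediction(res, truth, "drop").total == 2
        assert score_prediction(res, truth, "positive").fp == 1

    def test_no_decision_dropped(self):
        res = self.result_with([Label.PERTURBED, Label.NO_DECISION])
        assert score_prediction(res, {ResidueKey("A", 1)}).total == 1

    def test_empty_truth_raises(self):
        res = self.result_with([Label.PERTURBED])
        with pytest.raises(ValueError):
            score_prediction(res, set())

    def test_selection_scoring_counts_unselected_as_negative(self):
        universe = [ResidueKey("A", i + 1) for i in range(4)]
        counts = score_selection({universe[0]}, universe, {universe[0], universe[1]})
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (1, 1, 2, 0)
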