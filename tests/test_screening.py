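"""Modulator screening: candidate selection, classification, significance."""

import numpy as np
import pytest

from logicnem.errors import ValidationError
from logicnem.graph import GATES, Gate, PerturbationExperiment, SignalingGraph
from logicnem.inference import ModelHypothesis
from logicnem.likelihood import AttachmentMap, EffectDataset, NoiseRates
from logicnem.screening import (
    CATEGORIES,
    ScreenResult,
    candidate_modulators,
    classify_result,
    common_effect_set,
    gate_distribution,
    pair_epistasis_label,
    screen_pair,
    significance_filter,
)
from logicnem.simulation import simulate_data

from conftest import triple_with_gate


def planted_screen_data(gate, seed, m=100, decoy_attached=True):
    """Pair X,Y gating child Z, plus decoy W; singles + X:Y double measured."""
    rng = np.random.default_rng(seed)
    genes = ("X", "Y", "Z", "W")
    truth = SignalingGraph(
        genes, [("X", "Z"), ("Y", "Z")], {"Z": Gate(gate, "X", "Y")}
    )
    if decoy_attached:
        assignment = rng.integers(0, 4, size=m)
    else:
        assignment = rng.integers(0, 3, size=m)  # nothing attached to W
    theta = AttachmentMap(genes, assignment, tuple(f"E{i}" for i in range(m)))
    exps = [PerturbationExperiment([g]) for g in genes]
    exps.append(PerturbationExperiment(["X", "Y"]))
    data = simulate_data(truth, theta, exps, NoiseRates(0.1, 0.1), 1, rng)
    return truth, theta, data


class TestCandidateModulators:
    def test_all_zero_single_excluded(self):
        values = np.zeros((3, 4), dtype=np.uint8)
        values[:, 0] = 1  # only X shows effects
        data = EffectDataset(["E1", "E2", "E3"], ["X", "Y", "Z", "X:Y"], values)
        assert candidate_modulators(data, ("X", "Y")) == []

    def test_counts_on_generated_fixture(self):
        rng = np.random.default_rng(3)
        labels = ["X", "Y", "X:Y"] + [f"C{i}" for i in range(10)]
        values = rng.integers(0, 2, size=(8, len(labels)))
        values[:, 5:8] = 0  # three candidates without any effect
        values[:, :3] = 1
        data = EffectDataset([f"E{i}" for i in range(8)], labels, values)
        got = candidate_modulators(data, ("X", "Y"))
        expected = [
            f"C{i}" for i in range(10) if values[:, 3 + i].any()
        ]
        assert got == expected
        assert len(got) == 7

    def test_missing_pair_column_is_an_error(self):
        data = EffectDataset(["E1"], ["X", "Z"], np.ones((1, 2)))
        with pytest.raises(ValidationError, match="Y"):
            candidate_modulators(data, ("X", "Y"))


class TestCommonEffectSet:
    def test_union_matches_set_arithmetic(self):
        labels = ["X", "Y", "Z", "W", "X:Y"]
        values = np.zeros((6, 5), dtype=np.uint8)
        values[0, 0] = 1  # X only
        values[1, 1] = 1  # Y only
        values[2, 2] = 1  # Z only
        values[3, 3] = 1  # W only: not in the union for modulator Z
        values[4, 4] = 1  # double only: included
        data = EffectDataset([f"E{i}" for i in range(6)], labels, values)
        mask = common_effect_set(data, ("X", "Y"), "Z")
        assert mask.tolist() == [True, True, True, False, True, False]

    def test_missing_double_names_the_pair(self):
        data = EffectDataset(["E1"], ["X", "Y", "Z"], np.ones((1, 3)))
        with pytest.raises(ValidationError, match="X:Y"):
            common_effect_set(data, ("X", "Y"), "Z")


class TestClassification:
    def _hyp(self, graph):
        return ModelHypothesis(graph, 0.0, 0)

    def test_gated_triple_maps_to_its_gate(self):
        top = [self._hyp(triple_with_gate("AND"))]
        category, labels, ambiguous = classify_result(top, ("X", "Y"), "Z", True)
        assert category == "AND" and labels == ("AND",) and not ambiguous

    def test_masking_orientation_follows_the_pair_order(self):
        # gate stored with parents (Y, X): NOT-A there means Y masks X
        graph = SignalingGraph(
            ("X", "Y", "Z"), [("X", "Z"), ("Y", "Z")], {"Z": Gate("NOT-A", "Y", "X")}
        )
        category, _, _ = classify_result([self._hyp(graph)], ("X", "Y"), "Z", True)
        assert category == "NOT-B"  # reported relative to (X, Y)

    def test_unconnected_with_shared_reporters_is_no_epistasis(self):
        top = [self._hyp(SignalingGraph(("X", "Y", "Z")))]
        category, _, _ = classify_result(top, ("X", "Y"), "Z", True)
        assert category == "no-epistasis"

    def test_no_shared_reporters_is_no_information(self):
        category, _, _ = classify_result([], ("X", "Y"), "Z", False)
        assert category == "no-information"

    def test_mixed_top_class_reports_all_labels(self):
        top = [self._hyp(triple_with_gate("NOT-B")), self._hyp(triple_with_gate("XOR"))]
        category, labels, ambiguous = classify_result(top, ("X", "Y"), "Z", True)
        assert ambiguous and set(labels) == {"XOR", "NOT-B"}
        assert category == "XOR"  # canonical gate order


class TestScreenPair:
    @pytest.mark.parametrize("gate", GATES)
    def test_planted_gate_recovered_and_ranked_first(self, gate):
        _, _, data = planted_screen_data(gate, seed=11)
        results = screen_pair(data, ("X", "Y"), ["Z", "W"], NoiseRates(0.1, 0.1))
        assert results[0].modulator == "Z"
        assert results[0].category == gate

    def test_candidate_without_shared_reporters_is_no_information(self):
        # W's effect reporters are disjoint from the pair's
        labels = ["X", "Y", "W", "X:Y"]
        values = np.zeros((3, 4), dtype=np.uint8)
        values[0, 0] = 1  # E1 reacts to X
        values[1, 3] = 1  # E2 reacts to the double
        values[2, 2] = 1  # E3 reacts to W only
        data = EffectDataset(["E1", "E2", "E3"], labels, values)
        results = screen_pair(data, ("X", "Y"), ["W"], NoiseRates(0.1, 0.1))
        assert results[0].category == "no-information"
        assert results[0].score is None
        assert results[0].n_common_reporters == 3  # E1, E2 and E3's W effect

    def test_separability_across_candidates(self):
        _, _, data = planted_screen_data("XOR", seed=7)
        both = screen_pair(data, ("X", "Y"), ["Z", "W"], NoiseRates(0.1, 0.1))
        alone = screen_pair(data, ("X", "Y"), ["Z"], NoiseRates(0.1, 0.1))
        z_both = next(r for r in both if r.modulator == "Z")
        z_alone = alone[0]
        assert z_both.score == z_alone.score
        assert z_both.category == z_alone.category


class TestSignificanceFilter:
    def test_infinite_margin_keeps_nothing(self):
        _, _, data = planted_screen_data("AND", seed=1)
        results = screen_pair(data, ("X", "Y"), ["Z", "W"], NoiseRates(0.1, 0.1))
        assert significance_filter(results, margin=float("inf")) == []

    def test_planted_modulator_retained_at_zero_margin(self):
        _, _, data = planted_screen_data("AND", seed=2)
        results = screen_pair(data, ("X", "Y"), ["Z", "W"], NoiseRates(0.1, 0.1))
        kept = significance_filter(results, margin=0.0)
        assert "Z" in {r.modulator for r in kept}

    def test_permutation_mode_keeps_planted_drops_null(self):
        _, _, data = planted_screen_data("AND", seed=8, m=60)
        rates = NoiseRates(0.1, 0.1)
        results = screen_pair(data, ("X", "Y"), ["Z"], rates)
        kept = significance_filter(
            results, margin=0.0, permutations=19, seed=0, data=data, rates=rates
        )
        assert [r.modulator for r in kept] == ["Z"]

    def test_negative_margin_rejected(self):
        with pytest.raises(ValidationError):
            significance_filter([], margin=-1.0)

    def test_permutation_pvalues_not_inflated_under_the_null(self):
        """When the modulator is unrelated to the pair, p-values stay away
        from zero (the permutation null is conservative: reassigning the
        modulator column to random reporters can only create coherence
        with the pair, never remove real coherence that is not there)."""
        from logicnem.screening import permutation_pvalue

        rates = NoiseRates(0.1, 0.1)
        genes = ("X", "Y", "Z", "W")
        pvals = []
        for trial in range(12):
            rng = np.random.default_rng(60_000 + trial)
            # pair interacts via a gate on W; Z is disconnected noise
            truth = SignalingGraph(
                genes, [("X", "W"), ("Y", "W")], {"W": Gate("AND", "X", "Y")}
            )
            theta = AttachmentMap(genes, rng.integers(0, 4, size=60))
            exps = [PerturbationExperiment([g]) for g in genes]
            exps.append(PerturbationExperiment(["X", "Y"]))
            data = simulate_data(truth, theta, exps, rates, 1, rng)
            pvals.append(
                permutation_pvalue(data, ("X", "Y"), "Z", rates, permutations=19, rng=trial)
            )
        pvals = np.array(pvals)
        assert (pvals <= 0.05).mean() == 0.0
        assert pvals.mean() > 0.5


class TestSummaries:
    def _result(self, pair, modulator, category):
        return ScreenResult(
            pair=pair,
            modulator=modulator,
            category=category,
            labels=(category,) if category in GATES else (),
            ambiguous=False,
            score=-1.0 if category != "no-information" else None,
            gate_score=None,
            no_epistasis_score=None,
            n_common_reporters=5,
        )

    def test_empty_histogram(self):
        table = gate_distribution([])
        assert table.empty

    def test_counts_and_conservation(self):
        results = [self._result(("X", "Y"), f"M{i}", "AND") for i in range(5)]
        results += [self._result(("X", "Y"), f"N{i}", "NOT-A") for i in range(3)]
        results += [self._result(("A", "B"), "Q", "no-information")]
        table = gate_distribution(results)
        assert table.loc["X:Y", "AND"] == 5
        assert table.loc["X:Y", "NOT-A"] == 3
        assert table.sum(axis=1).tolist() == [1, 8]

    def test_pair_epistasis_labels(self):
        mixed = [self._result(("X", "Y"), "M", "AND"), self._result(("X", "Y"), "N", "NOT-B")]
        assert pair_epistasis_label(mixed) == "mixed"
        assert pair_epistasis_label(mixed[:1]) == "AND"
        assert pair_epistasis_label([]) == "none"
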