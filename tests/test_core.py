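"""Hypnodensity construction, scorer weighting, consensus and stage assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypnodense.core import (
    FIVE_STAGE,
    FOUR_STAGE,
    Hypnodensity,
    Hypnogram,
    ScorerPanel,
    ScorerWeights,
    StageVocabulary,
    assign_stage_argmax,
    assign_stage_hierarchical,
    build_hypnodensity,
    collapse_to_four_stage,
    scorer_weights_by_kappa,
    weighted_consensus,
)
from hypnodense.errors import (
    AlignmentError,
    DegenerateScorerError,
    VocabularyError,
)

from conftest import random_panel


class TestTypes:
    def test_vocabulary_rejects_duplicates_and_missing_wake(self):
        with pytest.raises(VocabularyError):
            StageVocabulary("bad", ("W", "W", "R"))
        with pytest.raises(VocabularyError):
            StageVocabulary("bad", ("N1", "N2"))

    def test_stage_codes_canonicalized_case_insensitively(self):
        h = Hypnogram(("w", "n2", "r"))
        assert h.stages == ("W", "N2", "R")

    def test_unknown_stage_code_rejected(self):
        with pytest.raises(VocabularyError):
            Hypnogram(("W", "N9"))

    def test_panel_rejects_misaligned_scorers(self):
        a = Hypnogram(("W", "N1"))
        b = Hypnogram(("W",))
        with pytest.raises(AlignmentError):
            ScorerPanel(("a", "b"), (a, b))

    def test_hypnodensity_rejects_bad_row_sums(self):
        with pytest.raises(VocabularyError):
            Hypnodensity(np.array([[0.5, 0.2, 0.1, 0.1, 0.05]]))

    def test_weights_must_be_normalized_and_nonnegative(self):
        with pytest.raises(VocabularyError):
            ScorerWeights(np.array([0.7, 0.7]))
        with pytest.raises(VocabularyError):
            ScorerWeights(np.array([1.5, -0.5]))


class TestBuildHypnodensity:
    def test_worked_twelve_scorer_epoch(self, fig1_panel):
        """7 N2 / 4 N1 / 1 W votes give probabilities 0.58 / 0.33 / 0.08."""
        h = build_hypnodensity(fig1_panel)
        row = dict(zip(FIVE_STAGE.stages, np.round(h.probs[0], 2)))
        assert row == {"W": 0.08, "N1": 0.33, "N2": 0.58, "N3": 0.0, "R": 0.0}

    def test_single_scorer_gives_one_hot_rows(self):
        panel = ScorerPanel(("solo",), (Hypnogram(("W", "N2", "R")),))
        h = build_hypnodensity(panel)
        assert np.array_equal(h.p_max, np.ones(3))
        assert h.probs[1, FIVE_STAGE.index("N2")] == 1.0

    def test_unanimous_epoch(self):
        panel = ScorerPanel(
            ("a", "b", "c"), tuple(Hypnogram(("N3",)) for _ in range(3))
        )
        h = build_hypnodensity(panel)
        assert np.array_equal(h.probs[0], [0, 0, 0, 1, 0])

    def test_weight_count_mismatch_rejected(self, fig1_panel):
        with pytest.raises(AlignmentError):
            build_hypnodensity(fig1_panel, ScorerWeights.uniform(5))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(n_scorers=st.integers(2, 8), seed=st.integers(0, 10_000))
    def test_uniform_entries_are_vote_fractions(self, n_scorers, seed):
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, n_scorers=n_scorers, n_epochs=20)
        h = build_hypnodensity(panel)
        counts = h.probs * n_scorers
        assert np.allclose(counts, np.round(counts), atol=1e-9)
        assert np.allclose(h.probs.sum(axis=1), 1.0, atol=1e-9)


class TestKappaWeights:
    def test_identical_scorers_get_equal_weights(self):
        h = Hypnogram(("W", "N1", "N2", "R", "W", "N3"))
        panel = ScorerPanel(("a", "b", "c"), (h, h, h))
        w = scorer_weights_by_kappa(panel)
        assert np.allclose(w.weights, 1 / 3)

    def test_random_scorer_downweighted(self, rng):
        truth = Hypnogram.from_indices(rng.integers(0, 5, 500))
        noise = Hypnogram.from_indices(rng.integers(0, 5, 500))
        panel = ScorerPanel(("s1", "s2", "s3"), (truth, truth, noise))
        w = scorer_weights_by_kappa(panel)
        assert w.weights[0] == pytest.approx(w.weights[1])
        assert w.weights[0] > w.weights[2]

    def test_two_scorers_always_split_evenly(self, rng):
        a = Hypnogram.from_indices(rng.integers(0, 5, 100))
        b = Hypnogram.from_indices(rng.integers(0, 5, 100))
        w = scorer_weights_by_kappa(ScorerPanel(("a", "b"), (a, b)))
        assert np.allclose(w.weights, 0.5)

    def test_degenerate_constant_scorers_signaled(self):
        a = Hypnogram(("W", "W", "W"))
        panel = ScorerPanel(("a", "b"), (a, a))
        with pytest.raises(DegenerateScorerError):
            scorer_weights_by_kappa(panel)


class TestConsensus:
    def test_worked_majority_epoch_is_n2(self, fig1_panel):
        assert weighted_consensus(fig1_panel).stages == ("N2",)

    def test_unanimity(self):
        panel = ScorerPanel(("a", "b"), (Hypnogram(("R",)), Hypnogram(("R",))))
        assert weighted_consensus(panel).stages == ("R",)

    def test_weighted_vote_beats_headcount(self):
        panel = ScorerPanel(
            ("a", "b", "c", "d"),
            tuple(Hypnogram((s,)) for s in ("W", "W", "N1", "N1")),
        )
        w = ScorerWeights(np.array([0.3, 0.3, 0.2, 0.2]))
        assert weighted_consensus(panel, w).stages == ("W",)

    def test_tie_resolved_by_heaviest_scorer_then_sleep(self):
        panel = ScorerPanel(
            ("a", "b", "c"), tuple(Hypnogram((s,)) for s in ("W", "N2", "N2"))
        )
        w = ScorerWeights(np.array([0.5, 0.25, 0.25]))
        # summed weights tie at 0.5; scorer 'a' (weight .5) voted W -> W wins
        assert weighted_consensus(panel, w).stages == ("W",)
        # uniform weights: headcount majority
        assert weighted_consensus(panel).stages == ("N2",)
        # full tie with equal per-scorer weights: sleep preferred over W
        panel2 = ScorerPanel(
            ("a", "b"), (Hypnogram(("W",)), Hypnogram(("N1",)))
        )
        assert weighted_consensus(panel2).stages == ("N1",)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_uniform_consensus_matches_modal_stage(self, seed):
        """With uniform weights, consensus equals the brute-force mode when unique."""
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, n_scorers=5, n_epochs=30)
        cons = weighted_consensus(panel)
        labels = panel.to_index_matrix()
        for e in range(panel.n_epochs):
            counts = np.bincount(labels[:, e], minlength=5)
            if (counts == counts.max()).sum() == 1:
                assert cons.stages[e] == FIVE_STAGE.stages[int(np.argmax(counts))]


class TestStageAssignment:
    def test_wake_dominant_epoch_assigned_wake(self):
        h = Hypnodensity(np.array([[0.6, 0.1, 0.1, 0.1, 0.1]]))
        assert assign_stage_hierarchical(h).stages == ("W",)

    def test_hierarchical_diverges_from_argmax_on_split_sleep(self):
        """p_W = 0.4 is the single largest stage, yet sleep wins 0.6 to 0.4."""
        h = Hypnodensity(np.array([[0.4, 0.25, 0.2, 0.05, 0.1]]))
        assert assign_stage_hierarchical(h).stages == ("N1",)
        assert assign_stage_argmax(h).stages == ("W",)

    def test_rem_beats_summed_nrem(self):
        h = Hypnodensity(np.array([[0.2, 0.1, 0.15, 0.1, 0.45]]))
        assert assign_stage_hierarchical(h).stages == ("R",)

    def test_cascade_uses_strict_inequalities(self):
        # p_W exactly 0.5 falls through to sleep
        h = Hypnodensity(np.array([[0.5, 0.0, 0.5, 0.0, 0.0]]))
        assert assign_stage_hierarchical(h).stages == ("N2",)

    def test_argmax_tie_prefers_earlier_vocabulary_stage(self):
        h = Hypnodensity(np.array([[0.0, 0.5, 0.5, 0.0, 0.0]]))
        assert assign_stage_argmax(h).stages == ("N1",)

    def test_four_stage_input_rejected_by_hierarchical(self):
        h = Hypnodensity(np.array([[0.25, 0.25, 0.25, 0.25]]), FOUR_STAGE)
        with pytest.raises(VocabularyError):
            assign_stage_hierarchical(h)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_assignments_agree_on_one_hot_rows(self, seed):
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, 5, 20)
        probs = np.eye(5)[idx]
        h = Hypnodensity(probs)
        assert assign_stage_hierarchical(h).stages == assign_stage_argmax(h).stages


class TestCollapse:
    def test_probability_sum_rule(self):
        h = Hypnodensity(np.array([[0.1, 0.2, 0.3, 0.2, 0.2]]))
        out = collapse_to_four_stage(h)
        assert out.vocabulary == FOUR_STAGE
        assert np.allclose(out.probs[0], [0.1, 0.5, 0.2, 0.2])

    def test_hypnogram_relabeling(self):
        h = Hypnogram(("W", "N1", "N2", "N3", "R"))
        assert collapse_to_four_stage(h).stages == ("W", "LS", "LS", "DS", "R")

    def test_row_sums_and_sleep_probability_preserved(self, rng):
        probs = rng.dirichlet(np.ones(5), size=40)
        h = Hypnodensity(probs)
        out = collapse_to_four_stage(h)
        assert np.allclose(out.probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.array_equal(out.probs[:, 0], h.probs[:, 0])  # p_W exact

    def test_four_stage_input_rejected(self):
        h = Hypnodensity(np.array([[0.25, 0.25, 0.25, 0.25]]), FOUR_STAGE)
        with pytest.raises(VocabularyError):
            collapse_to_four_stage(h)
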