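"""Core types and operations for hypnodensity analysis.

A *hypnogram* is one sleep-stage label per 30-second epoch.  When several
scorers stage the same recording independently, the per-epoch relative vote
frequencies form a *hypnodensity*: an epochs x stages matrix of
probabilities whose rows sum to 1.  This module defines the stage
vocabularies, the hypnogram / panel / hypnodensity containers, and the
operations that connect them: building a hypnodensity from a scorer panel
(optionally with kappa-derived scorer weights), majority-vote consensus,
and the two stage-assignment rules (plain argmax and the hierarchical
cascade that prefers sleep over wake when the combined sleep probability
dominates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import AlignmentError, DegenerateScorerError, VocabularyError

__all__ = [
    "StageVocabulary",
    "FIVE_STAGE",
    "FOUR_STAGE",
    "Hypnogram",
    "ScorerPanel",
    "ScorerWeights",
    "Hypnodensity",
    "build_hypnodensity",
    "scorer_weights_by_kappa",
    "weighted_consensus",
    "assign_stage_hierarchical",
    "assign_stage_argmax",
    "collapse_to_four_stage",
]

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class StageVocabulary:
    """An ordered set of stage codes.

    The order is fixed and meaningful: it defines hypnodensity matrix
    columns, plot band order, and the deterministic tie-break for argmax
    assignment.
    """

    name: str
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.stages)) != len(self.stages):
            raise VocabularyError(f"duplicate stage codes in {self.stages}")
        if "W" not in self.stages:
            raise VocabularyError("vocabulary must contain the wake stage 'W'")

    def __len__(self) -> int:
        return len(self.stages)

    def __contains__(self, code: str) -> bool:
        return code in self.stages

    def index(self, code: str) -> int:
        try:
            return self.stages.index(code)
        except ValueError:
            raise VocabularyError(
                f"unknown stage code {code!r} for vocabulary {self.name!r}"
            ) from None

    def canonicalize(self, code: str) -> str:
        """Case-insensitive lookup returning the canonical code."""
        c = str(code).strip().upper()
        if c not in self.stages:
            raise VocabularyError(
                f"unknown stage code {code!r} for vocabulary {self.name!r}"
            )
        return c

    @property
    def sleep_stages(self) -> tuple[str, ...]:
        return tuple(s for s in self.stages if s != "W")


#: AASM five-stage vocabulary: wake, three NREM stages (light to deep), REM.
FIVE_STAGE = StageVocabulary("aasm5", ("W", "N1", "N2", "N3", "R"))

#: Four-stage vocabulary used by cardiorespiratory (HSAT) staging:
#: N1 and N2 merge into light sleep (LS), N3 becomes deep sleep (DS).
FOUR_STAGE = StageVocabulary("cardio4", ("W", "LS", "DS", "R"))


@dataclass(frozen=True)
class Hypnogram:
    """One stage label per epoch."""

    stages: tuple[str, ...]
    epoch_seconds: float = 30.0
    vocabulary: StageVocabulary = FIVE_STAGE

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise VocabularyError("hypnogram must contain at least one epoch")
        if self.epoch_seconds <= 0:
            raise VocabularyError("epoch_seconds must be positive")
        canon = tuple(self.vocabulary.canonicalize(s) for s in self.stages)
        object.__setattr__(self, "stages", canon)

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def epoch_minutes(self) -> float:
        return self.epoch_seconds / 60.0

    def as_indices(self) -> np.ndarray:
        """Stage labels as integer indices into the vocabulary."""
        lut = {s: i for i, s in enumerate(self.vocabulary.stages)}
        return np.fromiter((lut[s] for s in self.stages), dtype=np.intp,
                           count=self.n_epochs)

    @classmethod
    def from_indices(
        cls,
        idx: Sequence[int],
        vocabulary: StageVocabulary = FIVE_STAGE,
        epoch_seconds: float = 30.0,
    ) -> "Hypnogram":
        stages = tuple(vocabulary.stages[int(i)] for i in idx)
        return cls(stages, epoch_seconds, vocabulary)


@dataclass(frozen=True)
class ScorerPanel:
    """n_scorers hypnograms of the same recording, aligned epoch-for-epoch."""

    scorer_ids: tuple[str, ...]
    hypnograms: tuple[Hypnogram, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scorer_ids", tuple(str(s) for s in self.scorer_ids))
        object.__setattr__(self, "hypnograms", tuple(self.hypnograms))
        if len(self.hypnograms) < 1:
            raise AlignmentError("panel must contain at least one scorer")
        if len(self.scorer_ids) != len(self.hypnograms):
            raise AlignmentError("scorer_ids and hypnograms differ in length")
        if len(set(self.scorer_ids)) != len(self.scorer_ids):
            raise AlignmentError("scorer ids must be unique")
        ref = self.hypnograms[0]
        for sid, h in zip(self.scorer_ids, self.hypnograms):
            if h.n_epochs != ref.n_epochs:
                raise AlignmentError(
                    f"scorer {sid!r} has {h.n_epochs} epochs, expected {ref.n_epochs}"
                )
            if h.epoch_seconds != ref.epoch_seconds:
                raise AlignmentError(f"scorer {sid!r} has a different epoch duration")
            if h.vocabulary != ref.vocabulary:
                raise AlignmentError(f"scorer {sid!r} uses a different vocabulary")

    @property
    def n_scorers(self) -> int:
        return len(self.hypnograms)

    @property
    def n_epochs(self) -> int:
        return self.hypnograms[0].n_epochs

    @property
    def epoch_seconds(self) -> float:
        return self.hypnograms[0].epoch_seconds

    @property
    def vocabulary(self) -> StageVocabulary:
        return self.hypnograms[0].vocabulary

    def to_index_matrix(self) -> np.ndarray:
        """(n_scorers, n_epochs) integer label matrix."""
        return np.stack([h.as_indices() for h in self.hypnograms])


@dataclass(frozen=True)
class ScorerWeights:
    """Nonnegative per-scorer weights normalized to sum to 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise VocabularyError("weights must be a nonempty 1-D sequence")
        if np.any(w < 0):
            raise VocabularyError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > ROW_SUM_TOL:
            raise VocabularyError(f"weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "weights", w)

    @classmethod
    def uniform(cls, n: int) -> "ScorerWeights":
        return cls(np.full(n, 1.0 / n))

    @classmethod
    def from_raw(cls, raw: Sequence[float]) -> "ScorerWeights":
        """Floor at zero and normalize to sum 1."""
        w = np.clip(np.asarray(raw, dtype=float), 0.0, None)
        total = w.sum()
        if total <= 0:
            raise DegenerateScorerError("all raw weights are non-positive")
        return cls(w / total)

    def __len__(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class Hypnodensity:
    """Epochs x stages matrix of sleep-stage probabilities.

    Rows sum to 1 (within 1e-9).  ``p_max`` — the per-epoch maximum
    probability — quantifies how unequivocal the epoch is and underlies
    the ambiguity and continuity features.
    """

    probs: np.ndarray
    vocabulary: StageVocabulary = FIVE_STAGE
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] < 1:
            raise VocabularyError("probs must be a nonempty 2-D matrix")
        if p.shape[1] != len(self.vocabulary):
            raise VocabularyError(
                f"probs has {p.shape[1]} columns, vocabulary "
                f"{self.vocabulary.name!r} has {len(self.vocabulary)} stages"
            )
        if np.any(p < -ROW_SUM_TOL) or np.any(p > 1 + ROW_SUM_TOL):
            raise VocabularyError("probabilities must lie in [0, 1]")
        sums = p.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)
        if bad.size:
            raise VocabularyError(
                f"hypnodensity rows must sum to 1; first offending epoch "
                f"{bad[0]} sums to {sums[bad[0]]!r}"
            )
        object.__setattr__(self, "probs", p)

    @property
    def n_epochs(self) -> int:
        return self.probs.shape[0]

    @property
    def epoch_minutes(self) -> float:
        return self.epoch_seconds / 60.0

    @property
    def p_max(self) -> np.ndarray:
        """Highest stage probability per epoch."""
        return self.probs.max(axis=1)

    def stage_prob(self, code: str) -> np.ndarray:
        """Probability curve for one stage across the night."""
        return self.probs[:, self.vocabulary.index(self.vocabulary.canonicalize(code))]


# ---------------------------------------------------------------------------
# operations


def build_hypnodensity(
    panel: ScorerPanel, weights: ScorerWeights | None = None
) -> Hypnodensity:
    """Per-epoch stage probabilities as (weighted) scorer vote shares.

    With uniform weights (the default) each entry is the relative vote
    frequency, e.g. 7 of 12 scorers voting N2 gives p_N2 = 7/12.
    """
    if weights is None:
        weights = ScorerWeights.uniform(panel.n_scorers)
    if len(weights) != panel.n_scorers:
        raise AlignmentError(
            f"{len(weights)} weights for {panel.n_scorers} scorers"
        )
    labels = panel.to_index_matrix()  # (J, E)
    n_stages = len(panel.vocabulary)
    probs = np.zeros((panel.n_epochs, n_stages))
    for j in range(panel.n_scorers):
        np.add.at(probs, (np.arange(panel.n_epochs), labels[j]), weights.weights[j])
    # vote shares sum to 1 by construction; clean float dust
    probs /= probs.sum(axis=1, keepdims=True)
    return Hypnodensity(probs, panel.vocabulary, panel.epoch_seconds)


def scorer_weights_by_kappa(panel: ScorerPanel) -> ScorerWeights:
    """Weight each scorer by its mean pairwise Cohen's kappa with the others.

    Scorers that agree more with the rest of the panel receive larger
    weight; negative mean kappas are floored at zero before normalizing.
    A scorer whose labels make kappa undefined against every other scorer
    raises :class:`DegenerateScorerError`.
    """
    from .agreement import cohens_kappa  # local import: agreement depends on core
    from .errors import UndefinedStatisticError

    if panel.n_scorers < 2:
        raise AlignmentError("kappa weighting requires at least two scorers")
    n = panel.n_scorers
    kappas = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                k = cohens_kappa(panel.hypnograms[i], panel.hypnograms[j])
            except UndefinedStatisticError:
                continue
            kappas[i, j] = kappas[j, i] = k
    defined = np.isfinite(kappas)
    if not defined.any(axis=1).all():
        bad = [panel.scorer_ids[i] for i in np.flatnonzero(~defined.any(axis=1))]
        raise DegenerateScorerError(
            f"kappa undefined for scorer(s) {bad}: constant labels against all peers"
        )
    means = np.where(defined, kappas, 0.0).sum(axis=1) / defined.sum(axis=1)
    return ScorerWeights.from_raw(means)


def weighted_consensus(
    panel: ScorerPanel, weights: ScorerWeights | None = None
) -> Hypnogram:
    """Per-epoch majority vote, with votes weighted per scorer.

    Tie-break when summed weights tie (deterministic, in order):

    1. the stage chosen by the single highest-weighted scorer among the
       tied stages;
    2. a sleep stage over W;
    3. vocabulary order.
    """
    if weights is None:
        weights = ScorerWeights.uniform(panel.n_scorers)
    if len(weights) != panel.n_scorers:
        raise AlignmentError(f"{len(weights)} weights for {panel.n_scorers} scorers")
    labels = panel.to_index_matrix()
    w = weights.weights
    vocab = panel.vocabulary
    n_stages = len(vocab)
    scores = np.zeros((panel.n_epochs, n_stages))
    for j in range(panel.n_scorers):
        np.add.at(scores, (np.arange(panel.n_epochs), labels[j]), w[j])

    w_index = vocab.index("W")
    out = np.empty(panel.n_epochs, dtype=np.intp)
    tol = 1e-12
    for e in range(panel.n_epochs):
        row = scores[e]
        tied = np.flatnonzero(row >= row.max() - tol)
        if tied.size == 1:
            out[e] = tied[0]
            continue
        # 1. stage of the heaviest scorer voting for a tied stage
        voters = [
            (w[j], labels[j, e]) for j in range(panel.n_scorers)
            if labels[j, e] in tied
        ]
        top_w = max(v[0] for v in voters)
        top_stages = sorted({s for wt, s in voters if wt >= top_w - tol})
        if len(top_stages) == 1:
            out[e] = top_stages[0]
            continue
        # 2. prefer sleep over W; 3. vocabulary order
        sleep = [s for s in top_stages if s != w_index]
        out[e] = sleep[0] if sleep else top_stages[0]
    return Hypnogram.from_indices(out, vocab, panel.epoch_seconds)


def assign_stage_hierarchical(h: Hypnodensity) -> Hypnogram:
    """Hierarchical stage assignment from a five-stage hypnodensity.

    Cascade (strict inequalities): W if p_W > 0.5; else R if p_R exceeds the
    summed NREM probability; else N3 if p_N3 exceeds p_N1 + p_N2; else N2 if
    p_N2 > p_N1; else N1.  Unlike argmax this scores an epoch as sleep
    whenever the combined sleep probability dominates wake, even when W is
    the single most probable stage.
    """
    if h.vocabulary != FIVE_STAGE:
        raise VocabularyError(
            "hierarchical assignment is defined for the five-stage vocabulary"
        )
    pW, pN1, pN2, pN3, pR = (h.probs[:, i] for i in range(5))
    idx = np.empty(h.n_epochs, dtype=np.intp)
    for e in range(h.n_epochs):
        if pW[e] > 0.5:
            idx[e] = 0
        elif pR[e] > pN1[e] + pN2[e] + pN3[e]:
            idx[e] = 4
        elif pN3[e] > pN1[e] + pN2[e]:
            idx[e] = 3
        elif pN2[e] > pN1[e]:
            idx[e] = 2
        else:
            idx[e] = 1
    return Hypnogram.from_indices(idx, FIVE_STAGE, h.epoch_seconds)


def assign_stage_argmax(h: Hypnodensity) -> Hypnogram:
    """Per-epoch argmax assignment; ties resolve to the earlier vocabulary stage."""
    idx = h.probs.argmax(axis=1)
    return Hypnogram.from_indices(idx, h.vocabulary, h.epoch_seconds)


def collapse_to_four_stage(x: Hypnodensity | Hypnogram):
    """Collapse five-stage data to the four-stage cardiorespiratory vocabulary.

    N1 and N2 probabilities sum into a single light-sleep (LS) probability,
    N3 maps to deep sleep (DS); W and R are unchanged.  Row sums (and hence
    total sleep probability 1 - p_W) are preserved exactly.
    """
    if x.vocabulary != FIVE_STAGE:
        raise VocabularyError("collapse requires five-stage input")
    if isinstance(x, Hypnodensity):
        p = x.probs
        out = np.column_stack([p[:, 0], p[:, 1] + p[:, 2], p[:, 3], p[:, 4]])
        return Hypnodensity(out, FOUR_STAGE, x.epoch_seconds)
    mapping = {"W": "W", "N1": "LS", "N2": "LS", "N3": "DS", "R": "R"}
    return Hypnogram(tuple(mapping[s] for s in x.stages), x.epoch_seconds, FOUR_STAGE)
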