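"""Seeded generators for every input the pipeline consumes.

The generators make the whole analysis chain testable without recordings:

* a latent ("true") hypnogram from a first-order Markov chain over the
  five stages;
* a multi-scorer panel, each scorer labelling every epoch by sampling its
  own confusion row for the true stage (errors independent across scorers
  and epochs given the truth) — panel reliability, and hence the decay of
  complete agreement with the number of scorers, is controlled by the
  confusion templates;
* a hypnodensity as a Dirichlet perturbation around the one-hot truth,
  where the concentration parameter controls ambiguity;
* an oximetry trace with event-coupled trapezoidal desaturations whose
  analytic areas are returned alongside, so hypoxic-burden estimates can
  be checked against ground truth.

All generators are pure functions of (parameters, seed).  Default
transition matrices and confusion templates live in ``presets.yaml``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import yaml

from .core import FIVE_STAGE, Hypnogram, ScorerPanel, StageVocabulary
from .errors import HypnodensityError
from .sdb import OximetryTrace, RespiratoryEvent

__all__ = [
    "ScorerModel",
    "SdbScenario",
    "SdbSimulation",
    "load_presets",
    "transition_matrix_preset",
    "confusion_template",
    "stationary_distribution",
    "simulate_true_hypnogram",
    "simulate_scorer_panel",
    "simulate_hypnodensity",
    "simulate_oximetry",
]


@lru_cache(maxsize=1)
def load_presets() -> dict:
    """Parse the shipped presets file (transition matrices, confusion templates)."""
    text = importlib.resources.files("hypnodense").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def _row_stochastic(m, name: str) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise HypnodensityError(f"{name} must be a square matrix")
    if np.any(a < 0) or np.any(np.abs(a.sum(axis=1) - 1.0) > 1e-9):
        raise HypnodensityError(f"{name} rows must be nonnegative and sum to 1")
    return a


def transition_matrix_preset(name: str = "adult_sleep") -> np.ndarray:
    presets = load_presets()["transition_matrices"]
    if name not in presets:
        raise HypnodensityError(f"unknown transition-matrix preset {name!r}")
    return _row_stochastic(presets[name]["matrix"], name)


def confusion_template(name: str) -> np.ndarray:
    presets = load_presets()["confusion_templates"]
    if name not in presets:
        raise HypnodensityError(f"unknown confusion template {name!r}")
    return _row_stochastic(presets[name]["matrix"], name)


@dataclass(frozen=True)
class ScorerModel:
    """A scorer as a stage-confusion matrix P(label | true stage).

    ``from_bias`` interpolates between the shipped high-precision and
    high-sensitivity templates: bias 0 is the conservative scorer that
    under-calls N1/N3, bias 1 the liberal one that over-calls them —
    mimicking the documented precision-to-sensitivity spectrum of human
    scorers.
    """

    confusion: np.ndarray
    sensitivity_bias: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "confusion", _row_stochastic(self.confusion, "confusion")
        )

    @classmethod
    def from_bias(cls, bias: float) -> "ScorerModel":
        if not 0.0 <= bias <= 1.0:
            raise HypnodensityError("sensitivity_bias must lie in [0, 1]")
        prec = confusion_template("precision")
        sens = confusion_template("sensitivity")
        return cls((1.0 - bias) * prec + bias * sens, bias)

    @classmethod
    def from_template(cls, name: str) -> "ScorerModel":
        return cls(confusion_template(name))

    @classmethod
    def uniform(cls, n_stages: int = 5) -> "ScorerModel":
        """Scorer labelling uniformly at random (independence baseline)."""
        return cls(np.full((n_stages, n_stages), 1.0 / n_stages))

    @classmethod
    def with_accuracy(cls, p: float, n_stages: int = 5) -> "ScorerModel":
        """Diagonal accuracy ``p``, errors spread evenly over other stages."""
        if not 0.0 < p <= 1.0:
            raise HypnodensityError("accuracy must lie in (0, 1]")
        off = (1.0 - p) / (n_stages - 1)
        m = np.full((n_stages, n_stages), off)
        np.fill_diagonal(m, p)
        return cls(m)


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary stage distribution (left eigenvector for eigenvalue 1)."""
    P = _row_stochastic(transition_matrix, "transition matrix")
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_true_hypnogram(
    transition_matrix: np.ndarray,
    initial_stage: str,
    n_epochs: int,
    seed: int | np.random.Generator,
    vocabulary: StageVocabulary = FIVE_STAGE,
    epoch_seconds: float = 30.0,
) -> Hypnogram:
    """Seeded realization of a first-order Markov chain over the stages."""
    P = _row_stochastic(transition_matrix, "transition matrix")
    if P.shape[0] != len(vocabulary):
        raise HypnodensityError("transition matrix size does not match vocabulary")
    rng = np.random.default_rng(seed)
    idx = np.empty(n_epochs, dtype=np.intp)
    idx[0] = vocabulary.index(vocabulary.canonicalize(initial_stage))
    for t in range(1, n_epochs):
        idx[t] = rng.choice(len(vocabulary), p=P[idx[t - 1]])
    return Hypnogram.from_indices(idx, vocabulary, epoch_seconds)


def simulate_scorer_panel(
    true: Hypnogram,
    models: list[ScorerModel],
    seed: int | np.random.Generator,
) -> ScorerPanel:
    """Each scorer samples its confusion row for the true stage, independently."""
    if not models:
        raise HypnodensityError("at least one scorer model is required")
    rng = np.random.default_rng(seed)
    true_idx = true.as_indices()
    n_stages = len(true.vocabulary)
    hyps = []
    for m in models:
        if m.confusion.shape[0] != n_stages:
            raise HypnodensityError("confusion matrix size does not match vocabulary")
        # inverse-CDF sampling, vectorized over epochs
        cdf = np.cumsum(m.confusion, axis=1)
        u = rng.random(true.n_epochs)
        labels = (u[:, None] > cdf[true_idx]).sum(axis=1)
        hyps.append(
            Hypnogram.from_indices(labels, true.vocabulary, true.epoch_seconds)
        )
    ids = tuple(f"S{i + 1}" for i in range(len(models)))
    return ScorerPanel(ids, tuple(hyps))


def simulate_hypnodensity(
    true: Hypnogram,
    concentration: float,
    seed: int | np.random.Generator,
):
    """Dirichlet rows centred on the true stage.

    Row i ~ Dirichlet(alpha) with alpha = concentration on the true stage
    and 1 elsewhere: concentration -> infinity gives one-hot rows (zero
    ambiguity); concentration 1 gives the symmetric Dirichlet(1,...,1).
    """
    from .core import Hypnodensity

    if concentration < 1.0:
        raise HypnodensityError("concentration must be >= 1")
    rng = np.random.default_rng(seed)
    n_stages = len(true.vocabulary)
    true_idx = true.as_indices()
    probs = np.empty((true.n_epochs, n_stages))
    for e in range(true.n_epochs):
        alpha = np.ones(n_stages)
        alpha[true_idx[e]] = concentration
        probs[e] = rng.dirichlet(alpha)
    return Hypnodensity(probs, true.vocabulary, true.epoch_seconds)


@dataclass(frozen=True)
class SdbScenario:
    """Parameters of a synthetic HSAT night with event-coupled desaturations.

    Each respiratory event is followed by a trapezoidal SpO2 dip: the
    saturation falls linearly over ``desat_fall_s`` starting
    ``desat_delay_s`` after the event termination, holds the nadir
    (baseline minus ``desat_depth_pct``) for ``desat_hold_s``, and
    recovers over ``desat_rise_s``.  Defaults emulate a moderate OSA
    night: ~20 s obstructive events, 4% desaturations of ~45 s total
    footprint, a 95% baseline and 1 Hz oximetry.
    """

    n_events: int = 60
    event_duration_s: float = 20.0
    event_spacing_s: float = 120.0
    desat_depth_pct: float = 4.0
    desat_delay_s: float = 5.0
    desat_fall_s: float = 10.0
    desat_hold_s: float = 20.0
    desat_rise_s: float = 15.0
    baseline_spo2_pct: float = 95.0
    noise_sd_pct: float = 0.0
    rate_hz: float = 1.0
    sleep_latency_min: float = 10.0
    rem_start_min: float | None = None  # REM block start; None -> no REM
    rem_duration_min: float = 0.0

    def __post_init__(self) -> None:
        if self.n_events < 0 or self.event_duration_s <= 0:
            raise HypnodensityError("event counts/durations must be positive")
        if self.desat_depth_pct < 0:
            raise HypnodensityError("desaturation depth must be nonnegative")

    @property
    def desat_area_pct_min(self) -> float:
        """Closed-form area of one desaturation (%·min): depth x trapezoid."""
        trap_s = self.desat_hold_s + 0.5 * (self.desat_fall_s + self.desat_rise_s)
        return self.desat_depth_pct * trap_s / 60.0


@dataclass(frozen=True)
class SdbSimulation:
    """Outputs of :func:`simulate_oximetry`, with analytic per-event areas."""

    trace: OximetryTrace
    events: list[RespiratoryEvent]
    hypnogram: Hypnogram
    event_areas_pct_min: np.ndarray


def _desat_profile(t_after_term: np.ndarray, sc: SdbScenario) -> np.ndarray:
    """Depth of the trapezoidal desaturation (%) as a function of time."""
    t0 = sc.desat_delay_s
    t1 = t0 + sc.desat_fall_s
    t2 = t1 + sc.desat_hold_s
    t3 = t2 + sc.desat_rise_s
    d = np.zeros_like(t_after_term)
    falling = (t_after_term >= t0) & (t_after_term < t1)
    if sc.desat_fall_s > 0:
        d[falling] = (t_after_term[falling] - t0) / sc.desat_fall_s
    hold = (t_after_term >= t1) & (t_after_term < t2)
    d[hold] = 1.0
    rising = (t_after_term >= t2) & (t_after_term < t3)
    if sc.desat_rise_s > 0:
        d[rising] = 1.0 - (t_after_term[rising] - t2) / sc.desat_rise_s
    return sc.desat_depth_pct * d


def simulate_oximetry(
    scenario: SdbScenario, seed: int | np.random.Generator
) -> SdbSimulation:
    """Synthetic oximetry night: baseline + noise + event-coupled dips.

    Events are placed at regular intervals once sleep begins; the
    hypnogram is wake for the scenario's sleep latency, then N2 (with an
    optional REM block).  The returned analytic per-event areas are the
    validation targets for the hypoxic-burden estimator.
    """
    rng = np.random.default_rng(seed)
    sc = scenario
    footprint = sc.desat_delay_s + sc.desat_fall_s + sc.desat_hold_s + sc.desat_rise_s
    total_s = (
        sc.sleep_latency_min * 60.0
        + max(sc.n_events, 1) * sc.event_spacing_s
        + footprint
        + 300.0
    )
    n_epochs = int(np.ceil(total_s / 30.0))
    total_s = n_epochs * 30.0

    # hypnogram: wake block, then N2, with an optional REM block
    stages = ["W"] * int(sc.sleep_latency_min * 2) + ["N2"] * (
        n_epochs - int(sc.sleep_latency_min * 2)
    )
    if sc.rem_start_min is not None and sc.rem_duration_min > 0:
        i0 = int(sc.rem_start_min * 2)
        i1 = min(i0 + int(sc.rem_duration_min * 2), n_epochs)
        for i in range(i0, i1):
            stages[i] = "R"
    hyp = Hypnogram(tuple(stages), 30.0, FIVE_STAGE)

    dt = 1.0 / sc.rate_hz
    n_samples = int(round(total_s / dt)) + 1
    t = np.arange(n_samples) * dt
    spo2 = np.full(n_samples, sc.baseline_spo2_pct)
    if sc.noise_sd_pct > 0:
        spo2 = spo2 + rng.normal(0.0, sc.noise_sd_pct, n_samples)

    events = []
    first_start = sc.sleep_latency_min * 60.0 + 60.0
    for i in range(sc.n_events):
        start = first_start + i * sc.event_spacing_s
        ev = RespiratoryEvent("hypopnea", start, sc.event_duration_s)
        events.append(ev)
        spo2 -= _desat_profile(t - ev.end_s, sc)

    trace = OximetryTrace(spo2, sc.rate_hz, 0.0)
    areas = np.full(len(events), sc.desat_area_pct_min)
    return SdbSimulation(trace, events, hyp, areas)
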