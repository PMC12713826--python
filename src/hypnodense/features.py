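"""Sleep parameters and hypnodensity-derived features.

Standard report parameters (TST, latencies, WASO, sleep efficiency, stage
minutes) are computed two ways: from a discrete hypnogram, and from a
hypnodensity by integrating the per-stage probability curves (the "area
under the probability curve" parameters).  For a hypnodensity built from a
panel with uniform weights the two routes coincide in expectation: stage
minutes from the hypnodensity equal the mean of the per-scorer stage
minutes (linearity of the vote-share average).

The per-epoch features quantify how unequivocal the staging is:

* ambiguity  = 100 * (1 - p_max)          per epoch
* continuity = 100 * (1 - |delta p_max|)  per adjacent same-stage pair
* an epoch is *ambiguous* when p_max <= 0.95
* two adjacent NREM epochs are *stable* when p_N2 + p_N3 > 0.95 in both;
  two adjacent REM epochs when p_R > 0.95 in both
* NREM depth = 100 * (p_N1 + 2 p_N2 + 4 p_N3) / 4 over NREM epochs
  (pure N1/N2/N3 epochs score 25/50/100).

Undefined quantities (no REM, empty denominators) propagate as NaN, never
as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    FIVE_STAGE,
    Hypnodensity,
    Hypnogram,
    assign_stage_hierarchical,
)
from .errors import AlignmentError, HypnodensityError, VocabularyError

__all__ = [
    "SleepParameters",
    "HypnodensityFeatures",
    "hypnogram_parameters",
    "hypnodensity_parameters",
    "epoch_ambiguity",
    "epoch_continuity",
    "ambiguous_fraction",
    "stable_fraction",
    "nrem_depth",
    "hypnodensity_features",
    "mean_sleep_parameters",
]

AMBIGUITY_THRESHOLD = 0.95  # p_max at or below this marks an epoch ambiguous
STABILITY_THRESHOLD = 0.95  # strict > for the stable NREM/REM pair rule


@dataclass(frozen=True)
class SleepParameters:
    """Standard sleep-report parameters.  Times in minutes, SEFF in percent."""

    tst_min: float
    sleep_latency_min: float
    rem_latency_min: float
    waso_min: float
    sleep_efficiency_pct: float
    stage_minutes: dict[str, float]
    stage_pct_tst: dict[str, float]

    def as_dict(self) -> dict[str, float]:
        out = {
            "tst_min": self.tst_min,
            "sleep_latency_min": self.sleep_latency_min,
            "rem_latency_min": self.rem_latency_min,
            "waso_min": self.waso_min,
            "sleep_efficiency_pct": self.sleep_efficiency_pct,
        }
        out.update({f"{s}_min": v for s, v in self.stage_minutes.items()})
        out.update({f"{s}_pct_tst": v for s, v in self.stage_pct_tst.items()})
        return out


def _pct_tst(stage_minutes: dict[str, float], tst: float) -> dict[str, float]:
    if tst > 0:
        return {s: 100.0 * m / tst for s, m in stage_minutes.items()}
    return {s: math.nan for s in stage_minutes}


def hypnogram_parameters(
    h: Hypnogram, recording_start_to_lights_off_min: float = 0.0
) -> SleepParameters:
    """Standard parameters from a discrete hypnogram.

    TST counts non-W epochs; sleep latency runs from lights-off to the
    first non-W epoch; REM latency from sleep onset to the first R epoch;
    WASO counts W epochs strictly between sleep onset and the final non-W
    epoch (trailing wake is excluded); sleep efficiency is TST over the
    analysis duration (recording minus the pre-lights-off offset).  An
    all-wake hypnogram yields TST 0 and NaN latencies.
    """
    em = h.epoch_minutes
    offset = float(recording_start_to_lights_off_min)
    analysis_min = h.n_epochs * em - offset
    if analysis_min <= 0:
        raise HypnodensityError("lights-off offset exceeds the recording duration")
    is_sleep = np.array([s != "W" for s in h.stages])
    sleep_stages = h.vocabulary.sleep_stages
    stage_minutes = {
        s: em * sum(1 for x in h.stages if x == s) for s in sleep_stages
    }
    tst = float(sum(stage_minutes.values()))

    if not is_sleep.any():
        return SleepParameters(
            0.0, math.nan, math.nan, math.nan, 0.0,
            stage_minutes, _pct_tst(stage_minutes, 0.0),
        )

    onset = int(np.flatnonzero(is_sleep)[0])
    last_sleep = int(np.flatnonzero(is_sleep)[-1])
    sl = max(onset * em - offset, 0.0)
    waso = em * float((~is_sleep[onset:last_sleep + 1]).sum())
    if "R" in h.vocabulary.stages:
        r_idx = [i for i, s in enumerate(h.stages) if s == "R" and i >= onset]
        reml = (r_idx[0] - onset) * em if r_idx else math.nan
    else:
        reml = math.nan
    seff = 100.0 * tst / analysis_min
    return SleepParameters(tst, sl, reml, waso, seff,
                           stage_minutes, _pct_tst(stage_minutes, tst))


def hypnodensity_parameters(h: Hypnodensity) -> SleepParameters:
    """Area-under-the-probability-curve sleep parameters.

    Stage minutes integrate each stage's probability curve over epochs;
    TST is their sum.  Sleep onset is the first epoch whose sleep
    probability exceeds its wake probability (p_W < 0.5); sleep latency is
    the time up to that epoch.  WASO integrates the wake probability
    strictly between onset and the last sleep-dominant epoch; REM latency
    is taken from the hierarchical stage assignment (five-stage input) —
    both are package conventions, since only the stage areas and the onset
    rule are prescribed by the construction.
    """
    em = h.epoch_minutes
    sleep_stages = h.vocabulary.sleep_stages
    stage_minutes = {
        s: em * float(h.stage_prob(s).sum()) for s in sleep_stages
    }
    tst = float(sum(stage_minutes.values()))
    duration = h.n_epochs * em
    seff = 100.0 * tst / duration

    p_w = h.stage_prob("W")
    sleep_dominant = np.flatnonzero(p_w < 0.5)
    if sleep_dominant.size == 0:
        return SleepParameters(tst, math.nan, math.nan, math.nan, seff,
                               stage_minutes, _pct_tst(stage_minutes, tst))
    onset, last = int(sleep_dominant[0]), int(sleep_dominant[-1])
    sl = onset * em
    waso = em * float(p_w[onset + 1:last].sum()) if last > onset + 1 else 0.0

    reml = math.nan
    if h.vocabulary == FIVE_STAGE:
        assigned = assign_stage_hierarchical(h)
        r_idx = [i for i, s in enumerate(assigned.stages) if s == "R" and i >= onset]
        if r_idx:
            reml = (r_idx[0] - onset) * em
    return SleepParameters(tst, sl, reml, waso, seff,
                           stage_minutes, _pct_tst(stage_minutes, tst))


def mean_sleep_parameters(params: list[SleepParameters]) -> SleepParameters:
    """Element-wise mean of per-scorer sleep parameters.

    This is the panel-mean aggregation: averaging per-scorer stage minutes
    gives the same stage minutes as integrating the uniform-weight
    hypnodensity (linearity).
    """
    if not params:
        raise HypnodensityError("cannot aggregate an empty parameter list")
    stages = list(params[0].stage_minutes)
    stage_minutes = {
        s: float(np.mean([p.stage_minutes[s] for p in params])) for s in stages
    }
    tst = float(np.mean([p.tst_min for p in params]))
    return SleepParameters(
        tst,
        float(np.nanmean([p.sleep_latency_min for p in params])),
        float(np.nanmean([p.rem_latency_min for p in params])),
        float(np.nanmean([p.waso_min for p in params])),
        float(np.mean([p.sleep_efficiency_pct for p in params])),
        stage_minutes,
        _pct_tst(stage_minutes, tst),
    )


# ---------------------------------------------------------------------------
# per-epoch hypnodensity features


def epoch_ambiguity(h: Hypnodensity) -> np.ndarray:
    """100 * (1 - p_max) per epoch: 0 for a one-hot row, 80 for uniform-over-5."""
    return 100.0 * (1.0 - h.p_max)


def epoch_continuity(
    h: Hypnodensity, assigned: Hypnogram, same_class: str = "stage"
) -> np.ndarray:
    """100 * (1 - |p_max(i) - p_max(i+1)|) for adjacent same-class epoch pairs.

    Returns one value per adjacent pair (length n_epochs - 1); pairs whose
    epochs belong to different classes are NaN and excluded from means.
    ``same_class`` is ``"stage"`` (identical assigned stage, the default)
    or ``"wnr"`` (same W / NREM / REM class).
    """
    _check_assigned(h, assigned)
    pm = h.p_max
    vals = 100.0 * (1.0 - np.abs(np.diff(pm)))
    if same_class == "stage":
        cls = list(assigned.stages)
    elif same_class == "wnr":
        cls = [_wnr_class(s) for s in assigned.stages]
    else:
        raise HypnodensityError(f"unknown same_class mode {same_class!r}")
    same = np.array([cls[i] == cls[i + 1] for i in range(len(cls) - 1)])
    return np.where(same, vals, np.nan)


def _wnr_class(stage: str) -> str:
    if stage == "W":
        return "W"
    if stage == "R":
        return "R"
    return "NREM"


def _check_assigned(h: Hypnodensity, assigned: Hypnogram) -> None:
    if assigned.n_epochs != h.n_epochs:
        raise AlignmentError("assigned hypnogram is not aligned with the hypnodensity")
    if assigned.vocabulary != h.vocabulary:
        raise AlignmentError("assigned hypnogram uses a different vocabulary")


def _class_mask(assigned: Hypnogram, which: str) -> np.ndarray:
    which = which.upper()
    if which == "NREM":
        members = {"N1", "N2", "N3", "LS", "DS"}
    elif which == "REM":
        members = {"R"}
    elif which == "SLEEP":
        members = set(assigned.vocabulary.sleep_stages)
    else:
        raise HypnodensityError(f"unknown class filter {which!r}")
    return np.array([s in members for s in assigned.stages])


def ambiguous_fraction(
    h: Hypnodensity, assigned: Hypnogram, class_filter: str
) -> float:
    """Percentage of class epochs with p_max <= 0.95 (boundary inclusive)."""
    _check_assigned(h, assigned)
    mask = _class_mask(assigned, class_filter)
    if not mask.any():
        return math.nan
    return 100.0 * float((h.p_max[mask] <= AMBIGUITY_THRESHOLD).mean())


def stable_fraction(h: Hypnodensity, assigned: Hypnogram, which: str) -> float:
    """Percentage of adjacent same-class pairs meeting the stability rule.

    NREM pairs are stable when p_N2 + p_N3 > 0.95 in both epochs; REM pairs
    when p_R > 0.95 in both (strict inequalities).  The denominator is all
    adjacent pairs with both epochs assigned to the class; NaN when empty.
    """
    _check_assigned(h, assigned)
    which = which.upper()
    if which == "NREM":
        if h.vocabulary != FIVE_STAGE:
            raise VocabularyError("stable NREM fraction requires five-stage input")
        strength = h.stage_prob("N2") + h.stage_prob("N3")
    elif which == "REM":
        strength = h.stage_prob("R")
    else:
        raise HypnodensityError(f"unknown class {which!r}")
    mask = _class_mask(assigned, which)
    pair = mask[:-1] & mask[1:]
    if not pair.any():
        return math.nan
    stable = (strength[:-1] > STABILITY_THRESHOLD) & (strength[1:] > STABILITY_THRESHOLD)
    return 100.0 * float(stable[pair].mean())


def nrem_depth(h: Hypnodensity, assigned: Hypnogram) -> float:
    """Weighted-average NREM depth over NREM-assigned epochs.

    Per epoch: 100 * (p_N1 + 2 p_N2 + 4 p_N3) / 4, so a pure N3 epoch
    scores 100, pure N2 scores 50 and pure N1 scores 25.  NaN if no epoch
    is assigned to NREM.
    """
    if h.vocabulary != FIVE_STAGE:
        raise VocabularyError("NREM depth requires five-stage input")
    _check_assigned(h, assigned)
    mask = _class_mask(assigned, "NREM")
    if not mask.any():
        return math.nan
    depth = 100.0 * (
        h.stage_prob("N1") + 2.0 * h.stage_prob("N2") + 4.0 * h.stage_prob("N3")
    ) / 4.0
    return float(depth[mask].mean())


@dataclass(frozen=True)
class HypnodensityFeatures:
    """Night-level summary of the per-epoch features (all percentages)."""

    mean_ambiguity_pct: float
    mean_ambiguity_sleep_pct: float
    mean_ambiguity_nrem_pct: float
    mean_ambiguity_rem_pct: float
    mean_continuity_pct: float
    ambiguous_fraction_nrem_pct: float
    ambiguous_fraction_rem_pct: float
    stable_nrem_pct: float
    stable_rem_pct: float
    nrem_depth_pct: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def hypnodensity_features(
    h: Hypnodensity, assigned: Hypnogram | None = None
) -> HypnodensityFeatures:
    """Aggregate the ambiguity / continuity / stability / depth features.

    Class membership for the restricted means and denominators comes from
    the hierarchical assignment (computed here when ``assigned`` is not
    given).  Empty denominators yield NaN.
    """
    if assigned is None:
        assigned = assign_stage_hierarchical(h)
    _check_assigned(h, assigned)
    amb = epoch_ambiguity(h)

    def _mean_over(which: str) -> float:
        mask = _class_mask(assigned, which)
        return float(amb[mask].mean()) if mask.any() else math.nan

    cont = epoch_continuity(h, assigned)
    mean_cont = float(np.nanmean(cont)) if np.isfinite(cont).any() else math.nan
    return HypnodensityFeatures(
        mean_ambiguity_pct=float(amb.mean()),
        mean_ambiguity_sleep_pct=_mean_over("SLEEP"),
        mean_ambiguity_nrem_pct=_mean_over("NREM"),
        mean_ambiguity_rem_pct=_mean_over("REM"),
        mean_continuity_pct=mean_cont,
        ambiguous_fraction_nrem_pct=ambiguous_fraction(h, assigned, "NREM"),
        ambiguous_fraction_rem_pct=ambiguous_fraction(h, assigned, "REM"),
        stable_nrem_pct=stable_fraction(h, assigned, "NREM"),
        stable_rem_pct=stable_fraction(h, assigned, "REM"),
        nrem_depth_pct=nrem_depth(h, assigned),
    )
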