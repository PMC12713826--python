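"""Sleep-disordered-breathing metrics from event lists, staging and oximetry.

Given scored respiratory events (apneas / hypopneas), a hypnogram, and an
SpO2 trace, this module computes:

* AHI per hour of total / NREM / REM sleep (events attributed to the sleep
  state at their *termination* time) and the REI, the same count per hour
  of monitoring time — the HSAT fallback when sleep time is unknown;
* the hypoxic burden: for each event, the area between the pre-event
  baseline (maximum SpO2 in the 100 s before event termination) and the
  desaturation curve, integrated over a subject-specific search window
  anchored at the termination, summed and normalized per hour of sleep
  (%·min/h);
* the subject-specific search window itself, derived from the
  ensemble-averaged desaturation curve (all events aligned at
  termination): the contiguous span around the termination where the
  averaged curve lies below its pre-event baseline level;
* the REM-related OSA rule: AHI_NREM < 5 and AHI_REM >= 5 with at least
  30 minutes of REM sleep.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Hypnogram
from .errors import HypnodensityError

__all__ = [
    "RespiratoryEvent",
    "OximetryTrace",
    "SdbIndices",
    "HypoxicBurdenResult",
    "EnsembleCurve",
    "SearchWindow",
    "validate_events",
    "ahi",
    "rei",
    "ensemble_average_desaturation",
    "search_window",
    "hypoxic_burden",
    "classify_rem_related_osa",
    "sdb_summary",
]

BASELINE_LOOKBACK_S = 100.0  # pre-termination span searched for the SpO2 baseline
MAX_GAP_INTERP_S = 3.0       # SpO2 gaps shorter than this are linearly interpolated
BASELINE_SMOOTH_S = 60.0     # moving-average width for baseline estimation


@dataclass(frozen=True)
class RespiratoryEvent:
    """A scored apnea or hypopnea.  Times in seconds from recording start."""

    kind: str
    start_s: float
    duration_s: float

    def __post_init__(self) -> None:
        kind = str(self.kind).strip().lower()
        if kind not in ("apnea", "hypopnea"):
            raise HypnodensityError(f"unknown event kind {self.kind!r}")
        if self.duration_s <= 0:
            raise HypnodensityError("event duration must be positive")
        object.__setattr__(self, "kind", kind)

    @property
    def end_s(self) -> float:
        """Event termination time — the anchor for desaturation analysis."""
        return self.start_s + self.duration_s


def validate_events(events: list[RespiratoryEvent]) -> list[RespiratoryEvent]:
    """Sort events by start time and reject overlapping ones."""
    ev = sorted(events, key=lambda e: e.start_s)
    for a, b in zip(ev, ev[1:]):
        if b.start_s < a.end_s:
            raise HypnodensityError(
                f"overlapping events at {a.start_s:.1f}s and {b.start_s:.1f}s"
            )
    return ev


@dataclass(frozen=True)
class OximetryTrace:
    """SpO2 samples (percent) at a fixed rate, starting at ``start_s``.

    Physiologically implausible samples (outside [0, 100]) are flagged with
    a warning but kept; NaN samples mark signal dropouts.
    """

    spo2_pct: np.ndarray
    rate_hz: float
    start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise HypnodensityError("sampling rate must be positive")
        x = np.asarray(self.spo2_pct, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise HypnodensityError("oximetry trace must be a 1-D series")
        finite = x[np.isfinite(x)]
        n_bad = int(((finite < 0) | (finite > 100)).sum())
        if n_bad:
            warnings.warn(
                f"{n_bad} SpO2 samples outside [0, 100] retained", stacklevel=2
            )
        object.__setattr__(self, "spo2_pct", x)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.start_s + (self.spo2_pct.size - 1) * self.dt

    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.spo2_pct.size) * self.dt

    def interpolate_short_gaps(self, max_gap_s: float = MAX_GAP_INTERP_S) -> "OximetryTrace":
        """Linearly bridge NaN runs shorter than ``max_gap_s``; keep longer ones."""
        x = self.spo2_pct.copy()
        isnan = np.isnan(x)
        if not isnan.any():
            return self
        max_run = int(round(max_gap_s * self.rate_hz))
        i = 0
        n = x.size
        while i < n:
            if isnan[i]:
                j = i
                while j < n and isnan[j]:
                    j += 1
                if (j - i) < max_run and i > 0 and j < n:
                    x[i:j] = np.interp(np.arange(i, j), [i - 1, j], [x[i - 1], x[j]])
                i = j
            else:
                i += 1
        return OximetryTrace(x, self.rate_hz, self.start_s)


@dataclass(frozen=True)
class SdbIndices:
    """Event indices per hour: by sleep state, and per monitoring hour (REI)."""

    ahi_total: float
    ahi_nrem: float
    ahi_rem: float
    rei: float = math.nan
    rem_related_osa: bool | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _state_minutes(hypnogram: Hypnogram) -> dict[str, float]:
    em = hypnogram.epoch_minutes
    nrem_codes = {"N1", "N2", "N3", "LS", "DS"}
    nrem = em * sum(1 for s in hypnogram.stages if s in nrem_codes)
    rem = em * sum(1 for s in hypnogram.stages if s == "R")
    return {"NREM": nrem, "REM": rem, "SLEEP": nrem + rem}


def _state_at(hypnogram: Hypnogram, t_s: float) -> str | None:
    """W/NREM/REM class of the epoch containing time ``t_s``; None if outside."""
    idx = int(t_s // hypnogram.epoch_seconds)
    if not 0 <= idx < hypnogram.n_epochs:
        return None
    s = hypnogram.stages[idx]
    if s == "W":
        return "W"
    if s == "R":
        return "REM"
    return "NREM"


def ahi(events: list[RespiratoryEvent], hypnogram: Hypnogram) -> SdbIndices:
    """Apnea-hypopnea indices per hour of total, NREM and REM sleep.

    Events are attributed by the sleep state at their termination; events
    terminating in wake (or outside the staged period) do not count.
    States with zero sleep time yield NaN rather than an index.
    """
    mins = _state_minutes(hypnogram)
    counts = {"NREM": 0, "REM": 0}
    for e in events:
        state = _state_at(hypnogram, e.end_s)
        if state in counts:
            counts[state] += 1

    def _index(n: int, minutes: float) -> float:
        return n / (minutes / 60.0) if minutes > 0 else math.nan

    return SdbIndices(
        ahi_total=_index(counts["NREM"] + counts["REM"], mins["SLEEP"]),
        ahi_nrem=_index(counts["NREM"], mins["NREM"]),
        ahi_rem=_index(counts["REM"], mins["REM"]),
    )


def rei(events: list[RespiratoryEvent], monitoring_duration_h: float) -> float:
    """Respiratory event index: all events per hour of monitoring time.

    Because monitoring time >= sleep time, REI <= AHI for the same events —
    the known downward bias of HSAT indices when wake is present.
    """
    if monitoring_duration_h <= 0:
        raise HypnodensityError("monitoring duration must be positive")
    return len(events) / monitoring_duration_h


@dataclass(frozen=True)
class EnsembleCurve:
    """Event-termination-aligned average SpO2 curve.

    ``offsets_s`` runs from -pre to +post around the termination (0 s).
    """

    offsets_s: np.ndarray
    spo2_pct: np.ndarray
    n_events_used: int
    n_events_excluded: int


def ensemble_average_desaturation(
    trace: OximetryTrace,
    events: list[RespiratoryEvent],
    window_s: tuple[float, float] = (60.0, 120.0),
) -> EnsembleCurve:
    """Pointwise mean of SpO2 segments aligned at each event's termination.

    Events whose window is not fully covered by the trace are excluded and
    counted.  Raises if no event is fully covered.
    """
    pre, post = window_s
    if pre < 0 or post < 0:
        raise HypnodensityError("window bounds must be nonnegative")
    trace = trace.interpolate_short_gaps()
    dt = trace.dt
    offsets = np.arange(-round(pre / dt), round(post / dt) + 1) * dt
    segments = []
    excluded = 0
    for e in events:
        idx = np.round((e.end_s + offsets - trace.start_s) / dt).astype(int)
        if idx[0] < 0 or idx[-1] >= trace.spo2_pct.size:
            excluded += 1
            continue
        seg = trace.spo2_pct[idx]
        if np.isnan(seg).any():
            excluded += 1
            continue
        segments.append(seg)
    if not segments:
        raise HypnodensityError("no event is fully covered by the oximetry trace")
    avg = np.mean(segments, axis=0)
    return EnsembleCurve(offsets, avg, len(segments), excluded)


@dataclass(frozen=True)
class SearchWindow:
    """Subject-specific integration window relative to event termination."""

    pre_s: float
    post_s: float
    baseline_pct: float = math.nan
    zero_width: bool = False

    @property
    def width_s(self) -> float:
        return self.pre_s + self.post_s


def search_window(curve: EnsembleCurve) -> SearchWindow:
    """Derive the search window from the averaged desaturation curve.

    Baseline = mean of the averaged curve over the earliest quarter of the
    pre-termination segment.  The window is the contiguous run of samples
    below baseline that contains the curve's nadir — the event-associated
    desaturation, whose trough trails the termination; bounds are snapped
    to sample resolution.  A curve never dipping below baseline yields a
    zero-width window with the ``zero_width`` flag set.
    """
    t = curve.offsets_s
    y = curve.spo2_pct
    pre_idx = np.flatnonzero(t < 0)
    if pre_idx.size < 4:
        raise HypnodensityError("averaged curve has no usable pre-termination segment")
    quarter = pre_idx[: max(1, pre_idx.size // 4)]
    baseline = float(y[quarter].mean())
    below = y < baseline
    if not below.any():
        return SearchWindow(0.0, 0.0, baseline, zero_width=True)
    # contiguous below-baseline runs
    runs = []
    i = 0
    while i < below.size:
        if below[i]:
            j = i
            while j < below.size and below[j]:
                j += 1
            runs.append((i, j - 1))
            i = j
        else:
            i += 1
    nadir = int(np.argmin(y))
    containing = [r for r in runs if r[0] <= nadir <= r[1]]
    lo, hi = containing[0] if containing else max(runs, key=lambda r: r[1] - r[0])
    return SearchWindow(float(max(-t[lo], 0.0)), float(max(t[hi], 0.0)), baseline)


@dataclass(frozen=True)
class HypoxicBurdenResult:
    """Hypoxic burden in %·min per hour of (state) sleep."""

    hb_total: float
    hb_nrem: float
    hb_rem: float
    search_window_s: tuple[float, float]
    per_event_areas: np.ndarray  # %·min, aligned with the included events
    n_events_excluded: int = 0

    def as_dict(self) -> dict:
        return {
            "hb_total": self.hb_total,
            "hb_nrem": self.hb_nrem,
            "hb_rem": self.hb_rem,
            "search_window_pre_s": self.search_window_s[0],
            "search_window_post_s": self.search_window_s[1],
            "n_events_excluded": self.n_events_excluded,
        }


def _moving_average(x: np.ndarray, width_samples: int) -> np.ndarray:
    if width_samples <= 1:
        return x
    kernel = np.ones(width_samples) / width_samples
    # same-length centred average with edge correction
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def hypoxic_burden(
    trace: OximetryTrace,
    events: list[RespiratoryEvent],
    hypnogram: Hypnogram,
    window: SearchWindow | tuple[float, float],
    baseline_lookback_s: float = BASELINE_LOOKBACK_S,
    baseline_smooth_s: float = BASELINE_SMOOTH_S,
) -> HypoxicBurdenResult:
    """Respiratory event-associated desaturation area per hour of sleep.

    Per event: baseline = maximum SpO2 in the ``baseline_lookback_s``
    before the termination; area = integral of max(0, baseline - SpO2)
    over [termination - pre, termination + post] in %·min (SpO2 above
    baseline contributes zero).  HB = summed area / TST hours; NREM/REM
    components split events by sleep state at termination and normalize by
    the state's hours.  Events whose window or baseline span leaves the
    trace, or overlaps an unbridgeable signal gap, are excluded and counted.

    The baseline maximum is taken on a centred moving-average copy of the
    trace (width ``baseline_smooth_s``; the raw trace is still what is
    integrated).  True saturation varies slowly, so on a noisy trace the
    raw per-sample maximum systematically overestimates the pre-event
    baseline (extreme-value bias) and with it every event's area; the
    moving average suppresses sampling noise without shifting a constant
    or slowly-varying baseline.  Set ``baseline_smooth_s=0`` for the raw
    maximum.
    """
    if isinstance(window, tuple):
        window = SearchWindow(*window)
    mins = _state_minutes(hypnogram)
    if mins["SLEEP"] <= 0:
        raise HypnodensityError("hypoxic burden requires TST > 0")
    trace = trace.interpolate_short_gaps()
    dt = trace.dt
    smooth = _moving_average(
        trace.spo2_pct, int(round(baseline_smooth_s * trace.rate_hz))
    )
    areas, states = [], []
    excluded = 0
    for e in events:
        lo_t = e.end_s - window.pre_s
        hi_t = e.end_s + window.post_s
        if lo_t < trace.start_s - 1e-9 or hi_t > trace.end_s + 1e-9:
            excluded += 1
            continue
        # baseline lookback truncates at the trace start rather than excluding
        base_idx = np.round(
            (e.end_s - np.arange(0, baseline_lookback_s + dt / 2, dt)[::-1]
             - trace.start_s) / dt
        ).astype(int)
        base_idx = base_idx[(base_idx >= 0) & (base_idx < trace.spo2_pct.size)]
        base_seg = smooth[base_idx]
        win_off = np.arange(-round(window.pre_s / dt), round(window.post_s / dt) + 1) * dt
        win_idx = np.round((e.end_s + win_off - trace.start_s) / dt).astype(int)
        seg = trace.spo2_pct[win_idx]
        raw_base = trace.spo2_pct[base_idx]
        if np.isnan(raw_base).any() or np.isnan(seg).any():
            excluded += 1
            continue
        baseline = float(base_seg.max())
        deficit = np.clip(baseline - seg, 0.0, None)
        areas.append(float(np.trapezoid(deficit, dx=dt)) / 60.0)  # %·min
        states.append(_state_at(hypnogram, e.end_s))

    areas_arr = np.asarray(areas)

    def _hb(mask_states: set[str] | None, minutes: float) -> float:
        if minutes <= 0:
            return math.nan
        if mask_states is None:
            total = float(areas_arr.sum()) if areas_arr.size else 0.0
        else:
            total = float(sum(a for a, s in zip(areas, states) if s in mask_states))
        return total / (minutes / 60.0)

    return HypoxicBurdenResult(
        hb_total=_hb(None, mins["SLEEP"]),
        hb_nrem=_hb({"NREM"}, mins["NREM"]),
        hb_rem=_hb({"REM"}, mins["REM"]),
        search_window_s=(window.pre_s, window.post_s),
        per_event_areas=areas_arr,
        n_events_excluded=excluded,
    )


def classify_rem_related_osa(indices: SdbIndices, rem_minutes: float) -> bool:
    """REM-related OSA: AHI_NREM < 5, AHI_REM >= 5, and >= 30 min REM sleep."""
    if math.isnan(indices.ahi_nrem) or math.isnan(indices.ahi_rem):
        return False
    return (
        indices.ahi_nrem < 5.0
        and indices.ahi_rem >= 5.0
        and rem_minutes >= 30.0
    )


def sdb_summary(
    trace: OximetryTrace,
    events: list[RespiratoryEvent],
    hypnogram: Hypnogram,
    monitoring_duration_h: float | None = None,
    ensemble_window_s: tuple[float, float] = (60.0, 120.0),
    fixed_window_s: tuple[float, float] | None = None,
) -> tuple[SdbIndices, HypoxicBurdenResult]:
    """One-call SDB report: AHI/REI, subject-specific window, HB, REM-OSA flag.

    ``fixed_window_s`` bypasses the averaged-curve window derivation with a
    fixed (pre, post) window — the configurable fallback for traces where
    the ensemble average is unreliable.
    """
    events = validate_events(events)
    indices = ahi(events, hypnogram)
    if monitoring_duration_h is None:
        monitoring_duration_h = hypnogram.n_epochs * hypnogram.epoch_minutes / 60.0
    rei_val = rei(events, monitoring_duration_h)
    if fixed_window_s is not None:
        window = SearchWindow(*fixed_window_s)
    else:
        window = search_window(
            ensemble_average_desaturation(trace, events, ensemble_window_s)
        )
    hb = hypoxic_burden(trace, events, hypnogram, window)
    rem_min = _state_minutes(hypnogram)["REM"]
    indices = SdbIndices(
        ahi_total=indices.ahi_total,
        ahi_nrem=indices.ahi_nrem,
        ahi_rem=indices.ahi_rem,
        rei=rei_val,
        rem_related_osa=classify_rem_related_osa(indices, rem_min),
    )
    return indices, hb
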