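"""Plain-text readers and writers.

Formats (all CSV, epoch indices 0-based, times in seconds):

* hypnogram:     columns ``epoch_index, stage``
* panel:         wide, ``epoch_index`` plus one column per scorer
* hypnodensity:  header row of stage codes, one probability row per epoch
* events:        columns ``kind, start_s, duration_s``
* oximetry:      columns ``time_s, spo2``, uniformly sampled

Readers reject malformed rows (unknown stage codes are reported with line
numbers) rather than coercing them; every writer/reader pair round-trips
losslessly at the stated precision.  Hypnodensity rows off from 1 by at
most 1e-6 are renormalized with a logged warning; larger deviations are
errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    FIVE_STAGE,
    FOUR_STAGE,
    Hypnodensity,
    Hypnogram,
    ScorerPanel,
    StageVocabulary,
)
from .errors import AlignmentError, FileFormatError
from .sdb import OximetryTrace, RespiratoryEvent

__all__ = [
    "read_hypnogram", "write_hypnogram",
    "read_panel", "write_panel",
    "read_hypnodensity", "write_hypnodensity",
    "read_events", "write_events",
    "read_oximetry", "write_oximetry",
    "StudyBundle",
]

log = logging.getLogger("hypnodense")

RENORM_TOL = 1e-6


def _vocab_for(codes: set[str]) -> StageVocabulary:
    up = {c.upper() for c in codes}
    if up <= set(FIVE_STAGE.stages):
        return FIVE_STAGE
    if up <= set(FOUR_STAGE.stages):
        return FOUR_STAGE
    raise FileFormatError(f"stage codes {sorted(up)} match no known vocabulary")


def _canonical_column(df: pd.DataFrame, col: str, path) -> list[str]:
    vocab = _vocab_for(set(df[col].astype(str).str.upper()))
    out = []
    for line_no, raw in zip(df.index, df[col]):
        code = str(raw).strip().upper()
        if code not in vocab:
            raise FileFormatError(
                f"{path}: unknown stage code {raw!r} at data row {line_no}"
            )
        out.append(code)
    return out


def read_hypnogram(path, epoch_seconds: float = 30.0) -> Hypnogram:
    df = pd.read_csv(path)
    if "stage" not in df.columns:
        raise FileFormatError(f"{path}: expected a 'stage' column")
    stages = _canonical_column(df, "stage", path)
    vocab = _vocab_for(set(stages))
    return Hypnogram(tuple(stages), epoch_seconds, vocab)


def write_hypnogram(h: Hypnogram, path) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(h.n_epochs), "stage": list(h.stages)}
    ).to_csv(path, index=False)


def read_panel(path, epoch_seconds: float = 30.0) -> ScorerPanel:
    df = pd.read_csv(path)
    scorer_cols = [c for c in df.columns if c != "epoch_index"]
    if not scorer_cols:
        raise FileFormatError(f"{path}: no scorer columns found")
    for c in scorer_cols:
        if df[c].isna().any():
            bad = int(df.index[df[c].isna()][0])
            raise FileFormatError(
                f"{path}: scorer column {c!r} has a missing label at data row {bad}"
            )
    all_codes = {
        str(v).strip().upper() for c in scorer_cols for v in df[c]
    }
    vocab = _vocab_for(all_codes)
    hyps = []
    for c in scorer_cols:
        stages = _canonical_column(df, c, path)
        hyps.append(Hypnogram(tuple(stages), epoch_seconds, vocab))
    return ScorerPanel(tuple(scorer_cols), tuple(hyps))


def write_panel(panel: ScorerPanel, path) -> None:
    data = {"epoch_index": np.arange(panel.n_epochs)}
    for sid, h in zip(panel.scorer_ids, panel.hypnograms):
        data[sid] = list(h.stages)
    pd.DataFrame(data).to_csv(path, index=False)


def read_hypnodensity(path, epoch_seconds: float = 30.0) -> Hypnodensity:
    df = pd.read_csv(path)
    stage_cols = [c for c in df.columns if c != "epoch_index"]
    vocab = _vocab_for(set(stage_cols))
    ordered = [s for s in vocab.stages]
    if set(stage_cols) != set(ordered):
        raise FileFormatError(
            f"{path}: header {stage_cols} does not match vocabulary {ordered}"
        )
    probs = df[ordered].to_numpy(dtype=float)
    sums = probs.sum(axis=1)
    off = np.abs(sums - 1.0)
    if np.any(off > RENORM_TOL):
        bad = int(np.argmax(off))
        raise FileFormatError(
            f"{path}: probability row {bad} sums to {sums[bad]!r} (off by > {RENORM_TOL})"
        )
    if np.any(off > 1e-9):
        log.warning(
            "%s: %d rows renormalized (row sums off by <= %g)",
            path, int((off > 1e-9).sum()), RENORM_TOL,
        )
        probs = probs / sums[:, None]
    return Hypnodensity(probs, vocab, epoch_seconds)


def write_hypnodensity(h: Hypnodensity, path) -> None:
    df = pd.DataFrame(h.probs, columns=list(h.vocabulary.stages))
    df.insert(0, "epoch_index", np.arange(h.n_epochs))
    df.to_csv(path, index=False, float_format="%.12f")


def read_events(path) -> list[RespiratoryEvent]:
    df = pd.read_csv(path)
    required = {"kind", "start_s", "duration_s"}
    if not required <= set(df.columns):
        raise FileFormatError(f"{path}: expected columns {sorted(required)}")
    return [
        RespiratoryEvent(str(r.kind), float(r.start_s), float(r.duration_s))
        for r in df.itertuples()
    ]


def write_events(events: list[RespiratoryEvent], path) -> None:
    pd.DataFrame(
        {
            "kind": [e.kind for e in events],
            "start_s": [e.start_s for e in events],
            "duration_s": [e.duration_s for e in events],
        }
    ).to_csv(path, index=False)


def read_oximetry(path) -> OximetryTrace:
    df = pd.read_csv(path)
    if not {"time_s", "spo2"} <= set(df.columns):
        raise FileFormatError(f"{path}: expected columns ['time_s', 'spo2']")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FileFormatError(f"{path}: need at least two samples")
    dts = np.diff(t)
    if np.any(np.abs(dts - dts[0]) > 1e-6):
        raise FileFormatError(f"{path}: sampling is not uniform")
    return OximetryTrace(df["spo2"].to_numpy(dtype=float), 1.0 / dts[0], float(t[0]))


def write_oximetry(trace: OximetryTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times(), "spo2": trace.spo2_pct}).to_csv(
        path, index=False, float_format="%.6f"
    )


@dataclass(frozen=True)
class StudyBundle:
    """Optional container tying together one study's inputs.

    All present components must share the same time base: hypnogram-like
    components epoch-aligned, oximetry covering the staged period.
    """

    panel: ScorerPanel | None = None
    hypnodensity: Hypnodensity | None = None
    hypnogram: Hypnogram | None = None
    events: list[RespiratoryEvent] | None = None
    oximetry: OximetryTrace | None = None
    subject_id: str = ""
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        n_epochs = {
            name: comp.n_epochs
            for name, comp in (
                ("panel", self.panel),
                ("hypnodensity", self.hypnodensity),
                ("hypnogram", self.hypnogram),
            )
            if comp is not None
        }
        if len(set(n_epochs.values())) > 1:
            raise AlignmentError(f"components disagree on epoch count: {n_epochs}")
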