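"""Landmark-table and behavioural event-log I/O, segmentation and labelling.

The raw material is (a) per-frame landmark tables — timestamp, x/y for six
body landmarks, detector confidence — and (b) event logs in the tabular
export dialect of the BORIS annotation tool, coding which of the three
scent-wall areas the dog occupied and when it performed the trained alert
(nose held at a hole for >= 4 s).

A trial is split into per-area search segments on the half-open interval
convention [start, stop): a frame exactly on a boundary belongs to the
later interval, so no frame is ever assigned twice.  Alert windows are
excised clock-based: every frame from 1.0 s before alert onset through
alert end is removed, and whatever follows a completed alert within the
same area visit is discarded too (post-alert footage is reward and handler
interaction, not search).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import FRAME_COLUMNS

log = logging.getLogger(__name__)

AREA_BEHAVIOURS = ("area1", "area2", "area3")
ALERT_BEHAVIOUR = "alert"
KNOWN_BEHAVIOURS = AREA_BEHAVIOURS + (ALERT_BEHAVIOUR,)

SUB_LABELS = ("target", "distractor", "no_odour")

#: segments shorter than this after excision are dropped (velocity needs
#: >= 2 frames; clips this short carry no usable wag cycle)
MIN_SEGMENT_SECONDS = 0.5
PRE_ALERT_BUFFER_S = 1.0


@dataclass(frozen=True)
class EventRecord:
    behaviour: str
    start: float
    stop: float

    def __post_init__(self):
        if not self.stop > self.start:
            raise ValueError(f"event {self.behaviour}: stop ({self.stop}) must exceed start ({self.start})")


@dataclass(frozen=True)
class TrialLayout:
    """Per-trial placement of the odours over the three wall areas."""

    trial: int
    mapping: dict[str, str]          # area -> {target, distractor, no_odour}
    outcome: str = "hit"             # {hit, miss, false_alert, correct_rejection}

    def __post_init__(self):
        unknown = set(self.mapping.values()) - set(SUB_LABELS)
        if unknown:
            raise ValueError(f"unknown sub-labels in layout: {sorted(unknown)}")
        n_target = sum(v == "target" for v in self.mapping.values())
        if n_target != 1:
            raise ValueError(f"layout must place exactly one target area, got {n_target}")


@dataclass
class TrajectorySegment:
    """An uninterrupted search of one wall area by one dog."""

    frames: pd.DataFrame             # landmark table, columns FRAME_COLUMNS
    dog_id: str = ""
    session: int = 0
    trial: int = 0
    area: str = ""
    label: str | None = None         # {target, non_target}
    sub_label: str | None = None     # {target, distractor, no_odour}
    test_phase: str = "test1"
    dilution_exponent: int | None = None
    alerted: bool | None = None
    segment_id: str = ""

    def __post_init__(self):
        t = self.frames["t"].to_numpy()
        if len(t) < 2:
            raise ValueError("segment needs >= 2 frames")
        if not np.all(np.diff(t) > 0):
            raise ValueError("segment timestamps must be strictly increasing")
        if self.label is not None and (self.label == "target") != (self.sub_label == "target"):
            raise ValueError("label is 'target' iff sub_label is 'target'")

    @property
    def duration(self) -> float:
        t = self.frames["t"].to_numpy()
        return float(t[-1] - t[0])

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# landmark tables
# ---------------------------------------------------------------------------

def write_landmark_table(frames: pd.DataFrame, path) -> None:
    """Write a landmark table as CSV (full float precision, round-trips exactly)."""
    frames.loc[:, list(FRAME_COLUMNS)].to_csv(path, index=False)


def read_landmark_table(path, sort: bool = False) -> pd.DataFrame:
    """Read a landmark table (CSV, dot decimal, header required).

    Missing landmark cells become NaN (missing, never zero).  Rows with an
    unparseable or missing timestamp are rejected with their line numbers.
    Non-monotone timestamps raise unless ``sort=True``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(FRAME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing required columns {sorted(missing)}")
    df = df[list(FRAME_COLUMNS)]
    for col in FRAME_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[df["t"].isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(f"{path.name}: malformed timestamp on line(s) {lines}")
    t = df["t"].to_numpy()
    if not np.all(np.diff(t) > 0):
        if sort:
            df = df.sort_values("t", kind="stable").reset_index(drop=True)
        else:
            raise ValueError(f"{path.name}: timestamps not strictly increasing (pass sort=True to sort)")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# event logs
# ---------------------------------------------------------------------------

_BEHAVIOUR_ALIASES = {"behaviour", "behavior"}
_START_ALIASES = {"start", "start (s)"}
_STOP_ALIASES = {"stop", "stop (s)"}


def _find_column(columns, aliases, what):
    for c in columns:
        if c.strip().lower() in aliases:
            return c
    raise ValueError(f"event log: no {what} column among {list(columns)}")


def read_event_log(path, unknown: str = "reject", rezero: bool = False) -> list[EventRecord]:
    """Parse a BORIS-style tabular event export (TSV or CSV).

    Columns are matched case-insensitively against behaviour / start / stop
    (BORIS writes "Behavior", "Start (s)", "Stop (s)").  ``unknown``:
    "reject" raises on behaviours outside the ethogram, "pass" keeps them.
    ``rezero=True`` shifts all times so the earliest start is 0 (for
    exports carrying media offsets).  Overlapping area records are an
    error: the areas are mutually exclusive by definition.
    """
    if unknown not in ("reject", "pass"):
        raise ValueError("unknown must be 'reject' or 'pass'")
    df = pd.read_csv(path, sep=None, engine="python")
    bcol = _find_column(df.columns, _BEHAVIOUR_ALIASES, "behaviour")
    scol = _find_column(df.columns, _START_ALIASES, "start")
    ecol = _find_column(df.columns, _STOP_ALIASES, "stop")
    records = []
    for i, row in df.iterrows():
        beh = str(row[bcol]).strip().lower().replace(" ", "")
        if beh not in KNOWN_BEHAVIOURS:
            if unknown == "reject":
                raise ValueError(f"event log line {i + 2}: unknown behaviour {row[bcol]!r}")
            continue
        start, stop = float(row[scol]), float(row[ecol])
        if stop <= start:
            raise ValueError(f"event log line {i + 2}: stop <= start ({stop} <= {start})")
        records.append(EventRecord(beh, start, stop))
    if rezero and records:
        t0 = min(r.start for r in records)
        records = [EventRecord(r.behaviour, r.start - t0, r.stop - t0) for r in records]
    _check_area_overlap(records)
    return records


def _check_area_overlap(records: list[EventRecord]) -> None:
    areas = [(i, r) for i, r in enumerate(records) if r.behaviour in AREA_BEHAVIOURS]
    areas.sort(key=lambda ir: ir[1].start)
    for (i, a), (j, b) in zip(areas, areas[1:]):
        if b.start < a.stop:  # half-open: touching intervals do not overlap
            raise ValueError(
                f"overlapping area events: row {i} ({a.behaviour} {a.start}-{a.stop}) "
                f"and row {j} ({b.behaviour} {b.start}-{b.stop})"
            )


# ---------------------------------------------------------------------------
# segmentation, excision, labelling
# ---------------------------------------------------------------------------

def split_segments(frames: pd.DataFrame, events: list[EventRecord], **meta) -> list[TrajectorySegment]:
    """Split a trial's frames into one segment per area event.

    Frames are assigned by the half-open convention t in [start, stop).
    Candidate segments with fewer than 2 frames are dropped (count stored
    in the returned list's ``.dropped_frames`` via function attribute-free
    logging; conservation is: kept + dropped = frames inside area events).
    """
    area_events = [r for r in events if r.behaviour in AREA_BEHAVIOURS]
    if not area_events:
        raise ValueError("no area events in event log")
    t = frames["t"].to_numpy(dtype=float)
    segments, dropped = [], 0
    for ev in sorted(area_events, key=lambda r: r.start):
        mask = (t >= ev.start) & (t < ev.stop)
        n = int(mask.sum())
        if n < 2:
            dropped += n
            log.info("dropping %d-frame sliver in %s [%g, %g)", n, ev.behaviour, ev.start, ev.stop)
            continue
        segments.append(
            TrajectorySegment(frames=frames.loc[mask].reset_index(drop=True), area=ev.behaviour, **meta)
        )
    split_segments.last_dropped_frames = dropped  # inspectable for conservation checks
    return segments


def excise_alert(
    segments: list[TrajectorySegment],
    events: list[EventRecord],
    pre_buffer: float = PRE_ALERT_BUFFER_S,
    min_duration: float = MIN_SEGMENT_SECONDS,
) -> list[TrajectorySegment]:
    """Remove alert windows (and the post-alert remainder) from segments.

    For every alert event [s, e), frames with t in the half-open window
    [s - pre_buffer, e) are removed (half-open like every other interval
    here, so a frame exactly at the alert's end belongs to whatever
    follows); if the excision cut a segment's interior, only the pre-alert
    part is kept.  Segments left with < 2 frames or shorter than
    ``min_duration`` are dropped.  With no alert events the input is
    returned unchanged.
    """
    alerts = [r for r in events if r.behaviour == ALERT_BEHAVIOUR]
    if not alerts:
        return segments
    out = []
    for seg in segments:
        t = seg.frames["t"].to_numpy(dtype=float)
        keep = np.ones(t.size, dtype=bool)
        for al in alerts:
            lo, hi = al.start - pre_buffer, al.stop
            in_window = (t >= lo) & (t < hi)
            if in_window.any():
                keep &= ~in_window
                keep &= t < lo  # discard the post-alert remainder
        if keep.sum() < 2:
            continue
        sub = seg.frames.loc[keep].reset_index(drop=True)
        cand = replace(seg, frames=sub)
        if cand.duration < min_duration:
            continue
        out.append(cand)
    return out


def label_segments(segments: list[TrajectorySegment], layout: TrialLayout) -> list[TrajectorySegment]:
    """Attach target/non-target labels from the trial layout."""
    out = []
    for seg in segments:
        if seg.area not in layout.mapping:
            raise ValueError(f"segment area {seg.area!r} missing from trial layout {sorted(layout.mapping)}")
        sub = layout.mapping[seg.area]
        out.append(
            replace(
                seg,
                sub_label=sub,
                label="target" if sub == "target" else "non_target",
                alerted=layout.outcome == "hit",
                trial=layout.trial,
            )
        )
    counts = pd.Series([s.label for s in out]).value_counts().to_dict()
    log.info("labelled %d segments: %s", len(out), counts)
    return out


def filter_training_positives(
    segments: list[TrajectorySegment],
    keep_nontarget: bool = True,
    balance: bool = False,
    seed: int | None = None,
) -> list[TrajectorySegment]:
    """Training-set protocol filter.

    Positives are target-area segments from trials where the dog alerted
    correctly; other target segments are excluded.  Non-target segments
    pass through (``keep_nontarget``); ``balance=True`` subsamples them
    without replacement to match the positive count, so that chance
    accuracy is 0.5 for the downstream classifiers.
    """
    if any(s.alerted is None for s in segments):
        raise ValueError("alerted flag not populated; label segments first")
    positives = [s for s in segments if s.label == "target" and s.alerted]
    if not keep_nontarget:
        return positives
    negatives = [s for s in segments if s.label == "non_target"]
    if balance and len(negatives) > len(positives):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(negatives), size=len(positives), replace=False)
        negatives = [negatives[i] for i in sorted(idx)]
    return positives + negatives


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = (
    "segment_id", "dog_id", "session", "trial", "area", "label", "sub_label",
    "test_phase", "dilution_exponent", "alerted", "n_frames", "duration",
)


def segment_metadata(segments: list[TrajectorySegment]) -> pd.DataFrame:
    rows = [
        {
            "segment_id": s.segment_id,
            "dog_id": s.dog_id,
            "session": s.session,
            "trial": s.trial,
            "area": s.area,
            "label": s.label,
            "sub_label": s.sub_label,
            "test_phase": s.test_phase,
            "dilution_exponent": s.dilution_exponent,
            "alerted": s.alerted,
            "n_frames": s.n_frames,
            "duration": s.duration,
        }
        for s in segments
    ]
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))


def write_metadata(segments: list[TrajectorySegment], path) -> None:
    segment_metadata(segments).to_csv(path, index=False)
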