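"""Data model and I/O for breath/distortion annotation streams.

An annotation stream is the sequence of timestamped marks one reviewer
placed on one video: certain breaths, uncertain breaths, and distortion
boundaries.  Streams are keyed by ``(video_id, reviewer_id)``.  All times
are seconds from the start of the video; every interval in this package is
half-open ``[start, end)`` so that calm and distorted durations add up to
the considered window length exactly.

Two distortion dialects are supported:

``paired``
    Distortions are recorded as explicit ``distortion_start`` /
    ``distortion_end`` event pairs (the default).
``moment``
    Distortions are recorded as instantaneous ``distortion`` marks; maximal
    runs of marks closer than ``gap_threshold_s`` become one interval, and
    an isolated mark expands to +/- ``moment_halfwidth_s`` around itself.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkKind",
    "AgeGroup",
    "AnnotationMark",
    "ConsideredWindow",
    "VideoMeta",
    "DistortedPeriod",
    "AnnotationFormatError",
    "AnnotationValidationError",
    "DistortionPairingError",
    "read_annotations",
    "write_annotations",
    "read_videos",
    "write_videos",
    "canonical_distorted_periods",
    "merge_periods",
    "total_distorted_s",
    "qc_video_eligibility",
]


class MarkKind(str, enum.Enum):
    """Kinds of timestamped reviewer events."""

    CERTAIN_BREATH = "certain"
    UNCERTAIN_BREATH = "uncertain"
    DISTORTION_START = "distortion_start"
    DISTORTION_END = "distortion_end"
    #: single instantaneous distortion mark ("moment" dialect only)
    DISTORTION_MARK = "distortion"


BREATH_KINDS = frozenset({MarkKind.CERTAIN_BREATH, MarkKind.UNCERTAIN_BREATH})


class AgeGroup(str, enum.Enum):
    """IMCI age strata for fast-breathing cut-offs."""

    LT2M = "lt2m"
    M2_11 = "2-11m"
    M12_59 = "12-59m"


class AnnotationFormatError(ValueError):
    """The annotation table does not have the expected shape/columns."""


class AnnotationValidationError(ValueError):
    """A row violates an annotation invariant (e.g. negative time)."""


class DistortionPairingError(ValueError):
    """Distortion start/end marks cannot be paired under strict policy."""


@dataclass(frozen=True, order=True)
class AnnotationMark:
    """One timestamped reviewer event on a video timeline."""

    time_s: float
    kind: MarkKind = field(compare=False)
    video_id: str = field(compare=False)
    reviewer_id: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise AnnotationValidationError(
                f"negative time {self.time_s} for video={self.video_id} "
                f"reviewer={self.reviewer_id}"
            )


@dataclass(frozen=True)
class ConsideredWindow:
    """Half-open time window ``[start_s, end_s)`` scored for one video.

    The window comes from video metadata and is identical for every
    reviewer of the video, so all reviewers' calm periods are computed
    over the same denominator base.
    """

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise AnnotationValidationError(f"window start {self.start_s} < 0")
        if self.end_s <= self.start_s:
            raise AnnotationValidationError(
                f"window [{self.start_s}, {self.end_s}) has non-positive length"
            )

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass(frozen=True)
class VideoMeta:
    """Per-video metadata: age stratum and the considered window."""

    video_id: str
    age_group: AgeGroup
    window: ConsideredWindow
    sex: str | None = None
    country: str | None = None
    #: reviewer annotation time as a multiple of the window length
    time_taken_multiple: float | None = None


@dataclass(frozen=True)
class DistortedPeriod:
    """Half-open interval ``[start_s, end_s)`` of distorted (excluded) time."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise AnnotationValidationError(
                f"distorted period [{self.start_s}, {self.end_s}) is empty"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = ["video_id", "reviewer_id", "time_s", "kind"]
_VIDEO_COLUMNS = ["video_id", "age_group", "window_start_s", "window_end_s"]

Streams = dict[tuple[str, str], list[AnnotationMark]]


def _to_marks(df: pd.DataFrame) -> Streams:
    kinds = {k.value: k for k in MarkKind}
    bad = set(df["kind"].astype(str)) - set(kinds)
    if bad:
        raise AnnotationFormatError(f"unknown annotation kinds: {sorted(bad)}")
    neg = df.index[df["time_s"].astype(float) < 0]
    if len(neg):
        raise AnnotationValidationError(
            f"negative time_s at table row(s) {list(neg[:5])}"
        )
    streams: Streams = {}
    for (vid, rid), grp in df.groupby(["video_id", "reviewer_id"], sort=True):
        grp = grp.sort_values("time_s", kind="stable")
        times = grp["time_s"].astype(float).to_numpy()
        ks = [kinds[k] for k in grp["kind"].astype(str)]
        # two breath marks may not share a timestamp within one stream
        seen: dict[float, MarkKind] = {}
        for t, k in zip(times, ks):
            if k in BREATH_KINDS and t in seen:
                raise AnnotationValidationError(
                    f"duplicate breath timestamp {t} in stream "
                    f"(video={vid}, reviewer={rid})"
                )
            if k in BREATH_KINDS:
                seen[t] = k
        streams[(str(vid), str(rid))] = [
            AnnotationMark(time_s=float(t), kind=k, video_id=str(vid), reviewer_id=str(rid))
            for t, k in zip(times, ks)
        ]
    return streams


def read_annotations(path: str | Path, sep: str = ",") -> Streams:
    """Read an annotation table into validated, time-sorted streams.

    The table must have columns ``video_id, reviewer_id, time_s, kind`` with
    ``kind`` one of ``certain, uncertain, distortion_start, distortion_end``
    (or ``distortion`` in the moment dialect).  Marks are returned grouped by
    ``(video_id, reviewer_id)`` and sorted by time within each stream.
    """
    df = pd.read_csv(
        path, sep=sep, dtype={"video_id": str, "reviewer_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationFormatError(f"annotation table missing column(s) {missing}")
    return _to_marks(df)


def annotations_frame(streams: Streams | Iterable[AnnotationMark]) -> pd.DataFrame:
    """Flatten streams (or an iterable of marks) into a tidy table."""
    if isinstance(streams, Mapping):
        marks: Iterable[AnnotationMark] = (m for s in streams.values() for m in s)
    else:
        marks = streams
    rows = [(m.video_id, m.reviewer_id, m.time_s, m.kind.value) for m in marks]
    return pd.DataFrame(rows, columns=_ANNOT_COLUMNS)


def write_annotations(streams: Streams | pd.DataFrame, path: str | Path) -> None:
    """Write streams to CSV; float times round-trip at full precision."""
    df = streams if isinstance(streams, pd.DataFrame) else annotations_frame(streams)
    df.to_csv(path, index=False)


def read_videos(path: str | Path, sep: str = ",") -> dict[str, VideoMeta]:
    """Read per-video metadata keyed by ``video_id``."""
    df = pd.read_csv(path, sep=sep, dtype={"video_id": str})
    missing = [c for c in _VIDEO_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationFormatError(f"video table missing column(s) {missing}")
    groups = {g.value: g for g in AgeGroup}
    metas: dict[str, VideoMeta] = {}
    for _, row in df.iterrows():
        ag = str(row["age_group"])
        if ag not in groups:
            raise AnnotationValidationError(
                f"unknown age_group {ag!r} for video {row['video_id']}"
            )
        metas[str(row["video_id"])] = VideoMeta(
            video_id=str(row["video_id"]),
            age_group=groups[ag],
            window=ConsideredWindow(float(row["window_start_s"]), float(row["window_end_s"])),
            sex=str(row["sex"]) if "sex" in df.columns and pd.notna(row.get("sex")) else None,
            country=str(row["country"])
            if "country" in df.columns and pd.notna(row.get("country"))
            else None,
            time_taken_multiple=float(row["time_taken_multiple"])
            if "time_taken_multiple" in df.columns and pd.notna(row.get("time_taken_multiple"))
            else None,
        )
    return metas


def write_videos(metas: Mapping[str, VideoMeta] | Iterable[VideoMeta], path: str | Path) -> None:
    if isinstance(metas, Mapping):
        metas = metas.values()
    rows = [
        {
            "video_id": m.video_id,
            "age_group": m.age_group.value,
            "window_start_s": m.window.start_s,
            "window_end_s": m.window.end_s,
            "sex": m.sex,
            "country": m.country,
            "time_taken_multiple": m.time_taken_multiple,
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Distorted-period canonicalization
# ---------------------------------------------------------------------------

def merge_periods(
    intervals: Iterable[tuple[float, float]], window: ConsideredWindow
) -> list[DistortedPeriod]:
    """Clip raw intervals to the window, drop empties, merge overlaps/adjacency."""
    clipped = []
    for s, e in intervals:
        s = max(s, window.start_s)
        e = min(e, window.end_s)
        if e > s:
            clipped.append((s, e))
    clipped.sort()
    merged: list[list[float]] = []
    for s, e in clipped:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [DistortedPeriod(s, e) for s, e in merged]


def canonical_distorted_periods(
    stream: Sequence[AnnotationMark],
    window: ConsideredWindow,
    policy: str = "strict",
    dialect: str = "paired",
    gap_threshold_s: float = 2.0,
    moment_halfwidth_s: float = 0.5,
) -> list[DistortedPeriod]:
    """Turn a reviewer's distortion marks into sorted disjoint periods.

    Parameters
    ----------
    policy
        ``strict`` raises :class:`DistortionPairingError` on an end mark with
        no open start, or a start mark left open at the end of the stream.
        ``lenient`` drops dangling ends and closes dangling starts at the
        window end, logging a warning for each repair.
    dialect
        ``paired`` pairs ``distortion_start``/``distortion_end`` events in
        time order (nesting/overlap allowed; the union is taken).  ``moment``
        clusters instantaneous ``distortion`` marks: runs with consecutive
        gaps below ``gap_threshold_s`` span ``[first, last)`` and isolated
        marks expand to ``+/- moment_halfwidth_s``.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"policy must be 'strict' or 'lenient', got {policy!r}")
    if dialect not in ("paired", "moment"):
        raise ValueError(f"dialect must be 'paired' or 'moment', got {dialect!r}")

    marks = sorted(stream, key=lambda m: m.time_s)
    raw: list[tuple[float, float]] = []
    if dialect == "paired":
        depth = 0
        open_at = 0.0
        for m in marks:
            if m.kind is MarkKind.DISTORTION_START:
                if depth == 0:
                    open_at = m.time_s
                depth += 1
            elif m.kind is MarkKind.DISTORTION_END:
                if depth == 0:
                    if policy == "strict":
                        raise DistortionPairingError(
                            f"distortion_end at {m.time_s}s with no open start "
                            f"(video={m.video_id}, reviewer={m.reviewer_id})"
                        )
                    logger.warning(
                        "dropping dangling distortion_end at %.3fs (video=%s, reviewer=%s)",
                        m.time_s, m.video_id, m.reviewer_id,
                    )
                    continue
                depth -= 1
                if depth == 0:
                    raw.append((open_at, m.time_s))
        if depth > 0:
            if policy == "strict":
                raise DistortionPairingError(
                    f"{depth} unclosed distortion_start mark(s) at end of stream"
                )
            logger.warning(
                "closing unclosed distortion_start at %.3fs at window end %.3fs",
                open_at, window.end_s,
            )
            raw.append((open_at, window.end_s))
    else:
        times = [m.time_s for m in marks if m.kind is MarkKind.DISTORTION_MARK]
        run: list[float] = []
        for t in times:
            if run and t - run[-1] >= gap_threshold_s:
                raw.append(_moment_run(run, moment_halfwidth_s))
                run = []
            run.append(t)
        if run:
            raw.append(_moment_run(run, moment_halfwidth_s))
    return merge_periods(raw, window)


def _moment_run(run: list[float], halfwidth: float) -> tuple[float, float]:
    if len(run) == 1:
        return (run[0] - halfwidth, run[0] + halfwidth)
    return (run[0], run[-1])


def total_distorted_s(periods: Iterable[DistortedPeriod]) -> float:
    return sum(p.duration_s for p in periods)


def qc_video_eligibility(
    periods: Iterable[DistortedPeriod], max_distortion_s: float = 30.0
) -> bool:
    """Eligibility rule: a video with more than ``max_distortion_s`` seconds
    of distortion is excluded.  The bound itself is still eligible."""
    return total_distorted_s(periods) <= max_distortion_s
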