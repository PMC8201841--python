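"""Respiratory rate from certain-breath marks over distortion-excluded time.

The rate for one reviewer-video is

    RR (bpm) = 60 * (full cycles + fractional boundary cycles) / calm seconds

where a *breath cycle* is the interval between two consecutive certain-breath
marks inside one calm segment, and the partial gaps between a calm segment's
edges and its first/last breath count as fractions of a reference cycle
length.  Calm segments are the considered window minus the reviewer's
distorted periods; uncertain breaths are counted but never enter the
numerator, and breaths falling inside a distorted period are shadowed
(recorded but excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    AgeGroup,
    AnnotationMark,
    ConsideredWindow,
    DistortedPeriod,
    MarkKind,
    VideoMeta,
    canonical_distorted_periods,
    total_distorted_s,
)

__all__ = [
    "CalmSegment",
    "FastBreathingCutoffs",
    "RRResult",
    "NoCalmPeriodError",
    "calm_segments",
    "reference_cycle_length",
    "compute_rr",
    "compute_all",
    "classify_fast_breathing",
    "annotation_summary",
]


class NoCalmPeriodError(ValueError):
    """Distortion covers the whole window; RR is undefined."""


@dataclass(frozen=True)
class CalmSegment:
    """A maximal undistorted interval with the certain breaths inside it."""

    start_s: float
    end_s: float
    breath_times: tuple[float, ...]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class FastBreathingCutoffs:
    """Age-specific fast-breathing thresholds (bpm), IMCI convention.

    ``rr >= threshold`` classifies as fast.  Defaults: 60 bpm below two
    months, 50 bpm for 2-11 months, 40 bpm for 12-59 months.
    """

    thresholds_bpm: Mapping[AgeGroup, float] = field(
        default_factory=lambda: {
            AgeGroup.LT2M: 60.0,
            AgeGroup.M2_11: 50.0,
            AgeGroup.M12_59: 40.0,
        }
    )

    def __post_init__(self) -> None:
        vals = [self.thresholds_bpm[g] for g in (AgeGroup.LT2M, AgeGroup.M2_11, AgeGroup.M12_59)]
        if not (vals[0] > vals[1] > vals[2]):
            raise ValueError(
                f"thresholds must decrease strictly with age group, got {vals}"
            )


@dataclass
class RRResult:
    """Per reviewer-video respiratory-rate accounting."""

    video_id: str
    reviewer_id: str
    rr_bpm: float | None
    n_full_cycles: int
    fractional_breaths: float
    calm_duration_s: float
    distorted_fraction: float
    n_certain: int
    n_uncertain: int
    n_shadowed: int
    classification: str | None  # "normal" | "fast" | None when RR undefined
    warnings: list[str] = field(default_factory=list)


def calm_segments(
    window: ConsideredWindow,
    periods: Sequence[DistortedPeriod],
    certain_times: Sequence[float],
) -> list[CalmSegment]:
    """Partition ``window`` minus ``periods`` into segments with their breaths.

    Breath times inside a distorted period (half-open: the period's start
    belongs to it, its end to the following calm segment) or outside the
    window are assigned to no segment.
    """
    bounds: list[tuple[float, float]] = []
    cursor = window.start_s
    for p in periods:
        if p.start_s > cursor:
            bounds.append((cursor, p.start_s))
        cursor = max(cursor, p.end_s)
    if cursor < window.end_s:
        bounds.append((cursor, window.end_s))
    times = np.asarray(sorted(certain_times), dtype=float)
    segments = []
    for s, e in bounds:
        inside = times[(times >= s) & (times < e)]
        segments.append(CalmSegment(s, e, tuple(inside.tolist())))
    return segments


def reference_cycle_length(
    segment: CalmSegment, all_segments: Sequence[CalmSegment]
) -> float | None:
    """Cycle length used to convert boundary gaps into fractional breaths.

    Mean inter-breath gap within the segment when it holds at least two
    breaths; otherwise the mean over all full cycles in every segment of
    this reviewer-video; ``None`` when no full cycle exists anywhere.
    """
    if len(segment.breath_times) >= 2:
        return float(np.mean(np.diff(segment.breath_times)))
    gaps: list[float] = []
    for seg in all_segments:
        if len(seg.breath_times) >= 2:
            gaps.extend(np.diff(seg.breath_times).tolist())
    if gaps:
        return float(np.mean(gaps))
    return None


def classify_fast_breathing(
    rr_bpm: float,
    age_group: AgeGroup,
    cutoffs: FastBreathingCutoffs | None = None,
) -> str:
    """``"fast"`` iff the rate reaches the age group's threshold (inclusive)."""
    cutoffs = cutoffs or FastBreathingCutoffs()
    try:
        thr = cutoffs.thresholds_bpm[age_group]
    except KeyError:
        raise ValueError(f"unknown age group {age_group!r}") from None
    return "fast" if rr_bpm >= thr else "normal"


def compute_rr(
    stream: Sequence[AnnotationMark],
    meta: VideoMeta,
    cutoffs: FastBreathingCutoffs | None = None,
    *,
    policy: str = "strict",
    dialect: str = "paired",
    fraction_warn_threshold: float = 1.5,
) -> RRResult:
    """Compute one reviewer's RR for one video.

    Each calm segment with ``m >= 1`` breaths contributes ``m - 1`` full
    cycles plus head and tail fractions ``gap / reference_cycle`` (uncapped;
    a warning is recorded when a fraction exceeds ``fraction_warn_threshold``).
    Segments without breaths contribute nothing to the numerator but their
    full duration stays in the denominator.

    Raises
    ------
    NoCalmPeriodError
        When distortion covers the entire considered window.
    """
    window = meta.window
    periods = canonical_distorted_periods(stream, window, policy=policy, dialect=dialect)
    warnings: list[str] = []

    certain_all = [m.time_s for m in stream if m.kind is MarkKind.CERTAIN_BREATH]
    n_uncertain = sum(
        1
        for m in stream
        if m.kind is MarkKind.UNCERTAIN_BREATH and window.contains(m.time_s)
    )
    certain_in = [t for t in certain_all if window.contains(t)]
    shadowed_set = {t for t in certain_in if any(p.contains(t) for p in periods)}
    shadowed = sorted(shadowed_set)
    if shadowed:
        warnings.append(f"{len(shadowed)} certain breath(s) inside distorted periods")

    distorted_s = total_distorted_s(periods)
    calm_duration = window.length_s - distorted_s
    distorted_fraction = distorted_s / window.length_s
    if calm_duration <= 0:
        raise NoCalmPeriodError(
            f"no calm period: distortion covers window of video {meta.video_id} "
            f"(reviewer {stream[0].reviewer_id if stream else '?'})"
        )

    segments = calm_segments(window, periods, [t for t in certain_in if t not in shadowed_set])
    n_full = 0
    frac = 0.0
    for seg in segments:
        m = len(seg.breath_times)
        if m == 0:
            continue
        n_full += m - 1
        ref = reference_cycle_length(seg, segments)
        if ref is None:
            warnings.append(
                f"no full breath cycle anywhere; boundary fractions of segment "
                f"[{seg.start_s:g},{seg.end_s:g}) set to 0"
            )
            continue
        head = (seg.breath_times[0] - seg.start_s) / ref
        tail = (seg.end_s - seg.breath_times[-1]) / ref
        for name, f in (("head", head), ("tail", tail)):
            if f > fraction_warn_threshold:
                warnings.append(
                    f"{name} fraction {f:.2f} > {fraction_warn_threshold:g} in "
                    f"segment [{seg.start_s:g},{seg.end_s:g})"
                )
        frac += head + tail

    rr = 60.0 * (n_full + frac) / calm_duration
    return RRResult(
        video_id=meta.video_id,
        reviewer_id=stream[0].reviewer_id if stream else "",
        rr_bpm=rr,
        n_full_cycles=n_full,
        fractional_breaths=frac,
        calm_duration_s=calm_duration,
        distorted_fraction=distorted_fraction,
        n_certain=len(certain_in),
        n_uncertain=n_uncertain,
        n_shadowed=len(shadowed),
        classification=classify_fast_breathing(rr, meta.age_group, cutoffs),
        warnings=warnings,
    )


def compute_all(
    streams: Mapping[tuple[str, str], Sequence[AnnotationMark]],
    metas: Mapping[str, VideoMeta],
    cutoffs: FastBreathingCutoffs | None = None,
    **kwargs,
) -> list[RRResult]:
    """Run :func:`compute_rr` over every stream; a stream whose window is
    fully distorted yields a record with ``rr_bpm=None`` (a missing cell
    downstream) instead of aborting the batch."""
    results = []
    for (vid, rid), stream in streams.items():
        meta = metas[vid]
        try:
            results.append(compute_rr(stream, meta, cutoffs, **kwargs))
        except NoCalmPeriodError as exc:
            periods = canonical_distorted_periods(
                stream, meta.window,
                policy=kwargs.get("policy", "strict"),
                dialect=kwargs.get("dialect", "paired"),
            )
            results.append(
                RRResult(
                    video_id=vid,
                    reviewer_id=rid,
                    rr_bpm=None,
                    n_full_cycles=0,
                    fractional_breaths=0.0,
                    calm_duration_s=0.0,
                    distorted_fraction=total_distorted_s(periods) / meta.window.length_s,
                    n_certain=sum(1 for m in stream if m.kind is MarkKind.CERTAIN_BREATH),
                    n_uncertain=sum(1 for m in stream if m.kind is MarkKind.UNCERTAIN_BREATH),
                    n_shadowed=0,
                    classification=None,
                    warnings=[str(exc)],
                )
            )
    return results


def results_frame(results: Iterable[RRResult]) -> pd.DataFrame:
    """Tidy table of RR results, one row per reviewer-video."""
    rows = []
    for r in results:
        rows.append(
            {
                "video_id": r.video_id,
                "reviewer_id": r.reviewer_id,
                "rr_bpm": r.rr_bpm,
                "n_full_cycles": r.n_full_cycles,
                "fractional_breaths": r.fractional_breaths,
                "calm_duration_s": r.calm_duration_s,
                "distorted_fraction": r.distorted_fraction,
                "n_certain": r.n_certain,
                "n_uncertain": r.n_uncertain,
                "n_shadowed": r.n_shadowed,
                "classification": r.classification,
                "warnings": "; ".join(r.warnings),
            }
        )
    return pd.DataFrame(rows)


def annotation_summary(
    results: Iterable[RRResult], metas: Mapping[str, VideoMeta]
) -> pd.DataFrame:
    """Cohort-level annotation summary (mean/SD rows).

    Reports window length, reviewer time-taken multiple when present,
    per-video mean distorted fraction, and RR overall and per age group —
    the descriptive measures one tabulates for an annotated video set.
    """
    df = results_frame(results)
    if df.empty:
        raise ValueError("no results to summarize")
    per_video = df.groupby("video_id").agg(
        mean_rr=("rr_bpm", "mean"),
        mean_distorted_fraction=("distorted_fraction", "mean"),
    )
    per_video["age_group"] = [metas[v].age_group.value for v in per_video.index]
    wins = [metas[v].window.length_s for v in per_video.index]
    rows = [
        _stat_row("considered_window_s", "all", wins),
        _stat_row(
            "distorted_fraction", "all", per_video["mean_distorted_fraction"].to_numpy()
        ),
        _stat_row("rr_bpm", "all", df["rr_bpm"].dropna().to_numpy()),
    ]
    ttm = [
        metas[v].time_taken_multiple
        for v in per_video.index
        if metas[v].time_taken_multiple is not None
    ]
    if ttm:
        rows.append(_stat_row("time_taken_multiple", "all", ttm))
    for g in AgeGroup:
        vids = per_video.index[per_video["age_group"] == g.value]
        sub = df[df["video_id"].isin(vids)]["rr_bpm"].dropna().to_numpy()
        if len(sub):
            rows.append(_stat_row("rr_bpm", g.value, sub))
    return pd.DataFrame(rows, columns=["measure", "group", "n", "mean", "sd"])


def _stat_row(measure: str, group: str, values) -> tuple:
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return (measure, group, len(arr), float(np.mean(arr)), sd)
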