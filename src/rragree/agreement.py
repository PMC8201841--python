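"""Interrater reliability and agreement statistics on the RR matrix.

The unit of analysis is a videos x rater-slot matrix of respiratory rates
(and, in parallel, binary fast-breathing classifications).  Because each
video's raters were drawn at random from a larger panel, slots carry no
rater identity and the default reliability model is a one-way
random-effects ANOVA with videos as groups:

* SEM = sqrt(MS_within), the absolute measurement error in bpm, with a
  chi-square confidence interval on sigma_within,
* ICC(1) = (MS_b - MS_w) / (MS_b + (k0 - 1) MS_w)  (Searle's unbalanced
  one-way form, k0 the adjusted replicate count),
* Fleiss' kappa and the all-raters-agree proportion for the binary
  classification,
* Kruskal-Wallis and Dunn/Holm comparisons for stratified contrasts.

A two-way crossed model (raters as a second random factor) is provided for
datasets where every rater scored every video.
"""

from __future__ import annotations

import itertools
import logging
import warnings as _pywarnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AgeGroup, VideoMeta
from .rr import RRResult

logger = logging.getLogger(__name__)

__all__ = [
    "RRMatrix",
    "SemResult",
    "AgreementReport",
    "build_matrix",
    "sem_oneway",
    "sem_twoway",
    "icc_oneway",
    "variance_components_oneway",
    "fleiss_kappa",
    "fleiss_kappa_from_classifications",
    "kappa_band",
    "all_agree_proportion",
    "distortion_tertiles",
    "stratified_agreement",
    "kruskal_wallis",
    "dunn_holm",
]

KAPPA_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass
class RRMatrix:
    """Videos x rater-slot rates with parallel binary classifications.

    ``values``: float array (n_videos, k) with NaN for missing cells;
    ``classifications``: float array with 1.0 = fast, 0.0 = normal, NaN
    missing; slots are ordered by reviewer id per video but carry no
    cross-video rater identity.
    """

    values: np.ndarray
    classifications: np.ndarray
    video_ids: list[str]
    age_groups: list[AgeGroup]
    distorted_fractions: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.classifications = np.asarray(self.classifications, dtype=float)
        self.distorted_fractions = np.asarray(self.distorted_fractions, dtype=float)
        if self.values.shape != self.classifications.shape:
            raise ValueError("values and classifications shapes differ")

    @property
    def n_videos(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SemResult:
    sem: float
    ci_lower: float
    ci_upper: float
    df: int
    ms_within: float


@dataclass
class AgreementReport:
    """Agreement statistics for one stratum of videos."""

    stratum: str
    n_videos: int
    sem: float | None
    sem_ci: tuple[float, float] | None
    icc: float | None
    fleiss_kappa: float | None
    kappa_band: str | None
    prop_all_agree: float | None
    n_all_agree: int | None
    insufficient: bool = False


def build_matrix(
    results: Iterable[RRResult],
    metas: Mapping[str, VideoMeta],
    k: int = 5,
) -> RRMatrix:
    """Assemble per-reviewer results into the videos x slots matrix.

    Within each video, reviewers fill slots in sorted reviewer-id order (a
    deterministic but arbitrary choice, since slots are exchangeable).  A
    reviewer with undefined RR leaves a NaN cell.
    """
    by_video: dict[str, list[RRResult]] = {}
    for r in results:
        by_video.setdefault(r.video_id, []).append(r)
    video_ids = sorted(by_video)
    values = np.full((len(video_ids), k), np.nan)
    classif = np.full((len(video_ids), k), np.nan)
    dist = np.zeros(len(video_ids))
    ages = []
    for i, vid in enumerate(video_ids):
        rows = sorted(by_video[vid], key=lambda r: r.reviewer_id)
        if len(rows) > k:
            raise ValueError(f"video {vid} has {len(rows)} reviewers > k={k}")
        for j, r in enumerate(rows):
            if r.rr_bpm is not None:
                values[i, j] = r.rr_bpm
                classif[i, j] = 1.0 if r.classification == "fast" else 0.0
        dist[i] = float(np.mean([r.distorted_fraction for r in rows]))
        ages.append(metas[vid].age_group)
    return RRMatrix(values, classif, video_ids, ages, dist, k)


def _usable_rows(values: np.ndarray, min_per_row: int = 2) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    counts = np.sum(~np.isnan(values), axis=1)
    keep = counts >= min_per_row
    n_drop = int(np.sum(~keep))
    if n_drop:
        logger.warning(
            "dropping %d row(s) with fewer than %d ratings (pairwise deletion)",
            n_drop, min_per_row,
        )
    return values[keep]


def sem_oneway(matrix: RRMatrix | np.ndarray, alpha: float = 0.05) -> SemResult:
    """Standard error of measurement from one-way random-effects ANOVA.

    SEM = sqrt(MS_within) with df = sum_i (k_i - 1).  The 95% CI follows
    the chi-square interval for a variance:

        [ sqrt(df * MS_w / chi2_{1-alpha/2, df}),
          sqrt(df * MS_w / chi2_{alpha/2, df}) ]

    The *upper* chi-square quantile gives the *lower* limit.  Rows with
    fewer than two ratings are dropped (pairwise deletion).
    """
    values = matrix.values if isinstance(matrix, RRMatrix) else matrix
    rows = _usable_rows(values)
    if rows.shape[0] < 1:
        raise ValueError("no rows with >= 2 ratings")
    with _pywarnings.catch_warnings():
        _pywarnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.nanmean(rows, axis=1)
    ss_within = float(np.nansum((rows - row_means[:, None]) ** 2))
    df = int(np.sum(~np.isnan(rows)) - rows.shape[0])
    if df == 0:
        raise ValueError("zero within-video degrees of freedom")
    ms_within = ss_within / df
    sem = float(np.sqrt(ms_within))
    lower = float(np.sqrt(df * ms_within / stats.chi2.ppf(1 - alpha / 2, df)))
    upper = float(np.sqrt(df * ms_within / stats.chi2.ppf(alpha / 2, df)))
    return SemResult(sem, lower, upper, df, ms_within)


def variance_components_oneway(
    values: np.ndarray,
) -> tuple[float, float, float]:
    """One-way ANOVA mean squares ``(ms_between, ms_within, k0)``.

    ``k0`` is Searle's adjusted replicate count for unbalanced designs,
    ``(N - sum k_i^2 / N) / (n - 1)``; it equals ``k`` in the balanced case.
    """
    rows = _usable_rows(values)
    n = rows.shape[0]
    if n < 2:
        raise ValueError("need >= 2 videos for between-video variance")
    k_i = np.sum(~np.isnan(rows), axis=1).astype(float)
    N = float(k_i.sum())
    row_means = np.nanmean(rows, axis=1)
    grand = float(np.nansum(rows) / N)
    ms_between = float(np.sum(k_i * (row_means - grand) ** 2) / (n - 1))
    ss_within = float(np.nansum((rows - row_means[:, None]) ** 2))
    df_w = int(N - n)
    if df_w == 0:
        raise ValueError("zero within-video degrees of freedom")
    ms_within = ss_within / df_w
    k0 = float((N - np.sum(k_i**2) / N) / (n - 1))
    return ms_between, ms_within, k0


def icc_oneway(matrix: RRMatrix | np.ndarray) -> float:
    """ICC(1): proportion of total variance due to true between-video
    differences.  Satisfies ``SEM^2 = SD_total^2 * (1 - ICC)`` with the
    variance-component estimate ``SD_total^2 = sigma_b^2 + MS_within``."""
    values = matrix.values if isinstance(matrix, RRMatrix) else matrix
    msb, msw, k0 = variance_components_oneway(values)
    denom = msb + (k0 - 1.0) * msw
    if denom == 0:
        return float("nan")
    return float((msb - msw) / denom)


def sem_twoway(matrix: RRMatrix | np.ndarray, alpha: float = 0.05) -> SemResult:
    """SEM from a two-way crossed design (videos x raters, both random).

    Residual mean square after removing video and rater-slot main effects;
    requires a complete matrix (every slot filled for every video).  Useful
    when the same raters scored all videos, so slot means are meaningful.
    """
    values = matrix.values if isinstance(matrix, RRMatrix) else matrix
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("two-way crossed SEM requires a complete matrix")
    n, k = values.shape
    grand = values.mean()
    row_eff = values.mean(axis=1) - grand
    col_eff = values.mean(axis=0) - grand
    resid = values - grand - row_eff[:, None] - col_eff[None, :]
    df = (n - 1) * (k - 1)
    if df == 0:
        raise ValueError("two-way residual has zero degrees of freedom")
    ms_resid = float(np.sum(resid**2) / df)
    sem = float(np.sqrt(ms_resid))
    lower = float(np.sqrt(df * ms_resid / stats.chi2.ppf(1 - alpha / 2, df)))
    upper = float(np.sqrt(df * ms_resid / stats.chi2.ppf(alpha / 2, df)))
    return SemResult(sem, lower, upper, df, ms_resid)


# ---------------------------------------------------------------------------
# Categorical agreement
# ---------------------------------------------------------------------------

def fleiss_kappa(counts: np.ndarray) -> float | None:
    """Fleiss' kappa from an (n_subjects, n_categories) count table.

    Every subject must have the same number of ratings k >= 2.  Returns
    ``None`` (undefined, 0/0) when all ratings fall in a single category.
    """
    counts = np.asarray(counts, dtype=float)
    k_i = counts.sum(axis=1)
    if counts.shape[0] == 0:
        raise ValueError("empty count table")
    k = k_i[0]
    if k < 2 or not np.all(k_i == k):
        raise ValueError("all subjects must have the same number of ratings >= 2")
    n = counts.shape[0]
    p_i = (np.sum(counts**2, axis=1) - k) / (k * (k - 1))
    p_bar = float(np.mean(p_i))
    p_j = counts.sum(axis=0) / (n * k)
    p_e = float(np.sum(p_j**2))
    if p_e == 1.0:
        return None
    return float((p_bar - p_e) / (1.0 - p_e))


def _counts_from_classifications(
    classifications: np.ndarray, k: int, policy: str
) -> np.ndarray:
    cls = np.asarray(classifications, dtype=float)
    n_rated = np.sum(~np.isnan(cls), axis=1)
    rows = cls[n_rated >= 2]
    n_rated = n_rated[n_rated >= 2]
    if rows.shape[0] == 0:
        raise ValueError("no videos with >= 2 classifications")
    if policy == "exclude":
        keep = n_rated == k
        n_drop = int(np.sum(~keep))
        if n_drop:
            logger.warning(
                "kappa: excluding %d video(s) with fewer than %d ratings", n_drop, k
            )
        rows = rows[keep]
        if rows.shape[0] == 0:
            raise ValueError(f"no videos with the full {k} ratings")
        k_common = k
    elif policy == "reduce":
        k_common = int(n_rated.min())
        trimmed = np.full((rows.shape[0], k_common), np.nan)
        for i, row in enumerate(rows):
            vals = row[~np.isnan(row)][:k_common]  # first slots, deterministic
            trimmed[i] = vals
        rows = trimmed
    else:
        raise ValueError(f"policy must be 'exclude' or 'reduce', got {policy!r}")
    fast = np.nansum(rows, axis=1)
    normal = k_common - fast
    return np.column_stack([normal, fast])


def fleiss_kappa_from_classifications(
    classifications: np.ndarray, k: int, policy: str = "exclude"
) -> float | None:
    """Kappa on a binary classification matrix with possible missing cells.

    ``policy='exclude'`` (default) drops videos with fewer than ``k``
    ratings; ``policy='reduce'`` analyses all videos at the smallest common
    rating count, trimming extra ratings in slot order.
    """
    return fleiss_kappa(_counts_from_classifications(classifications, k, policy))


def kappa_band(kappa: float) -> str:
    """Verbal interpretation band for a kappa value.

    Negative kappa is "poor"; the published band edges 0.20 / 0.40 / 0.60 /
    0.80 are inclusive upper limits, and the nominal gap below 0.01 is
    closed downward into "slight".
    """
    if kappa < 0:
        return "poor"
    for upper, label in KAPPA_BANDS:
        if kappa <= upper:
            return label
    return "almost perfect"


def all_agree_proportion(classifications: np.ndarray) -> tuple[float, int, int]:
    """Fraction of videos whose non-missing classifications are unanimous.

    Returns ``(proportion, n_unanimous, n_videos)`` over videos with at
    least one classification.
    """
    cls = np.asarray(classifications, dtype=float)
    rated = np.sum(~np.isnan(cls), axis=1) >= 1
    cls = cls[rated]
    if cls.shape[0] == 0:
        raise ValueError("no classified videos")
    with _pywarnings.catch_warnings():
        _pywarnings.simplefilter("ignore", RuntimeWarning)
        unanimous = np.nanmax(cls, axis=1) == np.nanmin(cls, axis=1)
    n_agree = int(np.sum(unanimous))
    return n_agree / cls.shape[0], n_agree, cls.shape[0]


# ---------------------------------------------------------------------------
# Stratified reports
# ---------------------------------------------------------------------------

def distortion_tertiles(fractions: Sequence[float]) -> np.ndarray:
    """Split videos into lowest/medium/highest distortion tertiles.

    Videos are ranked by mean distorted fraction (ties broken by stable
    order); ranks are cut into three nearly equal groups, extra members
    going to the lower strata (n=50 -> 17/17/16).
    """
    fractions = np.asarray(fractions, dtype=float)
    order = np.argsort(fractions, kind="stable")
    labels = np.empty(len(fractions), dtype=object)
    for name, idx in zip(
        ("lowest", "medium", "highest"), np.array_split(order, 3)
    ):
        labels[idx] = name
    return labels


def _report_for(
    label: str,
    values: np.ndarray,
    classifications: np.ndarray,
    k: int,
    alpha: float,
    kappa_policy: str,
) -> AgreementReport:
    n = values.shape[0]
    if n < 2:
        return AgreementReport(
            stratum=label, n_videos=n, sem=None, sem_ci=None, icc=None,
            fleiss_kappa=None, kappa_band=None, prop_all_agree=None,
            n_all_agree=None, insufficient=True,
        )
    s = sem_oneway(values, alpha=alpha)
    icc = icc_oneway(values)
    try:
        kap = fleiss_kappa_from_classifications(classifications, k, kappa_policy)
    except ValueError:
        kap = None
    prop, n_agree, _ = all_agree_proportion(classifications)
    return AgreementReport(
        stratum=label,
        n_videos=n,
        sem=s.sem,
        sem_ci=(s.ci_lower, s.ci_upper),
        icc=icc,
        fleiss_kappa=kap,
        kappa_band=kappa_band(kap) if kap is not None else None,
        prop_all_agree=prop,
        n_all_agree=n_agree,
    )


def stratified_agreement(
    matrix: RRMatrix,
    strata: str = "age_group",
    alpha: float = 0.05,
    kappa_policy: str = "exclude",
    tertile_thresholds: tuple[float, float] | None = None,
) -> list[AgreementReport]:
    """Overall plus per-stratum agreement reports.

    ``strata`` is ``"age_group"`` or ``"distortion_tertile"``.  Distortion
    tertiles come from the empirical distribution of per-video mean
    distorted fraction by default; pass ``tertile_thresholds=(lo, hi)``
    to cut at fixed fractions instead.
    """
    reports = [
        _report_for(
            "overall", matrix.values, matrix.classifications, matrix.k,
            alpha, kappa_policy,
        )
    ]
    if strata == "age_group":
        labels = np.array([g.value for g in matrix.age_groups], dtype=object)
        order = [g.value for g in AgeGroup]
    elif strata == "distortion_tertile":
        if tertile_thresholds is not None:
            lo, hi = tertile_thresholds
            f = matrix.distorted_fractions
            labels = np.where(f < lo, "lowest", np.where(f < hi, "medium", "highest")).astype(object)
        else:
            labels = distortion_tertiles(matrix.distorted_fractions)
        order = ["lowest", "medium", "highest"]
    else:
        raise ValueError(f"unknown strata {strata!r}")
    for lab in order:
        mask = labels == lab
        if not mask.any():
            continue
        reports.append(
            _report_for(
                lab, matrix.values[mask], matrix.classifications[mask],
                matrix.k, alpha, kappa_policy,
            )
        )
    return reports


def reports_frame(reports: Iterable[AgreementReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "stratum": r.stratum,
                "n_videos": r.n_videos,
                "sem_bpm": r.sem,
                "sem_ci_lower": r.sem_ci[0] if r.sem_ci else None,
                "sem_ci_upper": r.sem_ci[1] if r.sem_ci else None,
                "icc": r.icc,
                "fleiss_kappa": r.fleiss_kappa,
                "kappa_band": r.kappa_band,
                "prop_all_agree": r.prop_all_agree,
                "n_all_agree": r.n_all_agree,
                "insufficient": r.insufficient,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 1 for a in arrays):
        raise ValueError("every group needs >= 1 observation")
    pooled = np.concatenate(arrays)
    if len(pooled) < 3:
        raise ValueError("need >= 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_holm(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests with Holm-adjusted p-values.

    Uses pooled mid-ranks with the tie-corrected variance
    ``(N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j)`` and the
    step-down Holm adjustment over all pairs.
    """
    from statsmodels.stats.multitest import multipletests

    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(a) for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        float(np.mean(ranks[bounds[i]: bounds[i + 1]])) for i in range(len(arrays))
    ]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((labels[i], labels[j], float(z), float(p)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    df["p_holm"] = multipletests(df["p_raw"], method="holm")[1]
    return df
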