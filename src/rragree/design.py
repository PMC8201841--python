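"""Study-design utilities: ICC precision sample size and rater assignment."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SampleSizeSpec", "bonett_n", "assign_reviewers"]


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to Bonett's ICC-precision sample-size formula.

    ``rho`` is the planning ICC, ``k`` the raters per subject,
    ``half_width`` the desired confidence-interval half-width (the CI
    should land within +/- half_width of the true ICC), ``alpha`` the
    two-sided error rate.
    """

    rho: float
    k: int
    half_width: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.half_width <= 0:
            raise ValueError(f"half_width must be > 0, got {self.half_width}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def bonett_n(spec: SampleSizeSpec) -> int:
    """Subjects needed to estimate an ICC to the requested precision.

    Bonett's approximation for the one-way model,

        n = ceil( 1 + 8 z^2 (1 - rho)^2 [1 + (k - 1) rho]^2 / (k (k - 1) w^2) )

    with ``w = 2 * half_width`` the full CI width and ``z`` the two-sided
    normal quantile.  The ceiling (never rounding) guarantees the precision
    target is met.
    """
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    w = 2.0 * spec.half_width
    n = 1.0 + (
        8.0
        * z**2
        * (1.0 - spec.rho) ** 2
        * (1.0 + (spec.k - 1) * spec.rho) ** 2
        / (spec.k * (spec.k - 1) * w**2)
    )
    return int(math.ceil(n))


def assign_reviewers(
    video_ids: Sequence[str],
    panel: Sequence[str],
    k: int,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simple random sampling of ``k`` distinct panel members per video.

    Returns a long table with columns ``video_id, reviewer_id``; the same
    seed always yields the same assignment.
    """
    if k > len(panel):
        raise ValueError(f"cannot pick k={k} reviewers from a panel of {len(panel)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    panel_arr = np.asarray(panel, dtype=object)
    rows = []
    for vid in video_ids:
        chosen = rng.choice(panel_arr, size=k, replace=False)
        rows.extend((vid, rid) for rid in sorted(chosen))
    return pd.DataFrame(rows, columns=["video_id", "reviewer_id"])
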