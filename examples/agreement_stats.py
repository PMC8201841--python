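"""Interrater agreement on a tiny hand-checkable rating matrix.

Three videos, three raters each.  SEM is the square root of the within-video
mean square of a one-way random-effects ANOVA; its 95% CI comes from the
chi-square interval for a variance.  Fleiss' kappa summarizes agreement on
the binary fast-breathing call.
"""

import numpy as np

from rragree import fleiss_kappa, icc_oneway, kappa_band, sem_oneway

rates = np.array([
    [40.0, 42.0, 44.0],
    [50.0, 50.0, 50.0],
    [60.0, 58.0, 62.0],
])

s = sem_oneway(rates)
print(f"SEM  = {s.sem:.3f} bpm (95% CI {s.ci_lower:.3f}-{s.ci_upper:.3f}, df={s.df})")
print(f"ICC  = {icc_oneway(rates):.3f}")

# fast-counts out of 5 raters on three videos: 5, 4, 3
kappa = fleiss_kappa(np.array([[0, 5], [1, 4], [2, 3]]))
print(f"kappa = {kappa:.4f} ({kappa_band(kappa)})")
# SEM 1.633 bpm: a single reviewer's rate is typically ~1.6 bpm off the
# video's true score; the negative kappa shows agreement below chance on
# this deliberately discordant toy example.
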