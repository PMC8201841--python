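"""Full pipeline on a simulated annotated cohort.

Generates 50 videos (19 / 14 / 17 across the three IMCI age groups) with
ground-truth breathing, distortion episodes, and five noisy reviewers each
drawn from a panel of ten; then computes per-reviewer rates, builds the
rating matrix, and reports agreement overall, by age group and by
distortion tertile.
"""

import numpy as np

from rragree import (
    AgeGroup,
    AnnotationMark,
    ConsideredWindow,
    MarkKind,
    SimulationConfig,
    VideoMeta,
    build_matrix,
    compute_all,
    generate_dataset,
    stratified_agreement,
)
from rragree.rr import results_frame

cfg = SimulationConfig(seed=7)
annotations, videos, truths = generate_dataset(cfg)

metas = {
    row.video_id: VideoMeta(
        row.video_id, AgeGroup(row.age_group),
        ConsideredWindow(row.window_start_s, row.window_end_s),
    )
    for row in videos.itertuples()
}
streams = {
    (v, r): [AnnotationMark(float(t), MarkKind(k), v, r)
             for t, k in zip(grp["time_s"], grp["kind"])]
    for (v, r), grp in annotations.groupby(["video_id", "reviewer_id"])
}

results = compute_all(streams, metas)
matrix = build_matrix(results, metas, k=cfg.reviewers_per_video)

print(f"{len(truths)} videos, {len(results)} reviewer-video rates")
for strata in ("age_group", "distortion_tertile"):
    print(f"\nagreement by {strata}:")
    for rep in stratified_agreement(matrix, strata):
        kap = f"{rep.fleiss_kappa:.2f} ({rep.kappa_band})" if rep.fleiss_kappa is not None else "undefined"
        print(
            f"  {rep.stratum:<8} n={rep.n_videos:<3} "
            f"SEM {rep.sem:.2f} ({rep.sem_ci[0]:.2f}-{rep.sem_ci[1]:.2f}) bpm  "
            f"kappa {kap}  all-agree {rep.prop_all_agree:.0%}"
        )

per_video = results_frame(results).groupby("video_id")["rr_bpm"].mean()
err = np.mean([abs(per_video[t.video_id] - t.true_rr_bpm) for t in truths])
print(f"\nmean |reviewer-mean - true RR| = {err:.2f} bpm")
# SEM is the per-reviewer measurement error in bpm; the all-agree column is
# the share of videos where all five reviewers give the same fast-breathing
# call.  The recovery error reflects reviewer noise: missed and
# uncertain-flagged breaths shrink the estimate by ~7% of the true rate.
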