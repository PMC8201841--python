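import numpy as np
import pytest

from rragree.annotations import (
    AgeGroup,
    AnnotationMark,
    ConsideredWindow,
    MarkKind,
    VideoMeta,
)


def make_stream(
    breaths=(),
    distortions=(),
    uncertain=(),
    video_id="v1",
    reviewer_id="r1",
):
    """Build a sorted annotation stream from breath times and (s, e) pairs."""
    marks = [
        AnnotationMark(float(t), MarkKind.CERTAIN_BREATH, video_id, reviewer_id)
        for t in breaths
    ]
    marks += [
        AnnotationMark(float(t), MarkKind.UNCERTAIN_BREATH, video_id, reviewer_id)
        for t in uncertain
    ]
    for s, e in distortions:
        marks.append(AnnotationMark(float(s), MarkKind.DISTORTION_START, video_id, reviewer_id))
        marks.append(AnnotationMark(float(e), MarkKind.DISTORTION_END, video_id, reviewer_id))
    return sorted(marks, key=lambda m: m.time_s)


def make_meta(window=(0.0, 60.0), age_group=AgeGroup.M12_59, video_id="v1"):
    return VideoMeta(
        video_id=video_id,
        age_group=age_group,
        window=ConsideredWindow(*window),
    )


@pytest.fixture
def worked_example_stream():
    """Window [0, 60) with distortion [18, 33) and eight uniform breaths."""
    return make_stream(
        breaths=[5, 10, 15, 35, 40, 45, 50, 55], distortions=[(18, 33)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
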