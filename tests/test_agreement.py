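import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rragree.agreement import (
    all_agree_proportion,
    build_matrix,
    distortion_tertiles,
    dunn_holm,
    fleiss_kappa,
    fleiss_kappa_from_classifications,
    icc_oneway,
    kappa_band,
    kruskal_wallis,
    sem_oneway,
    sem_twoway,
    stratified_agreement,
    variance_components_oneway,
)
from rragree.annotations import AgeGroup
from rragree.rr import RRResult
from conftest import make_meta
from oracles import fleiss_kappa_oracle, kruskal_h_oracle

M3 = np.array([[40.0, 42.0, 44.0], [50.0, 50.0, 50.0], [60.0, 58.0, 62.0]])


def _result(video_id, reviewer_id, rr, cls, dist=0.1):
    return RRResult(
        video_id=video_id, reviewer_id=reviewer_id, rr_bpm=rr,
        n_full_cycles=0, fractional_breaths=0.0, calm_duration_s=50.0,
        distorted_fraction=dist, n_certain=0, n_uncertain=0, n_shadowed=0,
        classification=cls,
    )


class TestBuildMatrix:
    def test_complete_matrix(self):
        metas = {v: make_meta(video_id=v) for v in ("v1", "v2")}
        results = [
            _result(v, r, 40.0 + i, "fast")
            for v in ("v1", "v2")
            for i, r in enumerate("abcde")
        ]
        m = build_matrix(results, metas, k=5)
        assert m.values.shape == (2, 5)
        assert not np.isnan(m.values).any()

    def test_undefined_rr_leaves_missing_cell(self):
        metas = {"v1": make_meta(video_id="v1")}
        results = [_result("v1", r, 40.0, "fast") for r in "abcd"]
        results.append(_result("v1", "e", None, None))
        m = build_matrix(results, metas, k=5)
        assert np.isnan(m.values).sum() == 1

    def test_too_many_reviewers_errors(self):
        metas = {"v1": make_meta(video_id="v1")}
        results = [_result("v1", r, 40.0, "fast") for r in "abcdef"]
        with pytest.raises(ValueError, match="6 reviewers"):
            build_matrix(results, metas, k=5)


class TestSem:
    def test_hand_anova_example(self):
        s = sem_oneway(M3)
        assert s.df == 6
        assert s.sem == pytest.approx(np.sqrt(16 / 6), abs=1e-9)
        assert s.ci_lower == pytest.approx(1.052, abs=1e-3)
        assert s.ci_upper == pytest.approx(3.596, abs=1e-3)
        assert s.ci_lower <= s.sem <= s.ci_upper

    def test_identical_reviewers_zero_sem(self):
        m = np.tile(np.array([[40.0], [50.0], [60.0]]), (1, 4))
        s = sem_oneway(m)
        assert s.sem == 0.0
        assert (s.ci_lower, s.ci_upper) == (0.0, 0.0)

    def test_scale_equivariance_and_shift_invariance(self):
        base = sem_oneway(M3)
        doubled = sem_oneway(2.0 * M3)
        shifted = sem_oneway(M3 + 17.0)
        assert doubled.sem == pytest.approx(2 * base.sem)
        assert doubled.ci_lower == pytest.approx(2 * base.ci_lower)
        assert doubled.ci_upper == pytest.approx(2 * base.ci_upper)
        assert shifted.sem == pytest.approx(base.sem)

    def test_single_ratings_dropped_pairwise(self):
        m = np.array([[40.0, 42.0], [50.0, np.nan], [60.0, 58.0]])
        s = sem_oneway(m)  # middle row has 1 value -> dropped
        assert s.df == 2

    def test_zero_df_errors(self):
        with pytest.raises(ValueError):
            sem_oneway(np.array([[1.0, np.nan], [2.0, np.nan]]))

    def test_twoway_removes_rater_effect(self):
        rng = np.random.default_rng(5)
        videos = rng.normal(50, 10, size=(20, 1))
        rater_bias = np.array([[-3.0, -1.0, 0.0, 1.0, 3.0]])
        noise = rng.normal(0, 1.0, size=(20, 5))
        m = videos + rater_bias + noise
        one = sem_oneway(m)
        two = sem_twoway(m)
        assert two.sem < one.sem  # constant rater offsets inflate one-way SEM


class TestIcc:
    def test_balanced_identity(self):
        msb, msw, k0 = variance_components_oneway(M3)
        icc = icc_oneway(M3)
        sd2 = (msb - msw) / k0 + msw
        assert sem_oneway(M3).sem ** 2 == pytest.approx(sd2 * (1 - icc), abs=1e-9)

    def test_sign_contracts(self):
        no_between = np.array([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0], [2.0, 3.0, 1.0]])
        assert icc_oneway(no_between) <= 0
        no_within = np.tile(np.array([[40.0], [50.0], [60.0]]), (1, 3))
        assert icc_oneway(no_within) == pytest.approx(1.0)

    def test_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(11)
        m = rng.normal(50, 10, size=(12, 1)) + rng.normal(0, 3, size=(12, 4))
        long = pd.DataFrame(
            [
                (i, j, m[i, j])
                for i in range(m.shape[0])
                for j in range(m.shape[1])
            ],
            columns=["targets", "raters", "ratings"],
        )
        ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="ratings")
        icc1 = float(ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0])
        assert icc_oneway(m) == pytest.approx(icc1, abs=1e-9)


class TestFleissKappa:
    def test_hand_worked_example(self):
        counts = np.array([[0, 5], [1, 4], [2, 3]])
        k = fleiss_kappa(counts)
        assert k == pytest.approx(-1 / 24, abs=1e-9)

    def test_unanimous_is_one(self):
        counts = np.array([[5, 0], [0, 5], [5, 0]])
        assert fleiss_kappa(counts) == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        counts = np.array([[1, 4], [3, 2], [0, 5], [2, 3]])
        assert fleiss_kappa(counts) == pytest.approx(fleiss_kappa(counts[:, ::-1]))

    def test_single_category_undefined(self):
        assert fleiss_kappa(np.array([[5, 0], [5, 0]])) is None

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(3)
        fast = rng.integers(0, 6, size=20)
        counts = np.column_stack([5 - fast, fast])
        if len(np.unique(counts[:, 1])) > 1:
            assert fleiss_kappa(counts) == pytest.approx(
                float(sm_fleiss(counts)), abs=1e-12
            )
        assert fleiss_kappa(counts) == pytest.approx(
            fleiss_kappa_oracle(counts), abs=1e-12
        )

    def test_missing_policies(self):
        cls = np.array(
            [
                [1, 1, 1, 1, 1],
                [0, 0, 0, 0, np.nan],
                [1, 0, 1, 0, 1],
            ]
        )
        # exclude: only rows with all 5 ratings enter
        k_ex = fleiss_kappa_from_classifications(cls, k=5, policy="exclude")
        assert k_ex == pytest.approx(fleiss_kappa(np.array([[0, 5], [2, 3]])))
        # reduce: all rows analysed at the common k = 4
        k_red = fleiss_kappa_from_classifications(cls, k=5, policy="reduce")
        assert k_red == pytest.approx(
            fleiss_kappa(np.array([[0, 4], [4, 0], [2, 2]]))
        )


class TestKappaBand:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (0.71, "substantial"),
            (0.84, "almost perfect"),
            (-0.1, "poor"),
            (0.005, "slight"),
            (0.20, "slight"),
            (0.41, "moderate"),
            (1.0, "almost perfect"),
        ],
    )
    def test_bands(self, kappa, label):
        assert kappa_band(kappa) == label


class TestAllAgree:
    def test_thirty_five_of_fifty(self):
        cls = np.zeros((50, 5))
        cls[35:, 0] = 1.0  # 15 split videos
        prop, n, total = all_agree_proportion(cls)
        assert (prop, n, total) == (0.70, 35, 50)

    def test_all_unanimous(self):
        assert all_agree_proportion(np.ones((4, 5)))[0] == 1.0

    def test_constant_splits_zero(self):
        cls = np.tile(np.array([[1.0, 1.0, 1.0, 0.0, 0.0]]), (6, 1))
        assert all_agree_proportion(cls)[0] == 0.0


class TestStratified:
    def test_tertile_sizes_fifty_videos(self):
        rng = np.random.default_rng(0)
        labels = distortion_tertiles(rng.uniform(0, 0.5, size=50))
        sizes = {lab: int(np.sum(labels == lab)) for lab in np.unique(labels)}
        assert sizes == {"lowest": 17, "medium": 17, "highest": 16}

    def test_single_stratum_equals_overall(self):
        metas = {f"v{i}": make_meta(video_id=f"v{i}", age_group=AgeGroup.LT2M)
                 for i in range(6)}
        rng = np.random.default_rng(1)
        results = [
            _result(v, r, float(rng.normal(60, 8)), rng.choice(["fast", "normal"]))
            for v in metas
            for r in "abcde"
        ]
        m = build_matrix(results, metas, k=5)
        reports = stratified_agreement(m, "age_group")
        overall, stratum = reports[0], reports[1]
        assert stratum.stratum == "lt2m"
        assert stratum.sem == pytest.approx(overall.sem)
        assert stratum.fleiss_kappa == pytest.approx(overall.fleiss_kappa)

    def test_small_stratum_flagged_insufficient(self):
        metas = {
            "v1": make_meta(video_id="v1", age_group=AgeGroup.LT2M),
            "v2": make_meta(video_id="v2", age_group=AgeGroup.M2_11),
            "v3": make_meta(video_id="v3", age_group=AgeGroup.M2_11),
        }
        results = [
            _result(v, r, 40.0 + ord(r), "fast") for v in metas for r in "abcde"
        ]
        m = build_matrix(results, metas, k=5)
        reports = {r.stratum: r for r in stratified_agreement(m, "age_group")}
        assert reports["lt2m"].insufficient
        assert not reports["2-11m"].insufficient


class TestKruskalWallis:
    def test_hand_rank_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-9)

    def test_identical_groups(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert (h, p) == (0.0, 1.0)

    def test_group_relabeling_invariance_and_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            sizes = rng.integers(1, 4, size=3)
            if sizes.sum() < 3:
                continue
            groups = [list(rng.integers(0, 5, size=s).astype(float)) for s in sizes]
            if all(x == groups[0][0] for g in groups for x in g):
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kruskal_h_oracle(groups), abs=1e-9)
            for perm in itertools.permutations(groups):
                hp, _ = kruskal_wallis(list(perm))
                assert hp == pytest.approx(h, abs=1e-9)


class TestDunnHolm:
    def test_single_pair_adjustment_is_identity(self):
        df = dunn_holm([[1.0, 2.0, 5.0], [3.0, 4.0, 8.0]])
        assert df["p_holm"].iloc[0] == pytest.approx(df["p_raw"].iloc[0])

    def test_holm_step_down_by_hand(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.9], method="holm")[1]
        assert adj == pytest.approx([0.03, 0.04, 0.9])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.data())
    def test_adjusted_at_least_raw_and_monotone(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        groups = [list(rng.normal(size=rng.integers(2, 6))) for _ in range(3)]
        df = dunn_holm(groups)
        assert (df["p_holm"] >= df["p_raw"] - 1e-15).all()
        assert (df["p_holm"] <= 1.0).all()
        srt = df.sort_values("p_raw")
        assert srt["p_holm"].is_monotonic_increasing
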