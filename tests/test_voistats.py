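import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gratiomap.voistats import (VOISet, build_cohort_report, dilate_mask,
                                erode_mask, extract_voi_means, label_lesions,
                                make_lesion_shell, make_perilesion,
                                pearson_corr, threshold_masks,
                                two_sample_ttest)
from gratiomap.volume import VolumeMap
from oracles import (brute_dilate, brute_erode, closed_form_pearson,
                     closed_form_ttest)


def cube_mask(shape, lo, hi):
    m = np.zeros(shape, bool)
    m[lo:hi, lo:hi, lo:hi] = True
    return m


class TestThresholdMasks:
    def test_exact_half_excluded_from_lesion(self):
        prob = np.full((3, 3, 3), 0.5)
        vois = threshold_masks({}, lesion_probability=prob)
        assert not vois["lesion"].any()

    def test_all_zero_probability(self):
        vois = threshold_masks({"WM": np.zeros((3, 3, 3))})
        assert not vois["WM"].any()

    def test_counted_lesion_voxels(self):
        rng = np.random.default_rng(0)
        prob = np.zeros((4, 4, 4))
        idx = rng.choice(64, 7, replace=False)
        prob.flat[idx] = 0.8
        vois = threshold_masks({}, lesion_probability=prob)
        assert vois["lesion"].sum() == 7

    def test_lesion_excluded_from_tissue_masks(self):
        wm_prob = np.ones((3, 3, 3))
        lesion_prob = np.zeros((3, 3, 3))
        lesion_prob[1, 1, 1] = 0.9
        vois = threshold_masks({"WM": wm_prob}, lesion_probability=lesion_prob)
        assert not vois["WM"][1, 1, 1]
        assert vois["WM"].sum() == 26

    def test_strict_tissue_threshold(self):
        prob = np.full((2, 2, 2), 0.9)
        vois = threshold_masks({"GM": prob})
        assert not vois["GM"].any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            threshold_masks({"WM": np.full((2, 2, 2), 1.5)})


class TestErodeMask:
    def test_empty_in_empty_out(self):
        assert not erode_mask(np.zeros((4, 4, 4), bool)).any()

    def test_cube_3_to_center(self):
        m = cube_mask((5, 5, 5), 1, 4)
        out = erode_mask(m)
        assert out.sum() == 1
        assert out[2, 2, 2]

    def test_cube_5_to_cube_3(self):
        m = cube_mask((7, 7, 7), 1, 6)
        assert erode_mask(m).sum() == 27

    def test_boundary_counts_as_outside(self):
        m = np.ones((3, 3, 3), bool)
        out = erode_mask(m)
        assert out.sum() == 1 and out[1, 1, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((8, 8, 8)) > 0.5
        assert np.array_equal(erode_mask(m), brute_erode(m))
        assert np.array_equal(dilate_mask(m), brute_dilate(m))

    @pytest.mark.parametrize("seed", range(3))
    def test_erosion_dilation_duality(self, seed):
        # erosion of the mask == complement of dilation of the complement
        rng = np.random.default_rng(100 + seed)
        m = rng.random((8, 8, 8)) > 0.5
        inner = ~m
        # pad-free duality holds away from borders; compare on interior
        a = erode_mask(m)[1:-1, 1:-1, 1:-1]
        b = (~dilate_mask(~m))[1:-1, 1:-1, 1:-1]
        assert np.array_equal(a, b)


class TestPerilesion:
    def test_empty_lesion(self):
        z = np.zeros((5, 5, 5), bool)
        assert not make_perilesion(z, np.ones((5, 5, 5), bool)).any()

    def test_single_voxel_two_step_shell(self):
        lesion = np.zeros((7, 7, 7), bool)
        lesion[3, 3, 3] = True
        wm = np.ones((7, 7, 7), bool)
        peri = make_perilesion(lesion, wm, width=2)
        # 6 at Manhattan distance 1 plus 18 reachable in two face steps
        assert peri.sum() == 24

    @pytest.mark.parametrize("seed", range(3))
    def test_disjoint_from_lesion(self, seed):
        rng = np.random.default_rng(seed)
        lesion = rng.random((8, 8, 8)) > 0.8
        wm = rng.random((8, 8, 8)) > 0.3
        peri = make_perilesion(lesion, wm)
        assert not (peri & lesion).any()


class TestLesionShell:
    def test_single_voxel_is_its_own_shell(self):
        lesion = np.zeros((5, 5, 5), bool)
        lesion[2, 2, 2] = True
        assert np.array_equal(make_lesion_shell(lesion), lesion)

    def test_cube_3_shell_is_26(self):
        m = cube_mask((5, 5, 5), 1, 4)
        assert make_lesion_shell(m).sum() == 26

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_contract(self, seed):
        rng = np.random.default_rng(seed)
        lesion = rng.random((8, 8, 8)) > 0.6
        shell = make_lesion_shell(lesion)
        eroded = erode_mask(lesion)
        assert np.array_equal(shell | eroded, lesion)
        assert not (shell & eroded).any()


class TestExtractVoiMeans:
    def _vois(self):
        shape = (6, 6, 6)
        return VOISet(masks={"WM": cube_mask(shape, 0, 4),
                             "lesion": cube_mask(shape, 4, 6)})

    def test_constant_map(self):
        vois = self._vois()
        maps = {"m": VolumeMap(np.full((6, 6, 6), 3.5))}
        tbl = extract_voi_means(maps, vois)
        assert (tbl["mean"] == 3.5).all()

    def test_nan_exclusion(self):
        vois = self._vois()
        vals = np.full((6, 6, 6), 2.0)
        vals[:2] = np.nan  # half of the WM cube
        tbl = extract_voi_means({"m": VolumeMap(vals)}, vois)
        wm_row = tbl[(tbl.voi == "WM") & (tbl.metric == "m")].iloc[0]
        assert wm_row["mean"] == 2.0
        assert wm_row["n_voxels"] == 32

    def test_empty_voi_logged_as_nan(self):
        vois = VOISet(masks={"WM": np.zeros((3, 3, 3), bool)})
        tbl = extract_voi_means({"m": VolumeMap(np.ones((3, 3, 3)))}, vois)
        assert math.isnan(tbl.iloc[0]["mean"])
        assert tbl.iloc[0]["n_voxels"] == 0

    def test_per_lesion_rows(self):
        shape = (8, 8, 8)
        lesion = np.zeros(shape, bool)
        lesion[1, 1, 1] = True
        lesion[5:7, 5, 5] = True
        vals = np.zeros(shape)
        vals[1, 1, 1] = 10.0
        vals[5:7, 5, 5] = 20.0
        vois = VOISet(masks={"lesion": lesion})
        tbl = extract_voi_means({"m": VolumeMap(vals)}, vois, per_lesion=True)
        per = tbl[tbl.voi.str.startswith("lesion_")]
        assert len(per) == 2
        assert sorted(per["mean"]) == [10.0, 20.0]

    def test_lesion_labeling_connectivity(self):
        m = np.zeros((4, 4, 4), bool)
        m[0, 0, 0] = True
        m[1, 1, 1] = True  # diagonal: separate components under 6-connectivity
        _, n = label_lesions(m)
        assert n == 2


class TestTwoSampleTtest:
    def test_identical_groups(self):
        t, p, degen = two_sample_ttest([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_degenerate_variance(self):
        t, p, degen = two_sample_ttest([0, 0, 0, 0], [1, 1, 1, 1])
        assert math.isinf(t) and p == 0.0 and degen

    def test_hand_computed_example(self):
        t, p, _ = two_sample_ttest([1, 2, 3, 4], [3, 4, 5, 6])
        assert t == pytest.approx(-2.1909, abs=1e-3)
        assert p == pytest.approx(0.0707, abs=1e-3)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_closed_form_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(2, 7))
        b = rng.normal(0.5, 1, rng.integers(2, 7))
        t, p, _ = two_sample_ttest(a, b)
        t_o, p_o = closed_form_ttest(a, b)
        assert t == pytest.approx(t_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)
        res = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(res.statistic, abs=1e-10)
        assert p == pytest.approx(res.pvalue, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1, 2, 3])


class TestPearsonCorr:
    def test_perfect_linear(self):
        x = np.array([1.0, 2, 3, 4])
        r, p, _ = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2, 3, 4])
        r, _, _ = pearson_corr(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # R = 10 / sqrt(10 * 14.8)
        r, p, _ = pearson_corr([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert r == pytest.approx(10.0 / math.sqrt(10.0 * 14.8), abs=1e-12)
        assert r == pytest.approx(0.822, abs=1e-3)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_closed_form_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 6)
        y = x + rng.normal(0, 1, 6)
        r, p, _ = pearson_corr(x, y)
        r_o, p_o = closed_form_pearson(x, y)
        assert r == pytest.approx(r_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)
        res = sps.pearsonr(x, y)
        assert r == pytest.approx(res.statistic, abs=1e-10)
        assert p == pytest.approx(res.pvalue, abs=1e-10)

    def test_zero_variance_flagged(self):
        r, p, degen = pearson_corr([1, 1, 1, 1], [1, 2, 3, 4])
        assert degen and math.isnan(r)


class TestBuildCohortReport:
    def _means_table(self, effect=0.0, seed=0, n=5):
        rng = np.random.default_rng(seed)
        rows = []
        metrics = ["m1", "m2", "m3", "m4", "m5"]
        for group, prefix in (("healthy", "hc"), ("patient", "ms")):
            for i in range(n):
                for voi in ("WM", "lesion", "perilesion"):
                    for m in metrics:
                        shift = -effect if (group == "patient" and voi == "lesion") else 0.0
                        rows.append({"subject": f"{prefix}{i}", "group": group,
                                     "voi": voi, "metric": m,
                                     "mean": rng.normal(1.0 + shift, 0.05)})
        return pd.DataFrame(rows)

    def test_ten_pairs_per_tissue(self):
        stats = build_cohort_report(self._means_table(),
                                    metric_families={"myelin": ["m1", "m2", "m3", "m4", "m5"]})
        per_tissue = stats.correlations.groupby("tissue").size()
        assert (per_tissue == 10).all()

    def test_synthetic_effect_detected(self):
        stats = build_cohort_report(self._means_table(effect=1.0, seed=1))
        sel = stats.ttests[stats.ttests.comparison == "nawm_vs_lesion"]
        assert (sel["p"] < 0.01).all()

    def test_null_effect_mostly_nonsignificant(self):
        # patients == controls by construction: WM-vs-NAWM t-stats small
        reject = 0
        n_rep = 30
        for seed in range(n_rep):
            stats = build_cohort_report(self._means_table(effect=0.0, seed=seed),
                                        metric_families={"f": ["m1"]})
            sel = stats.ttests[(stats.ttests.comparison == "healthy_wm_vs_nawm")
                               & (stats.ttests.metric == "m1")]
            reject += int(sel.iloc[0]["p"] < 0.05)
        assert reject <= 6  # ~5% nominal over 30 replicates

    def test_missing_group_skipped(self):
        tbl = self._means_table()
        tbl = tbl[tbl.group != "patient"]
        stats = build_cohort_report(tbl)
        sel = stats.ttests[stats.ttests.comparison == "nawm_vs_lesion"]
        assert sel["skipped"].all()

    def test_required_columns_enforced(self):
        with pytest.raises(ValueError):
            build_cohort_report(pd.DataFrame({"a": [1]}))
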