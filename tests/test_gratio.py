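import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gratiomap import (CohortSpec, build_phantom, simulate_mt_quadruple,
                       simulate_noddi_fractions)
from gratiomap.gratio import (CalibrationSpec, HydrationModel, NoddiFractions,
                              calibrate_alpha, compute_avf, compute_gratio,
                              mvf_from_mtv, mvf_from_mwf, mvf_from_mwf_values,
                              mvf_linear, mwf_from_mvf, mwf_from_mvf_values,
                              run_gratio_pipeline)
from gratiomap.mtmaps import compute_ihmtr
from gratiomap.volume import VolumeMap

MODEL = HydrationModel()


def vmap(value, role="MWF", shape=(2, 2, 2)):
    return VolumeMap(np.full(shape, float(value)), role=role)


class TestHydrationModel:
    def test_defaults(self):
        assert MODEL.kappa_my == 0.36
        assert MODEL.kappa_nm == 0.86

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            HydrationModel(kappa_my=0.9, kappa_nm=0.8)


class TestMvfFromMwf:
    def test_zero_maps_to_zero(self):
        assert mvf_from_mwf(vmap(0.0), MODEL).values.max() == 0.0

    def test_one_maps_to_one(self):
        assert mvf_from_mwf(vmap(1.0), MODEL).values.max() == pytest.approx(1.0)

    def test_lesion_mwf_nnls_worked_example(self):
        # cohort-mean lesion MWF of 8.0% maps to MVF 0.17 (2 d.p.)
        mvf = mvf_from_mwf_values(0.080, MODEL)
        assert mvf == pytest.approx(0.172, abs=5e-4)
        assert round(float(mvf), 2) == 0.17

    def test_lesion_mwf_spijn_worked_example(self):
        # cohort-mean lesion MWF of 4.1% maps to MVF 0.09 (2 d.p.)
        mvf = mvf_from_mwf_values(0.041, MODEL)
        assert mvf == pytest.approx(0.0927, abs=5e-4)
        assert round(float(mvf), 2) == 0.09

    @given(mwf=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_unit_interval_round_trip(self, mwf):
        mvf = mvf_from_mwf_values(mwf, MODEL)
        assert 0.0 <= mvf <= 1.0
        assert mwf_from_mvf_values(mvf, MODEL) == pytest.approx(mwf, abs=1e-12)

    def test_monotone_increasing(self):
        xs = np.linspace(0, 1, 101)
        ys = mvf_from_mwf_values(xs, MODEL)
        assert np.all(np.diff(ys) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mvf_from_mwf(vmap(1.5), MODEL)


class TestMwfFromMvf:
    def test_fixed_points(self):
        assert mwf_from_mvf(vmap(0.0, "MVF")).values.max() == 0.0
        assert mwf_from_mvf(vmap(1.0, "MVF")).values.max() == pytest.approx(1.0)

    def test_inverse_of_worked_example(self):
        assert mwf_from_mvf_values(0.172043, MODEL) == pytest.approx(0.080, abs=1e-4)


class TestMvfLinear:
    def test_zero_input(self):
        out, n = mvf_linear(vmap(0.0, "ihMTR"), alpha=3.0)
        assert out.values.max() == 0.0 and n == 0

    def test_direct_arithmetic(self):
        out, _ = mvf_linear(vmap(0.3, "ihMTR"), alpha=0.2)
        assert np.allclose(out.values, 0.06)

    def test_clipping_counted(self):
        out, n = mvf_linear(vmap(0.8, "MTsat"), alpha=2.0)
        assert out.values.max() == 1.0
        assert n == 8

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            mvf_linear(vmap(0.3, "ihMTR"), alpha=0.0)


class TestMvfFromMtv:
    def test_identity_values(self):
        out = mvf_from_mtv(vmap(0.31, "MTV"))
        assert np.allclose(out.values, 0.31)
        assert out.role == "MVF"

    def test_purity(self):
        src = vmap(0.2, "MTV")
        out = mvf_from_mtv(src)
        out.values[:] = 0.9
        assert np.allclose(src.values, 0.2)


class TestComputeAvf:
    def test_full_axon_limit(self):
        fr = NoddiFractions(np.ones((2, 2, 2)), np.zeros((2, 2, 2)))
        avf = compute_avf(vmap(0.0, "MVF"), fr)
        assert np.allclose(avf.values, 1.0)

    def test_direct_arithmetic(self):
        fr = NoddiFractions(np.full((2, 2, 2), 0.6), np.full((2, 2, 2), 0.1))
        avf = compute_avf(vmap(0.3, "MVF"), fr)
        assert np.allclose(avf.values, 0.378, atol=1e-12)

    def test_nmvf_reduces_avf(self):
        fr = NoddiFractions(np.full((2, 2, 2), 0.6), np.full((2, 2, 2), 0.1))
        avf = compute_avf(vmap(0.3, "MVF"), fr, nmvf=vmap(0.1, "NMVF"))
        assert np.allclose(avf.values, 0.324, atol=1e-12)

    def test_zero_nmvf_reduces_to_base_model(self):
        fr = NoddiFractions(np.full((2, 2, 2), 0.6), np.full((2, 2, 2), 0.1))
        a = compute_avf(vmap(0.3, "MVF"), fr)
        b = compute_avf(vmap(0.3, "MVF"), fr, nmvf=vmap(0.0, "NMVF"))
        assert np.array_equal(a.values, b.values)

    def test_overfull_voxel_invalid(self):
        fr = NoddiFractions(np.full((2, 2, 2), 0.6), np.full((2, 2, 2), 0.1))
        avf = compute_avf(vmap(0.95, "MVF"), fr, nmvf=vmap(0.10, "NMVF"))
        assert np.all(np.isnan(avf.values))

    @given(mvf=st.floats(0, 1), nmvf=st.floats(0, 1), vic=st.floats(0, 1),
           viso=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_conservation(self, mvf, nmvf, vic, viso):
        if mvf + nmvf > 1:
            return
        fr = NoddiFractions(np.full((1, 1, 1), vic), np.full((1, 1, 1), viso))
        avf = compute_avf(vmap(mvf, "MVF", (1, 1, 1)), fr,
                          vmap(nmvf, "NMVF", (1, 1, 1)))
        assert mvf + nmvf + avf.values.item() <= 1.0 + 1e-12


class TestComputeGratio:
    def test_no_myelin_gives_one(self):
        g = compute_gratio(vmap(0.0, "MVF"), vmap(0.4, "AVF"))
        assert np.allclose(g.values, 1.0)

    def test_equal_fractions(self):
        g = compute_gratio(vmap(0.3, "MVF"), vmap(0.3, "AVF"))
        assert np.allclose(g.values, np.sqrt(0.5), atol=1e-12)

    def test_direct_arithmetic(self):
        g = compute_gratio(vmap(0.3, "MVF"), vmap(0.4, "AVF"))
        assert np.allclose(g.values, np.sqrt(0.4 / 0.7), atol=1e-12)

    def test_both_zero_invalid(self):
        g = compute_gratio(vmap(0.0, "MVF"), vmap(0.0, "AVF"))
        assert np.all(np.isnan(g.values))

    def test_strictly_decreasing_in_mvf(self):
        # basis of calibration well-posedness, checked on a grid
        vic, viso = 0.6, 0.1
        mvfs = np.linspace(0.0, 0.95, 50)
        fr = NoddiFractions(np.full((1, 1, 1), vic), np.full((1, 1, 1), viso))
        gs = []
        for m in mvfs:
            avf = compute_avf(vmap(m, "MVF", (1, 1, 1)), fr)
            gs.append(compute_gratio(vmap(m, "MVF", (1, 1, 1)), avf).values.item())
        assert np.all(np.diff(gs) < 0)

    def test_nmvf_decreases_g_at_fixed_mvf(self):
        fr = NoddiFractions(np.full((2, 2, 2), 0.6), np.full((2, 2, 2), 0.1))
        g0 = compute_gratio(vmap(0.3, "MVF"), compute_avf(vmap(0.3, "MVF"), fr))
        g1 = compute_gratio(vmap(0.3, "MVF"),
                            compute_avf(vmap(0.3, "MVF"), fr, vmap(0.1, "NMVF")))
        assert np.all(g1.values < g0.values)


class TestCalibrateAlpha:
    def test_single_voxel_closed_form(self):
        # x = 1, v_ic = 1, v_iso = 0: g^2 = 1 - alpha, so alpha = 1 - 0.49
        shape = (1, 1, 1)
        x = VolumeMap(np.ones(shape), role="ihMTR")
        fr = NoddiFractions(np.ones(shape), np.zeros(shape))
        mask = np.ones(shape, bool)
        alpha = calibrate_alpha([x], [fr], [mask], g_target=0.7)
        assert alpha == pytest.approx(0.51, abs=1e-6)

    def test_self_consistency_recovery(self, small_spec):
        # phantom generated with MVF = alpha0 * x: calibrating to the true
        # cohort splenium g must return alpha0
        alpha0 = 1.0 / 0.15
        xs, frs, masks, g_means = [], [], [], []
        for seed in (21, 22, 23):
            truth, vois = build_phantom(small_spec, "healthy", seed=seed)
            quad = simulate_mt_quadruple(truth, forward_slope=0.15)
            ihmtr, _ = compute_ihmtr(quad)
            fr = simulate_noddi_fractions(truth, 0.0, 0)
            sp = vois["splenium"]
            avf = truth.avf_true
            g_true = np.sqrt(avf[sp] / (avf[sp] + truth.mvf_true[sp]))
            g_means.append(g_true.mean())
            xs.append(ihmtr)
            frs.append(fr)
            masks.append(sp)
        g_target = float(np.mean(g_means))
        alpha = calibrate_alpha(xs, frs, masks, g_target=g_target)
        assert alpha == pytest.approx(alpha0, rel=1e-6)

    def test_monotone_in_target(self):
        shape = (1, 1, 1)
        x = VolumeMap(np.ones(shape), role="ihMTR")
        fr = NoddiFractions(np.ones(shape), np.zeros(shape))
        mask = np.ones(shape, bool)
        a_lo = calibrate_alpha([x], [fr], [mask], g_target=0.6)
        a_hi = calibrate_alpha([x], [fr], [mask], g_target=0.8)
        assert a_hi < a_lo

    def test_unattainable_target_rejected(self):
        # one voxel saturates (MVF = 1, g = 0) while the other barely scales,
        # so the cohort mean cannot be driven below ~0.5
        shape = (2, 1, 1)
        x = VolumeMap(np.array([1.0, 0.01]).reshape(shape), role="ihMTR")
        fr = NoddiFractions(np.ones(shape), np.zeros(shape))
        mask = np.ones(shape, bool)
        with pytest.raises(ValueError):
            calibrate_alpha([x], [fr], [mask], g_target=0.3)

    def test_empty_mask_rejected(self):
        shape = (2, 2, 2)
        x = VolumeMap(np.ones(shape), role="ihMTR")
        fr = NoddiFractions(np.ones(shape), np.zeros(shape))
        with pytest.raises(ValueError):
            calibrate_alpha([x], [fr], [np.zeros(shape, bool)], g_target=0.7)


class TestRunGratioPipeline:
    def _exact_channels(self, spec, seed=31):
        """Noiseless self-consistent subject: every channel encodes mvf_true."""
        truth, vois = build_phantom(spec, "healthy", seed=seed)
        quad = simulate_mt_quadruple(truth, forward_slope=0.15)
        ihmtr, _ = compute_ihmtr(quad)
        fr = simulate_noddi_fractions(truth, 0.0, 0)
        aff = truth.affine
        maps = {
            "MWF_NNLS": VolumeMap(truth.mwf_true, aff, role="MWF_NNLS"),
            "MWF_SPIJN": VolumeMap(truth.mwf_true, aff, role="MWF_SPIJN"),
            "ihMTR": ihmtr,
            "MTsat": VolumeMap(100.0 * 0.12 * truth.mvf_true, aff, role="MTsat", units="%"),
            "MTV": VolumeMap(truth.mvf_true + truth.nmvf_true, aff, role="MTV"),
        }
        return truth, vois, maps, fr

    def test_mtv_method_equals_closed_form(self, small_spec):
        truth, vois, maps, fr = self._exact_channels(small_spec)
        gm = run_gratio_pipeline(maps, "mtv", fr)
        mvf = truth.mvf_true
        avf = (1 - mvf) * (1 - truth.v_iso_true) * truth.v_ic_true
        with np.errstate(invalid="ignore", divide="ignore"):
            expected = np.sqrt(avf / (avf + mvf))
        sel = np.isfinite(expected)
        assert np.allclose(gm.g.values[sel], expected[sel], atol=1e-12)

    def test_all_five_methods_identical_on_self_consistent_phantom(self, small_spec):
        truth, vois, maps, fr = self._exact_channels(small_spec)
        sp = vois["splenium"]
        avf = truth.avf_true
        g_true = np.sqrt(avf[sp] / (avf[sp] + truth.mvf_true[sp]))
        g_target = float(g_true.mean())
        alpha_ihmt = calibrate_alpha([maps["ihMTR"]], [fr], [sp], g_target=g_target)
        alpha_mtsat = calibrate_alpha([maps["MTsat"]], [fr], [sp], g_target=g_target)
        cal = CalibrationSpec(alpha_mtsat=alpha_mtsat, alpha_ihmt=alpha_ihmt,
                              g_target=g_target)
        gmaps = [run_gratio_pipeline(maps, m, fr, cal).g.values
                 for m in ("mwf_nnls", "mwf_spijn", "ihmtr", "mtsat", "mtv")]
        ref = gmaps[0]
        sel = np.isfinite(ref)
        for g in gmaps[1:]:
            assert np.nanmax(np.abs(g[sel] - ref[sel])) < 1e-6

    def test_mt_method_without_calibration_fails(self, small_spec):
        _, _, maps, fr = self._exact_channels(small_spec)
        with pytest.raises(ValueError):
            run_gratio_pipeline(maps, "ihmtr", fr)

    def test_missing_map_fails(self, small_spec):
        _, _, maps, fr = self._exact_channels(small_spec)
        del maps["MTV"]
        with pytest.raises(ValueError):
            run_gratio_pipeline(maps, "mtv", fr)

    def test_provenance_recorded(self, small_spec):
        _, _, maps, fr = self._exact_channels(small_spec)
        gm = run_gratio_pipeline(maps, "mwf_nnls", fr)
        assert gm.provenance["method"] == "mwf_nnls"
        assert gm.provenance["kappa_my"] == 0.36
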