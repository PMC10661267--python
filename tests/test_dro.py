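import numpy as np
import pytest

from qmrifit import (DCEFitter, DROSpec, IVIMFitter, add_noise,
                     generate_dce_dro, generate_dro, generate_dw_dro,
                     generate_relaxometry_dro, repeatability_coefficient,
                     score_maps)


class TestAddNoise:
    def test_sigma_zero_identity(self):
        x = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(add_noise(x, "gaussian", 0.0, seed=1), x)

    def test_seeded_reproducibility(self):
        x = np.ones((50, 50))
        a = add_noise(x, "rician", 2.0, seed=9)
        b = add_noise(x, "rician", 2.0, seed=9)
        np.testing.assert_array_equal(a, b)
        c = add_noise(x, "rician", 2.0, seed=10)
        assert not np.array_equal(a, c)

    def test_rician_background_mean(self):
        # zero-signal magnitude noise has mean sigma*sqrt(pi/2)
        sigma = 3.0
        bg = add_noise(np.zeros(200_000), "rician", sigma, seed=5)
        expected = sigma * np.sqrt(np.pi / 2.0)
        se = sigma * np.sqrt(2 - np.pi / 2) / np.sqrt(bg.size)
        assert abs(bg.mean() - expected) < 4 * se

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.zeros(3), "poisson", 1.0)


@pytest.fixture(scope="module")
def bundle():
    return generate_dce_dro(DROSpec(kind="dce", patch_size=2, frames=661,
                                    model="etm", seed=3))


class TestDCEDRO:
    def test_layout_and_truth_alignment(self, bundle):
        assert bundle.series.n_frames == 661
        assert bundle.tissue_mask.sum() == 30 * 4  # 6x5 grid, 2x2 patches
        assert bundle.artery_mask.sum() > 0
        for m in bundle.truth_maps.values():
            assert m.values.shape == bundle.series.shape3d

    def test_same_seed_identical_bytes(self):
        spec = DROSpec(kind="dce", patch_size=2, frames=121, model="etm", seed=5,
                       noise={"model": "gaussian", "sigma": 1.0})
        a = generate_dce_dro(spec)
        b = generate_dce_dro(spec)
        assert a.series.data.tobytes() == b.series.data.tobytes()

    def test_ktrans_zero_patch_is_flat(self):
        spec = DROSpec(kind="dce", patch_size=1, frames=121, model="tm",
                       param_grid={"ktrans": [0.0], "ve": [0.1]},
                       include_artery=False)
        bundle = generate_dce_dro(spec)
        curve = bundle.series.data[0, 0, 0]
        np.testing.assert_allclose(curve, curve[0], rtol=1e-12)

    def test_noise_free_end_to_end_recovery(self, bundle):
        ct, flat = bundle.tissue_concentration(baseline_frames=50)
        est = DCEFitter(model="etm", aif=bundle.aif).fit(ct)
        for p in ("ktrans", "ve", "vp"):
            rel = np.abs(est.params_[p] - flat[p]) / flat[p]
            assert rel.max() < 0.01, p

    def test_memory_guard(self):
        spec = DROSpec(kind="dce", patch_size=100, frames=661,
                       max_elements=10_000)
        with pytest.raises(ValueError, match="memory guard"):
            generate_dce_dro(spec)


class TestDWDRO:
    def test_pure_mono_grid(self):
        spec = DROSpec(kind="dw", patch_size=1,
                       param_grid={"d": [0.8e-3, 1.2e-3], "f": [0.0], "k": [0.0]})
        bundle = generate_dw_dro(spec)
        X, flat = bundle.tissue_curves()
        b = np.asarray(spec.b_values, float)
        for row, d in zip(X, flat["d"]):
            np.testing.assert_allclose(row, spec.s0 * np.exp(-b * d), rtol=1e-12)

    def test_dicom_scaling_quantises(self):
        spec = DROSpec(kind="dw", patch_size=1, scaling=True)
        bundle = generate_dw_dro(spec)
        data = bundle.series.data
        steps = (data - bundle.scaling_intercept) / bundle.scaling_slope
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-6)
        assert np.round(steps).max() <= 4095

    def test_rician_floor_raises_high_b_mean(self):
        # SNR 10: at the highest b the measured mean exceeds the true signal
        spec = DROSpec(kind="dw", patch_size=8,
                       param_grid={"d": [2.5e-3], "f": [0.0], "k": [0.0]},
                       noise={"model": "rician", "sigma": 100.0}, seed=6)
        bundle = generate_dw_dro(spec)
        X, _ = bundle.tissue_curves()
        b = np.asarray(spec.b_values, float)
        true_high = spec.s0 * np.exp(-b[-1] * 2.5e-3)
        assert X[:, -1].mean() > true_high

    def test_noise_free_ngivim_recovery_within_five_percent(self):
        spec = DROSpec(kind="dw", patch_size=1)
        bundle = generate_dw_dro(spec)
        X, flat = bundle.tissue_curves()
        from qmrifit import NGIVIMFitter

        est = NGIVIMFitter(b_values=spec.b_values).fit(X)
        for p in ("f", "dstar", "d", "k"):
            rel = np.abs(est.params_[p] - flat[p]) / flat[p]
            assert rel.max() < 0.05, p


class TestRelaxometryDRO:
    def test_vfa_grid_recovery(self):
        bundle = generate_dro(DROSpec(kind="vfa_t1", patch_size=2))
        X, flat = bundle.tissue_curves()
        from qmrifit import VFAT1Fitter

        est = VFAT1Fitter(flip_angles_deg=bundle.spec.flip_angles_deg,
                          tr=bundle.spec.tr).fit(X)
        rel = np.abs(est.params_["t10"] - flat["t10"]) / flat["t10"]
        assert rel.max() < 1e-3

    def test_me_t2_grid_recovery(self):
        bundle = generate_relaxometry_dro(DROSpec(kind="me_t2", patch_size=2))
        X, flat = bundle.tissue_curves()
        from qmrifit import MultiEchoT2Fitter

        est = MultiEchoT2Fitter(echo_times=bundle.spec.echo_times).fit(X)
        rel = np.abs(est.params_["t2"] - flat["t2"]) / flat["t2"]
        assert rel.max() < 1e-6


class TestScoring:
    def test_identical_maps_zero_error(self):
        m = {"ktrans": np.array([0.1, 0.2, 0.3])}
        rep = score_maps(m, m, retest=m)
        assert rep["ktrans"]["bias"] == 0.0
        assert rep["ktrans"]["rmse"] == 0.0
        assert rep["ktrans"]["rc"] == 0.0

    def test_known_offset_bias(self):
        t = {"ve": np.full(10, 0.3)}
        f = {"ve": np.full(10, 0.4)}
        rep = score_maps(f, t)
        assert rep["ve"]["bias"] == pytest.approx(0.1)
        assert rep["ve"]["rmse"] == pytest.approx(0.1)

    def test_nan_masked_pairwise(self):
        t = {"d": np.array([1.0, 2.0, 3.0])}
        f = {"d": np.array([1.0, np.nan, 3.5])}
        rep = score_maps(f, t)
        assert rep["d"]["n"] == 2
        assert rep["d"]["bias"] == pytest.approx(0.25)

    def test_rc_matches_hand_computed_oracle_four_patch_toy(self):
        # within-subject SD from paired replicates, by hand:
        # d = a-b; wSD = sqrt(mean(d^2)/2); RC = 1.96*sqrt(2)*wSD
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.2, 1.9, 3.3, 3.8])
        d = a - b
        wsd = np.sqrt(np.mean(d ** 2) / 2)
        expected = 1.96 * np.sqrt(2) * wsd
        assert repeatability_coefficient(a, b) == pytest.approx(expected, abs=1e-15)
        rep = score_maps({"adc": a}, {"adc": a}, retest={"adc": b})
        assert rep["adc"]["rc"] == pytest.approx(expected, abs=1e-15)

    def test_rc_on_seeded_noise_replicates(self):
        clean = np.full(400, 1.0)
        r1 = add_noise(clean, "gaussian", 0.05, seed=1)
        r2 = add_noise(clean, "gaussian", 0.05, seed=2)
        rc = repeatability_coefficient(r1, r2)
        # wSD estimates the per-measurement SD: RC ~ 1.96*sqrt(2)*0.05
        assert rc == pytest.approx(1.96 * np.sqrt(2) * 0.05, rel=0.15)
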