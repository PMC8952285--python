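import numpy as np
import pytest

from capcri.causality import (GCSpectrum, cri_track, extract_cri, fit_bivar_ar,
                              gc_spectrum, gc_time)
from capcri.preprocess import InvalidInputError
from tests.conftest import simulate_var


class TestFitBivarAR:
    def test_known_var2_recovered_at_T480(self, var2_known):
        (A1, A2), sigma = var2_known
        rng = np.random.default_rng(0)
        y = simulate_var([A1, A2], sigma, 480, rng)
        m = fit_bivar_ar(y[:, 0], y[:, 1], p=2)
        err = np.max(np.abs(np.stack([m.coeffs[0] - A1, m.coeffs[1] - A2])))
        assert err < 0.05

    def test_independent_series_have_null_cross_terms(self, rng):
        T = 4000
        x = rng.standard_normal(T)
        z = rng.standard_normal(T)
        m = fit_bivar_ar(x, z, p=1)
        # ~3 standard errors of a white-noise cross coefficient
        assert abs(m.coeffs[0][0, 1]) < 3 / np.sqrt(T)
        assert abs(m.coeffs[0][1, 0]) < 3 / np.sqrt(T)

    def test_order_exceeding_sample_rejected(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(InvalidInputError):
            fit_bivar_ar(x, rng.standard_normal(20), p=20)

    def test_constant_input_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            fit_bivar_ar(np.ones(100), rng.standard_normal(100), p=2)

    def test_matches_statsmodels_var(self, var2_known):
        from statsmodels.tsa.api import VAR
        (A1, A2), sigma = var2_known
        rng = np.random.default_rng(3)
        y = simulate_var([A1, A2], sigma, 2000, rng)
        m = fit_bivar_ar(y[:, 0], y[:, 1], p=2)
        ref = VAR(y - y.mean(axis=0)).fit(2, trend="n")
        np.testing.assert_allclose(
            np.stack([m.coeffs[0], m.coeffs[1]]),
            ref.coefs, atol=1e-6)


class TestGCTime:
    def test_independent_series_near_zero(self, rng):
        T = 8000
        g = gc_time(rng.standard_normal(T), rng.standard_normal(T), p=2)
        assert 0 <= g < 3 * 2 / T * 10   # small-sample bias scale p/T

    def test_analytic_limit_ln_181(self, rng):
        # RRI(t) = 0.9 RSP(t-1) + e ; restricted variance 0.81 + 1
        T = 120000
        rsp = rng.standard_normal(T)
        e = rng.standard_normal(T)
        rri = np.empty(T)
        rri[0] = e[0]
        rri[1:] = 0.9 * rsp[:-1] + e[1:]
        g = gc_time(rri, rsp, p=1)
        assert g == pytest.approx(np.log(1.81), rel=0.02)

    def test_nonnegative_by_construction(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            g = gc_time(r.standard_normal(300), r.standard_normal(300), p=4)
            assert g >= 0.0


class TestGCSpectrum:
    def test_no_cross_terms_zero_everywhere(self):
        from capcri.causality import BivarARModel
        coeffs = np.array([[[0.5, 0.0], [0.0, 0.4]]])
        m = BivarARModel(p=1, coeffs=coeffs, sigma=np.eye(2), nobs=100)
        spec = gc_spectrum(m)
        assert np.allclose(spec.g, 0.0, atol=1e-10)

    def test_unstable_model_rejected(self):
        from capcri.causality import BivarARModel
        coeffs = np.array([[[1.1, 0.0], [0.0, 0.5]]])
        m = BivarARModel(p=1, coeffs=coeffs, sigma=np.eye(2), nobs=100)
        with pytest.raises(InvalidInputError):
            gc_spectrum(m)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_band_integral_matches_time_domain(self, seed, var2_known):
        """Geweke integral identity: mean of g(f) over the full band equals
        the time-domain log variance ratio."""
        (A1, A2), sigma = var2_known
        rng = np.random.default_rng(seed)
        y = simulate_var([A1, A2], sigma, 8000, rng)
        p = 12
        gt = gc_time(y[:, 0], y[:, 1], p=p)
        m = fit_bivar_ar(y[:, 0], y[:, 1], p=p)
        freqs = np.linspace(2.0 / 2048, 2.0, 2048)
        spec = gc_spectrum(m, freqs)
        assert spec.band_mean() == pytest.approx(gt, rel=0.05)

    def test_coupled_var_peak_at_coupling_band(self, rng):
        # x1 driven by a narrowband x2 through one lag
        T = 6000
        fs = 4.0
        t = np.arange(T) / fs
        phase = 2 * np.pi * 0.25 * t + np.cumsum(rng.normal(0, 0.05, T))
        x2 = np.sin(phase) + 0.2 * rng.standard_normal(T)
        x1 = np.roll(x2, 1) * 0.8 + 0.5 * rng.standard_normal(T)
        m = fit_bivar_ar(x1, x2, p=8)
        spec = gc_spectrum(m)
        f_peak = spec.freqs[np.argmax(spec.g)]
        assert abs(f_peak - 0.25) < 0.03


class TestExtractCRI:
    @pytest.fixture
    def lorentzian(self):
        f = np.linspace(2.0 / 512, 2.0, 512)
        g = 2.0 / (1 + ((f - 0.25) / 0.025) ** 2)   # FWHM = 0.05
        return GCSpectrum(f, g)

    def test_lorentzian_indices_recovered(self, lorentzian):
        rec = extract_cri(lorentzian)
        assert rec.valid
        assert rec.f_a == pytest.approx(0.25, abs=2.0 / 512)
        assert rec.cra == pytest.approx(2.0, rel=1e-6)
        assert rec.crb == pytest.approx(0.05, abs=2 * 2.0 / 512)
        assert rec.crq == pytest.approx(0.25 / 0.05, rel=0.05)
        assert rec.crr == pytest.approx(0.05 / (2 * np.pi * 0.25 ** 2),
                                        rel=0.05)

    def test_resonance_identity(self, lorentzian):
        rec = extract_cri(lorentzian)
        assert rec.crq * rec.crr * 2 * np.pi * rec.f_a == pytest.approx(1.0)

    def test_scale_behaviour(self, lorentzian):
        doubled = GCSpectrum(lorentzian.freqs, 2 * lorentzian.g)
        r1, r2 = extract_cri(lorentzian), extract_cri(doubled)
        assert r2.cra == pytest.approx(2 * r1.cra)
        for attr in ("f_a", "crb", "crq", "crr"):
            assert getattr(r2, attr) == pytest.approx(getattr(r1, attr))

    def test_flat_spectrum_degenerate(self):
        f = np.linspace(0.01, 2.0, 256)
        rec = extract_cri(GCSpectrum(f, np.zeros_like(f)))
        assert not rec.valid
        assert np.isnan(rec.cra)

    def test_identity_on_random_unimodal_curves(self, rng):
        f = np.linspace(2.0 / 512, 2.0, 512)
        for _ in range(20):
            f0 = rng.uniform(0.1, 0.4)
            w = rng.uniform(0.02, 0.1)
            h = rng.uniform(0.5, 5.0)
            rec = extract_cri(GCSpectrum(f, h / (1 + ((f - f0) / w) ** 2)))
            if rec.valid:
                assert rec.crq * rec.crr * 2 * np.pi * rec.f_a == \
                    pytest.approx(1.0, rel=1e-9)


class TestCriTrack:
    def test_600s_recording_gives_49_records(self):
        from capcri.synthetic import HEALTHY, SimConfig, simulate_cardioresp
        cfg = SimConfig(duration_s=630.0, seed=1)
        sim = simulate_cardioresp(["S2-NA"] * 21, HEALTHY, cfg,
                                  np.random.default_rng(1))
        track = cri_track(sim["rri"], sim["rsp"].slice(0.0, 600.0))
        # coverage trimmed by beat span; grid stays regular at 10-s steps
        starts = np.diff([r.t0 for r in track])
        assert np.allclose(starts, 10.0)
        assert len(track) >= 45

    def test_noise_respiration_marked_missing_not_dropped(self, rng):
        from capcri.synthetic import HEALTHY, SimConfig, simulate_cardioresp
        from capcri.types import SignalSegment
        cfg = SimConfig(duration_s=600.0, seed=1)
        sim = simulate_cardioresp(["S2-NA"] * 20, HEALTHY, cfg,
                                  np.random.default_rng(1))
        noise = SignalSegment(rng.standard_normal(6000), 10.0, 0.0, "resp")
        track = cri_track(sim["rri"], noise, denoise_resp=False)
        assert len(track) > 0
        assert all(not r.valid for r in track)
        assert all("low_quality" in r.flags for r in track)
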