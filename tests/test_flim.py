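"""Decay-fitting accuracy, calibration algebra and FLIM-map behaviour."""

import numpy as np
import pytest

from oxmembrane import flim
from oxmembrane import synthetic_data as syn
from oxmembrane.containers import DecayTrace
from oxmembrane.flim import ViscosityMap


def _noiseless_trace(tau=1.0, n_channels=256, width=0.05, peak=10_000):
    """Delta-IRF, zero-background trace holding the exact expectation
    (float counts, so the fit and the regression oracle see the same
    noise-free curve)."""
    t = np.arange(n_channels) * width
    mu = peak * np.exp(-t / tau)
    irf = np.zeros(n_channels)
    irf[0] = peak
    return DecayTrace(channel_times=t, counts=mu, irf_counts=irf)


class TestFitDecay:
    def test_recovery_precision_mono(self):
        taus = []
        for seed in range(20):
            spec = syn.DecaySimSpec(lifetimes=[2.1], amplitudes=[1.0], seed=seed)
            fit = flim.fit_decay(syn.gen_decay(spec))
            taus.append(fit.lifetimes[0])
        taus = np.array(taus)
        assert abs(taus.mean() - 2.1) / 2.1 < 0.01
        assert taus.std(ddof=1) <= 0.07

    def test_matches_tail_regression_oracle(self):
        trace = _noiseless_trace(tau=1.0)
        fit = flim.fit_decay(trace)
        # independent oracle: log-linear regression on the pure tail
        t = trace.channel_times
        c = trace.counts.astype(float)
        ok = c > 30
        slope = np.polyfit(t[ok], np.log(c[ok]), 1)[0]
        tau_oracle = -1.0 / slope
        assert fit.lifetimes[0] == pytest.approx(tau_oracle, abs=1e-3)

    def test_empty_decay_rejected(self):
        t = np.arange(64) * 0.05
        trace = DecayTrace(t, np.zeros(64, dtype=int), np.ones(64))
        with pytest.raises(ValueError, match="empty decay"):
            flim.fit_decay(trace)

    def test_biexponential_recovery(self):
        spec = syn.DecaySimSpec(
            lifetimes=[2.3, 0.6], amplitudes=[0.6, 0.4], peak_counts=50_000, seed=4
        )
        fit = flim.fit_decay(syn.gen_decay(spec), n_components=2)
        assert fit.lifetimes[0] == pytest.approx(2.3, rel=0.05)
        assert fit.lifetimes[1] == pytest.approx(0.6, rel=0.15)

    def test_poisson_and_lsq_agree_at_high_counts(self):
        spec = syn.DecaySimSpec(lifetimes=[2.1], amplitudes=[1.0], peak_counts=10_000, seed=8)
        trace = syn.gen_decay(spec)
        f1 = flim.fit_decay(trace, method="poisson_mle")
        f2 = flim.fit_decay(trace, method="lsq")
        sd = 0.02  # photon-noise scale of τ̂ at 10⁴ peak counts
        assert abs(f1.lifetimes[0] - f2.lifetimes[0]) < sd

    def test_precision_scales_with_counts(self):
        # Cramér–Rao-style scaling: SD(τ̂) ∝ 1/√counts over 10³–10⁵
        sds = []
        for peak in (1_000, 100_000):
            taus = [
                flim.fit_decay(
                    syn.gen_decay(
                        syn.DecaySimSpec(
                            lifetimes=[2.1], amplitudes=[1.0], peak_counts=peak, seed=s
                        )
                    )
                ).lifetimes[0]
                for s in range(12)
            ]
            sds.append(np.std(taus, ddof=1))
        ratio = sds[0] / sds[1]
        assert 3.0 < ratio < 33.0  # expect ~10, allow sampling scatter


class TestReportedLifetime:
    def test_bi_long_takes_longer_component(self):
        fit = flim.LifetimeFit(
            lifetimes=np.array([0.6, 2.3]), amplitudes=np.array([0.4, 0.6]),
            scale=1.0, shift=0.0, background=0.0, reduced_chi2=1.0,
            covariance=None, converged=True, method="poisson_mle",
        )
        assert flim.select_reported_lifetime(fit, "bi_long") == 2.3

    def test_mono_returns_single(self):
        fit = flim.LifetimeFit(
            lifetimes=np.array([1.8]), amplitudes=np.array([1.0]),
            scale=1.0, shift=0.0, background=0.0, reduced_chi2=1.0,
            covariance=None, converged=True, method="poisson_mle",
        )
        assert flim.select_reported_lifetime(fit, "mono") == 1.8

    def test_tie_flagged(self):
        fit = flim.LifetimeFit(
            lifetimes=np.array([2.0, 2.0]), amplitudes=np.array([0.5, 0.5]),
            scale=1.0, shift=0.0, background=0.0, reduced_chi2=1.0,
            covariance=None, converged=True, method="poisson_mle",
        )
        assert flim.select_reported_lifetime(fit, "bi_long") == 2.0
        assert fit.flags.get("lifetime_tie") is True

    def test_mode_mismatch_rejected(self):
        fit = flim.LifetimeFit(
            lifetimes=np.array([1.8]), amplitudes=np.array([1.0]),
            scale=1.0, shift=0.0, background=0.0, reduced_chi2=1.0,
            covariance=None, converged=True, method="poisson_mle",
        )
        with pytest.raises(ValueError):
            flim.select_reported_lifetime(fit, "bi_long")


class TestCalibration:
    def test_two_point_exponent_closed_form(self):
        cal = flim.calibrate_from_pairs([(100.0, 1.0), (400.0, 2.0)])
        assert cal.exponent == pytest.approx(np.log(2) / np.log(4), abs=1e-12)

    def test_anchor_pairs_reproduced_exactly(self):
        cal = flim.default_calibration()
        assert flim.lifetime_to_viscosity(1.8, cal) == pytest.approx(159.0, abs=1e-10)
        assert flim.lifetime_to_viscosity(2.1, cal) == pytest.approx(241.0, abs=1e-10)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            flim.calibrate_from_pairs([(100.0, 1.0)])

    def test_identity_calibration(self):
        cal = flim.ViscosityCalibration(coefficient=1.0, exponent=1.0, valid_range=(0, 100))
        assert flim.lifetime_to_viscosity(3.7, cal) == pytest.approx(3.7)

    def test_roundtrip_identity(self):
        cal = flim.default_calibration()
        for tau in (1.5, 1.8, 2.1, 2.5):
            eta = flim.lifetime_to_viscosity(tau, cal)
            assert flim.viscosity_to_lifetime(eta, cal) == pytest.approx(tau, abs=1e-10)

    def test_monotonicity(self):
        cal = flim.default_calibration()
        taus = np.linspace(1.0, 3.0, 50)
        etas = [flim.lifetime_to_viscosity(t, cal) for t in taus]
        assert np.all(np.diff(etas) > 0)

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ValueError):
            flim.lifetime_to_viscosity(0.0, flim.default_calibration())


class TestFlimStackFitting:
    def test_planted_pass_count(self):
        # two bright pixels above threshold, the rest dim: exactly 2 fitted
        n_ch = 128
        t = np.arange(n_ch) * 0.05
        irf = np.zeros(n_ch)
        irf[10] = 1.0
        bright = np.round(500 * np.exp(-np.maximum(t - 0.5, 0) / 2.0)).astype(int)
        dim = np.round(50 * np.exp(-np.maximum(t - 0.5, 0) / 2.0)).astype(int)
        data = np.tile(dim, (3, 3, 1))
        data[0, 0] = bright
        data[2, 2] = bright
        stack = syn.FLIMStack(data=data, channel_width=0.05, irf_counts=irf)
        vmap = flim.fit_flim_stack(stack, min_peak_counts=200)
        assert vmap.metadata["n_fitted"] == 2

    def test_threshold_monotonicity(self, rim_stack):
        counts = [
            flim.fit_flim_stack(rim_stack, min_peak_counts=m).metadata["n_fitted"]
            for m in (100, 300, 600)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_binning_equals_presummed_decay(self, rim_stack):
        vmap = flim.fit_flim_stack(rim_stack, binning=1, min_peak_counts=500)
        iy, ix = np.argwhere(vmap.mask)[0]
        summed = rim_stack.data[iy - 1 : iy + 2, ix - 1 : ix + 2].sum(axis=(0, 1))
        trace = DecayTrace(
            channel_times=rim_stack.channel_times,
            counts=summed,
            irf_counts=rim_stack.irf_counts,
        )
        fit = flim.fit_decay(trace)
        assert fit.lifetimes[0] == pytest.approx(vmap.lifetime[iy, ix], abs=1e-6)


class TestSpatialStructure:
    def test_random_assignment_has_no_autocorrelation(self, rim_stack):
        # lifetimes assigned at random over the rim: photon noise only,
        # Moran's I consistent with the permutation null
        vmap = flim.fit_flim_stack(rim_stack, min_peak_counts=200)
        i_obs, p = flim.morans_i(vmap, seed=1)
        assert p > 0.01

    def test_angular_domains_detected(self):
        geom = syn.RimGeometry(shape=(40, 40), radius=13.0, rim_width=3.0)
        dspec = syn.DecaySimSpec(
            lifetimes=[2.0], amplitudes=[1.0], peak_counts=500, background_rate=0.2, seed=6
        )
        stack = syn.gen_flim_stack(
            geom, [(2.0, 0.5, (0.0, 180.0)), (2.4, 0.5, (180.0, 360.0))], dspec
        )
        vmap = flim.fit_flim_stack(stack, min_peak_counts=200)
        i_obs, p = flim.morans_i(vmap, seed=1)
        assert i_obs > 0.5 and p < 0.01


class TestHeterogeneity:
    def test_two_population_rim_detected(self, rim_stack):
        vmap = flim.fit_flim_stack(rim_stack, min_peak_counts=200)
        h = flim.histogram_heterogeneity(vmap)
        assert h.delta_bic > 10
        truth = sorted(tau for tau, _ in rim_stack.metadata["populations"])
        np.testing.assert_allclose(h.gmm_means, truth, atol=0.1)

    def test_homogeneous_map_prefers_one_component(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(2.0, 0.05, 400).astype(np.float32)
        vmap = ViscosityMap(
            lifetime=vals.reshape(20, 20), viscosity=vals.reshape(20, 20),
            mask=np.ones((20, 20), bool), empty=False,
        )
        h = flim.histogram_heterogeneity(vmap)
        assert h.delta_bic <= 2.0  # at best marginal support for 2 components

    def test_constant_map_zero_sd(self):
        vals = np.full((10, 10), 2.0, dtype=np.float32)
        vmap = ViscosityMap(lifetime=vals, viscosity=vals, mask=np.ones((10, 10), bool), empty=False)
        h = flim.histogram_heterogeneity(vmap)
        assert h.sd == 0.0

    def test_too_few_pixels_rejected(self):
        vals = np.full((5, 5), 2.0, dtype=np.float32)
        vmap = ViscosityMap(lifetime=vals, viscosity=vals, mask=np.ones((5, 5), bool), empty=False)
        with pytest.raises(ValueError):
            flim.histogram_heterogeneity(vmap)
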