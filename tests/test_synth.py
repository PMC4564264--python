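"""Generator correctness: conservation, Poisson statistics, determinism,
and agreement with closed forms and brute-force recomputation."""

import numpy as np
import pytest

from ohcmobility import (
    FrapSimParams,
    NandbSimParams,
    NlcSimParams,
    boltzmann_nlc,
    compute_fluctuation_map,
    simulate_frap_series,
    simulate_nandb_series,
    simulate_nlc_trace,
)
from ohcmobility.synth import ParameterError

from .conftest import roiset_from_ground_truth, simulated_curve
from .oracles import brute_force_moments


class TestFrapGenerator:
    def test_seed_determinism(self):
        a = simulate_frap_series(FrapSimParams(seed=42))
        b = simulate_frap_series(FrapSimParams(seed=42))
        c = simulate_frap_series(FrapSimParams(seed=43))
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_conservation_without_bleaching(self):
        """With beta=0 and k_acq=0 diffusion redistributes but does not
        destroy signal: per-frame totals are flat to within shot noise."""
        p = FrapSimParams(seed=5, bleach_depth=1e-12, acquisition_bleach_rate=0.0,
                          background_rate=0.0)
        s = simulate_frap_series(p)
        totals = s.frames.sum(axis=(1, 2))
        expected = p.photon_gain * (p.strip_rows[1] - p.strip_rows[0]) * p.grid_cols
        assert np.all(np.abs(totals - expected) < 6 * np.sqrt(expected))

    def test_immobile_spot_trace_is_flat(self):
        """phi=0: no recovery by construction; the late normalized f stays
        near zero."""
        curve = simulated_curve(seed=2, mobile_fraction=0.0)
        assert abs(curve.post_f_percent[5:].mean()) < 5.0

    def test_instantaneous_mixing_limit(self):
        """phi=1, beta=1, very large D: one frame after the bleach the raw
        spot intensity has re-equilibrated to the pre-bleach level scaled by
        the surviving fraction of total signal (the reference-ratio
        correction would absorb this global dilution, so the check uses the
        background-subtracted raw trace)."""
        p = FrapSimParams(seed=3, mobile_fraction=1.0, bleach_depth=1.0,
                          diffusion_coeff=30.0, acquisition_bleach_rate=0.0)
        s = simulate_frap_series(p)
        from ohcmobility import correct_and_normalize
        curve = correct_and_normalize(s, roiset_from_ground_truth(s))
        strip_area = (p.strip_rows[1] - p.strip_rows[0]) * p.grid_cols
        disc_area = np.pi * p.bleach_radius_px ** 2
        surviving = 1.0 - p.bleach_depth * disc_area / strip_area
        raw_pre = curve.raw_i[:5].mean()
        i_next = curve.raw_i[s.bleach_frame_index + 1]
        assert i_next == pytest.approx(raw_pre * surviving, rel=0.03)

    def test_recovery_monotone_in_mobile_fraction(self):
        """Late-time spot recovery increases stochastically with phi."""
        def late_mean(phi):
            vals = [simulated_curve(seed, mobile_fraction=phi).post_f_percent[-5:].mean()
                    for seed in (1, 2, 3)]
            return np.mean(vals)

        levels = [late_mean(phi) for phi in (0.0, 0.4, 0.8)]
        assert levels[0] < levels[1] < levels[2]

    @pytest.mark.parametrize("bad", [
        {"mobile_fraction": 1.5},
        {"bleach_depth": 0.0},
        {"acquisition_bleach_rate": 1.0},
        {"frame_interval_s": -1.0},
        {"n_prebleach": 3},
        {"bleach_center": (33, 2)},   # disc pokes out of the strip
    ])
    def test_parameter_errors(self, bad):
        with pytest.raises(ParameterError):
            simulate_frap_series(FrapSimParams(seed=0, **bad))


class TestNandbGenerator:
    def test_pure_background_ratio_near_one(self):
        """Poisson-only series: variance equals mean, so sigma^2/mu ~ 1."""
        p = NandbSimParams(seed=9, n_frames=225, grid_rows=64, grid_cols=64,
                           n_fixed=0, n_mobile=0)
        fmap = compute_fluctuation_map(simulate_nandb_series(p))
        assert fmap.mean_ratio() == pytest.approx(1.0, abs=0.01)

    def test_fixed_emitters_stay_poisson(self):
        """Static emitters only rescale the Poisson mean: ratio stays ~ 1."""
        p = NandbSimParams(seed=10, n_frames=225, grid_rows=64, grid_cols=64,
                           n_fixed=100, n_mobile=0, brightness=5.0)
        fmap = compute_fluctuation_map(simulate_nandb_series(p))
        assert fmap.mean_ratio() == pytest.approx(1.0, abs=0.01)

    def test_mobile_emitters_super_poisson(self):
        """Bright diffusing emitters add number fluctuations on top of shot
        noise: the occupied region is clearly super-Poisson."""
        p = NandbSimParams(seed=4, n_frames=150, grid_rows=48, grid_cols=48,
                           n_fixed=0, n_mobile=80, brightness=10.0,
                           background_rate=0.2)
        s = simulate_nandb_series(p)
        fmap = compute_fluctuation_map(s)
        assert fmap.mean_ratio(s.ground_truth["mobile_mask"]) > 1.05

    def test_matches_brute_force_moments(self):
        """Mapper output equals a direct per-pixel loop over the same
        realized counts to near machine precision."""
        p = NandbSimParams(seed=7, n_frames=60, grid_rows=24, grid_cols=24,
                           n_fixed=10, n_mobile=20)
        s = simulate_nandb_series(p)
        fmap = compute_fluctuation_map(s)
        mean, var = brute_force_moments(s.frames)
        assert np.allclose(fmap.mean_map, mean, atol=1e-12)
        assert np.allclose(fmap.variance_map, var, atol=1e-10)
        defined = mean > 0
        assert np.allclose(fmap.ratio_map[defined], (var / mean)[defined], atol=1e-10)

    def test_determinism_and_defaults(self):
        a = simulate_nandb_series(NandbSimParams(seed=1, grid_rows=16, grid_cols=16,
                                                 n_frames=10, n_fixed=3, n_mobile=3))
        b = simulate_nandb_series(NandbSimParams(seed=1, grid_rows=16, grid_cols=16,
                                                 n_frames=10, n_fixed=3, n_mobile=3))
        assert np.array_equal(a.frames, b.frames)
        defaults = NandbSimParams(seed=0)
        assert (defaults.n_frames, defaults.grid_rows, defaults.grid_cols) == (225, 256, 256)

    def test_zero_size_grid_rejected(self):
        with pytest.raises(ParameterError):
            simulate_nandb_series(NandbSimParams(seed=0, grid_rows=0))


class TestNlcGenerator:
    def test_peak_value_identity(self):
        """At V = Vh, b = 1 and the NLC peaks at Clin + Qmax alpha / 4."""
        p = NlcSimParams(seed=0, noise_sd=0.0)
        c_peak = boltzmann_nlc(p.vh, p.qmax, p.alpha, p.vh, p.clin)
        assert c_peak == pytest.approx(p.clin + p.qmax * p.alpha / 4.0, rel=1e-12)

    def test_integral_recovers_qmax(self):
        """The NLC is the derivative of Qmax/(1+b): it integrates to Qmax."""
        p = NlcSimParams(seed=0, noise_sd=0.0,
                         voltage_grid=np.arange(-500.0, 400.0, 0.5))
        tr = simulate_nlc_trace(p)
        q = np.trapezoid(tr.capacitance_pf - p.clin, tr.voltage_mv)
        assert q == pytest.approx(p.qmax, rel=1e-4)

    def test_noise_and_determinism(self):
        a = simulate_nlc_trace(NlcSimParams(seed=8))
        b = simulate_nlc_trace(NlcSimParams(seed=8))
        assert np.array_equal(a.capacitance_pf, b.capacitance_pf)

    def test_grid_must_span_vh(self):
        with pytest.raises(ParameterError):
            simulate_nlc_trace(NlcSimParams(seed=0, vh=100.0))
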