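import numpy as np
import pytest

from phylofold.foldstab import (
    DenaturationCurve,
    KineticTrace,
    R_KCAL,
    burst_amplitude,
    delta_delta_g,
    fit_equilibrium,
    fit_kinetics,
    fraction_unfolded,
    read_denaturation_tsv,
    read_trace_tsv,
    santoro_bolen_signal,
)
from phylofold.synthetic_data import (
    CurveSimSpec,
    EQUILIBRIUM_PRESETS,
    TraceSimSpec,
    simulate_denaturation,
    simulate_trace,
)

WT = EQUILIBRIUM_PRESETS["wt_equilibrium"]


class TestSantoroBolenSignal:
    def test_native_limit_at_zero_denaturant(self):
        y = santoro_bolen_signal(0.0, dG=10.0, m=4.0, yN=-4500, mN=60,
                                 yU=-1500, mU=-40, T=293.15)
        assert y == pytest.approx(-4500, abs=1e-4 * 4500)

    def test_midpoint_is_baseline_average(self):
        dG, m = 7.6, 4.0
        Cm = dG / m
        y = santoro_bolen_signal(Cm, dG, m, -4500, 60, -1500, -40, 293.15)
        expected = ((-4500 + 60 * Cm) + (-1500 - 40 * Cm)) / 2
        assert y == pytest.approx(expected, abs=1e-9)

    def test_unfolded_limit(self):
        D = 8.0
        y = santoro_bolen_signal(D, 7.6, 4.0, -4500, 60, -1500, -40, 293.15)
        assert y == pytest.approx(-1500 - 40 * D, rel=1e-4)


class TestFitEquilibrium:
    def test_noiseless_recovery_is_exact(self):
        spec = CurveSimSpec.from_preset("wt_equilibrium", seed=0, noise_frac=0.0)
        fit = fit_equilibrium(simulate_denaturation(spec))
        assert fit.dG == pytest.approx(WT["dG"], rel=1e-6)
        assert fit.m == pytest.approx(WT["m"], rel=1e-6)
        assert fit.Cm == pytest.approx(WT["dG"] / WT["m"], rel=1e-6)

    def test_noisy_recovery_of_midpoint(self):
        fit = fit_equilibrium(
            simulate_denaturation(CurveSimSpec.from_preset("wt_equilibrium", seed=11))
        )
        assert fit.Cm == pytest.approx(1.9, abs=0.05)
        assert fit.baselines_ok

    def test_median_recovery_over_replicates(self):
        """Cm and dG recovery across 50 noisy wild-type replicates."""
        cms, dgs = [], []
        for seed in range(50):
            fit = fit_equilibrium(
                simulate_denaturation(
                    CurveSimSpec.from_preset("wt_equilibrium", seed=seed)
                )
            )
            cms.append(fit.Cm)
            dgs.append(fit.dG)
        assert np.median(np.abs(np.array(cms) - 1.9)) < 0.03
        assert np.median(np.abs(np.array(dgs) - 7.6)) < 0.3

    def test_residuals_within_noise(self):
        spec = CurveSimSpec.from_preset("wt_equilibrium", seed=4)
        curve = simulate_denaturation(spec)
        fit = fit_equilibrium(curve)
        pred = santoro_bolen_signal(
            curve.denaturant, fit.dG, fit.m, fit.yN, fit.mN, fit.yU, fit.mU,
            curve.temperature,
        )
        noiseless = simulate_denaturation(
            CurveSimSpec.from_preset("wt_equilibrium", seed=4, noise_frac=0.0)
        )
        sigma = spec.noise_frac * np.ptp(noiseless.signal)
        rms = np.sqrt(np.mean((pred - curve.signal) ** 2))
        assert rms <= 1.5 * sigma

    def test_transition_outside_range_flagged(self):
        # sampling stops at 1.5 M, short of the 1.9 M midpoint: the
        # unfolded baseline is never reached
        spec = CurveSimSpec.from_preset(
            "wt_equilibrium", seed=1, d_max=1.5, noise_frac=0.005
        )
        with pytest.warns(UserWarning, match="poorly determined baselines"):
            fit = fit_equilibrium(simulate_denaturation(spec))
        assert not fit.baselines_ok

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            DenaturationCurve(np.linspace(0, 4, 5), np.zeros(5))


class TestFractionUnfolded:
    @pytest.fixture
    def fit(self):
        return fit_equilibrium(
            simulate_denaturation(
                CurveSimSpec.from_preset("wt_equilibrium", seed=0, noise_frac=0.0)
            )
        )

    def test_baseline_endpoints(self, fit):
        D = np.array([0.5, 1.0, 3.5, 3.8, 0.2, 1.2, 2.4, 3.9])
        native = fit.yN + fit.mN * D
        unfolded = fit.yU + fit.mU * D
        mid = (native + unfolded) / 2
        curve = DenaturationCurve(D, native)
        assert np.allclose(fraction_unfolded(curve, fit), 0.0, atol=1e-12)
        curve = DenaturationCurve(D, unfolded)
        assert np.allclose(fraction_unfolded(curve, fit), 1.0, atol=1e-12)
        curve = DenaturationCurve(D, mid)
        assert np.allclose(fraction_unfolded(curve, fit), 0.5, atol=1e-12)


class TestDeltaDeltaG:
    def test_identical_fits_are_zero(self):
        fit = fit_equilibrium(
            simulate_denaturation(
                CurveSimSpec.from_preset("wt_equilibrium", seed=0, noise_frac=0.0)
            )
        )
        dd = delta_delta_g(fit, fit)
        assert dd["ddG_direct"] == 0.0 and dd["ddG_midpoint"] == 0.0

    def test_preset_pair_consistency(self):
        """dG 7.6 vs 6.6 with shared m=4: both routes give 1.0 kcal/mol."""
        a = fit_equilibrium(
            simulate_denaturation(
                CurveSimSpec.from_preset("wt_equilibrium", seed=0, noise_frac=0.0)
            )
        )
        b = fit_equilibrium(
            simulate_denaturation(
                CurveSimSpec.from_preset("w95l_equilibrium", seed=0, noise_frac=0.0)
            )
        )
        dd = delta_delta_g(a, b)
        assert dd["ddG_direct"] == pytest.approx(1.0, abs=1e-5)
        assert dd["ddG_midpoint"] == pytest.approx(4.0 * (1.9 - 1.65), abs=1e-5)

    def test_antisymmetry(self):
        a = fit_equilibrium(
            simulate_denaturation(CurveSimSpec.from_preset("wt_equilibrium", seed=1))
        )
        b = fit_equilibrium(
            simulate_denaturation(CurveSimSpec.from_preset("w95l_equilibrium", seed=2))
        )
        ab, ba = delta_delta_g(a, b), delta_delta_g(b, a)
        assert ab["ddG_direct"] == pytest.approx(-ba["ddG_direct"])
        assert ab["ddG_midpoint"] == pytest.approx(-ba["ddG_midpoint"])


class TestFitKinetics:
    def test_noiseless_single_exponential_exact(self):
        spec = TraceSimSpec.from_preset("unfold_wt", seed=0, snr=0)
        fit = fit_kinetics(simulate_trace(spec))
        assert fit.phases[0]["k"] == pytest.approx(0.22, rel=1e-6)

    @pytest.mark.parametrize(
        "preset,true_k",
        [
            ("fold_fast", 1.65),
            ("fold_slow", 0.003),
            ("unfold_wt", 0.22),
            ("unfold_w95l", 0.4),
        ],
    )
    def test_noisy_rate_recovery_within_ten_percent(self, preset, true_k):
        fit = fit_kinetics(simulate_trace(TraceSimSpec.from_preset(preset, seed=3)))
        assert fit.phases[0]["k"] == pytest.approx(true_k, rel=0.10)

    @pytest.mark.parametrize(
        "preset,true_k",
        [
            ("fold_fast", 1.65),
            ("fold_slow", 0.003),
            ("unfold_wt", 0.22),
            ("unfold_w95l", 0.4),
        ],
    )
    def test_recovery_bias_below_two_percent(self, preset, true_k):
        ks = [
            fit_kinetics(
                simulate_trace(TraceSimSpec.from_preset(preset, seed=s))
            ).phases[0]["k"]
            for s in range(12)
        ]
        assert abs(np.mean(ks) / true_k - 1) < 0.02

    def test_two_phase_fit_recovers_both_rates(self):
        rng = np.random.default_rng(8)
        t = np.arange(0.01, 30, 0.01)
        y = -2000 + 900 * np.exp(-1.5 * t) + 600 * np.exp(-0.1 * t)
        trace = KineticTrace(t, y + rng.normal(0, 5, len(t)))
        fit = fit_kinetics(trace, n_phases=2)
        ks = sorted(fit.rate_constants, reverse=True)
        assert ks[0] == pytest.approx(1.5, rel=0.1)
        assert ks[1] == pytest.approx(0.1, rel=0.1)

    def test_constant_trace_flagged_no_signal(self):
        t = np.arange(0.1, 5, 0.1)
        fit = fit_kinetics(KineticTrace(t, np.full_like(t, -2000.0)))
        assert fit.no_signal

    def test_dead_time_points_excluded(self):
        spec = TraceSimSpec.from_preset("fold_fast", seed=0, snr=0)
        trace = simulate_trace(spec)
        t_fit, _ = trace.fit_window()
        assert t_fit.min() > 0.005


class TestBurstAmplitude:
    def make_fit(self, frac_burst):
        # total amplitude 1000; frac_burst lost before t=0
        t = np.arange(0.01, 10, 0.01)
        y = -3000 + (1 - frac_burst) * 1000 * np.exp(-0.8 * t)
        return fit_kinetics(KineticTrace(t, y))

    def test_no_burst(self):
        fit = self.make_fit(0.0)
        assert burst_amplitude(fit, -2000.0) == pytest.approx(0.0, abs=1e-6)

    def test_full_burst(self):
        # the whole transition happens inside the dead time: flat trace
        fit = self.make_fit(1.0)
        assert burst_amplitude(fit, -2000.0) == pytest.approx(1.0, abs=1e-6)

    def test_thirty_percent_burst(self):
        fit = self.make_fit(0.30)
        assert burst_amplitude(fit, -2000.0) == pytest.approx(0.30, abs=0.02)

    def test_zero_amplitude_errors(self):
        fit = self.make_fit(0.0)
        with pytest.raises(ValueError, match="zero total"):
            burst_amplitude(fit, fit.offset)


class TestIO:
    def test_round_trip_with_metadata(self, tmp_path):
        p = tmp_path / "curve.tsv"
        p.write_text(
            "# temperature_K: 293.15\n0.0\t-4500\n0.1\t-4490\n0.2\t-4480\n"
            "0.3\t-4470\n0.5\t-4400\n1.0\t-4000\n2.0\t-2500\n4.0\t-1600\n"
        )
        curve = read_denaturation_tsv(p)
        assert curve.temperature == 293.15
        assert len(curve.denaturant) == 8

    def test_trace_metadata(self, tmp_path):
        p = tmp_path / "trace.tsv"
        rows = "\n".join(f"{0.01 * i:.2f}\t{-2000 + i}" for i in range(1, 20))
        p.write_text("# dead_time_s: 0.005\n# wavelength_nm: 215\n" + rows + "\n")
        trace = read_trace_tsv(p)
        assert trace.dead_time == 0.005
        assert trace.wavelength == 215
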