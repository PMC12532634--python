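import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import prediarem as pr
from prediarem.units import TimedSeries

from conftest import make_record, make_series

GRID = np.array([0.0, 30.0, 60.0, 90.0, 120.0])


class TestKineticParams:
    def test_deterministic(self, kinetics):
        again = pr.vancauter_params(55.0, "F", 1.68, 84.0, "prediabetes")
        assert again == kinetics

    def test_rate_half_life_round_trip(self):
        for status in ("normal", "obese", "t2d"):
            p = pr.vancauter_params(50, "M", 1.8, 80, status)
            ts, tl = p.half_lives_from_rates()
            assert ts == pytest.approx(p.t_half_short, rel=1e-9)
            assert tl == pytest.approx(p.t_half_long, rel=1e-9)
            assert p.k01 > 0 and p.k12 > 0 and p.k21 > 0

    def test_population_table(self):
        """Class table matches the pinned population kinetics (fast fraction,
        fast/slow half-lives) and volume scales with body size."""
        p = pr.vancauter_params(40, "M", 1.80, 75, "normal")
        assert (p.fraction, p.t_half_short, p.t_half_long) == (0.76, 4.95, 29.2)
        big = pr.vancauter_params(40, "M", 1.95, 110, "normal")
        assert big.volume > p.volume

    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError):
            pr.vancauter_params(50, "F", 1.7, 70, "unknown")


class TestForwardModel:
    def test_zero_secretion_zero_start(self, kinetics):
        isr = pr.ISRProfile(GRID, np.zeros(5))
        out = pr.forward_cpeptide(isr, kinetics, c0=0.0)
        assert np.allclose(out.values, 0.0)

    def test_steady_state(self, kinetics):
        s = 200.0
        c_ss = s / (kinetics.volume * kinetics.k01)
        isr = pr.ISRProfile(GRID, np.full(5, s))
        out = pr.forward_cpeptide(isr, kinetics, c0=c_ss)
        assert np.allclose(out.values, c_ss, rtol=1e-9)

    def test_matches_fine_step_integrator(self, kinetics):
        """Matrix-exponential propagation equals a tiny-step ODE reference."""
        p = kinetics
        isr_vals = np.array([200.0, 700.0, 550.0, 400.0, 250.0])
        isr = pr.ISRProfile(GRID, isr_vals)
        c0 = isr_vals[0] / (p.volume * p.k01)

        def isr_at(t):
            return np.interp(t, GRID, isr_vals)

        def rhs(t, y):
            c1, c2 = y
            return [
                isr_at(t) / p.volume - (p.k01 + p.k12) * c1 + p.k21 * c2,
                p.k12 * c1 - p.k21 * c2,
            ]

        sol = solve_ivp(
            rhs,
            (0, 120),
            [c0, c0 * p.k12 / p.k21],
            t_eval=GRID,
            rtol=1e-11,
            atol=1e-9,
        )
        out = pr.forward_cpeptide(isr, p, c0)
        assert np.allclose(out.values, sol.y[0], rtol=1e-6)

    def test_mass_balance_of_decay(self, kinetics):
        """With no secretion, the eliminated mass converges to the initial mass."""
        p = kinetics
        c0 = 500.0
        m0 = p.volume * (c0 + c0 * p.k12 / p.k21)  # both compartments
        grid = np.linspace(0, 2000, 2001)
        isr = pr.ISRProfile(grid, np.zeros_like(grid))
        c1 = pr.forward_cpeptide(isr, p, c0).values
        eliminated = np.trapezoid(p.k01 * c1 * p.volume, grid)
        assert eliminated == pytest.approx(m0, rel=1e-3)


class TestDeconvolution:
    def test_steady_state_inversion_exact(self, kinetics):
        c_star = 700.0
        cpep = make_series([c_star] * 5, unit="pmol/l")
        prof = pr.deconvolve_isr(cpep, kinetics, pr.RegularizationConfig(rule="fixed", lam=0.0))
        expected = c_star * kinetics.volume * kinetics.k01
        assert np.allclose(prof.isr, expected, rtol=1e-6)

    def test_round_trip_smooth_profiles(self, kinetics):
        """Noise-free forward-then-inverse recovers 100 random smooth
        profiles far inside the 10% RMSE band."""
        rng = np.random.default_rng(42)
        reg = pr.RegularizationConfig(rule="fixed", lam=0.0)
        for _ in range(100):
            basal = rng.uniform(100, 300)
            amp = rng.uniform(200, 800)
            tp, w = rng.uniform(25, 70), rng.uniform(25, 60)
            shape = np.exp(-0.5 * ((GRID - tp) / w) ** 2)
            shape = np.maximum(shape - shape[0], 0.0)
            isr = pr.ISRProfile(GRID, basal + amp * shape)
            c0 = isr.isr[0] / (kinetics.volume * kinetics.k01)
            cpep = pr.forward_cpeptide(isr, kinetics, c0)
            rec = pr.deconvolve_isr(cpep, kinetics, reg)
            rmse = np.sqrt(np.mean((rec.isr - isr.isr) ** 2)) / isr.isr.mean()
            assert rmse <= 0.10

    def test_noisy_round_trip_with_discrepancy_rule(self, kinetics):
        """With 4% assay noise the default discrepancy smoothing keeps the
        mean recovery error modest."""
        rng = np.random.default_rng(42)
        rmses = []
        for _ in range(30):
            basal = rng.uniform(100, 300)
            amp = rng.uniform(200, 800)
            tp, w = rng.uniform(25, 70), rng.uniform(25, 60)
            shape = np.exp(-0.5 * ((GRID - tp) / w) ** 2)
            shape = np.maximum(shape - shape[0], 0.0)
            isr = pr.ISRProfile(GRID, basal + amp * shape)
            c0 = isr.isr[0] / (kinetics.volume * kinetics.k01)
            clean = pr.forward_cpeptide(isr, kinetics, c0)
            noisy = TimedSeries(GRID, clean.values * np.exp(rng.normal(0, 0.04, 5)), "pmol/l")
            rec = pr.deconvolve_isr(noisy, kinetics)
            rmses.append(np.sqrt(np.mean((rec.isr - isr.isr) ** 2)) / isr.isr.mean())
        assert np.mean(rmses) < 0.15

    def test_large_lambda_flattens(self, kinetics):
        cpep = make_series([700, 1400, 1800, 1600, 1300], unit="pmol/l")
        prof = pr.deconvolve_isr(
            cpep, kinetics, pr.RegularizationConfig(rule="fixed", lam=1e9)
        )
        second_diff = np.diff(prof.isr, 2)
        assert np.max(np.abs(second_diff)) < 1e-2 * prof.isr.mean()

    def test_unit_rescaling_invariance(self, kinetics):
        """Rescaling C-peptide units with a co-scaled volume leaves ISR shape
        fixed up to the same factor (dimensional consistency)."""
        cpep = make_series([700, 1400, 1800, 1600, 1300], unit="pmol/l")
        prof = pr.deconvolve_isr(cpep, kinetics, pr.RegularizationConfig(rule="fixed", lam=0.0))
        k = 0.001  # pmol/l -> nmol/l with volume unchanged => ISR scales by k
        cpep2 = make_series([v * k for v in [700, 1400, 1800, 1600, 1300]], unit="nmol/l")
        prof2 = pr.deconvolve_isr(cpep2, kinetics, pr.RegularizationConfig(rule="fixed", lam=0.0))
        assert np.allclose(prof2.isr, k * prof.isr, rtol=1e-6)

    def test_non_negativity_forced(self, kinetics):
        # sharply falling curve would imply negative secretion without the bound
        cpep = make_series([2000, 300, 100, 60, 40], unit="pmol/l")
        prof = pr.deconvolve_isr(cpep, kinetics, pr.RegularizationConfig(rule="fixed", lam=0.0))
        assert np.all(prof.isr >= 0.0)

    def test_input_guards(self, kinetics):
        with pytest.raises(ValueError):
            pr.deconvolve_isr(make_series([1, 2, 3], times=(0, 30, 60)), kinetics)
        with pytest.raises(ValueError):
            pr.deconvolve_isr(make_series([0, 0, 0, 0, 0]), kinetics)


class TestHormoneSummaries:
    def test_glp1_sensitivity_ratio(self):
        isr = pr.ISRProfile(GRID, np.array([200.0, 400.0, 350.0, 300.0, 250.0]))
        glp1 = make_series([15.0, 25.0, 22.0, 20.0, 18.0], unit="pmol/l")
        iauc_isr, iauc_glp1, ratio = pr.beta_cell_glp1_sensitivity(isr, glp1)
        assert iauc_isr == pytest.approx(3000.0)  # (0+200)/2*30
        assert iauc_glp1 == pytest.approx(150.0)
        assert ratio == pytest.approx(20.0)

    def test_glp1_zero_increment_flagged(self):
        isr = pr.ISRProfile(GRID, np.array([200.0, 400.0, 350.0, 300.0, 250.0]))
        flat = make_series([15.0] * 5, unit="pmol/l")
        *_, ratio = pr.beta_cell_glp1_sensitivity(isr, flat)
        assert math.isnan(ratio)

    @pytest.mark.parametrize(
        "g0,g30,expected", [(20.0, 10.0, 50.0), (20.0, 20.0, 0.0), (20.0, 24.0, -20.0)]
    )
    def test_glucagon_suppression(self, g0, g30, expected):
        s = make_series([g0, g30, 10, 10, 10], unit="pmol/l")
        assert pr.glucagon_suppression(s) == pytest.approx(expected)

    def test_hormone_aucs_missing_and_constant(self):
        rec = make_record([6] * 5, [100] * 5)
        rec.glp1 = make_series([10.0] * 5, unit="pmol/l")
        out = pr.hormone_aucs(rec)
        assert out["glp1_auc"] == pytest.approx(1200.0)
        assert out["glp1_iauc"] == pytest.approx(0.0)
        assert math.isnan(out["gip_auc"])
        assert math.isnan(out["glucagon_iauc"])
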