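"""Train metrics: I/O fit, PPR, normalization, RRP back-extrapolation, charge."""

import numpy as np
import pytest

from synaptoquant.simulate import ReleaseModelSpec, simulate_depression_train
from synaptoquant.simulate.trains import pool_fixed_point
from synaptoquant.trains import (
    charge_transfer,
    io_curve,
    normalize_train,
    paired_pulse_ratio,
    phase_means,
    recovery_curve,
    rrp_back_extrapolation,
)


class TestIOCurve:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        c = io_curve(x, 2 * x + 1)
        assert (c.slope, c.intercept, c.r_squared) == pytest.approx((2.0, 1.0, 1.0))

    def test_two_points_interpolate(self):
        c = io_curve([0.0, 2.0], [1.0, 5.0])
        assert c.slope == pytest.approx(2.0) and c.intercept == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        x = rng.uniform(0, 5, 40)
        y = 3 * x - 2 + rng.normal(0, 0.5, 40)
        c = io_curve(x, y)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert c.slope == pytest.approx(beta[0], abs=1e-10)
        assert c.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_x_errors(self):
        with pytest.raises(ValueError, match="identical"):
            io_curve([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPPR:
    def test_basic_ratio(self):
        assert paired_pulse_ratio(1.0, 1.5) == 1.5
        assert paired_pulse_ratio(2.0, 2.0) == 1.0

    def test_zero_first_peak_errors(self):
        with pytest.raises(ValueError, match="first peak"):
            paired_pulse_ratio(0.0, 1.0)

    def test_facilitation_with_fast_replenishment(self):
        """With near-complete inter-pulse recovery the model PPR approaches 1."""
        spec = ReleaseModelSpec(N=100, q=1, p=0.2, k_rep=50.0, n_pulses=2, frequency=20.0)
        rec = simulate_depression_train(spec)
        ppr = paired_pulse_ratio(rec.amplitudes[0], rec.amplitudes[1])
        # oracle from the recurrence
        r = 1 - np.exp(-spec.k_rep / spec.frequency)
        P2 = 100 * 0.8 + (100 - 100 * 0.8) * r
        assert ppr == pytest.approx(P2 / 100)
        assert ppr > 0.95


class TestNormalize:
    def test_basic(self):
        np.testing.assert_allclose(normalize_train([2.0, 1.0, 0.5]), [1.0, 0.5, 0.25])

    def test_idempotent_and_scale_invariant(self, rng):
        a = rng.uniform(0.5, 2.0, 30)
        n1 = normalize_train(a)
        np.testing.assert_allclose(normalize_train(7.3 * a), n1)
        np.testing.assert_allclose(normalize_train(n1), n1)

    def test_zero_first_errors(self):
        with pytest.raises(ValueError):
            normalize_train([0.0, 1.0])


class TestPhaseMeans:
    def test_constant(self):
        assert phase_means(np.ones(100)) == (1.0, 1.0)

    def test_decreasing_order(self, rng):
        a = np.sort(rng.uniform(0, 1, 50))[::-1]
        f, l = phase_means(a)
        assert f > l

    def test_geometric_closed_form(self):
        a = 0.5 ** np.arange(100)
        f, l = phase_means(a)
        assert f == pytest.approx((1 - 0.5**10) / (10 * 0.5))
        assert l == pytest.approx(0.0, abs=1e-20)

    def test_short_train_errors(self):
        with pytest.raises(ValueError, match="short"):
            phase_means(np.ones(19))


class TestRrp:
    def test_constant_train_intercept_zero(self):
        est = rrp_back_extrapolation(np.ones(100))
        assert est.intercept == pytest.approx(0.0, abs=1e-9)
        assert est.steady_slope == pytest.approx(1.0)

    def test_single_release_intercept_one(self):
        a = np.zeros(50)
        a[0] = 1.0
        est = rrp_back_extrapolation(a, (21, 50))
        assert est.intercept == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("p", [0.3, 0.5, 0.8])
    def test_depletion_model_recovers_nq(self, p):
        """Zero-replenishment model: intercept x A1 within 5% of Nq = 100."""
        rec = simulate_depression_train(ReleaseModelSpec(N=100, q=1.0, p=p, k_rep=0.0,
                                                         n_pulses=100))
        est = rrp_back_extrapolation(normalize_train(rec.amplitudes), (71, 100))
        assert est.intercept * rec.amplitudes[0] == pytest.approx(100.0, rel=0.05)

    def test_intercept_invariant_to_appended_stimuli(self):
        rec = simulate_depression_train(ReleaseModelSpec(N=50, q=1, p=0.4, k_rep=2.0, n_pulses=120))
        norm = normalize_train(rec.amplitudes)
        e1 = rrp_back_extrapolation(norm[:100], (71, 100))
        e2 = rrp_back_extrapolation(norm, (71, 100))
        assert e1.intercept == pytest.approx(e2.intercept, abs=1e-12)

    def test_nonsteady_window_flagged(self):
        rec = simulate_depression_train(ReleaseModelSpec(N=100, q=1, p=0.5, k_rep=0.0, n_pulses=100))
        est = rrp_back_extrapolation(normalize_train(rec.amplitudes), (1, 20))
        assert not est.steady

    def test_window_validation(self):
        with pytest.raises(ValueError):
            rrp_back_extrapolation(np.ones(100), (90, 120))
        with pytest.raises(ValueError):
            rrp_back_extrapolation(np.ones(100), (50, 53))


class TestRecovery:
    def test_baseline_normalization(self):
        c = recovery_curve([0.1, 0.3], [2.0, 4.0], baseline=4.0)
        np.testing.assert_allclose(c.normalized_amplitudes, [0.5, 1.0])

    def test_model_recovery_matches_recurrence(self):
        """Post-train recovery follows 1 - (1 - P_end/N) exp(-k_rep dt)."""
        spec = ReleaseModelSpec(N=100, q=1, p=0.5, k_rep=1.0, n_pulses=100, frequency=20.0)
        rec = simulate_depression_train(spec)
        # pool after the last release, before any recovery
        P_end = (rec.amplitudes[-1] / (spec.q * spec.p)) * (1 - spec.p)
        intervals = np.arange(0.1, 3.0, 0.2)
        pools = spec.N - (spec.N - P_end) * np.exp(-spec.k_rep * intervals)
        amps = spec.q * spec.p * pools
        c = recovery_curve(intervals, amps, baseline=spec.q * spec.p * spec.N)
        expect = 1 - (1 - P_end / spec.N) * np.exp(-spec.k_rep * intervals)
        np.testing.assert_allclose(c.normalized_amplitudes, expect, rtol=1e-12)

    def test_zero_replenishment_stays_depleted(self):
        spec = ReleaseModelSpec(N=100, q=1, p=1.0, k_rep=0.0, n_pulses=10)
        rec = simulate_depression_train(spec)
        c = recovery_curve([0.1, 1.0, 3.0], [0.0, 0.0, 0.0], baseline=rec.amplitudes[0])
        np.testing.assert_allclose(c.normalized_amplitudes, 0.0)

    def test_zero_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            recovery_curve([0.1], [1.0], baseline=0.0)


class TestChargeTransfer:
    def test_rectangular_pulse(self):
        t = np.linspace(0, 0.05, 5001)
        v = np.where((t >= 0.001) & (t <= 0.011), 1.0, 0.0)
        total, sync, asyn = charge_transfer(t, v, [0.001], sync_window=0.012)
        assert sync == pytest.approx(0.010, rel=1e-3)
        assert asyn == pytest.approx(0.0, abs=1e-9)

    def test_zero_trace(self):
        t = np.linspace(0, 1, 1000)
        assert charge_transfer(t, np.zeros_like(t), [0.1, 0.2]) == (0.0, 0.0, 0.0)

    def test_partition_sums_exactly(self, rng):
        t = np.linspace(0, 5.0, 20_000)
        v = rng.normal(0, 1, t.shape)
        stim = np.arange(0.5, 4.5, 0.05)
        total, sync, asyn = charge_transfer(t, v, stim, sync_window=0.01)
        assert total == pytest.approx(sync + asyn, abs=1e-12)

    def test_kernel_sum_matches_analytic_area(self):
        """Trace built from known alpha-kernels integrates to the analytic area."""
        t = np.linspace(0, 6.0, 600_000)
        stim = np.array([1.0, 1.05, 1.1])
        tau = 0.004
        v = np.zeros_like(t)
        for ts in stim:
            dt = np.clip(t - ts, 0, None)
            v += dt / tau * np.exp(1 - dt / tau)  # peak 1 at dt = tau
        total, sync, asyn = charge_transfer(t, v, stim, sync_window=0.04)
        analytic = 3 * tau * np.e  # integral of each kernel over [0, inf)
        assert total == pytest.approx(analytic, rel=0.005)

    def test_sync_window_vs_isi(self):
        t = np.linspace(0, 1, 1000)
        with pytest.raises(ValueError, match="sync_window"):
            charge_transfer(t, np.zeros_like(t), [0.1, 0.15], sync_window=0.05)
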