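"""Stochastic transcription: tau-leap scheme, cuts, ensembles.

The immigration-death process (constant birth rate b, per-molecule death
rate d2) is the analytic backbone: its mean relaxes as
(b/d2)*(1 - exp(-d2*t)) and its stationary law is Poisson(b/d2).  An
exact event-driven (Gillespie) simulator implemented here serves as the
independent oracle for the fixed-step kernel.
"""

import numpy as np
import pytest
from scipy import stats

from tfchannel import (
    ConfigurationError,
    CutTimes,
    InputSpec,
    KineticParams,
    Modulation,
    SimConfig,
    cut_times_for,
    run_ensemble,
    run_grid,
    simulate_transcription,
)


class TestCutTimes:
    def test_frequency_cuts(self):
        ct = cut_times_for(Modulation.FREQUENCY, 0.05)
        assert (ct.Ta, ct.Tb, ct.Tc) == (10.0, 50.0, 100.0)
        assert not ct.Ta_is_event

    def test_amplitude_cuts_independent_of_value(self):
        ct = cut_times_for(Modulation.AMPLITUDE, 0.0)
        assert (ct.Ta, ct.Tb, ct.Tc) == (1.0, 10.0, 100.0)

    def test_duration_cut_is_pulse_end(self):
        ct = cut_times_for(Modulation.DURATION, 7.0)
        assert ct.Ta == 7.0 and ct.Ta_is_event
        assert (ct.Tb, ct.Tc) == (10.0, 100.0)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            CutTimes(50.0, 10.0, 100.0)


class TestSimulateTranscription:
    def test_zero_tf_means_zero_output(self, fig_a, fast_config):
        n = fast_config.n_steps
        res = simulate_transcription(
            fig_a, np.zeros(n), np.zeros(n), fast_config, record_times=[10, 100]
        )
        assert np.all(res.x == 0)
        assert np.all(res.outs == 0.0)

    def test_grid_mismatch_rejected(self, fig_a, fast_config):
        with pytest.raises(ConfigurationError, match="grid"):
            simulate_transcription(
                fig_a, np.zeros(10), np.zeros(10), fast_config
            )

    def test_unstable_dt_rejected(self):
        params = KineticParams(k1=90.0, k2=1.0, n=1.0, Kd=10.0, d1=90.0)
        cfg = SimConfig(dt=0.05, total_time=1.0, n_reps=1)
        with pytest.raises(ConfigurationError):
            simulate_transcription(params, np.zeros(20), np.zeros(20), cfg)


def _constant_rate_setup(b=6.0, d2=0.12, dt=0.01, total=50.0):
    """Parameters making the kernel an immigration-death process of rate b."""
    # tf huge & n=1 so hill ~ 1; P1 held at 1 via p1 array
    params = KineticParams(k1=0.5, k2=b, n=1.0, Kd=1e-6, d1=1e-9, d2=d2)
    cfg = SimConfig(dt=dt, total_time=total, n_reps=1)
    n = cfg.n_steps
    tf = np.full(n, 1e6)
    p1 = np.ones(n)
    return params, cfg, tf, p1


class TestImmigrationDeathOracle:
    def test_mean_relaxation(self):
        b, d2 = 6.0, 0.12
        params, cfg, tf, p1 = _constant_rate_setup(b, d2)
        times = np.array([5.0, 20.0, 50.0])
        xs = []
        for seed in range(400):
            res = simulate_transcription(
                params, tf, p1, cfg, record_times=times, seed=seed
            )
            xs.append(res.x[np.rint(times / cfg.dt).astype(int) - 1])
        mean_x = np.mean(xs, axis=0)
        expected = (b / d2) * (1 - np.exp(-d2 * times))
        se = np.std(xs, axis=0) / np.sqrt(len(xs))
        assert np.all(np.abs(mean_x - expected) < 4 * se + 0.5)

    def test_stationary_poisson_distribution(self):
        b, d2 = 6.0, 0.12
        params, cfg, tf, p1 = _constant_rate_setup(b, d2, total=80.0)
        final_x = [
            simulate_transcription(params, tf, p1, cfg, seed=1000 + s).x[-1]
            for s in range(500)
        ]
        final_x = np.asarray(final_x)
        lam = b / d2
        kmax = int(lam + 6 * np.sqrt(lam))
        observed = np.bincount(np.minimum(final_x, kmax), minlength=kmax + 1)
        probs = stats.poisson.pmf(np.arange(kmax), lam)
        probs = np.append(probs, 1.0 - probs.sum())
        keep = probs * final_x.size >= 1.0
        res = stats.chisquare(
            np.append(observed[keep], observed[~keep].sum()),
            np.append(probs[keep], probs[~keep].sum()) * final_x.size,
        )
        assert res.pvalue > 0.005

    def test_against_gillespie_oracle(self):
        """Fixed-step tau-leap agrees with exact event-driven simulation."""
        b, d2, T = 8.0, 0.12, 30.0

        def gillespie(seed):
            rng = np.random.default_rng(seed)
            t, x, out = 0.0, 0, 0.0
            while True:
                total_rate = b + d2 * x
                wait = rng.exponential(1.0 / total_rate)
                if t + wait >= T:
                    out += x * (T - t)
                    return x, out
                out += x * wait
                t += wait
                if rng.random() < b / total_rate:
                    x += 1
                else:
                    x -= 1

        exact = np.array([gillespie(s) for s in range(600)])
        params, cfg, tf, p1 = _constant_rate_setup(b, d2, dt=0.01, total=T)
        leap = []
        for seed in range(600):
            res = simulate_transcription(
                params, tf, p1, cfg, record_times=[T], seed=seed
            )
            leap.append((res.x[-1], res.outs[0]))
        leap = np.array(leap)
        for col in (0, 1):
            se = np.sqrt(
                exact[:, col].var() / len(exact) + leap[:, col].var() / len(leap)
            )
            assert abs(exact[:, col].mean() - leap[:, col].mean()) < 4 * se
        # variances consistent too (within ~15%)
        assert leap[:, 0].var() == pytest.approx(exact[:, 0].var(), rel=0.25)

    def test_step_halving_consistency(self):
        """Halving dt leaves the ensemble mean output unchanged within MC error."""
        b, d2, T = 8.0, 0.12, 30.0
        means = []
        for dt in (0.02, 0.01):
            params, cfg, tf, p1 = _constant_rate_setup(b, d2, dt=dt, total=T)
            outs = [
                simulate_transcription(params, tf, p1, cfg, record_times=[T], seed=s).outs[0]
                for s in range(300)
            ]
            means.append((np.mean(outs), np.std(outs) / np.sqrt(len(outs))))
        (m1, s1), (m2, s2) = means
        assert abs(m1 - m2) < 4 * np.hypot(s1, s2)


class TestRunEnsemble:
    def test_output_nondecreasing_in_cut_time(self, fig_a):
        cfg = SimConfig(dt=0.02, n_reps=30, seed=5)
        spec = InputSpec(Modulation.AMPLITUDE, 80.0)
        res = run_ensemble(fig_a, spec, cfg, record_times=[1, 10, 50, 100])
        assert np.all(np.diff(res.outs, axis=1) >= 0.0)

    def test_no_degradation_keeps_all_mrna(self):
        # with a negligible death rate Out grows ~linearly at late times
        params = KineticParams(k1=1.0, k2=20.0, n=1.0, Kd=1e-6, d1=1e-9, d2=1e-12)
        cfg = SimConfig(dt=0.02, n_reps=10, seed=8)
        spec = InputSpec(Modulation.DURATION, 10.0)
        res = run_ensemble(params, spec, cfg, record_times=[25, 50, 75, 100])
        increments = np.diff(res.outs, axis=1)
        assert np.all(increments[:, 1:] >= increments[:, :-1] * 0.95)

    def test_deterministic_under_fixed_seed(self, fig_a):
        cfg = SimConfig(dt=0.05, n_reps=5, seed=42)
        spec = InputSpec(Modulation.FREQUENCY, 0.05)
        r1 = run_ensemble(fig_a, spec, cfg)
        r2 = run_ensemble(fig_a, spec, cfg)
        assert np.array_equal(r1.outs, r2.outs)
        r3 = run_ensemble(fig_a, spec, cfg.replace(seed=43))
        assert not np.array_equal(r1.outs, r3.outs)

    def test_three_amplitudes_strong_pulse_dominates(self, fig_a):
        cfg = SimConfig(dt=0.02, n_reps=40, seed=17)
        means = {}
        for amp in (0.0, 10.0, 100.0):
            spec = InputSpec(Modulation.AMPLITUDE, amp)
            means[amp] = run_ensemble(fig_a, spec, cfg).outs[:, 2].mean()
        assert means[100.0] > 100 * max(means[0.0], means[10.0], 1e-9)

    def test_duplicate_record_times(self, fig_a):
        cfg = SimConfig(dt=0.05, n_reps=3, seed=2)
        spec = InputSpec(Modulation.DURATION, 10.0)
        res = run_ensemble(fig_a, spec, cfg, record_times=[10.0, 10.0, 100.0])
        assert np.array_equal(res.outs[:, 0], res.outs[:, 1])


class TestRunGrid:
    def test_shapes_and_event_cut(self, fig_a):
        cfg = SimConfig(dt=0.05, n_reps=4, seed=3)
        grid = run_grid(fig_a, Modulation.DURATION, cfg, n_inputs=5, use_cuts=True)
        assert grid.outs.shape == (5, 4, 3)
        # duration Ta equals each input value (event-defined)
        assert np.allclose(grid.record_times[:, 0], grid.inputs)

    def test_common_time_grid(self, fig_a):
        cfg = SimConfig(dt=0.05, n_reps=4, seed=3)
        times = [0.0, 50.0, 100.0]
        grid = run_grid(
            fig_a, Modulation.AMPLITUDE, cfg, record_times=times, n_inputs=4
        )
        assert np.all(grid.outs[:, :, 0] == 0.0)  # t = 0: nothing yet
        assert np.all(grid.outs[:, :, 2] >= grid.outs[:, :, 1])
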