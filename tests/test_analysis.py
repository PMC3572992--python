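"""Analysis layer: Lyapunov machinery, intervals, rhythm, PCA, PSTH."""

import numpy as np
import pytest

from clionesim import analysis as ana
from clionesim.engine import dopri_integrate
from clionesim.fixtures import FixtureSpec, make_traces


class TestLyapunovGeneric:
    def test_damped_linear_system_exponents(self):
        """dx/dt = -x in 3D: every exponent equals -1 per unit time."""
        A = -np.eye(3)
        res = ana.lyapunov_spectrum_generic(
            lambda t, y: A @ y, np.ones(3), n_exp=3, t_total=50.0,
            renorm_dt=0.5, dt=1e-2, jac=lambda t, y: A)
        assert res.exponents == pytest.approx([-1.0, -1.0, -1.0], rel=0.02)

    def test_lorenz_against_two_trajectory_oracle(self):
        """Largest exponent of the chaotic Lorenz flow, cross-checked with an
        independent finite-perturbation (two-trajectory) estimate."""

        def lorenz(t, y):
            x, yy, z = y
            return np.array([10.0 * (yy - x), x * (28.0 - z) - yy,
                             x * yy - 8.0 / 3.0 * z])

        spec = ana.lyapunov_spectrum_generic(
            lorenz, np.array([1.0, 1.0, 20.0]), n_exp=1, t_total=150.0,
            renorm_dt=0.5, dt=2e-3, seed=1)
        lam_qr = spec.exponents[0]

        # oracle: renormalized divergence of two nearby trajectories
        rng = np.random.default_rng(2)
        y = np.array([1.0, 1.0, 20.0])
        _, ys = dopri_integrate(lorenz, y, (0.0, 20.0), rtol=1e-9, atol=1e-9,
                                dt_out=20.0)
        y = ys[-1]
        delta = 1e-7
        z = y + delta * rng.standard_normal(3) / np.sqrt(3)
        log_sum, horizon, chunk = 0.0, 150.0, 0.5
        n_chunks = int(horizon / chunk)
        for _ in range(n_chunks):
            _, ya = dopri_integrate(lorenz, y, (0.0, chunk), rtol=1e-10,
                                    atol=1e-10, dt_out=chunk)
            _, yb = dopri_integrate(lorenz, z, (0.0, chunk), rtol=1e-10,
                                    atol=1e-10, dt_out=chunk)
            y, zb = ya[-1], yb[-1]
            d = zb - y
            dist = np.linalg.norm(d)
            log_sum += np.log(dist / delta)
            z = y + d * (delta / dist)
        lam_oracle = log_sum / horizon
        assert lam_qr == pytest.approx(lam_oracle, rel=0.05)

    def test_exponents_sorted_descending(self):
        A = np.diag([-1.0, -2.0, -3.0])
        res = ana.lyapunov_spectrum_generic(
            lambda t, y: A @ y, np.ones(3), n_exp=3, t_total=120.0,
            renorm_dt=0.5, dt=1e-2, jac=lambda t, y: A)
        assert np.all(np.diff(res.exponents) <= 0)
        assert res.exponents == pytest.approx([-1.0, -2.0, -3.0], rel=0.03)


class TestActivationIntervals:
    def test_all_below_empty(self):
        spec = FixtureSpec(duration=2000.0, schedule={})
        t, V, _ = make_traces(spec)
        from clionesim.engine import SimulationResult
        res = SimulationResult(t_grid=t, V=V, spikes={}, events=[],
                               cell_ids=tuple(f"ch{i+1}" for i in range(6)), meta={})
        iv = ana.activation_intervals(res, threshold=0.0)
        assert all(v.size == 0 for v in iv.intervals.values())

    def test_square_pulse_recovered(self):
        spec = FixtureSpec(duration=5000.0,
                           schedule={"ch1": [(1000.0, 2000.0)]})
        t, V, truth = make_traces(spec)
        from clionesim.engine import SimulationResult
        res = SimulationResult(t_grid=t, V=V, spikes={}, events=[],
                               cell_ids=tuple(f"ch{i+1}" for i in range(6)), meta={})
        iv = ana.activation_intervals(res, threshold=0.0)
        assert iv["ch1"] == pytest.approx(truth["ch1"])

    def test_min_duration_filters(self):
        spec = FixtureSpec(duration=5000.0,
                           schedule={"ch1": [(1000.0, 1050.0), (2000.0, 3000.0)]})
        t, V, _ = make_traces(spec)
        from clionesim.engine import SimulationResult
        res = SimulationResult(t_grid=t, V=V, spikes={}, events=[],
                               cell_ids=tuple(f"ch{i+1}" for i in range(6)), meta={})
        iv = ana.activation_intervals(res, threshold=0.0, min_duration=200.0)
        assert iv["ch1"].shape == (1, 2)


class TestRhythm:
    def test_synthetic_alternating_bursts(self):
        """Alternating 1A/2A bursts with a 1 s period: both frequencies 1 Hz
        and near-zero cycle variability."""
        onsets = np.arange(0.0, 30000.0, 1000.0)
        sp1 = np.concatenate([o + np.array([0.0, 50.0, 100.0]) for o in onsets])
        sp2 = sp1 + 500.0
        out = ana.rhythm_frequency(sp1, sp2, max_isi=400.0)
        assert out["ok"]
        assert out["dorsal_hz"] == pytest.approx(1.0, rel=1e-6)
        assert out["ventral_hz"] == pytest.approx(1.0, rel=1e-6)
        assert out["cycle_cv"] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_bursts_flagged(self):
        out = ana.rhythm_frequency(np.array([100.0]), np.array([600.0]))
        assert not out["ok"] and out["flags"]


class TestEpisodePCA:
    def _episodes(self, t, n=3):
        span = t[-1] / n
        return [ana.Episode(start=i * span + 10, end=(i + 1) * span - 10,
                            n_repeats=3) for i in range(n)]

    def test_rank_one_signal_single_component(self):
        t = np.arange(0, 10000.0, 0.5)
        base = np.sin(2 * np.pi * t / 3000.0)
        rates = np.vstack([(i + 1) * base for i in range(6)])
        p = ana.episode_pca(rates, t, self._episodes(t))
        assert p.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_spreads_evenly(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 60000.0, 2.0)
        rates = rng.standard_normal((6, t.size))
        p = ana.episode_pca(rates, t, self._episodes(t))
        assert p.explained_variance_ratio == pytest.approx(np.full(6, 1 / 6),
                                                           abs=0.02)

    def test_ratio_properties(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 30000.0, 2.0)
        mix = rng.standard_normal((6, 3)) @ rng.standard_normal((3, t.size))
        rates = mix + 0.01 * rng.standard_normal((6, t.size))
        p = ana.episode_pca(rates, t, self._episodes(t))
        r = p.explained_variance_ratio
        assert r.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(r) <= 1e-12)

    def test_degenerate_input_flagged(self):
        t = np.arange(0, 10000.0, 0.5)
        rates = np.zeros((6, t.size))
        with pytest.raises(ValueError, match="zero-variance|degenerate"):
            ana.episode_pca(rates, t, self._episodes(t))

    def test_too_few_episodes_rejected(self):
        t = np.arange(0, 10000.0, 0.5)
        with pytest.raises(ValueError, match="episodes"):
            ana.episode_pca(np.ones((6, t.size)), t, self._episodes(t, n=1))


class TestPSTH:
    def test_fixed_latency_single_bin(self):
        aligns = np.arange(0.0, 10000.0, 1000.0)
        spikes = {"1A": aligns + 50.0}
        h = ana.psth(spikes, aligns, window=(0.0, 1000.0), bin_width=100.0)
        assert h.counts["1A"][0] == aligns.size
        assert h.counts["1A"][1:].sum() == 0

    def test_no_spikes_zero_histogram(self):
        h = ana.psth({"1A": np.array([])}, np.array([100.0]),
                     window=(0.0, 1000.0), bin_width=100.0)
        assert h.counts["1A"].sum() == 0

    def test_unrelated_spikes_give_flat_histogram(self):
        rng = np.random.default_rng(3)
        spikes = {"1A": np.sort(rng.uniform(0, 600000.0, 12000))}
        aligns = np.sort(rng.uniform(0, 590000.0, 200))
        h = ana.psth(spikes, aligns, window=(0.0, 4000.0), bin_width=200.0)
        counts = h.counts["1A"]
        expected = counts.mean()
        # Poisson-level flatness: every bin within 5 sigma of the mean
        assert np.all(np.abs(counts - expected) < 5 * np.sqrt(expected))

    def test_needs_alignments(self):
        with pytest.raises(ValueError):
            ana.psth({"1A": np.array([1.0])}, np.array([]))


class TestMotorResponseClasses:
    def test_class_labels(self):
        w = (0.0, 1000.0)
        assert ana.classify_motor_response([], [], 0.0, w) == "none"
        assert ana.classify_motor_response([100.0], [], 0.0, w) == "1A"
        assert ana.classify_motor_response([], [100.0], 0.0, w) == "2A"
        assert ana.classify_motor_response([100.0], [700.0], 0.0, w) == "1A->2A"
        assert ana.classify_motor_response([900.0], [100.0], 0.0, w) == "2A->1A"

    def test_reliability_modal_fraction(self):
        onsets = np.array([0.0, 1000.0, 2000.0, 3000.0])
        sp1 = np.array([100.0, 1100.0, 2100.0])    # 1A fires after 3 of 4
        out = ana.response_reliability(onsets, sp1, np.array([]),
                                       window=(0.0, 500.0))
        assert out["modal_class"] == "1A"
        assert out["fraction"] == pytest.approx(0.75)


class TestSmoothRates:
    def test_kernel_integral_preserves_spike_count(self):
        t = np.arange(0, 20000.0, 0.5)
        spikes = {"c": np.array([5000.0, 9000.0, 9400.0, 15000.0])}
        r = ana.smooth_rates(spikes, t, kernel_ms=100.0, cells=["c"])
        total = r[0].sum() * 0.5 / 1000.0   # integral of rate over seconds
        assert total == pytest.approx(4.0, rel=1e-3)
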