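"""Local-likelihood EM: kernels, sufficient statistics, M-step, scans."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from trackem.model import (
    MotionParameters,
    PiecewiseModel,
    SmoothedState,
    Trajectory,
    VARIANCE_FLOOR,
)
from trackem.simulate import simulate_trajectory, four_regime_model
from trackem.localem import (
    KernelSpec,
    kernel_weight,
    window_weights,
    sufficient_stats,
    em_update,
    local_em_estimate,
    local_loglik,
    sliding_window_scan,
    segment_em,
    MIN_SEGMENT_LENGTH,
)


class TestKernel:
    @pytest.mark.parametrize(
        "v, gamma, expected",
        [(1.2, 0, 0.0), (-1.01, 2, 0.0), (0.0, 0, 0.5), (0.0, 1, 0.75)],
    )
    def test_values(self, v, gamma, expected):
        assert kernel_weight(v, gamma) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("gamma", [0, 1, 2, 3])
    def test_normalization(self, gamma):
        """Each kernel integrates to one over its support [-1, 1]."""
        val, _ = quad(lambda v: kernel_weight(v, gamma), -1, 1)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_nonnegative_and_symmetric(self):
        v = np.linspace(-1.5, 1.5, 101)
        for gamma in (0, 1, 2):
            w = kernel_weight(v, gamma)
            assert np.all(w >= 0)
            assert np.allclose(w, w[::-1])

    def test_window_truncated_at_boundary(self):
        lo, hi, w = window_weights(1, KernelSpec(gamma=1, h=10), n=100)
        assert lo == 1 and hi == 11
        assert len(w) == 11


class TestSufficientStats:
    def _smoothed(self):
        # fixed small smoothed moments for hand computation
        m = np.array([1.0, 2.0, 1.5, 0.5])
        P = np.array([0.1, 0.2, 0.1, 0.3])
        lag = np.array([0.05, 0.04, 0.02])
        return SmoothedState(mean=m, var=P, lag_one=lag)

    def test_hand_computed_sums(self):
        """Weighted moment sums match a direct term-by-term evaluation."""
        smo = self._smoothed()
        y = np.array([1.1, 1.9, 1.4, 0.6])
        w = np.array([0.5, 1.0, 1.0, 0.5])
        st = sufficient_stats(smo, y, w)
        m, P, lag = smo.mean, smo.var, smo.lag_one
        s00_00 = sum(w[k] * (m[k] ** 2 + P[k]) for k in range(3))
        s00_01 = sum(w[k] * m[k] for k in range(3))
        s01_0 = sum(w[k] * (m[k + 1] * m[k] + lag[k]) for k in range(3))
        s01_1 = sum(w[k] * m[k + 1] for k in range(3))
        s11 = sum(w[k] * (m[k + 1] ** 2 + P[k + 1]) for k in range(3))
        sr = sum(w[k] * ((y[k] - m[k]) ** 2 + P[k]) for k in range(4))
        assert st.S00[0, 0] == pytest.approx(s00_00)
        assert st.S00[0, 1] == st.S00[1, 0] == pytest.approx(s00_01)
        assert st.S00[1, 1] == pytest.approx(w[:3].sum())
        assert st.S01[0] == pytest.approx(s01_0)
        assert st.S01[1] == pytest.approx(s01_1)
        assert st.S11 == pytest.approx(s11)
        assert st.Sr == pytest.approx(sr)

    def test_weight_scaling_leaves_regression_invariant(self):
        """Doubling every kernel weight rescales all moment sums equally,
        so the (a, b) solve and the q, r ratios are unchanged."""
        smo = self._smoothed()
        y = np.array([1.1, 1.9, 1.4, 0.6])
        w = np.array([0.5, 1.0, 1.0, 0.5])
        cur = (1.0, 0.0, 0.01, 0.005)
        p1, _, _ = em_update(sufficient_stats(smo, y, w), cur)
        p2, _, _ = em_update(sufficient_stats(smo, y, 2 * w), cur)
        assert np.allclose(p1, p2, rtol=1e-12)

    def test_empty_window_rejected(self):
        smo = self._smoothed()
        with pytest.raises(ValueError):
            sufficient_stats(smo, np.zeros(4), np.zeros(4))


class TestEMUpdate:
    def test_matches_hand_solved_system(self):
        """The M-step equals the hand-solved 2x2 normal equations and the
        explicit residual-variance formulas on a fixed statistics set."""
        from trackem.localem import SufficientStats

        st = SufficientStats(
            S00=np.array([[4.0, 1.0], [1.0, 2.0]]),
            S01=np.array([3.0, 1.5]),
            S11=3.1,
            Sr=0.04,
            n_q=2.0,
            n_r=3.0,
        )
        (a, b, q, r), _, _ = em_update(st, (1.0, 0.0, 0.1, 0.1))
        # solve [a b] [[4,1],[1,2]] = [3, 1.5] by hand: det=7
        a_hand = (3 * 2 - 1.5 * 1) / 7.0
        b_hand = (4 * 1.5 - 1 * 3) / 7.0
        assert a == pytest.approx(a_hand, abs=1e-12)
        assert b == pytest.approx(b_hand, abs=1e-12)
        xi = np.array([a_hand, b_hand])
        q_hand = (3.1 - 2 * xi @ st.S01 + xi @ st.S00 @ xi) / 2.0
        assert q == pytest.approx(q_hand, rel=1e-12)
        assert r == pytest.approx(0.04 / 3.0, rel=1e-12)

    def test_constant_data_fixed_point(self):
        """Noiseless constant observations: the fitted dynamics satisfy
        a*c + b = c and the process variance collapses to the floor."""
        c = 0.7
        y = np.full(60, c)
        traj = Trajectory(y=y, dt=0.1)
        est = local_em_estimate(
            traj, 30, KernelSpec(gamma=0, h=60), init=(1.0, 0.0, 1e-4, 1e-4),
            tol=1e-10, max_iter=300,
        )
        assert est.params.a * c + est.params.b == pytest.approx(c, abs=1e-4)
        assert est.q <= 10 * VARIANCE_FLOOR

    def test_pinned_parameters_respected(self, rng):
        y = np.cumsum(rng.normal(0, 0.1, 120))
        traj = Trajectory(y=y, dt=0.1)
        pin = {"a": 1.0, "b": 0.0, "r": 0.004}
        est = local_em_estimate(
            traj, 60, KernelSpec(gamma=0, h=120), pinned=pin, tol=1e-8
        )
        assert est.params.a == 1.0 and est.params.b == 0.0
        assert est.params.r == 0.004


class TestEMConvergence:
    def test_auxiliary_never_decreases_within_iterations(self, rng):
        """EM ascent: every M-step improves the auxiliary function built
        from its own E-step, across 100 randomized runs."""
        for _ in range(100):
            n = int(rng.integers(40, 80))
            a = rng.uniform(0.6, 1.05)
            q = rng.uniform(1e-4, 0.05)
            r = rng.uniform(1e-4, 0.02)
            m = PiecewiseModel(
                [(1, MotionParameters.from_q(a, rng.uniform(-0.05, 0.05), q, r, 0.1))],
                n, 0.1,
            )
            traj = simulate_trajectory(m, rng=rng)
            gamma = int(rng.integers(0, 3))
            est = local_em_estimate(
                traj, n // 2, KernelSpec(gamma=gamma, h=n), max_iter=40
            )
            for before, after in est.aux_gains:
                assert after >= before - 1e-9 * abs(before)

    def test_local_likelihood_monotone_for_uniform_kernel(self, rng):
        """With a uniform kernel over the whole window the procedure is
        exact EM, so the innovation log-likelihood is non-decreasing."""
        m = PiecewiseModel([(1, MotionParameters(1, 0, 0.05, 0.002))], 150, 0.1)
        traj = simulate_trajectory(m, seed=5)
        est = local_em_estimate(
            traj, 75, KernelSpec(gamma=0, h=150), max_iter=60, track_loglik=True
        )
        ll = np.array(est.logliks)
        assert np.all(np.diff(ll) >= -1e-7 * np.maximum(1.0, np.abs(ll[:-1])))

    def test_q_only_estimate_matches_direct_maximization(self):
        """Pinning a, b, r and estimating q alone reproduces the argmax of
        the likelihood found by an independent 1-D bounded search."""
        m = PiecewiseModel([(1, MotionParameters(1, 0, 0.05, 0.001))], 400, 0.1)
        traj = simulate_trajectory(m, seed=7)
        kern = KernelSpec(gamma=0, h=400)
        pin = {"a": 1.0, "b": 0.0, "r": 0.001}
        est = local_em_estimate(
            traj, 200.5, kern, init=(1, 0, 0.02, 0.001), pinned=pin,
            tol=1e-10, max_iter=500,
        )
        nll = lambda q: -local_loglik(
            traj, 200.5, kern, MotionParameters.from_q(1, 0, q, 0.001, 0.1)
        )
        res = minimize_scalar(nll, bounds=(1e-5, 0.1), method="bounded",
                              options={"xatol": 1e-10})
        assert est.q == pytest.approx(res.x, abs=1e-4)


class TestRecovery:
    def test_pure_diffusion_parameter_recovery(self):
        """Seed-averaged EM on long pure-diffusion runs (D=0.05 um^2/s,
        r=0.001 um^2) recovers D within 10% and r within 20%."""
        Ds, rs = [], []
        for seed in range(20):
            m = PiecewiseModel([(1, MotionParameters(1, 0, 0.05, 0.001))], 5000, 0.1)
            traj = simulate_trajectory(m, seed=seed)
            e = segment_em(traj, 1, 5000, gamma=0, tol=1e-5, max_iter=150)
            Ds.append(e.params.D)
            rs.append(e.params.r)
        assert np.mean(Ds) == pytest.approx(0.05, rel=0.10)
        assert np.mean(rs) == pytest.approx(0.001, rel=0.20)

    def test_bias_shrinks_with_trajectory_length(self):
        """Estimation error of D contracts as the series grows."""
        errs = {}
        for n in (500, 2000, 8000):
            vals = []
            for seed in range(5):
                m = PiecewiseModel([(1, MotionParameters(1, 0, 0.05, 0.001))], n, 0.1)
                e = segment_em(
                    simulate_trajectory(m, seed=100 + seed), 1, n,
                    gamma=0, tol=1e-5, max_iter=150,
                )
                vals.append(e.params.D)
            errs[n] = abs(np.mean(vals) - 0.05)
        assert errs[8000] < errs[500]

    def test_ou_segment_recovery(self):
        """Mean reversion a = 0.86 recovered within 0.05 on 250-step
        segments (matching the benchmark regime-2 conditions)."""
        vals = []
        for seed in range(20):
            m = PiecewiseModel([(1, MotionParameters(0.86, 0, 0.01, 0.0045))], 250, 0.1)
            e = segment_em(simulate_trajectory(m, seed=seed), 1, 250)
            vals.append(e.params.a)
        assert abs(np.mean(vals) - 0.86) < 0.05

    def test_directed_segment_recovery(self):
        """Drift b = -0.1 um/step recovered within 20% on 250-step
        segments (benchmark regime-4 conditions)."""
        vals = []
        for seed in range(20):
            m = PiecewiseModel([(1, MotionParameters(1, -0.1, 0.01, 0.0045))], 250, 0.1)
            e = segment_em(simulate_trajectory(m, seed=seed), 1, 250)
            vals.append(e.params.b)
        assert np.mean(vals) == pytest.approx(-0.1, rel=0.20)


class TestScans:
    def test_constant_parameter_scan_is_stable(self):
        """On constant-parameter data the interior diffusion estimates
        vary by less than 25% of their mean."""
        m = PiecewiseModel([(1, MotionParameters(1, 0, 0.1, 0.0045))], 600, 0.1)
        traj = simulate_trajectory(m, seed=0)
        scan = sliding_window_scan(
            traj, KernelSpec(gamma=1, h=150), stride=10, tol=1e-5, max_iter=80
        )
        D = np.array([e.params.D for e in scan if 150 <= e.t <= 450])
        assert D.std() <= 0.25 * D.mean()

    def test_stride_subsamples_centers(self):
        """With a fixed (non-warm) init policy, stride only subsamples the
        evaluated centers: shared centers agree exactly."""
        m = PiecewiseModel([(1, MotionParameters(1, 0, 0.05, 0.002))], 120, 0.1)
        traj = simulate_trajectory(m, seed=3)
        kern = KernelSpec(gamma=1, h=40)
        kw = dict(init=(1, 0, 0.01, 0.002), init_policy="fixed", tol=1e-6, max_iter=40)
        s1 = sliding_window_scan(traj, kern, stride=1, **kw)
        s5 = sliding_window_scan(traj, kern, stride=5, **kw)
        d1 = {e.t: e for e in s1}
        for e in s5:
            ref = d1[e.t]
            assert abs(e.params.D - ref.params.D) < 1e-6
            assert abs(e.params.a - ref.params.a) < 1e-6

    def test_epanechnikov_scan_smoother_than_uniform(self):
        """Diffusion-switch scenario (D 0.1 -> 0.2 at k=200, h=150, a, b,
        r known): the Epanechnikov scan has smaller total variation than
        the rectangular one."""
        m = PiecewiseModel(
            [(1, MotionParameters(1, 0, 0.1, 0.1)), (200, MotionParameters(1, 0, 0.2, 0.1))],
            400, 0.1,
        )
        pin = {"a": 1.0, "b": 0.0, "r": 0.1}
        tv = {0: [], 1: []}
        for seed in range(2):
            traj = simulate_trajectory(m, seed=seed)
            for gamma in (0, 1):
                scan = sliding_window_scan(
                    traj, KernelSpec(gamma=gamma, h=150), stride=5,
                    pinned=pin, tol=1e-5, max_iter=60,
                )
                D = np.array([e.params.D for e in scan])
                tv[gamma].append(np.sum(np.abs(np.diff(D))))
        assert np.mean(tv[1]) < np.mean(tv[0])

    def test_benchmark_scan_reveals_model_changes(self):
        """On the four-regime schedule, the windowed diffusion estimate
        drops after the first switch and the a(t) curve dips during the
        mean-reverting regime."""
        traj = simulate_trajectory(four_regime_model(), seed=0)
        scan = sliding_window_scan(
            traj, KernelSpec(gamma=1, h=200), stride=25, tol=1e-5, max_iter=80
        )
        ts = np.array([e.t for e in scan])
        D = np.array([e.params.D for e in scan])
        a = np.array([e.params.a for e in scan])
        early = (ts >= 100) & (ts <= 200)
        ou = (ts >= 350) & (ts <= 450)
        assert D[ou].mean() < 0.5 * D[early].mean()
        assert a[ou].mean() < a[early].mean() - 0.02

    def test_segment_em_minimum_length(self):
        traj = simulate_trajectory(four_regime_model(), seed=0)
        with pytest.raises(ValueError, match=str(MIN_SEGMENT_LENGTH)):
            segment_em(traj, 10, 20)
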