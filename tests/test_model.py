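"""Unit and property tests of the switch-model core: activation switch
detection, joint state enumeration, the closed-form ODE solution against a
numerical integrator, the induced linear design, weighted least squares and
the heteroscedastic Gaussian log-likelihood."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from trswitch.model import (
    RedundantThresholdError,
    RegulatorProfile,
    TargetData,
    activation_trajectory,
    build_design,
    compute_activation,
    enumerate_states,
    fit_given_structure,
    log_likelihood,
    solve_trs_ode,
    wls_fit,
)


# ---------------------------------------------------------------------------
# activation
# ---------------------------------------------------------------------------


class TestComputeActivation:
    def test_linear_interpolation_of_crossings(self):
        # tent curve (0, 2, 0) at times (0, 5, 10) against threshold 1
        s0, s = compute_activation(np.array([0.0, 5.0, 10.0]), np.array([0.0, 2.0, 0.0]), 1.0)
        assert s0 == 0
        np.testing.assert_allclose(s, [2.5, 7.5])

    def test_dense_grid_agrees_with_coarse_knots(self, rng):
        # crossing times of a piecewise-linear curve are invariant to
        # refining the knot grid (dense-grid oracle)
        t = np.linspace(0, 10, 21)
        v = np.sin(t) + 0.3 * t
        td = np.linspace(0, 10, 2001)
        vd = np.interp(td, t, v)
        _, s_coarse = compute_activation(t, v, 1.7)
        _, s_dense = compute_activation(td, vd, 1.7)
        np.testing.assert_allclose(s_coarse, s_dense, atol=1e-9)

    def test_no_crossing_constant_state(self):
        s0, s = compute_activation(np.array([0.0, 10.0]), np.array([0.2, 0.4]), 0.9)
        assert s0 == 0 and len(s) == 0

    def test_state_closed_on_active_side(self):
        # value exactly at the threshold counts as active
        s0, _ = compute_activation(np.array([0.0, 1.0]), np.array([0.5, 0.6]), 0.5)
        assert s0 == 1

    def test_single_upward_crossing(self, two_exp_profiles):
        traj = activation_trajectory(two_exp_profiles["A"], 0.5)
        s0, s = traj["exp1"]
        assert s0 == 0 and len(s) == 1
        assert s[0] == pytest.approx(2.0, abs=1e-9)

    def test_redundant_threshold_rejected(self, two_exp_profiles):
        with pytest.raises(RedundantThresholdError):
            activation_trajectory(two_exp_profiles["A"], 2.0)


# ---------------------------------------------------------------------------
# state enumeration
# ---------------------------------------------------------------------------


def _scan_states(trajs, horizons, n_grid=20011):
    """Exhaustive dense-grid oracle for observed joint states."""
    observed = set()
    for exp, L in horizons.items():
        tg = np.linspace(0, L, n_grid, endpoint=False)
        cols = []
        for tf in trajs:
            s0, s = trajs[tf][exp]
            cols.append((s0 + np.searchsorted(np.sort(s), tg, side="right")) % 2)
        for row in np.stack(cols, 1):
            observed.add(tuple(row))
    return observed


class TestEnumerateStates:
    def test_single_tf_single_crossing(self):
        trajs = {"A": {"e1": (0, np.array([4.0]))}}
        part = enumerate_states(trajs, {"e1": 10.0})
        assert part.states == [(0,), (1,)]
        left, right, idx = part.segments["e1"]
        np.testing.assert_allclose(left, [0.0, 4.0])
        np.testing.assert_allclose(right, [4.0, 10.0])
        assert list(idx) == [0, 1]

    def test_repressed_activation_configuration(self, two_exp_profiles):
        # the canonical two-regulator pattern yields all four states, with
        # the active state (1,0) observed in both experiments
        trajs = {f: activation_trajectory(p, 0.5) for f, p in two_exp_profiles.items()}
        part = enumerate_states(trajs, {"exp1": 10.0, "exp2": 10.0})
        assert set(part.states) == {(0, 0), (1, 0), (1, 1), (0, 1)}
        i10 = part.states.index((1, 0))
        left1, right1, idx1 = part.segments["exp1"]
        left2, right2, idx2 = part.segments["exp2"]
        # exp1: (1,0) on [2,6); exp2: (1,0) on [0,3)
        seg1 = [(l, r) for l, r, i in zip(left1, right1, idx1) if i == i10]
        seg2 = [(l, r) for l, r, i in zip(left2, right2, idx2) if i == i10]
        assert seg1 == [pytest.approx((2.0, 6.0))]
        assert seg2 == [pytest.approx((0.0, 3.0))]

    def test_unobserved_state_carries_no_parameter(self):
        # two regulators switching simultaneously: (0,1) never occurs
        trajs = {
            "A": {"e1": (0, np.array([5.0]))},
            "B": {"e1": (1, np.array([5.0]))},
        }
        part = enumerate_states(trajs, {"e1": 10.0})
        assert part.q == 2
        assert set(part.states) == _scan_states(trajs, {"e1": 10.0})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan_and_tiles_horizon(self, seed):
        rng = np.random.default_rng(seed)
        horizons = {"e1": 10.0, "e2": 8.0}
        trajs = {}
        for tf in "ABC":
            trajs[tf] = {}
            for exp, L in horizons.items():
                ns = rng.integers(0, 4)
                trajs[tf][exp] = (
                    int(rng.integers(2)),
                    np.sort(rng.uniform(0.1, L - 0.1, ns)),
                )
        part = enumerate_states(trajs, horizons)
        assert set(part.states) == _scan_states(trajs, horizons)
        for exp, L in horizons.items():
            left, right, _ = part.segments[exp]
            # segments tile [0, L] exactly
            assert left[0] == 0.0 and right[-1] == pytest.approx(L)
            np.testing.assert_allclose(right[:-1], left[1:])
            assert np.sum(right - left) == pytest.approx(L)


# ---------------------------------------------------------------------------
# closed-form ODE solution
# ---------------------------------------------------------------------------


def _random_partition(rng, L=10.0, q_max=4):
    cuts = np.sort(rng.uniform(0, L, rng.integers(1, 5)))
    bounds = np.concatenate([[0.0], cuts, [L]])
    left, right = bounds[:-1], bounds[1:]
    idx = rng.integers(0, q_max, left.size)
    q = idx.max() + 1
    return (left, right, idx), q


class TestSolveTrsOde:
    def test_equilibrium(self):
        segs = (np.array([0.0]), np.array([10.0]), np.array([0]))
        t = np.linspace(0, 10, 30)
        M = solve_trs_ode(0.5, 4.0, segs, np.array([2.0]), t)  # tau = delta*M0
        np.testing.assert_allclose(M, 4.0, rtol=1e-12)

    def test_pure_decay(self):
        segs = (np.array([0.0]), np.array([10.0]), np.array([0]))
        t = np.linspace(0, 10, 30)
        M = solve_trs_ode(0.3, 1.0, segs, np.array([0.0]), t)
        np.testing.assert_allclose(M, np.exp(-0.3 * t), rtol=1e-12)

    def test_rejects_nonpositive_delta(self):
        segs = (np.array([0.0]), np.array([10.0]), np.array([0]))
        with pytest.raises(ValueError):
            solve_trs_ode(0.0, 1.0, segs, np.array([1.0]), [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_against_numerical_integrator(self, seed):
        # adaptive integration restarted at every jump (smooth rhs within
        # each segment) as the numerical oracle
        rng = np.random.default_rng(seed)
        segs, q = _random_partition(rng)
        tau = rng.uniform(0, 5, q)
        delta = rng.uniform(0.05, 1.5)
        M0 = rng.uniform(0, 10)
        left, right, idx = segs
        teval = np.linspace(0.01, 10, 23)
        oracle = np.empty(teval.size)
        m = float(M0)
        for l, r, i in zip(left, right, idx):
            rate = float(tau[i])
            inside = (teval >= l) & (teval < r + 1e-12)
            sol = solve_ivp(
                lambda t, y, rate=rate: rate - delta * y[0],
                (l, r), [m], dense_output=True, rtol=1e-11, atol=1e-13,
            )
            if inside.any():
                oracle[inside] = sol.sol(teval[inside])[0]
            m = float(sol.y[0, -1])
        M = solve_trs_ode(delta, M0, segs, tau, teval)
        np.testing.assert_allclose(M, oracle, rtol=1e-6)


# ---------------------------------------------------------------------------
# design matrix and weighted least squares
# ---------------------------------------------------------------------------


def _small_dataset(rng=None, K=2, n=12):
    rng = rng or np.random.default_rng(0)
    times = {f"e{k}": np.sort(rng.uniform(0, 10, n)) for k in range(K)}
    values = {k: rng.uniform(0, 5, n) for k in times}
    return TargetData(times, values, {k: 10.0 for k in times})


class TestBuildDesign:
    def test_initial_condition_only_row(self):
        data = TargetData({"e1": np.array([0.0])}, {"e1": np.array([3.0])}, {"e1": 10.0})
        part = enumerate_states({"A": {"e1": (0, np.array([]))}}, {"e1": 10.0})
        X, labels = build_design(part, 0.4, data)
        np.testing.assert_allclose(X, [[1.0, 0.0]])
        assert labels[0] == "M0[e1]"

    def test_reproduces_closed_form_solution(self, rng):
        data = _small_dataset(rng)
        trajs = {
            "A": {"e0": (0, np.array([3.0])), "e1": (1, np.array([2.0, 6.0]))},
            "B": {"e0": (0, np.array([7.0])), "e1": (0, np.array([]))},
        }
        part = enumerate_states(trajs, data.horizons)
        delta = 0.6
        X, _ = build_design(part, delta, data)
        tau = rng.uniform(0, 4, part.q)
        M0 = {"e0": 2.0, "e1": 5.0}
        coef = np.concatenate([[M0["e0"], M0["e1"]], tau])
        pred = X @ coef
        for k in data.experiments:
            direct = solve_trs_ode(delta, M0[k], part.segments[k], tau, data.times[k])
            np.testing.assert_allclose(pred[data.slices[k]], direct, rtol=1e-12)

    def test_shared_state_column_spans_experiments(self, two_exp_profiles):
        data = _small_dataset(K=2)
        data_exps = {"exp1": data.times["e0"], "exp2": data.times["e1"]}
        data2 = TargetData(data_exps, {"exp1": data.values["e0"], "exp2": data.values["e1"]},
                           {"exp1": 10.0, "exp2": 10.0})
        trajs = {f: activation_trajectory(p, 0.5) for f, p in two_exp_profiles.items()}
        part = enumerate_states(trajs, data2.horizons)
        X, _ = build_design(part, 0.3, data2)
        i10 = part.states.index((1, 0))
        col = X[:, 2 + i10]
        assert np.any(col[data2.slices["exp1"]] != 0)
        assert np.any(col[data2.slices["exp2"]] != 0)


class TestWlsFit:
    def test_noiseless_recovery(self, rng):
        X = rng.normal(size=(30, 4))
        beta = rng.normal(size=4)
        coef, resid, deficient = wls_fit(X, X @ beta)
        np.testing.assert_allclose(coef, beta, rtol=1e-8)
        assert not deficient
        np.testing.assert_allclose(resid, 0, atol=1e-9)

    def test_equal_weights_match_ols(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        c1, _, _ = wls_fit(X, y, np.full(20, 3.7))
        c0, _, _ = wls_fit(X, y)
        np.testing.assert_allclose(c1, c0, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_weighted_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        v = rng.uniform(0.5, 2.0, 12)
        coef, _, _ = wls_fit(X, y, v)
        W = np.diag(1.0 / v**2)
        oracle = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        np.testing.assert_allclose(coef, oracle, atol=1e-10)

    def test_singular_design_minimum_norm(self):
        X = np.ones((5, 2))  # duplicated column
        y = np.arange(5.0)
        with pytest.warns(RuntimeWarning):
            coef, _, deficient = wls_fit(X, y)
        assert deficient
        np.testing.assert_allclose(coef[0], coef[1])  # minimum-norm splits evenly


class TestLogLikelihood:
    def test_zero_residuals_unit_sigma(self):
        data = _small_dataset(n=5, K=2)
        r = np.zeros(data.n_total)
        ll = log_likelihood(r, data, {k: 1.0 for k in data.experiments},
                            {k: 0.0 for k in data.experiments})
        assert ll == pytest.approx(-(data.n_total / 2) * np.log(2 * np.pi))

    def test_doubling_sigma_with_zero_residuals(self):
        data = _small_dataset(n=6, K=1)
        r = np.zeros(data.n_total)
        psi = {k: 0.0 for k in data.experiments}
        ll1 = log_likelihood(r, data, {k: 1.0 for k in data.experiments}, psi)
        ll2 = log_likelihood(r, data, {k: 2.0 for k in data.experiments}, psi)
        assert ll1 - ll2 == pytest.approx(data.n_total * np.log(2))

    def test_term_by_term_oracle(self, rng):
        data = _small_dataset(rng, K=2, n=5)
        data.set_weight_curve({k: rng.uniform(1, 3, 5) for k in data.experiments})
        r = rng.normal(size=data.n_total)
        sigma = {k: rng.uniform(0.5, 2) for k in data.experiments}
        psi = {k: rng.uniform(0, 1) for k in data.experiments}
        expect = 0.0
        for k in data.experiments:
            v = np.exp(psi[k] * data.log_v_base[k])
            for ri, vi in zip(r[data.slices[k]], v):
                s2 = (sigma[k] * vi) ** 2
                expect += -0.5 * (np.log(2 * np.pi * s2) + ri**2 / s2)
        got = log_likelihood(r, data, sigma, psi)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_rejects_nonpositive_sigma(self):
        data = _small_dataset(n=4, K=1)
        with pytest.raises(ValueError):
            log_likelihood(np.zeros(data.n_total), data,
                           {k: 0.0 for k in data.experiments},
                           {k: 0.0 for k in data.experiments})


# ---------------------------------------------------------------------------
# plug-in structure fit
# ---------------------------------------------------------------------------


class TestFitGivenStructure:
    def _noiseless(self, two_exp_profiles, delta=0.4):
        trajs = {f: activation_trajectory(p, 0.5) for f, p in two_exp_profiles.items()}
        part = enumerate_states(trajs, {"exp1": 10.0, "exp2": 10.0})
        tau_true = np.array([1.0, 8.0, 1.5, 1.5])[: part.q]
        M0 = {"exp1": 2.0, "exp2": 4.0}
        times = {k: np.linspace(0.0, 10.0, 15) for k in part.segments}
        values = {
            k: solve_trs_ode(delta, M0[k], part.segments[k], tau_true, times[k])
            for k in times
        }
        return TargetData(times, values, {k: 10.0 for k in times}), tau_true, M0

    def test_noiseless_exact_recovery(self, two_exp_profiles):
        data, tau_true, M0 = self._noiseless(two_exp_profiles)
        fit = fit_given_structure(
            two_exp_profiles, ("A", "B"), {"A": 0.5, "B": 0.5}, 0.4, data
        )
        np.testing.assert_allclose(fit.tau, tau_true, rtol=1e-8)
        np.testing.assert_allclose(fit.M0, [M0["exp1"], M0["exp2"]], rtol=1e-8)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-8)

    def test_regulator_order_invariance(self, two_exp_profiles):
        # relabeling the states (by permuting the regulator order) leaves
        # the fit invariant
        data, _, _ = self._noiseless(two_exp_profiles)
        data.values = {k: v + 0.1 * np.sin(data.times[k]) for k, v in data.values.items()}
        data.y = np.concatenate([data.values[k] for k in data.experiments])
        f1 = fit_given_structure(two_exp_profiles, ("A", "B"), {"A": 0.5, "B": 0.5}, 0.4, data)
        f2 = fit_given_structure(two_exp_profiles, ("B", "A"), {"A": 0.5, "B": 0.5}, 0.4, data)
        r1 = float(f1.residuals @ f1.residuals)
        r2 = float(f2.residuals @ f2.residuals)
        assert r1 == pytest.approx(r2, rel=1e-10)
        assert sorted(np.round(f1.tau, 8)) == sorted(np.round(f2.tau, 8))

    def test_true_pair_beats_every_single_regulator(self, study1):
        # exhaustive one-regulator threshold grid cannot match the true
        # two-regulator structure's residual sum of squares
        data, profiles = study1["data"], study1["profiles"]
        best_pair = np.inf
        for ra in np.linspace(*profiles["f1"].range_, 15)[1:-1]:
            for rb in np.linspace(*profiles["f2"].range_, 15)[1:-1]:
                fit = fit_given_structure(
                    profiles, ("f1", "f2"), {"f1": ra, "f2": rb}, 0.345, data
                )
                best_pair = min(best_pair, float(fit.residuals @ fit.residuals))
        for tf in profiles:
            lo, hi = profiles[tf].range_
            for r0 in np.linspace(lo, hi, 40)[1:-1]:
                fit = fit_given_structure(profiles, (tf,), {tf: r0}, 0.345, data)
                assert float(fit.residuals @ fit.residuals) > best_pair

    def test_disjoint_experiments_decouple(self, rng):
        # when the two experiments observe entirely different states the
        # joint fit is block-diagonal: editing one experiment's data leaves
        # the other experiment's fitted rates untouched
        t = np.linspace(0, 10, 101)
        A = RegulatorProfile(
            "A",
            {
                "e1": (t, np.full_like(t, 0.2)),  # inactive throughout e1
                "e2": (t, np.full_like(t, 0.8)),  # active throughout e2
            },
        )
        B = RegulatorProfile(
            "B",
            {
                "e1": (t, np.full_like(t, 0.2)),
                "e2": (t, np.clip(0.5 + 0.08 * (t - 5), 0.1, 0.95)),  # crosses
            },
        )
        profiles = {"A": A, "B": B}
        rho = {"A": 0.5, "B": 0.5}
        times = {k: np.linspace(0, 10, 12) for k in ("e1", "e2")}
        values = {k: rng.uniform(1, 3, 12) for k in times}
        data1 = TargetData(times, values, {k: 10.0 for k in times})
        fit1 = fit_given_structure(profiles, ("A", "B"), rho, 0.3, data1)
        # e1 observes only (0,0); e2 observes (1,0) and (1,1)
        assert fit1.partition.states == [(0, 0), (1, 0), (1, 1)]
        values2 = dict(values)
        values2["e1"] = values["e1"] + rng.normal(0, 2, 12)
        data2 = TargetData(times, values2, {k: 10.0 for k in times})
        fit2 = fit_given_structure(profiles, ("A", "B"), rho, 0.3, data2)
        for state in [(1, 0), (1, 1)]:
            i = fit1.partition.states.index(state)
            assert fit1.tau[i] == pytest.approx(fit2.tau[i], rel=1e-9)

    def test_psi_zero_matches_ols_and_continuity(self, study1):
        data, profiles = study1["data"], study1["profiles"]
        rho = {"f1": 500.0, "f2": 500.0}
        base = fit_given_structure(profiles, ("f1", "f2"), rho, 0.345, data,
                                   {k: 0.0 for k in data.experiments})
        X = base.X
        coef_ols, _, _ = wls_fit(X, data.y)
        np.testing.assert_allclose(base.coef, coef_ols, rtol=1e-10)
        eps = 1e-6
        near = fit_given_structure(profiles, ("f1", "f2"), rho, 0.345, data,
                                   {k: eps for k in data.experiments})
        np.testing.assert_allclose(near.coef, base.coef, rtol=1e-4)
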