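"""Cox machinery: Breslow Newton vs brute-force partial-likelihood
maximization and lifelines; elastic-net path boundary/limit behaviour and
objective monotonicity; product-limit and IPCW AUC oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from metaprs.io_formats import SurvivalFrame
from metaprs.survival_core import (
    _ipcw_auc_arrays,
    cox_fit,
    coxnet_cv,
    coxnet_fit,
    ipcw_auc,
    km_curve,
)

from conftest import make_frame


def breslow_partial_loglik(beta, time, event, x):
    """Literal textbook definition, one covariate."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.array(x)[risk])))
    return ll


class TestCoxFit:
    def test_mirrored_groups_give_null_coefficient(self):
        # two groups with identical event-time patterns
        time = [1, 2, 3, 4, 1, 2, 3, 4.0]
        event = [1, 1, 0, 1, 1, 1, 0, 1]
        x = [0, 0, 0, 0, 1, 1, 1, 1.0]
        fit = cox_fit(make_frame(time, event, x=x), ["x"])
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_partial_likelihood(self, seed):
        rng = np.random.default_rng(seed)
        time = np.sort(rng.uniform(1, 10, size=5))  # no ties
        event = np.array([1, 1, 0, 1, 1])
        x = rng.normal(size=5)
        fit = cox_fit(make_frame(time, event, x=x), ["x"])
        res = minimize_scalar(
            lambda b: -breslow_partial_loglik(b, time, event, x),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-5)

    def test_parameter_recovery_at_scale(self):
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.normal(size=n)
        T = -np.log(rng.uniform(size=n)) / np.exp(0.6 * x) * 8
        C = rng.uniform(0, 12, size=n)
        fit = cox_fit(
            make_frame(np.minimum(T, C), (T <= C).astype(int), x=x), ["x"]
        )
        assert abs(fit.coef[0] - 0.6) < 3 * fit.se[0]

    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter
        n = 150
        x1, x2 = rng.normal(size=n), rng.binomial(1, 0.5, n).astype(float)
        T = -np.log(rng.uniform(size=n)) / np.exp(0.5 * x1 - 0.7 * x2)
        C = rng.uniform(0, 2, size=n)
        df = pd.DataFrame({"time": np.minimum(T, C),
                           "event": (T <= C).astype(int), "x1": x1, "x2": x2},
                          index=[f"s{i}" for i in range(n)])
        fit = cox_fit(SurvivalFrame(df, ["x1", "x2"], []), ["x1", "x2"])
        ref = CoxPHFitter().fit(df, "time", "event")
        np.testing.assert_allclose(fit.coef, ref.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.values,
                                   atol=1e-5)

    def test_zscored_predictor_scales_coefficient(self, rng):
        n = 300
        x = rng.normal(3.0, 2.5, size=n)
        T = -np.log(rng.uniform(size=n)) / np.exp(0.3 * x)
        frame = make_frame(T, np.ones(n), x=x, xz=(x - x.mean()) / x.std())
        raw = cox_fit(frame, ["x"]).coef[0]
        z = cox_fit(frame, ["xz"]).coef[0]
        assert z == pytest.approx(raw * x.std(), abs=1e-8)

    def test_time_rescaling_leaves_hr_unchanged(self, rng):
        n = 200
        x = rng.normal(size=n)
        T = -np.log(rng.uniform(size=n)) / np.exp(0.4 * x)
        ev = np.ones(n)
        hr_years = cox_fit(make_frame(T, ev, x=x), ["x"]).hr[0]
        hr_days = cox_fit(make_frame(T * 365.25, ev, x=x), ["x"]).hr[0]
        assert hr_years == pytest.approx(hr_days, rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit(make_frame([1, 2, 3], [0, 0, 0], x=[1, 2, 3.0]), ["x"])

    def test_collinear_predictors_named(self, rng):
        x = rng.normal(size=50)
        frame = make_frame(np.abs(x) + 1, np.ones(50), a=x, b=2 * x)
        with pytest.raises(ValueError, match="collinear|constant"):
            cox_fit(frame, ["a", "b"])


def _sim_frame(rng, n=300, p=3, betas=(0.8, -0.5, 0.0)):
    X = rng.normal(size=(n, p))
    eta = X @ np.asarray(betas)[:p]
    T = -np.log(rng.uniform(size=n)) / np.exp(eta) * 4
    C = rng.uniform(0, 8, size=n)
    cols = {f"x{j}": X[:, j] for j in range(p)}
    return make_frame(np.minimum(T, C), (T <= C).astype(int), **cols)


class TestCoxnet:
    def test_all_zero_at_lambda_max(self, rng):
        frame = _sim_frame(rng)
        path = coxnet_fit(frame, ["x0", "x1", "x2"], alpha=1.0, n_lambda=10)
        np.testing.assert_array_equal(path.coef[:, 0], 0.0)

    def test_lambda_to_zero_matches_unpenalized(self, rng):
        frame = _sim_frame(rng)
        cols = ["x0", "x1", "x2"]
        path = coxnet_fit(frame, cols, alpha=0.5, n_lambda=40,
                          lambda_min_ratio=1e-6)
        ref = cox_fit(frame, cols)
        np.testing.assert_allclose(path.coef[:, -1], ref.coef, atol=1e-3)

    def test_objective_monotone_nonincreasing_per_sweep(self, rng):
        frame = _sim_frame(rng)
        path = coxnet_fit(frame, ["x0", "x1", "x2"], alpha=0.5, n_lambda=20)
        for hist in path.objective_histories:
            assert np.all(np.diff(hist) <= 1e-10)

    def test_lambda_sequence_strictly_decreasing(self, rng):
        path = coxnet_fit(_sim_frame(rng), ["x0", "x1", "x2"], n_lambda=25)
        assert np.all(np.diff(path.lambdas) < 0)

    def test_cv_support_recovery_with_correlated_predictors(self):
        # 9 correlated predictors, 3 truly nonzero
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            n, p = 2000, 9
            Z = rng.normal(size=(n, p)) + 0.6 * rng.normal(size=(n, 1))
            eta = 0.5 * Z[:, 0] + 0.5 * Z[:, 1] + 0.5 * Z[:, 2]
            T = -np.log(rng.uniform(size=n)) / np.exp(eta) * 30
            C = rng.uniform(0, 12, size=n)
            frame = make_frame(np.minimum(T, C), (T <= C).astype(int),
                               **{f"x{j}": Z[:, j] for j in range(p)})
            cols = [f"x{j}" for j in range(p)]
            path = coxnet_cv(frame, cols, alpha=0.5, folds=5, seed=seed,
                             n_lambda=30)
            coef = path.coef[:, path.selected_index]
            top3 = set(np.argsort(-np.abs(coef))[:3])
            hits += top3 == {0, 1, 2}
        assert hits >= 18

    def test_cv_ties_resolve_to_larger_lambda(self, rng):
        frame = _sim_frame(rng, n=150)
        path = coxnet_cv(frame, ["x0", "x1", "x2"], folds=3, seed=0,
                         n_lambda=12)
        best = np.nanmax(path.cv_auc)
        ties = path.lambdas[path.cv_auc == best]
        assert path.selected_lambda == pytest.approx(ties.max())


def km_oracle(time, event):
    """Hand-coded product-limit: loop over distinct event times."""
    out = []
    s = 1.0
    for u in sorted(set(t for t, e in zip(time, event) if e == 1)):
        at_risk = sum(1 for t in time if t >= u)
        d = sum(1 for t, e in zip(time, event) if t == u and e == 1)
        s *= 1 - d / at_risk
        out.append((u, s))
    return out


class TestKmCurve:
    def test_no_events_flat_survival(self):
        km = km_curve([1, 2, 3.0], [0, 0, 0])
        assert km.times.size == 0  # S(t) = 1 everywhere

    def test_closed_form_all_events(self):
        km = km_curve([1, 2, 3, 4.0], [1, 1, 1, 1])
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_matches_hand_coded_oracle_exactly(self, rng):
        time = np.round(rng.uniform(0.5, 10, size=60), 1)  # forces ties
        event = rng.binomial(1, 0.6, size=60)
        km = km_curve(time, event)
        oracle = km_oracle(list(time), list(event))
        np.testing.assert_array_equal(km.times, [t for t, _ in oracle])
        np.testing.assert_allclose(km.survival, [s for _, s in oracle],
                                   rtol=0, atol=0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        time = rng.uniform(1, 5, size=40)
        km = km_curve(time, np.ones(40))
        for u, s in zip(km.times, km.survival):
            assert s == pytest.approx((time > u).mean(), abs=1e-12)


class TestIpcwAuc:
    def test_perfect_marker(self):
        time = np.array([1, 2, 3, 10, 11, 12.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        frame = make_frame(time, event)
        assert ipcw_auc(frame, event.astype(float), horizon=5.0) == 1.0

    def test_null_marker_near_half(self):
        rng = np.random.default_rng(7)
        n = 2000
        T = -np.log(rng.uniform(size=n)) * 5
        C = rng.uniform(0, 10, size=n)
        frame = make_frame(np.minimum(T, C), (T <= C).astype(int))
        auc = ipcw_auc(frame, rng.normal(size=n), horizon=3.0)
        assert abs(auc - 0.5) < 0.03

    def test_no_censoring_equals_pairwise_enumeration(self, rng):
        n = 80
        T = rng.uniform(0.5, 10, size=n)
        marker = rng.normal(size=n) + 0.3 * (T < 4)
        frame = make_frame(T, np.ones(n))
        horizon = 4.0
        cases = np.nonzero(T <= horizon)[0]
        controls = np.nonzero(T > horizon)[0]
        num = sum(
            1.0 if marker[i] > marker[j] else 0.5 if marker[i] == marker[j]
            else 0.0
            for i in cases for j in controls
        )
        assert ipcw_auc(frame, marker, horizon) == pytest.approx(
            num / (len(cases) * len(controls)), abs=1e-12
        )

    def test_sign_flip_maps_auc_to_complement(self, rng):
        n = 400
        T = -np.log(rng.uniform(size=n)) * 4
        C = rng.uniform(0, 8, size=n)
        frame = make_frame(np.minimum(T, C), (T <= C).astype(int))
        m = rng.normal(size=n) - 0.5 * np.minimum(T, 5)
        a = ipcw_auc(frame, m, horizon=3.0)
        b = ipcw_auc(frame, -m, horizon=3.0)
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_no_cases_rejected(self):
        with pytest.raises(ValueError):
            ipcw_auc(make_frame([5, 6, 7.0], [0, 0, 1]), np.arange(3.0), 1.0)

    def test_matches_scikit_survival(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        n = 250
        T = -np.log(rng.uniform(size=n)) * 5
        C = rng.uniform(0, 10, size=n)
        time, event = np.minimum(T, C), (T <= C).astype(int)
        marker = -T + rng.normal(0, 2, size=n)
        y = np.array(list(zip(event.astype(bool), time)),
                     dtype=[("e", bool), ("t", float)])
        horizon = float(np.median(time))
        mine = _ipcw_auc_arrays(time, event, marker, horizon)
        theirs = cumulative_dynamic_auc(y, y, marker, [horizon])[0][0]
        assert mine == pytest.approx(theirs, abs=1e-8)
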