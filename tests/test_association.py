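"""Survival/growth association machinery: fits, codings, selection, diagnostics."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from sowpatterns.association import (
    AssociationWorkspace,
    Candidate,
    SelectionTrace,
    compute_adg,
    cox_fit,
    fit_growth_model,
    global_step3,
    hazard_ratio_to_pct,
    km_estimator,
    litter_size_class,
    lrt,
    reduce_step2,
    schoenfeld_check,
    screen_step1,
    tertile_categorize,
)
from sowpatterns.errors import FitError, InputDataError, RankDeficiencyError

SEED = 1


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

class TestAdg:
    def test_weekly_gain_arithmetic(self):
        rec = pd.Series({"birth_weight": 1000.0, "weight_d7": 2050.0})
        assert compute_adg(rec) == pytest.approx(150.0)

    def test_no_gain(self):
        rec = pd.Series({"birth_weight": 900.0, "weight_d7": 900.0})
        assert compute_adg(rec) == 0.0

    def test_death_before_d7_gives_missing(self):
        df = pd.DataFrame({"birth_weight": [1000.0], "weight_d7": [np.nan]})
        assert compute_adg(df).isna().all()


class TestTertiles:
    def test_one_to_nine_split_evenly(self):
        out = tertile_categorize(np.arange(1, 10))
        assert list(out) == ["I"] * 3 + ["M"] * 3 + ["S"] * 3

    def test_identical_values_all_inferior(self):
        assert set(tertile_categorize([5.0] * 6)) == {"I"}

    @given(st.lists(st.integers(-500, 500), min_size=4, max_size=30, unique=True))
    def test_monotone_transform_preserves_classes(self, values):
        v = np.asarray(values, dtype=float)
        assert list(tertile_categorize(v)) == list(tertile_categorize(v**3))

    def test_needs_three_values(self):
        with pytest.raises(InputDataError):
            tertile_categorize([1.0, 2.0])


def test_litter_size_classes():
    assert list(litter_size_class([12, 14, 15, 16, 17, 21])) == [
        "12-14", "12-14", "15-16", "15-16", "17-21", "17-21"
    ]


class TestHazardRatioToPct:
    @pytest.mark.parametrize("hr, pct", [(0.56, 44.0), (0.72, 28.0), (0.74, 26.0), (1.0, 0.0)])
    def test_worked_conversions(self, hr, pct):
        assert hazard_ratio_to_pct(hr) == pytest.approx(pct)

    def test_positive_hr_required(self):
        with pytest.raises(InputDataError):
            hazard_ratio_to_pct(0.0)


class TestKaplanMeier:
    def test_product_limit_hand_calculation(self):
        # deaths at t=1, 2; censored at 3 and 7
        res = km_estimator([1, 2, 3, 7], [1, 1, 0, 0])
        assert res.survival_at("all", 1.5) == pytest.approx(0.75)
        assert res.survival_at("all", 5.0) == pytest.approx(0.50)

    def test_no_deaths_flat_at_one(self):
        res = km_estimator([5, 6, 7], [0, 0, 0])
        assert res.survival_at("all", 7.0) == 1.0

    def test_identical_groups_logrank_p_one(self):
        times = [1, 2, 3, 4] * 2
        events = [1, 1, 0, 1] * 2
        groups = ["a"] * 4 + ["b"] * 4
        res = km_estimator(times, events, groups)
        assert res.logrank_p == pytest.approx(1.0)


# --------------------------------------------------------------------------
# Cox fit against a hand-written partial likelihood
# --------------------------------------------------------------------------

def _partial_loglik(beta, times, events, x):
    """Brute-force Cox partial log-likelihood (no ties)."""
    order = np.argsort(times)
    t, e, xv = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(t)):
        if e[i]:
            risk = xv[i:] * beta
            ll += beta * xv[i] - logsumexp(risk)
    return ll


class TestCoxFit:
    def test_matches_brute_force_partial_likelihood(self):
        times = np.array([2.0, 3.0, 5.0, 7.0, 11.0])
        events = np.array([1, 1, 0, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        df = pd.DataFrame({"x": x, "time": times, "event": events})
        fit = cox_fit(df, {"x": ["x"]})
        # coarse grid then bracketed refinement of the oracle
        lls = [_partial_loglik(b, times, events, x) for b in np.arange(-5, 5, 0.05)]
        b0 = np.arange(-5, 5, 0.05)[int(np.argmax(lls))]
        res = minimize_scalar(
            lambda b: -_partial_loglik(b, times, events, x),
            bracket=(b0 - 0.1, b0, b0 + 0.1),
        )
        assert abs(fit.params["x"] - res.x) < 1e-4

    def test_null_covariate_hr_near_one(self, rng):
        n = 3000
        x = rng.normal(0, 1, n)
        times = np.ceil(rng.exponential(10, n)).clip(max=28)
        events = (times < 28).astype(int)
        df = pd.DataFrame({"x": x, "time": times, "event": events})
        fit = cox_fit(df, {"x": ["x"]})
        assert abs(fit.params["x"]) < 2 * fit.se["x"]

    def test_zero_events_rejected(self):
        df = pd.DataFrame({"x": [1.0, 0.0], "time": [5.0, 6.0], "event": [0, 0]})
        with pytest.raises(FitError):
            cox_fit(df, {"x": ["x"]})

    def test_collinear_terms_rejected(self):
        df = pd.DataFrame(
            {"x": [1.0, 0.0, 1.0, 0.0], "y": [2.0, 0.0, 2.0, 0.0],
             "time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 0]}
        )
        with pytest.raises(RankDeficiencyError):
            cox_fit(df, {"x": ["x"], "y": ["y"]})

    def test_hr_is_exp_coef_and_ci_ordered(self, rng):
        n = 400
        x = rng.normal(0, 1, n)
        lam = 0.1 * np.exp(0.5 * x)
        times = np.ceil(rng.exponential(1 / lam)).clip(max=30)
        df = pd.DataFrame({"x": x, "time": times, "event": (times < 30).astype(int)})
        fit = cox_fit(df, {"x": ["x"]})
        assert fit.hr["x"] == pytest.approx(np.exp(fit.params["x"]))
        assert fit.ci_lower["x"] < fit.hr["x"] < fit.ci_upper["x"]
        assert hazard_ratio_to_pct(fit.hr["x"]) == pytest.approx(
            (1 - np.exp(fit.params["x"])) * 100
        )


def test_growth_fit_matches_normal_equations(rng):
    X = rng.normal(0, 1, (10, 2))
    y = 3.0 + X @ np.array([2.0, -1.0]) + rng.normal(0, 0.1, 10)
    df = pd.DataFrame({"a": X[:, 0], "b": X[:, 1], "adg": y})
    fit = fit_growth_model(df, {"a": ["a"], "b": ["b"]})
    Xd = np.column_stack([np.ones(10), X])
    beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
    assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)


# --------------------------------------------------------------------------
# simulated data helpers for the selection protocol
# --------------------------------------------------------------------------

def make_survival_data(
    rng, n_sows=60, beta=0.0, trait_col="pcall_af", piglets_per_sow=(12, 16)
):
    """Piglet-level survival data with one dam-level behavioural trait."""
    trait = rng.normal(250, 120, n_sows).clip(min=20)
    rows = []
    for i in range(n_sows):
        n_p = int(rng.integers(*piglets_per_sow))
        lam = 0.006 * np.exp(beta * (trait[i] - 250.0))
        for j in range(n_p):
            t = np.ceil(rng.exponential(1 / max(lam, 1e-9))) if lam > 0 else np.inf
            time = min(t, 28.0)
            rows.append(
                {
                    "dam_id": f"S{i:03d}",
                    "genetic_type": ["LW/LW", "LW/MS", "MS/LW", "MS/MS"][int(rng.integers(4))],
                    "litter_size_class": ["12-14", "15-16", "17-21"][i % 3],
                    "pen": "ABCD"[i % 4],
                    trait_col: trait[i],
                    "time": time,
                    "event": int(time < 28.0),
                }
            )
    return pd.DataFrame(rows)


def _ws(data, outcome="survival"):
    return AssociationWorkspace(data, outcome)


class TestScreenStep1:
    def test_empty_candidate_list(self, rng):
        ws = _ws(make_survival_data(rng, beta=0.004))
        assert screen_step1(ws, [], 0.05) == {}

    def test_continuous_coding_wins_for_linear_effect(self):
        # a strong linear hazard effect should be coded continuous (by AIC)
        # in the vast majority of replicates
        master = np.random.default_rng(SEED)
        wins = kept = 0
        reps = 60
        for _ in range(reps):
            data = make_survival_data(master, n_sows=40, beta=0.004)
            ws = _ws(data)
            sel = screen_step1(ws, [Candidate("pcall_af", "count", "pcall_af", 0.01)], 0.05)
            if "pcall_af" in sel:
                kept += 1
                wins += sel["pcall_af"]["coding"] == "continuous"
        assert kept >= 0.9 * reps  # power: the planted effect is detected
        assert wins >= 0.85 * kept

    def test_cluster_replaced_by_mediating_raw_trait(self):
        # cluster = thresholded version of the raw trait that truly drives
        # the hazard: the raw trait should usually win the AIC comparison
        master = np.random.default_rng(SEED)
        raw_wins = 0
        reps = 30
        for _ in range(reps):
            data = make_survival_data(master, n_sows=50, beta=0.005, trait_col="llu_h_af")
            dams = data.groupby("dam_id")["llu_h_af"].first()
            labels = (dams > dams.median()).map({True: "A", False: "B"})
            data["cl_post_af"] = data["dam_id"].map(labels)
            ws = _ws(data)
            sel = screen_step1(
                ws,
                [Candidate("cl_post_af", "cluster", "cl_post_af", raw_trait="llu_h_af")],
                0.05,
            )
            if sel.get("cl_post_af", {}).get("coding") == "raw_trait":
                raw_wins += 1
        assert raw_wins > reps / 2


class TestReduceStep2:
    def test_all_noise_terms_usually_eliminated(self):
        # two pure-noise dam traits: the backward elimination should end with
        # an empty behavioural set in ~90 % of replicates (>= 3-sigma bound)
        master = np.random.default_rng(SEED)
        empty = 0
        reps = 50
        for _ in range(reps):
            data = make_survival_data(master, n_sows=50, beta=0.0)
            data["noise2"] = data["dam_id"].map(
                dict(zip(data["dam_id"].unique(),
                         master.normal(size=data["dam_id"].nunique())))
            )
            ws = _ws(data)
            for name, col in (("t1", "pcall_af"), ("t2", "noise2")):
                ws.register(name, pd.DataFrame({f"{name}__cont": data[col]}))
            kept = reduce_step2(ws, ["t1", "t2"], 0.05)
            empty += not kept
        assert empty >= 0.78 * reps

    def test_planted_effect_retained_among_noise(self):
        rng = np.random.default_rng(SEED)
        data = make_survival_data(rng, n_sows=150, beta=0.004)
        dams = data["dam_id"].unique()
        for name in ("n1", "n2"):
            data[name] = data["dam_id"].map(dict(zip(dams, rng.normal(size=dams.size))))
        ws = _ws(data)
        ws.register("planted", pd.DataFrame({"planted__cont": data["pcall_af"] / 100}))
        for name in ("n1", "n2"):
            ws.register(name, pd.DataFrame({f"{name}__cont": data[name]}))
        kept = reduce_step2(ws, ["planted", "n1", "n2"], 0.05)
        assert "planted" in kept


class TestGlobalStep3:
    def test_independent_effects_from_disjoint_periods_all_retained(self):
        rng = np.random.default_rng(SEED)
        n_sows = 150
        x1 = rng.normal(0, 1, n_sows)
        x2 = rng.normal(0, 1, n_sows)
        rows = []
        for i in range(n_sows):
            for j in range(12):
                lam = 0.01 * np.exp(0.5 * x1[i] - 0.5 * x2[i])
                t = min(np.ceil(rng.exponential(1 / lam)), 28.0)
                rows.append(
                    {"dam_id": f"S{i}", "genetic_type": "LW/LW",
                     "litter_size_class": "12-14", "pen": "A",
                     "x1": x1[i], "x2": x2[i], "time": t, "event": int(t < 28)}
                )
        data = pd.DataFrame(rows)
        ws = AssociationWorkspace(data, "survival", fixed_effects=())
        ws.register("bf_term", pd.DataFrame({"bf__c": data["x1"]}))
        ws.register("af_term", pd.DataFrame({"af__c": data["x2"]}))
        fit, kept = global_step3(ws, {"bf": ["bf_term"], "af": ["af_term"]}, 0.05)
        assert sorted(kept) == ["af_term", "bf_term"]

    def test_duplicated_collinear_term_dropped_and_traced(self, rng):
        data = make_survival_data(rng, n_sows=60, beta=0.004)
        ws = _ws(data)
        ws.register("a", pd.DataFrame({"a__c": data["pcall_af"] / 100}))
        ws.register("b", pd.DataFrame({"b__c": data["pcall_af"] / 100}))  # duplicate
        steps = []
        fit, kept = global_step3(ws, {"bf": ["a"], "af": ["b"]}, 0.05, trace_steps=steps)
        assert "b" not in kept
        assert any(s["action"] == "dropped_collinear" for s in steps)

    def test_no_survivors_gives_covariates_only_model(self, rng):
        data = make_survival_data(rng, beta=0.0)
        ws = _ws(data)
        fit, kept = global_step3(ws, {"bf": [], "df": [], "af": []}, 0.05)
        assert kept == []
        assert set(fit.params.index) == {
            c for cols in ws.fixed_terms.values() for c in cols
        }


class TestSchoenfeld:
    def test_single_term_global_equals_term_test(self, rng):
        data = make_survival_data(rng, n_sows=60, beta=0.004)
        df = data[["pcall_af", "time", "event"]].rename(columns={"pcall_af": "x"})
        fit = cox_fit(df, {"x": ["x"]})
        tab = schoenfeld_check(fit)
        assert tab.loc["GLOBAL", "chi2"] == pytest.approx(tab.loc["x", "chi2"])
        assert tab.loc["GLOBAL", "p"] == pytest.approx(tab.loc["x", "p"])

    def test_type_one_error_calibrated_under_ph(self):
        master = np.random.default_rng(SEED)
        reps, rejections = 100, 0
        for _ in range(reps):
            n = 120
            x = master.normal(0, 1, n)
            times = np.ceil(master.exponential(10 / np.exp(0.4 * x))).clip(max=25)
            df = pd.DataFrame({"x": x, "time": times, "event": (times < 25).astype(int)})
            tab = schoenfeld_check(cox_fit(df, {"x": ["x"]}))
            rejections += tab.loc["x", "p"] < 0.05
        assert 0.005 * reps <= rejections <= 0.12 * reps

    def test_detects_planted_time_varying_effect(self):
        master = np.random.default_rng(SEED)
        reps, rejections = 20, 0
        for _ in range(reps):
            n = 800
            x = master.normal(0, 1, n)
            # effect reverses sign after day 6: grossly non-proportional
            t = np.empty(n)
            for i in range(n):
                day, alive = 0, True
                while alive and day < 25:
                    day += 1
                    b = 0.8 if day <= 6 else -0.8
                    if master.random() < 1 - np.exp(-0.05 * np.exp(b * x[i])):
                        alive = False
                t[i] = day
            df = pd.DataFrame({"x": x, "time": t, "event": (t < 25).astype(int)})
            tab = schoenfeld_check(cox_fit(df, {"x": ["x"]}))
            rejections += tab.loc["x", "p"] < 0.05
        assert rejections >= reps / 2

    def test_close_to_lifelines_reference_test(self, rng):
        from lifelines.statistics import proportional_hazard_test

        data = make_survival_data(rng, n_sows=80, beta=0.003)
        df = data[["pcall_af", "time", "event"]].rename(columns={"pcall_af": "x"})
        fit = cox_fit(df, {"x": ["x"]})
        mine = schoenfeld_check(fit).loc["x", "p"]
        theirs = proportional_hazard_test(
            fit.model, fit.train_df, time_transform="rank"
        ).p_value
        assert abs(mine - float(np.atleast_1d(theirs)[0])) < 0.05


def test_selection_trace_round_trip_and_replay(rng):
    data = make_survival_data(rng, n_sows=120, beta=0.004)
    ws = _ws(data)
    trace = SelectionTrace()
    sel = screen_step1(
        ws, [Candidate("pcall_af", "count", "pcall_af", 0.01)], 0.05,
        trace_steps=trace.steps,
    )
    kept = reduce_step2(ws, sel, 0.05, trace_steps=trace.steps)
    fit, final = global_step3(ws, {"af": kept}, 0.05, trace_steps=trace.steps)
    trace.final_terms = {n: {"columns": ws.terms[n]} for n in final}
    trace.final_params = {k: float(v) for k, v in fit.params.items()}
    # JSON round trip
    restored = SelectionTrace.from_json(trace.to_json())
    assert restored.final_terms == trace.final_terms
    # replay: refitting the recorded term set reproduces the model exactly
    refit = ws.fit(list(restored.final_terms))
    for k, v in restored.final_params.items():
        assert refit.params[k] == pytest.approx(v, abs=1e-12)
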