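"""Associating sow behaviour with piglet survival and early growth.

Piglet-level outcomes (death during lactation, censored at weaning; average
daily gain D0-D7) are regressed on dam-level behavioural covariates with a
three-step protocol applied separately to survival (Cox proportional
hazards, Efron tie correction) and growth (ordinary least squares):

1. *Screening*: each behavioural item of each peripartum period is tested
   one at a time, adjusted for the fixed effects (piglet genetic type,
   litter-size class, pen).  Count traits are tried as a continuous
   covariate and as empirical tertile classes (I / M / S; growth models may
   additionally use the two-class S vs M+I coding); the coding with the
   lower AIC is kept.  A significant cluster factor may be replaced by the
   raw trait that mainly explains the cluster contrast when that trait has
   the lower AIC.  Items with a likelihood-ratio p < alpha survive.
2. *Per-period reduction*: survivors of one period enter a saturated model
   which is pruned by backward elimination on the likelihood-ratio test.
3. *Global model*: survivors of all periods are pooled and pruned again.

Fixed effects are never dropped.  Every decision is recorded in a
:class:`SelectionTrace` that can be replayed against the data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .config import PERIODS
from .errors import FitError, InputDataError, RankDeficiencyError

__all__ = [
    "GENETIC_TYPES",
    "LITTER_SIZE_CLASSES",
    "PENS",
    "compute_adg",
    "tertile_categorize",
    "litter_size_class",
    "km_estimator",
    "KMResult",
    "cox_fit",
    "CoxFit",
    "fit_growth_model",
    "GrowthFit",
    "hazard_ratio_to_pct",
    "Candidate",
    "AssociationWorkspace",
    "screen_step1",
    "reduce_step2",
    "global_step3",
    "schoenfeld_check",
    "SelectionTrace",
    "SurvivalAssociationModel",
    "GrowthAssociationModel",
    "AssociationResults",
]

GENETIC_TYPES: tuple[str, ...] = ("LW/MS", "LW/LW", "MS/LW", "MS/MS")
LITTER_SIZE_CLASSES: tuple[str, ...] = ("12-14", "15-16", "17-21")
PENS: tuple[str, ...] = ("A", "B", "C", "D")

DEFAULT_FIXED_EFFECTS: tuple[str, ...] = ("genetic_type", "litter_size_class", "pen")
_FIXED_LEVELS: dict[str, tuple[str, ...]] = {
    "genetic_type": GENETIC_TYPES,
    "litter_size_class": LITTER_SIZE_CLASSES,
    "pen": PENS,
}


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def compute_adg(record: "pd.Series | pd.DataFrame | Mapping") -> "float | pd.Series":
    """Average daily gain (g/d) from birth to D7: ``(w_D7 - w_D0) / 7``.

    Missing weights (e.g. the piglet died before D7) propagate to NaN; such
    piglets are excluded from growth models.
    """
    if isinstance(record, pd.DataFrame):
        return (record["weight_d7"] - record["birth_weight"]) / 7.0
    w7, w0 = record["weight_d7"], record["birth_weight"]
    if w7 is None or w0 is None:
        return float("nan")
    return (w7 - w0) / 7.0


def tertile_categorize(values: Sequence[float]) -> np.ndarray:
    """Empirical tertile classes: I (<= 33rd pct), M (<= 66th), S (above).

    Percentiles use linear interpolation of the empirical distribution
    (NumPy's default, Hyndman-Fan type 7); boundary values follow the
    stated <= / > rules, so identical values all land in class I.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise InputDataError("tertile coding needs at least 3 values")
    p33, p66 = np.percentile(v, [33, 66])
    return np.where(v <= p33, "I", np.where(v <= p66, "M", "S"))


def litter_size_class(n_born: "int | Sequence[int]") -> "str | np.ndarray":
    """Litter-size classes 12-14, 15-16, 17-21 piglets born alive."""
    n = np.asarray(n_born)
    out = np.where(n <= 14, "12-14", np.where(n <= 16, "15-16", "17-21"))
    return out[()] if out.ndim == 0 else out


def hazard_ratio_to_pct(hr: float) -> float:
    """Percent change in instantaneous risk: ``(1 - HR) * 100``.

    Positive values are risk reductions (HR 0.56 -> 44 % lower risk).
    """
    if hr <= 0:
        raise InputDataError("hazard ratio must be positive")
    return (1.0 - hr) * 100.0


@dataclass
class KMResult:
    """Product-limit survival curves per group plus a log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # group -> columns [time, survival]
    logrank_p: float | None
    logrank_stat: float | None

    def survival_at(self, group: str, t: float) -> float:
        c = self.curves[group]
        below = c[c["time"] <= t]
        return 1.0 if below.empty else float(below["survival"].iloc[-1])


def km_estimator(
    times: Sequence[float],
    events: Sequence[int],
    group: Sequence | None = None,
) -> KMResult:
    """Kaplan-Meier estimate per group with a log-rank test across groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(group) if group is not None else np.full(times.size, "all")
    curves = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise InputDataError(f"empty group {g!r}")
        kmf = KaplanMeierFitter().fit(times[mask], events[mask])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[str(g)] = sf
    p = stat = None
    if len(curves) > 1:
        res = multivariate_logrank_test(times, groups, events)
        p, stat = float(res.p_value), float(res.test_statistic)
    return KMResult(curves, p, stat)


# --------------------------------------------------------------------------
# model fits
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model (Efron tie handling)."""

    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    terms: dict[str, list[str]]
    ties: str = "efron"
    model: CoxPHFitter | None = field(default=None, repr=False)
    train_df: pd.DataFrame | None = field(default=None, repr=False)
    duration_col: str = "time"
    event_col: str = "event"

    @property
    def loglik(self) -> float:
        return self.log_likelihood

    @property
    def n_params(self) -> int:
        return int(self.params.size)

    def summary(self) -> str:
        lines = [
            f"Cox proportional-hazards fit ({self.ties} ties): "
            f"n={self.n}, events={self.n_events}, "
            f"partial logL={self.log_likelihood:.2f}, AIC={self.aic:.2f}",
            f"{'term':<32}{'coef':>9}{'HR':>8}{'95% CI':>18}{'p':>9}",
        ]
        for name in self.params.index:
            ci = f"[{self.ci_lower[name]:.2f}, {self.ci_upper[name]:.2f}]"
            lines.append(
                f"{name:<32}{self.params[name]:>9.3f}{self.hr[name]:>8.3f}"
                f"{ci:>18}{self.pvalues[name]:>9.3g}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "hr": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.pvalues,
                "risk_change_pct": [hazard_ratio_to_pct(h) for h in self.hr],
            }
        )


def _check_rank(X: pd.DataFrame) -> None:
    if X.shape[1] == 0:
        return
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise RankDeficiencyError("design matrix is rank deficient (collinear terms)")


def cox_fit(
    data: pd.DataFrame,
    terms: Mapping[str, Sequence[str]],
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Fit a Cox model on the named term columns of ``data``.

    ``terms`` maps a term name to the design columns it spans (a categorical
    term spans several dummy columns).  The partial likelihood is maximised
    with Efron's tie correction -- day-resolution death times make ties the
    rule, not the exception.  Numerical optimisation is delegated to
    lifelines; this function owns the contract (term bookkeeping, rank and
    event checks, AIC).
    """
    cols: list[str] = []
    for name, cs in terms.items():
        cols.extend(c for c in cs if c not in cols)
    df = data[cols + [duration_col, event_col]].astype(float).reset_index(drop=True)
    if df.isna().any().any():
        raise InputDataError("Cox design contains missing values")
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise FitError("cannot fit a Cox model with zero events")
    _check_rank(df[cols])
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(
                df,
                duration_col=duration_col,
                event_col=event_col,
                fit_options={"precision": 1e-9},
            )
        except ConvergenceError as err:  # pragma: no cover - defensive
            raise FitError(f"Cox fit did not converge: {err}") from err
    summ = cph.summary
    k = len(cph.params_)
    return CoxFit(
        params=cph.params_.copy(),
        se=cph.standard_errors_.copy(),
        pvalues=summ["p"].copy(),
        hr=summ["exp(coef)"].copy(),
        ci_lower=summ["exp(coef) lower 95%"].copy(),
        ci_upper=summ["exp(coef) upper 95%"].copy(),
        log_likelihood=float(cph.log_likelihood_),
        aic=-2.0 * float(cph.log_likelihood_) + 2.0 * k,
        n=int(df.shape[0]),
        n_events=n_events,
        terms={name: list(cs) for name, cs in terms.items()},
        model=cph,
        train_df=df,
        duration_col=duration_col,
        event_col=event_col,
    )


@dataclass
class GrowthFit:
    """An ordinary-least-squares fit of piglet average daily gain."""

    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    log_likelihood: float
    aic: float
    n: int
    sigma: float
    terms: dict[str, list[str]]
    model: object | None = field(default=None, repr=False)

    @property
    def loglik(self) -> float:
        return self.log_likelihood

    @property
    def n_params(self) -> int:
        return int(self.params.size)  # includes the intercept

    def summary(self) -> str:
        lines = [
            f"OLS fit of ADG (g/d): n={self.n}, sigma={self.sigma:.1f}, "
            f"logL={self.log_likelihood:.2f}, AIC={self.aic:.2f}",
            f"{'term':<32}{'estimate':>10}{'se':>8}{'p':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<32}{self.params[name]:>10.2f}{self.se[name]:>8.2f}"
                f"{self.pvalues[name]:>10.3g}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.pvalues,
            }
        )


def fit_growth_model(
    data: pd.DataFrame,
    terms: Mapping[str, Sequence[str]],
    y_col: str = "adg",
) -> GrowthFit:
    """OLS of average daily gain on the named term columns (plus intercept)."""
    cols: list[str] = []
    for name, cs in terms.items():
        cols.extend(c for c in cs if c not in cols)
    df = data[cols + [y_col]].astype(float).reset_index(drop=True)
    if df.isna().any().any():
        raise InputDataError("growth design contains missing values")
    _check_rank(df[cols])
    X = sm.add_constant(df[cols], has_constant="add")
    res = sm.OLS(df[y_col], X).fit()
    ci = res.conf_int()
    return GrowthFit(
        params=res.params.copy(),
        se=res.bse.copy(),
        pvalues=res.pvalues.copy(),
        ci_lower=ci[0].copy(),
        ci_upper=ci[1].copy(),
        log_likelihood=float(res.llf),
        aic=float(res.aic),
        n=int(res.nobs),
        sigma=float(np.sqrt(res.scale)),
        terms={name: list(cs) for name, cs in terms.items()},
        model=res,
    )


def lrt(full: "CoxFit | GrowthFit", reduced: "CoxFit | GrowthFit") -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (statistic, df, p)."""
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise InputDataError("models are not strictly nested")
    return stat, df, float(sps.chi2.sf(stat, df))


# --------------------------------------------------------------------------
# proportional-hazards diagnostic
# --------------------------------------------------------------------------

def schoenfeld_check(fit: CoxFit, transform: str = "rank") -> pd.DataFrame:
    """Schoenfeld-residual test of the proportional-hazards assumption.

    For each covariate, correlates the Schoenfeld residual at the event
    times with a transform of time (``rank`` or ``identity``); a small p
    flags a time-varying effect.  The last row, ``GLOBAL``, is the joint
    chi-square test over all covariates; for a single-covariate model it
    coincides with the covariate's own test.
    """
    if fit.model is None or fit.train_df is None:
        raise FitError("fit does not carry its training data")
    if fit.n_params == 0:
        raise FitError("no covariates to test")
    resid = fit.model.compute_residuals(fit.train_df, kind="schoenfeld")
    resid = resid[list(fit.params.index)]
    times = fit.train_df.loc[resid.index, fit.duration_col].to_numpy(dtype=float)
    if transform == "rank":
        g = sps.rankdata(times)
    elif transform == "identity":
        g = times
    else:
        raise InputDataError(f"unknown time transform {transform!r}")
    gc = g - g.mean()
    m = resid.shape[0]
    info = np.linalg.inv(fit.model.variance_matrix_.to_numpy(dtype=float))
    vbar = info / m  # average per-event covariance of the residuals
    z = resid.to_numpy(dtype=float).T @ gc
    denom = float((gc**2).sum())
    rows = []
    for j, name in enumerate(resid.columns):
        chi2 = z[j] ** 2 / (denom * vbar[j, j])
        rows.append((name, chi2, 1, float(sps.chi2.sf(chi2, 1))))
    chi2_g = float(z @ np.linalg.solve(denom * vbar, z))
    p_g = float(sps.chi2.sf(chi2_g, len(z)))
    rows.append(("GLOBAL", chi2_g, len(z), p_g))
    return pd.DataFrame(rows, columns=["term", "chi2", "df", "p"]).set_index("term")


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

def _categorical_dummies(
    values: pd.Series, name: str, levels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Treatment-coded dummies, reference = first level present."""
    if levels is None:
        levels = sorted(pd.unique(values.dropna()))
    levels = [lv for lv in levels if (values == lv).any()]
    cols = {}
    for lv in levels[1:]:
        cols[f"{name}={lv}"] = (values == lv).astype(float)
    return pd.DataFrame(cols, index=values.index)


@dataclass
class Candidate:
    """One behavioural item entering the screening step.

    ``kind`` is ``"count"`` for the daily posture-change counts (codeable as
    continuous or tertile classes) or ``"cluster"`` for an activity-pattern
    cluster factor.  ``scale`` rescales a continuous coding (0.01 reports a
    count effect per 100 changes/day).  ``raw_trait`` names the continuous
    trait that mainly explains a cluster contrast, eligible to replace a
    significant cluster factor when it wins on AIC.
    """

    name: str
    kind: str
    column: str
    scale: float = 1.0
    raw_trait: str | None = None


class AssociationWorkspace:
    """Shared design matrix + cached nested fits for one outcome.

    Holds the piglet-level data (with dam covariates merged in), the fixed
    effects design (always included), and the materialised design columns
    of every behavioural coding registered so far.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        fixed_effects: Sequence[str] = DEFAULT_FIXED_EFFECTS,
        duration_col: str = "time",
        event_col: str = "event",
        y_col: str = "adg",
    ) -> None:
        if outcome not in ("survival", "growth"):
            raise InputDataError("outcome must be 'survival' or 'growth'")
        self.outcome = outcome
        self.duration_col, self.event_col, self.y_col = duration_col, event_col, y_col
        self.data = data.reset_index(drop=True)
        self.design = pd.DataFrame(index=self.data.index)
        self.fixed_terms: dict[str, list[str]] = {}
        basis = np.ones((len(self.data), 1))  # aliasing is checked w.r.t. a constant
        for fe in fixed_effects:
            dummies = _categorical_dummies(
                self.data[fe], fe, _FIXED_LEVELS.get(fe)
            )
            kept_cols = []
            for c in dummies.columns:  # drop aliased dummies (tiny cohorts)
                cand = np.column_stack([basis, dummies[c].to_numpy(float)])
                if np.linalg.matrix_rank(cand) > basis.shape[1]:
                    basis = cand
                    kept_cols.append(c)
            if kept_cols:
                self.design = pd.concat([self.design, dummies[kept_cols]], axis=1)
                self.fixed_terms[fe] = kept_cols
        self._fixed_basis = basis
        outcome_cols = (
            [duration_col, event_col] if outcome == "survival" else [y_col]
        )
        for c in outcome_cols:
            self.design[c] = self.data[c].astype(float)
        self.terms: dict[str, list[str]] = {}
        self._cache: dict[tuple[str, ...], "CoxFit | GrowthFit"] = {}

    # -- term registry --------------------------------------------------------
    def register(self, name: str, columns: pd.DataFrame) -> str:
        """Add (or replace) the design columns of a behavioural term."""
        for c in columns.columns:
            self.design[c] = columns[c].astype(float)
        self.terms[name] = list(columns.columns)
        self._cache.clear()
        return name

    def dam_values(self, column: str) -> pd.Series:
        """One value per dam (behavioural covariates are dam-constant)."""
        return self.data.groupby("dam_id")[column].first()

    # -- codings --------------------------------------------------------------
    def code_continuous(self, cand: Candidate) -> pd.DataFrame:
        col = f"{cand.name}__cont"
        return pd.DataFrame({col: self.data[cand.column] * cand.scale})

    def code_tertile(self, cand: Candidate) -> pd.DataFrame:
        dams = self.dam_values(cand.column)
        classes = pd.Series(tertile_categorize(dams.to_numpy()), index=dams.index)
        per_row = self.data["dam_id"].map(classes)
        return pd.DataFrame(
            {
                f"{cand.name}__M": (per_row == "M").astype(float),
                f"{cand.name}__S": (per_row == "S").astype(float),
            }
        )

    def code_binary_s(self, cand: Candidate) -> pd.DataFrame:
        dams = self.dam_values(cand.column)
        classes = pd.Series(tertile_categorize(dams.to_numpy()), index=dams.index)
        per_row = self.data["dam_id"].map(classes)
        return pd.DataFrame({f"{cand.name}__S": (per_row == "S").astype(float)})

    def code_cluster(self, cand: Candidate) -> pd.DataFrame:
        return _categorical_dummies(self.data[cand.column], cand.name)

    def code_raw(self, cand: Candidate) -> pd.DataFrame:
        return pd.DataFrame({f"{cand.name}__raw": self.data[cand.raw_trait]})

    # -- fitting --------------------------------------------------------------
    def fit(self, term_names: Iterable[str] = ()) -> "CoxFit | GrowthFit":
        names = tuple(sorted(term_names))
        if names in self._cache:
            return self._cache[names]
        terms = dict(self.fixed_terms)
        for n in names:
            terms[n] = self.terms[n]
        if self.outcome == "survival":
            out = cox_fit(self.design, terms, self.duration_col, self.event_col)
        else:
            out = fit_growth_model(self.design, terms, self.y_col)
        self._cache[names] = out
        return out

    def term_min_z(self, fit: "CoxFit | GrowthFit", name: str) -> float:
        """Smallest |coef|/SE over a term's columns (elimination tie-break)."""
        cols = [c for c in self.terms[name] if c in fit.params.index]
        if not cols:
            return 0.0
        return float((fit.params[cols].abs() / fit.se[cols]).min())


# --------------------------------------------------------------------------
# the three-step selection protocol
# --------------------------------------------------------------------------

def screen_step1(
    ws: AssociationWorkspace,
    candidates: Sequence[Candidate],
    alpha: float = 0.05,
    allow_binary: bool = False,
    trace_steps: list | None = None,
) -> dict[str, dict]:
    """Step 1: per-item coding choice (AIC) and significance screen (LRT).

    Returns a mapping of significant term names to
    ``{"coding": ..., "p": ..., "aic": ...}``; the chosen design columns are
    registered on the workspace under the candidate's name.
    """
    steps = trace_steps if trace_steps is not None else []
    selected: dict[str, dict] = {}
    if not candidates:
        return selected
    base = ws.fit(())

    def _try_fit(name: str, cols: pd.DataFrame):
        ws.register(name, cols)
        try:
            return ws.fit((name,))
        except (RankDeficiencyError, FitError):
            return None

    for cand in candidates:
        fits: dict[str, "CoxFit | GrowthFit"] = {}
        codings: dict[str, pd.DataFrame] = {}
        if cand.kind == "count":
            codings["continuous"] = ws.code_continuous(cand)
            dams = ws.dam_values(cand.column)
            if dams.nunique() >= 3:
                codings["tertile"] = ws.code_tertile(cand)
                if allow_binary:
                    codings["binary_s"] = ws.code_binary_s(cand)
            for label, cols in codings.items():
                f = _try_fit(cand.name, cols)
                if f is not None:
                    fits[label] = f
            if not fits:
                ws.terms.pop(cand.name, None)
                steps.append({"stage": "screen", "term": cand.name,
                              "coding": None, "kept": False,
                              "note": "not estimable"})
                continue
            coding = min(fits, key=lambda c: fits[c].aic)
            ws.register(cand.name, codings[coding])
            fit = ws.fit((cand.name,))
            _, _, p = lrt(fit, base)
        elif cand.kind == "cluster":
            fit = _try_fit(cand.name, ws.code_cluster(cand))
            if fit is None:
                ws.terms.pop(cand.name, None)
                steps.append({"stage": "screen", "term": cand.name,
                              "coding": None, "kept": False,
                              "note": "not estimable"})
                continue
            fits["cluster"] = fit
            coding = "cluster"
            _, _, p = lrt(fit, base)
            if p < alpha and cand.raw_trait is not None:
                raw_fit = _try_fit(cand.name, ws.code_raw(cand))
                if raw_fit is not None:
                    fits["raw_trait"] = raw_fit
                if raw_fit is not None and raw_fit.aic < fit.aic:
                    coding, fit = "raw_trait", raw_fit
                    _, _, p = lrt(fit, base)
                else:
                    ws.register(cand.name, ws.code_cluster(cand))
                    fit = ws.fit((cand.name,))
        else:
            raise InputDataError(f"unknown candidate kind {cand.kind!r}")
        steps.append(
            {
                "stage": "screen",
                "term": cand.name,
                "codings_aic": {c: float(f.aic) for c, f in fits.items()},
                "coding": coding,
                "p": float(p),
                "kept": bool(p < alpha),
            }
        )
        if p < alpha:
            selected[cand.name] = {"coding": coding, "p": float(p), "aic": float(fit.aic)}
        else:
            ws.terms.pop(cand.name, None)
    return selected


def _backward_eliminate(
    ws: AssociationWorkspace,
    term_names: list[str],
    alpha: float,
    stage: str,
    steps: list,
) -> list[str]:
    """Drop, one at a time, the term whose removal has the largest LRT p > alpha."""
    current: list[str] = []
    basis = ws._fixed_basis
    for name in term_names:  # greedy rank filter before the saturated fit
        cand = np.column_stack(
            [basis] + [ws.design[c].to_numpy(float) for c in ws.terms[name]]
        )
        if np.linalg.matrix_rank(cand) < cand.shape[1]:
            steps.append({"stage": stage, "term": name, "action": "dropped_collinear"})
            continue
        basis = cand
        current.append(name)
    while current:
        full = ws.fit(current)
        pvals: dict[str, tuple[float, float, float]] = {}
        for name in current:
            reduced = ws.fit([n for n in current if n != name])
            stat, _, p = lrt(full, reduced)
            pvals[name] = (p, stat, ws.term_min_z(full, name))
        worst_p = max(p for p, _, _ in pvals.values())
        if worst_p <= alpha:
            break
        # ties on the LRT p-value resolved toward the smaller |coef|/SE
        tied = [n for n, (p, _, _) in pvals.items() if abs(p - worst_p) < 1e-9]
        drop = min(tied, key=lambda n: pvals[n][2])
        steps.append(
            {
                "stage": stage,
                "term": drop,
                "action": "dropped",
                "lrt_stat": pvals[drop][1],
                "p": pvals[drop][0],
            }
        )
        current.remove(drop)
    for name in current:
        reduced = ws.fit([n for n in current if n != name])
        stat, _, p = lrt(ws.fit(current), reduced)
        steps.append(
            {"stage": stage, "term": name, "action": "kept", "lrt_stat": stat, "p": p}
        )
    return current


def reduce_step2(
    ws: AssociationWorkspace,
    selected: Iterable[str],
    alpha: float = 0.05,
    trace_steps: list | None = None,
    stage: str = "reduce",
) -> list[str]:
    """Step 2: backward LRT elimination within one period's saturated model."""
    steps = trace_steps if trace_steps is not None else []
    return _backward_eliminate(ws, list(selected), alpha, stage, steps)


def global_step3(
    ws: AssociationWorkspace,
    terms_by_period: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    trace_steps: list | None = None,
) -> tuple["CoxFit | GrowthFit", list[str]]:
    """Step 3: pool period survivors, drop collinear duplicates, eliminate.

    Terms that make the pooled design rank deficient (e.g. the same trait
    surviving from two periods with identical values) are removed greedily
    in reverse pooling order before the backward elimination runs.
    """
    steps = trace_steps if trace_steps is not None else []
    pooled: list[str] = []
    for period in terms_by_period:
        for name in terms_by_period[period]:
            if name not in pooled:
                pooled.append(name)
    # greedy rank filter against the fixed effects design
    fixed_cols = [c for cols in ws.fixed_terms.values() for c in cols]
    kept: list[str] = []
    for name in pooled:
        cols = fixed_cols + [c for n in kept + [name] for c in ws.terms[n]]
        X = ws.design[cols]
        if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
            steps.append(
                {"stage": "global", "term": name, "action": "dropped_collinear"}
            )
            continue
        kept.append(name)
    final_terms = _backward_eliminate(ws, kept, alpha, "global", steps)
    return ws.fit(final_terms), final_terms


# --------------------------------------------------------------------------
# selection trace
# --------------------------------------------------------------------------

@dataclass
class SelectionTrace:
    """Replayable record of every decision of the three-step protocol."""

    steps: list[dict] = field(default_factory=list)
    final_terms: dict[str, dict] = field(default_factory=dict)
    final_params: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)

    @classmethod
    def from_json(cls, payload: str) -> "SelectionTrace":
        d = json.loads(payload)
        return cls(d["steps"], d["final_terms"], d["final_params"])


# --------------------------------------------------------------------------
# model facades
# --------------------------------------------------------------------------

def default_candidates(
    sow_covariates: pd.DataFrame,
    outcome: str,
    raw_trait_map: Mapping[str, str] | None = None,
) -> dict[str, list[Candidate]]:
    """Period-eligible candidate lists built from available covariate columns.

    Before farrowing only the two pattern factors and PCAll are eligible;
    PCStopNurse is excluded on the farrowing day for survival (no nursing
    bouts to interrupt yet) but eligible for growth; after farrowing all
    items are eligible.  PCAll enters continuous codings per 100 changes/day.
    """
    raw_trait_map = dict(raw_trait_map or {})
    eligible = {
        "survival": {
            "bf": ["cl_post", "cl_act", "pcall"],
            "df": ["cl_post", "cl_act", "pcall", "pcriskcrush"],
            "af": ["cl_post", "cl_act", "pcall", "pcriskcrush", "pcstopnurse"],
        },
        "growth": {
            "bf": ["cl_post", "cl_act", "pcall"],
            "df": ["cl_post", "cl_act", "pcall", "pcstopnurse"],
            "af": ["cl_post", "cl_act", "pcall", "pcstopnurse"],
        },
    }[outcome]
    out: dict[str, list[Candidate]] = {}
    for period, items in eligible.items():
        cands: list[Candidate] = []
        for item in items:
            col = f"{item}_{period}"
            if col not in sow_covariates.columns:
                continue
            if sow_covariates[col].dropna().empty:
                continue
            if item.startswith("cl_"):
                cands.append(
                    Candidate(col, "cluster", col, raw_trait=raw_trait_map.get(col))
                )
            else:
                scale = 0.01 if item == "pcall" else 1.0
                cands.append(Candidate(col, "count", col, scale=scale))
        out[period] = cands
    return out


class _BaseAssociationModel:
    """Shared machinery of the survival and growth association models."""

    outcome: str = ""

    def __init__(
        self,
        piglets: pd.DataFrame,
        sow_covariates: pd.DataFrame,
        candidates: Mapping[str, Sequence[Candidate]] | None = None,
        fixed_effects: Sequence[str] = DEFAULT_FIXED_EFFECTS,
        alpha: float = 0.05,
        raw_trait_map: Mapping[str, str] | None = None,
    ) -> None:
        sows = sow_covariates.copy()
        if sows.index.name != "sow_id" and "sow_id" in sows.columns:
            sows = sows.set_index("sow_id")
        data = piglets.merge(
            sows, left_on="dam_id", right_index=True, how="left", suffixes=("", "_sow")
        )
        self.alpha = float(alpha)
        self.fixed_effects = tuple(fixed_effects)
        if candidates is None:
            candidates = default_candidates(sows, self.outcome, raw_trait_map)
        self.candidates = {p: list(candidates.get(p, ())) for p in PERIODS}
        used_cols = [c.column for cs in self.candidates.values() for c in cs]
        used_cols += [c.raw_trait for cs in self.candidates.values() for c in cs if c.raw_trait]
        data = self._prepare(data)
        keep = data[used_cols].notna().all(axis=1) if used_cols else pd.Series(True, index=data.index)
        self.data = data[keep].reset_index(drop=True)
        self.workspace = AssociationWorkspace(
            self.data, self.outcome, self.fixed_effects
        )

    def _prepare(self, data: pd.DataFrame) -> pd.DataFrame:
        return data

    def fit(self) -> "AssociationResults":
        ws = self.workspace
        trace = SelectionTrace()
        per_period_selected: dict[str, list[str]] = {}
        for period in PERIODS:
            sel = screen_step1(
                ws,
                self.candidates[period],
                self.alpha,
                allow_binary=(self.outcome == "growth"),
                trace_steps=trace.steps,
            )
            kept = reduce_step2(
                ws, sel, self.alpha, trace_steps=trace.steps, stage=f"reduce_{period}"
            )
            per_period_selected[period] = kept
        final_fit, final_terms = global_step3(
            ws, per_period_selected, self.alpha, trace_steps=trace.steps
        )
        trace.final_terms = {
            n: {"columns": ws.terms[n]} for n in final_terms
        }
        trace.final_params = {k: float(v) for k, v in final_fit.params.items()}
        schoenfeld = None
        if self.outcome == "survival" and final_fit.n_params > 0:
            schoenfeld = schoenfeld_check(final_fit)
        return AssociationResults(
            outcome=self.outcome,
            fit=final_fit,
            behavioral_terms=final_terms,
            per_period_terms=per_period_selected,
            trace=trace,
            schoenfeld=schoenfeld,
            alpha=self.alpha,
        )

    def refit_from_trace(self, trace: SelectionTrace) -> "CoxFit | GrowthFit":
        """Replay: refit exactly the final term set recorded in a trace."""
        return self.workspace.fit(list(trace.final_terms))


class SurvivalAssociationModel(_BaseAssociationModel):
    """Cox-model association of sow behaviour with piglet survival."""

    outcome = "survival"


class GrowthAssociationModel(_BaseAssociationModel):
    """Linear-model association of sow behaviour with piglet growth (ADG D0-D7)."""

    outcome = "growth"

    def _prepare(self, data: pd.DataFrame) -> pd.DataFrame:
        data = data.copy()
        if "adg" not in data.columns:
            data["adg"] = compute_adg(data)
        return data[data["adg"].notna()].reset_index(drop=True)


@dataclass
class AssociationResults:
    """Final model of the three-step protocol plus its full decision record."""

    outcome: str
    fit: "CoxFit | GrowthFit"
    behavioral_terms: list[str]
    per_period_terms: dict[str, list[str]]
    trace: SelectionTrace
    schoenfeld: pd.DataFrame | None
    alpha: float

    def summary(self) -> str:
        head = [
            f"Three-step {self.outcome} association model (alpha={self.alpha})",
            "behavioural terms retained: "
            + (", ".join(self.behavioral_terms) if self.behavioral_terms else "none"),
        ]
        body = self.fit.summary()
        tail = []
        if self.schoenfeld is not None:
            tail.append("proportional-hazards check (Schoenfeld residuals):")
            tail.append(self.schoenfeld.to_string(float_format=lambda v: f"{v:.3g}"))
        return "\n".join(head + [body] + tail)
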