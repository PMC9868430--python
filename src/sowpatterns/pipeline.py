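"""End-to-end pipeline: simulate -> extract -> cluster -> associate -> report.

Each stage reads the artifacts of the previous one from ``out_dir`` and
writes its own, so stages can be re-run independently; a stage whose input
artifact is missing fails with an explicit error naming it.  Re-running a
stage with the same configuration is bit-identical for the deterministic
stages (and for the simulation, which is fully seeded).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .association import (
    GrowthAssociationModel,
    SurvivalAssociationModel,
    hazard_ratio_to_pct,
)
from .clustering import TrajectoryKMeans, most_discriminating_trait
from .compositions import (
    default_activity_basis,
    default_postural_basis,
    ilr_transform,
    zero_replace,
)
from .config import PERIOD_DAYS, PERIODS, RunConfig, config_hash
from .errors import PipelineError
from .simulate import build_cohort
from .streams import (
    assemble_period_dataset,
    compute_daily_traits,
    sow_period_covariates,
)

log = logging.getLogger("sowpatterns")

STAGES = ("simulate", "extract", "cluster", "associate", "report")

_ARTIFACTS = {
    "streams": "streams.csv.gz",
    "sows": "sows.csv",
    "piglets": "piglets.csv",
    "traits": "traits.csv",
    "clusters": "clusters.csv",
    "survival": "survival_model.json",
    "growth": "growth_model.json",
    "report": "report.txt",
}


def _path(cfg: RunConfig, key: str) -> Path:
    return Path(cfg.out_dir) / _ARTIFACTS[key]


def _require(cfg: RunConfig, key: str, stage: str) -> Path:
    p = _path(cfg, key)
    if not p.exists():
        raise PipelineError(
            f"stage {stage!r} requires artifact {p} (run the producing stage first)"
        )
    return p


def _stage_simulate(cfg: RunConfig) -> None:
    cohort = build_cohort(cfg.sim)
    h = config_hash(cfg)
    pio.write_streams_csv(
        (s for ss in cohort.streams.values() for s in ss), _path(cfg, "streams"), h
    )
    pio.write_table(cohort.sow_covariates.reset_index(), _path(cfg, "sows"), h)
    pio.write_table(cohort.piglets, _path(cfg, "piglets"), h)
    log.info(
        "simulated %d sows, %d ticks, %d piglets",
        cfg.sim.n_sows, cohort.total_ticks, len(cohort.piglets),
    )


def _stage_extract(cfg: RunConfig) -> None:
    streams = pio.read_stream_csv(_require(cfg, "streams", "extract"))
    if len(streams.missing_ticks):
        log.warning("gaps in %d sow-day(s)", len(streams.missing_ticks))
    traits = compute_daily_traits(
        streams,
        merge_map=cfg.analysis.merge_map,
        count_after_merge=cfg.analysis.count_after_merge,
    )
    pio.write_table(traits, _path(cfg, "traits"), config_hash(cfg))


def period_trajectories(
    traits: pd.DataFrame,
    period: str,
    budget: str = "postural",
    delta: float | None = None,
):
    """Complete-sow ILR trajectories (n x T x D-1) for one period and budget.

    Postural budgets use the merged-class columns (``prop_*``); standing
    budgets the ``act_*`` columns, with sows dropped if any day of the
    period lacks a standing budget.  Zero parts are multiplicatively
    replaced before the ILR.
    """
    ds = assemble_period_dataset(traits, period)
    sub = ds.traits
    if budget == "postural":
        cols = [c for c in sub.columns if c.startswith("prop_")]
        basis = default_postural_basis(tuple(c[len("prop_"):] for c in cols))
    elif budget == "activity":
        cols = [c for c in sub.columns if c.startswith("act_")]
        basis = default_activity_basis(tuple(c[len("act_"):] for c in cols))
    else:
        raise PipelineError(f"unknown budget type {budget!r}")
    days = list(ds.days)
    sow_ids, mats = [], []
    for sow in ds.complete_sows:
        rows = sub[sub["sow_id"] == sow].set_index("day").reindex(days)[cols]
        if rows.isna().any().any():
            continue  # e.g. a day without standing time: no activity budget
        comp = zero_replace(
            rows.to_numpy(dtype=float),
            delta if delta is not None else 1.0 / (2 * 17_280),
        )
        mats.append(ilr_transform(comp, basis))
        sow_ids.append(sow)
    traj = np.stack(mats) if mats else np.empty((0, len(days), max(len(cols) - 1, 0)))
    return sow_ids, traj, basis


def cluster_period_budget(
    traits: pd.DataFrame,
    period: str,
    budget: str,
    k_range: tuple[int, int] = (1, 6),
    n_init: int = 50,
    seed: int = 0,
    delta: float | None = None,
):
    """Elbow-selected k-means clustering of one period x budget combination."""
    sow_ids, traj, _ = period_trajectories(traits, period, budget, delta)
    if len(sow_ids) < 3:
        return sow_ids, None
    model = TrajectoryKMeans(traj, k_range=k_range, n_init=n_init, seed=seed)
    return sow_ids, model.fit()


def _stage_cluster(cfg: RunConfig) -> None:
    traits = pio.read_table(_require(cfg, "traits", "cluster"))
    rows = []
    for period in PERIODS:
        for budget, tag in (("postural", "cl_post"), ("activity", "cl_act")):
            sow_ids, res = cluster_period_budget(
                traits,
                period,
                budget,
                k_range=cfg.analysis.k_range,
                n_init=cfg.analysis.n_init,
                seed=cfg.seed,
                delta=cfg.analysis.delta,
            )
            if res is None:
                continue
            for sow, lab in zip(sow_ids, res.labels):
                rows.append(
                    {
                        "sow_id": sow,
                        "period": period,
                        "budget_type": budget,
                        "column": f"{tag}_{period}",
                        "cluster": lab,
                        "k": res.k,
                    }
                )
    pio.write_table(pd.DataFrame(rows), _path(cfg, "clusters"), config_hash(cfg))


def build_sow_covariate_table(
    sows: pd.DataFrame, traits: pd.DataFrame, clusters: pd.DataFrame | None
) -> pd.DataFrame:
    """Merge dam metadata, period trait summaries and cluster labels."""
    cov = sows.set_index("sow_id") if "sow_id" in sows.columns else sows.copy()
    summaries = sow_period_covariates(traits)
    fresh = [c for c in summaries.columns if c not in cov.columns]
    cov = cov.join(summaries[fresh], how="left")
    if clusters is not None and len(clusters):
        wide = clusters.pivot_table(
            index="sow_id", columns="column", values="cluster", aggfunc="first"
        )
        cov = cov.join(wide, how="left")
    return cov


def _raw_trait_map(
    cov: pd.DataFrame, clusters: pd.DataFrame | None
) -> dict[str, str]:
    """For each cluster factor, the raw trait that best separates its clusters."""
    out: dict[str, str] = {}
    if clusters is None or not len(clusters):
        return out
    for col in clusters["column"].unique():
        period = col.rsplit("_", 1)[-1]
        if col.startswith("cl_post"):
            cands = [
                c
                for c in cov.columns
                if c.endswith(f"_h_{period}")
                and not any(c.startswith(a) for a in ("eat", "drink", "other"))
            ]
        else:
            cands = [
                c
                for c in cov.columns
                if c.endswith(f"_h_{period}")
                and any(c.startswith(a) for a in ("eat", "drink", "other"))
            ]
        sub = cov[cov[col].notna()]
        if len(sub) < 4 or sub[col].nunique() < 2 or not cands:
            continue
        try:
            out[col] = most_discriminating_trait(sub, sub[col].to_numpy(), cands)
        except Exception:  # degenerate contrast: keep the cluster factor
            continue
    return out


def _fit_to_payload(res) -> dict:
    fit = res.fit
    payload = {
        "behavioral_terms": res.behavioral_terms,
        "per_period_terms": res.per_period_terms,
        "coefficients": fit.to_frame().reset_index().rename(
            columns={"index": "term"}
        ).to_dict(orient="records"),
        "aic": fit.aic,
        "log_likelihood": fit.log_likelihood,
        "n": fit.n,
        "trace": {
            "steps": res.trace.steps,
            "final_terms": res.trace.final_terms,
            "final_params": res.trace.final_params,
        },
    }
    if res.schoenfeld is not None:
        payload["schoenfeld"] = (
            res.schoenfeld.reset_index().to_dict(orient="records")
        )
    return payload


def _stage_associate(cfg: RunConfig) -> None:
    traits = pio.read_table(_require(cfg, "traits", "associate"))
    sows = pio.read_table(_require(cfg, "sows", "associate"))
    piglets = pio.read_table(_require(cfg, "piglets", "associate"))
    clusters_path = _path(cfg, "clusters")
    clusters = pio.read_table(clusters_path) if clusters_path.exists() else None
    cov = build_sow_covariate_table(sows, traits, clusters)
    raw_map = _raw_trait_map(cov, clusters)
    alpha = cfg.analysis.alpha
    try:
        surv = SurvivalAssociationModel(
            piglets, cov, alpha=alpha, raw_trait_map=raw_map
        ).fit()
        pio.write_json(_fit_to_payload(surv), _path(cfg, "survival"))
    except Exception as err:
        raise PipelineError(f"survival association failed: {err}") from err
    growth = GrowthAssociationModel(
        piglets, cov, alpha=alpha, raw_trait_map=raw_map
    ).fit()
    pio.write_json(_fit_to_payload(growth), _path(cfg, "growth"))


def render_report(
    survival: Mapping | None, growth: Mapping | None, clusters: pd.DataFrame | None
) -> str:
    """Human-readable run summary: model tables and cluster composition."""
    lines: list[str] = ["sowpatterns run report", "=" * 40]
    if clusters is not None and len(clusters):
        lines.append("\nActivity-pattern clusters (complete sows only):")
        comp = (
            clusters.groupby(["period", "budget_type", "cluster"])["sow_id"]
            .count()
            .rename("n_sows")
            .reset_index()
        )
        lines.append(comp.to_string(index=False))
    for name, payload in (("survival (Cox)", survival), ("growth (OLS)", growth)):
        lines.append(f"\nFinal {name} model:")
        if not payload:
            lines.append("  not fitted")
            continue
        terms = payload.get("behavioral_terms") or []
        lines.append(
            "  behavioural terms: " + (", ".join(terms) if terms else "none (covariates only)")
        )
        for row in payload.get("coefficients", []):
            term = row.get("term")
            if "hr" in row:
                pct = hazard_ratio_to_pct(row["hr"])
                direction = "reduction" if pct >= 0 else "increase"
                lines.append(
                    f"  {term}: HR={row['hr']:.2f} "
                    f"[{row['ci_lower']:.2f}, {row['ci_upper']:.2f}], "
                    f"p={row['p']:.3g} ({abs(pct):.0f}% {direction} in risk)"
                )
            else:
                lines.append(
                    f"  {term}: {row['estimate']:+.2f} g/d "
                    f"[{row['ci_lower']:.2f}, {row['ci_upper']:.2f}], p={row['p']:.3g}"
                )
    return "\n".join(lines)


def _stage_report(cfg: RunConfig) -> None:
    import json

    surv_p, growth_p = _path(cfg, "survival"), _path(cfg, "growth")
    survival = json.loads(surv_p.read_text()) if surv_p.exists() else None
    growth = json.loads(growth_p.read_text()) if growth_p.exists() else None
    if survival is None and growth is None:
        raise PipelineError(
            f"stage 'report' requires {surv_p} or {growth_p} (run 'associate' first)"
        )
    clusters_path = _path(cfg, "clusters")
    clusters = pio.read_table(clusters_path) if clusters_path.exists() else None
    text = render_report(survival, growth, clusters)
    _path(cfg, "report").write_text(text + "\n")


_STAGE_FN = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "cluster": _stage_cluster,
    "associate": _stage_associate,
    "report": _stage_report,
}


def run_pipeline(cfg: RunConfig, stages: Sequence[str] = STAGES) -> dict[str, Path]:
    """Execute the requested stages in canonical order; return artifact paths."""
    cfg.validate()
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    log.info("run config hash %s (seed %d)", config_hash(cfg), cfg.seed)
    for stage in STAGES:
        if stage in stages:
            log.info("stage: %s", stage)
            _STAGE_FN[stage](cfg)
    return {k: _path(cfg, k) for k in _ARTIFACTS if _path(cfg, k).exists()}
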