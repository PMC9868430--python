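"""Synthetic peripartum cohorts: posture streams, litters, outcomes.

Sow activity is generated by a continuous-time semi-Markov chain over the
six-posture ethogram with exponential holding times, discretised to 5-s
observation ticks.  All transition rates are scaled by a day-specific
restlessness multiplier (peaking the day before farrowing), a log-normal
per-sow random effect, and breed-specific biases on the rates *into*
selected postures (so breeds differ in their preferred lying posture while
sharing the overall activity level).  Each standing bout carries one
activity drawn from the period's eat/drink/other distribution.

Piglet outcomes are driven by the dam's *realised* behavioural traits (as
computed from her simulated streams): death days follow a discrete-time
proportional-hazards model with a log-hazard linear in configured traits,
and average daily gain follows a linear model with additive class effects.
This closes the loop needed for parameter-recovery studies: the association
stage should recover the planted hazard ratios and growth effects.

Randomness uses one substream per sow derived from ``(master seed, purpose,
sow index)``, so adding a sow to a cohort does not perturb the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import ethogram as eth
from .association import litter_size_class, tertile_categorize
from .config import SECONDS_PER_DAY, SimConfig, period_of_day
from .errors import ConfigError, InputDataError
from .streams import PostureStream, compute_daily_traits, sow_period_covariates

__all__ = [
    "SowProfile",
    "Cohort",
    "make_profiles",
    "simulate_posture_stream",
    "inject_label_noise",
    "simulate_litter",
    "simulate_piglet_table",
    "simulate_sow_trait_table",
    "build_cohort",
]

# purpose tags for per-sow random substreams
_RNG_STREAM, _RNG_NOISE, _RNG_MISSING, _RNG_LITTER, _RNG_PROFILE = 11, 17, 13, 19, 23


@dataclass
class SowProfile:
    """Identity and individual effects of one simulated sow."""

    sow_id: str
    breed: str
    pen: str
    index: int
    #: multiplicative restlessness random effect (log-normal, mean 1)
    restlessness: float = 1.0
    #: absolute time of the first birth (seconds into a nominal calendar day)
    farrowing_time: float = 0.0
    #: extra restlessness multiplier per peripartum period (log-normal, mean 1)
    period_effects: dict = field(default_factory=dict)
    #: per-sow multiplicative bias on rates into LLU (lying-posture preference)
    llu_bias: float = 1.0


def _sow_rng(config: SimConfig, purpose: int, index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, purpose, index])


def make_profiles(config: SimConfig) -> list[SowProfile]:
    """Deterministic sow roster: breeds by configured fractions, pens cycling A-D."""
    breeds = list(config.breeds)
    fractions = np.array([config.breeds[b].get("fraction", 0.0) for b in breeds])
    counts = np.floor(fractions * config.n_sows).astype(int)
    while counts.sum() < config.n_sows:  # distribute the remainder
        counts[int(np.argmin(counts / np.maximum(fractions, 1e-12)))] += 1
    roster: list[str] = []
    for b, c in zip(breeds, counts):
        roster.extend([b] * c)
    profiles = []
    for i in range(config.n_sows):
        rng = _sow_rng(config, _RNG_PROFILE, i)
        sigma = config.sow_sigma
        effect = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
        sp = config.sow_period_sigma
        period_effects = {
            per: float(rng.lognormal(mean=-0.5 * sp**2, sigma=sp))
            for per in ("bf", "df", "af")
        }
        sb = config.sow_posture_sigma
        llu_bias = float(rng.lognormal(mean=-0.5 * sb**2, sigma=sb))
        profiles.append(
            SowProfile(
                sow_id=f"S{i + 1:03d}",
                breed=roster[i] if roster else "NA",
                pen="ABCD"[i % 4],
                index=i,
                restlessness=effect,
                farrowing_time=float(rng.uniform(0, SECONDS_PER_DAY)),
                period_effects=period_effects,
                llu_bias=llu_bias,
            )
        )
    return profiles


def _effective_rates(
    config: SimConfig, profile: SowProfile, day: int
) -> np.ndarray:
    """Per-second transition-rate matrix for one sow-day."""
    period = period_of_day(day)
    base = config.posture_rates[period]
    mult = (
        config.restlessness_multiplier.get(day, 1.0)
        * profile.restlessness
        * profile.period_effects.get(period, 1.0)
    )
    bias = np.ones(len(eth.POSTURES))
    for posture, b in config.breeds.get(profile.breed, {}).get("posture_bias", {}).items():
        bias[eth.POSTURES.index(posture)] = b
    bias[eth.POSTURES.index("LLU")] *= profile.llu_bias
    q = base * mult * bias[np.newaxis, :] / 3600.0
    np.fill_diagonal(q, 0.0)
    return q


def _stationary(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a rate matrix (uniform if degenerate)."""
    n = q.shape[0]
    if not q.any():
        return np.full(n, 1.0 / n)
    g = q.copy()
    np.fill_diagonal(g, -q.sum(axis=1))
    a = np.vstack([g.T, np.ones(n)])
    b = np.r_[np.zeros(n), 1.0]
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def simulate_posture_stream(
    config: SimConfig,
    profile: SowProfile,
    initial_posture: str | None = None,
    days: Sequence[int] | None = None,
) -> list[PostureStream]:
    """Simulate one sow's posture/activity streams over the day grid.

    The chain is continuous across consecutive days (the last state of a day
    seeds the next); the first day starts from the stationary distribution of
    its effective chain, or from ``initial_posture`` if given.  Each tick is
    labelled with the state occupying its start time.  Deterministic given
    ``(config.seed, profile.index)``.
    """
    config.validate()
    days = tuple(days) if days is not None else config.day_grid
    rng = _sow_rng(config, _RNG_STREAM, profile.index)
    n_ticks = config.ticks_per_day
    tick_times = np.arange(n_ticks) * config.tick_s
    n_states = len(eth.POSTURES)
    st_code = eth.POSTURES.index("ST")

    state: int
    if initial_posture is not None:
        state = eth.POSTURES.index(initial_posture)
    else:
        state = int(rng.choice(n_states, p=_stationary(_effective_rates(config, profile, days[0]))))

    streams: list[PostureStream] = []
    current_act = -1
    for day in days:
        q = _effective_rates(config, profile, day)
        totals = q.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cum = np.cumsum(q / np.where(totals[:, None] > 0, totals[:, None], 1.0), axis=1)
        act_probs = np.asarray(config.activity_probs[period_of_day(day)], dtype=float)
        act_cum = np.cumsum(act_probs)
        if state == st_code and current_act < 0:
            current_act = int(np.searchsorted(act_cum, rng.random()))
        jump_times: list[float] = []
        seq_states = [state]
        seq_acts = [current_act if state == st_code else -1]
        t = 0.0
        while True:
            rate = totals[state]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= SECONDS_PER_DAY:
                break
            state = int(np.searchsorted(cum[state], rng.random()))
            if state == st_code:
                current_act = int(np.searchsorted(act_cum, rng.random()))
            else:
                current_act = -1
            jump_times.append(t)
            seq_states.append(state)
            seq_acts.append(current_act)
        idx = np.searchsorted(np.asarray(jump_times), tick_times, side="right")
        postures = np.asarray(seq_states, dtype=np.int8)[idx]
        activities = np.asarray(seq_acts, dtype=np.int8)[idx]
        streams.append(
            PostureStream(profile.sow_id, day, postures, activities, eth.POSTURES)
        )
    return streams


def inject_label_noise(
    stream: PostureStream, noise_rate: float, seed: "int | Sequence[int]"
) -> PostureStream:
    """Flip each tick's posture to a different random label with prob. ``noise_rate``.

    Emulates isolated classifier errors: flipped ticks form (mostly)
    single-tick runs, exactly the artefacts the despiking rule removes.  The
    input stream is left unmodified.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise InputDataError("noise_rate must lie in [0, 1]")
    out = stream.copy()
    if noise_rate == 0.0 or out.n_ticks == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.n_ticks) < noise_rate
    n_flip = int(mask.sum())
    if n_flip == 0:
        return out
    v = len(out.vocab)
    offset = rng.integers(1, v, size=n_flip)
    new_codes = (out.postures[mask] + offset) % v
    out.postures[mask] = new_codes.astype(np.int8)
    try:
        st_code = out.vocab.index("ST")
    except ValueError:
        st_code = -2
    new_acts = np.where(
        new_codes == st_code,
        rng.integers(0, len(eth.ACTIVITIES), size=n_flip),
        eth.NO_ACTIVITY,
    )
    out.activities[mask] = new_acts.astype(np.int8)
    return out


def _required_traits(config: SimConfig) -> list[str]:
    cols = list(config.survival_betas)
    cols += [key.split(":")[0] for key in config.growth_effects]
    return cols


def simulate_litter(
    config: SimConfig,
    sow: Mapping,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one litter of piglet records from a dam's trait summary.

    ``sow`` must provide the trait columns named in ``survival_betas``
    (values) and ``growth_effects`` (as ``<trait>_class`` tertile labels),
    plus ``sow_id`` and ``breed``.  Death days are drawn from the
    discrete-time proportional-hazards model; survivors are censored at the
    end of follow-up.  Weights before the death day are observed, later
    ones missing.
    """
    for col in config.survival_betas:
        if col not in sow or pd.isna(sow[col]):
            raise InputDataError(f"sow trait {col!r} missing for litter simulation")
    for key in config.growth_effects:
        ccol = key.split(":")[0] + "_class"
        if ccol not in sow or pd.isna(sow[ccol]):
            raise InputDataError(f"sow trait class {ccol!r} missing for litter simulation")

    lo, hi = config.litter_size_range
    size = int(rng.integers(lo, hi + 1))
    dam_breed = sow["breed"]
    other = [b for b in config.breeds if b != dam_breed] or [dam_breed]
    sire = np.where(rng.random(size) < 0.5, dam_breed, other[0])
    gtypes = np.array([f"{dam_breed}/{s}" for s in sire])

    eta = 0.0
    for col, beta in config.survival_betas.items():
        eta += beta * (float(sow[col]) - config.trait_centers.get(col, 0.0))
    p_day = 1.0 - np.exp(-config.baseline_hazard * math.exp(eta))
    u = rng.random((size, config.follow_up_days))
    dies = u < p_day[np.newaxis, :]
    any_death = dies.any(axis=1)
    day = np.where(any_death, dies.argmax(axis=1) + 1, config.follow_up_days)
    event = any_death.astype(int)

    adg = np.full(size, config.growth_intercept)
    adg += np.array([config.growth_genetic_effects.get(g, 0.0) for g in gtypes])
    for key, shift in config.growth_effects.items():
        trait, cls = key.split(":")
        if str(sow[f"{trait}_class"]) == cls:
            adg += shift
    adg += rng.normal(0.0, config.growth_sd, size)

    bw = np.array(
        [
            rng.normal(config.birth_weight_means.get(g, 1000.0), config.birth_weight_sd)
            for g in gtypes
        ]
    ).clip(min=300.0)

    rows = pd.DataFrame(
        {
            "piglet_id": [f"{sow['sow_id']}P{i + 1:02d}" for i in range(size)],
            "dam_id": sow["sow_id"],
            "genetic_type": gtypes,
            "birth_weight": bw.round(1),
            "time": day.astype(float),
            "event": event,
            "cause": np.where(event == 1, "death", "censored"),
            "litter_size": size,
        }
    )
    for d, col in ((1, "weight_d1"), (3, "weight_d3"), (7, "weight_d7")):
        observed = day > d  # weight at D_d recorded only if alive past day d
        w = bw + adg * d
        rows[col] = np.where(observed | (event == 0), w.round(1), np.nan)
    return rows


def simulate_piglet_table(
    config: SimConfig, sow_covariates: pd.DataFrame
) -> pd.DataFrame:
    """Litters for every sow in a covariate table (one substream per sow)."""
    frames = []
    for i, (sow_id, row) in enumerate(sow_covariates.iterrows()):
        rng = _sow_rng(config, _RNG_LITTER, int(row.get("index", i)))
        sow = dict(row)
        sow["sow_id"] = sow_id
        frames.append(simulate_litter(config, sow, rng))
    if not frames:
        return pd.DataFrame(
            columns=[
                "piglet_id", "dam_id", "genetic_type", "birth_weight", "time",
                "event", "cause", "litter_size", "weight_d1", "weight_d3", "weight_d7",
                "litter_size_class",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    out["litter_size_class"] = litter_size_class(out["litter_size"])
    return out


def _attach_trait_classes(cov: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Tertile class columns for every trait named in the growth effects."""
    cov = cov.copy()
    for key in config.growth_effects:
        trait = key.split(":")[0]
        if trait not in cov.columns or cov[trait].notna().sum() < 3:
            # period not simulated (or too few sows): everyone unremarkable
            cov[f"{trait}_class"] = "I"
            continue
        vals = cov[trait]
        if True:
            classes = pd.Series(index=cov.index, dtype=object)
            ok = vals.notna()
            classes[ok] = tertile_categorize(vals[ok].to_numpy())
            # a sow with the whole period missing is treated as unremarkable
            cov[f"{trait}_class"] = classes.fillna("I")
    return cov


def simulate_sow_trait_table(
    config: SimConfig, n_sows: int | None = None, seed_offset: int = 0
) -> pd.DataFrame:
    """Draw per-sow period trait summaries directly from the rate model.

    A fast stand-in for the full stream pipeline when only the association
    stage is under study (e.g. type-I-error replicates): expected daily
    posture-change counts and posture hours are computed analytically from
    the configured stationary chains, scaled by the log-normal sow effect,
    with day-level sampling noise approximated as Gaussian.
    """
    n = config.n_sows if n_sows is None else n_sows
    profiles = make_profiles(config)[:n] if n <= config.n_sows else None
    if profiles is None:
        cfg2 = SimConfig(**{**config.to_dict(), "n_sows": n})
        profiles = make_profiles(cfg2)
    rows = []
    for p in profiles:
        rng = np.random.default_rng(
            [config.seed & 0x7FFFFFFF, 29 + seed_offset, p.index]
        )
        row: dict[str, object] = {"sow_id": p.sow_id, "breed": p.breed, "pen": p.pen,
                                  "index": p.index}
        for period, days in (("bf", (-3, -2, -1)), ("df", (0,)), ("af", tuple(range(1, 8)))):
            q = config.posture_rates[period] / 3600.0
            pi = _stationary(q)
            jumps_day = float((pi * q.sum(axis=1)).sum()) * SECONDS_PER_DAY
            mults = np.array([config.restlessness_multiplier.get(d, 1.0) for d in days])
            daily = jumps_day * mults * p.restlessness
            noisy = np.maximum(daily + rng.normal(0, 0.15 * daily), 1.0)
            row[f"pcall_{period}"] = float(noisy.mean())
            row[f"pcriskcrush_{period}"] = float(noisy.mean()) * 0.2
            row[f"pcstopnurse_{period}"] = float(noisy.mean()) * 0.27
            llu = pi[eth.POSTURES.index("LLU")]
            row[f"llu_h_{period}"] = float(
                np.clip(24 * llu + rng.normal(0, 0.8), 0.1, 23.9)
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("sow_id")


@dataclass
class Cohort:
    """A complete synthetic study: streams, daily traits, dams, piglets."""

    config: SimConfig
    profiles: list[SowProfile]
    streams: dict[str, list[PostureStream]]
    traits: pd.DataFrame
    sow_covariates: pd.DataFrame
    piglets: pd.DataFrame

    @property
    def total_ticks(self) -> int:
        return sum(s.n_ticks for ss in self.streams.values() for s in ss)


def build_cohort(config: SimConfig) -> Cohort:
    """Simulate the full study: streams -> daily traits -> litters.

    Whole sow-days are dropped with probability ``missing_day_rate``
    (emulating lost video).  When a sow's period summary is unavailable
    because every day of the period is missing, her hazard covariates fall
    back to the configured centring constants (a neutral dam).
    """
    config.validate()
    profiles = make_profiles(config)
    streams: dict[str, list[PostureStream]] = {}
    for p in profiles:
        ss = simulate_posture_stream(config, p)
        if config.missing_day_rate > 0:
            rng = _sow_rng(config, _RNG_MISSING, p.index)
            keep = rng.random(len(ss)) >= config.missing_day_rate
            ss = [s for s, k in zip(ss, keep) if k]
        if config.noise_rate > 0:
            ss = [
                inject_label_noise(
                    s,
                    config.noise_rate,
                    [config.seed & 0x7FFFFFFF, _RNG_NOISE, p.index, s.day + 1000],
                )
                for s in ss
            ]
        streams[p.sow_id] = ss

    all_streams = [s for ss in streams.values() for s in ss]
    traits = compute_daily_traits(all_streams)
    if traits.empty:
        cov = pd.DataFrame()
        piglets = simulate_piglet_table(config, cov)
        return Cohort(config, profiles, streams, traits, cov, piglets)

    cov = sow_period_covariates(traits)
    meta = pd.DataFrame(
        {
            "breed": {p.sow_id: p.breed for p in profiles},
            "pen": {p.sow_id: p.pen for p in profiles},
            "index": {p.sow_id: p.index for p in profiles},
            "restlessness": {p.sow_id: p.restlessness for p in profiles},
        }
    )
    meta.index.name = "sow_id"
    cov = meta.join(cov, how="left")
    for col in config.survival_betas:
        center = config.trait_centers.get(col, 0.0)
        if col in cov.columns:
            cov[col] = cov[col].fillna(center)
        else:  # period not simulated: every dam at the neutral centre
            cov[col] = center
    for col, center in config.trait_centers.items():
        if col in cov.columns:
            cov[col] = cov[col].fillna(center)
    cov = _attach_trait_classes(cov, config)
    piglets = simulate_piglet_table(config, cov)
    return Cohort(config, profiles, streams, traits, cov, piglets)
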