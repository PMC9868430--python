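"""Configuration objects for the synthetic cohort and the analysis pipeline.

The simulator is a continuous-time semi-Markov process over the six-posture
ethogram, discretised to 5-second observation ticks.  Its default calibration
reproduces the stylised facts of peripartum sow activity in individual
farrowing pens:

* a restlessness peak on the day before farrowing (daily posture-change
  counts roughly doubling relative to neighbouring days),
* quiescence on the day of farrowing itself (about 92 % of time lying),
* breed-like heterogeneity in the preferred lying posture, and large
  between-sow variation in overall restlessness,
* litters of 12-21 piglets whose survival follows a proportional-hazards
  model and whose early growth follows a linear model, both driven by the
  dam's behavioural traits.

Transition-rate matrices use the "uniform jump" parameterisation
``q_ij = theta * pi_j`` (i != j), which is reversible with stationary
distribution ``pi`` and a total jump rate of ``theta * (1 - sum(pi^2))``.
This lets a target daily time budget and a target daily number of posture
changes be dialled in independently.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import ethogram as eth
from .errors import ConfigError

SECONDS_PER_DAY = 86_400

PERIODS: tuple[str, ...] = ("bf", "df", "af")
PERIOD_DAYS: dict[str, tuple[int, ...]] = {
    "bf": (-3, -2, -1),
    "df": (0,),
    "af": (1, 2, 3, 4, 5, 6, 7),
}
DAY_GRID: tuple[int, ...] = tuple(range(-3, 8))


def period_of_day(day: int) -> str:
    """Peripartum period a relative day belongs to (bf / df / af)."""
    if day < 0:
        return "bf"
    if day == 0:
        return "df"
    return "af"


# --- default simulator calibration -------------------------------------------
# Stationary posture distributions per period, ordered as ethogram.POSTURES
# (ST, SI, K, SL, LL, LLU).  They encode: before farrowing ~23 % upright and
# lying split LL-heavy; day of farrowing 92 % lying; after farrowing ~89 %
# lying dominated by lateral lying with udder exposed.
_PI: dict[str, tuple[float, ...]] = {
    "bf": (0.195, 0.030, 0.005, 0.120, 0.290, 0.360),
    "df": (0.065, 0.010, 0.005, 0.100, 0.120, 0.700),
    "af": (0.085, 0.020, 0.005, 0.050, 0.110, 0.730),
}

# Target mean number of posture changes per day per period (period means of
# the daily restlessness profile below).
_JUMPS_PER_DAY: dict[str, float] = {"bf": 329.0, "df": 282.0, "af": 245.6}

# Day-specific multipliers on all transition rates, normalised so the
# period mean is ~1; the D-1 peak reproduces the pre-farrowing
# nest-building surge in restlessness.
_RESTLESSNESS: dict[int, float] = {
    -3: 0.669, -2: 0.903, -1: 1.429,
    0: 1.0,
    1: 1.006, 2: 1.047, 3: 0.892, 4: 0.981, 5: 0.961, 6: 1.083, 7: 1.030,
}

# Distribution of standing activity (EAT, DRINK, OTHER) per period.
_ACTIVITY_PROBS: dict[str, tuple[float, float, float]] = {
    "bf": (0.24, 0.22, 0.54),
    "df": (0.22, 0.24, 0.54),
    "af": (0.27, 0.20, 0.53),
}


def stationary_rate_matrix(pi: Sequence[float], jumps_per_day: float) -> np.ndarray:
    """Rate matrix (events/hour) with stationary distribution ``pi`` and the
    requested expected number of transitions per day.

    Uses the reversible uniform-jump construction ``q_ij = theta * pi_j``.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 1 or np.any(pi < 0) or not math.isclose(pi.sum(), 1.0, abs_tol=1e-9):
        raise ConfigError("stationary distribution must be a probability vector")
    theta = jumps_per_day / (1.0 - float(np.sum(pi**2)))
    q = np.tile(pi, (pi.size, 1)) * (theta / 24.0)
    np.fill_diagonal(q, 0.0)
    return q


def _default_rates() -> dict[str, np.ndarray]:
    return {p: stationary_rate_matrix(_PI[p], _JUMPS_PER_DAY[p]) for p in PERIODS}


def _default_breeds() -> dict[str, dict[str, Any]]:
    # Column-multiplier biases on rates *into* a posture: Large White sows
    # favour lateral lying with the udder exposed, Meishan sows plain
    # lateral lying.  Reweighting within the lying block leaves the lying
    # total nearly unchanged.
    return {
        "LW": {"fraction": 0.5, "posture_bias": {"LLU": 1.3}},
        "MS": {"fraction": 0.5, "posture_bias": {"LL": 1.3}},
    }


def _default_baseline_hazard() -> np.ndarray:
    # Early-lactation death hazard, highest in the first days, cumulating to
    # ~0.16 over 28 days (≈85 % survival for an average litter).
    days = np.arange(1, 29)
    return 0.030 * np.exp(-(days - 1) / 3.5) + 0.0015


def _default_survival_betas() -> dict[str, float]:
    # Log-hazard per unit of the named dam trait: hazard ratio 0.56 per 100
    # posture changes/day after farrowing, 0.72 per extra hour/day lying
    # with the udder exposed after farrowing.
    return {
        "pcall_af": math.log(0.56) / 100.0,
        "llu_h_af": math.log(0.72),
    }


def _default_growth_effects() -> dict[str, float]:
    # Additive shifts on piglet average daily gain (g/d) for dams in the
    # upper tertile (class S) of the named trait.
    return {
        "pcall_bf:S": -22.37,
        "pcstopnurse_df:S": -45.33,
        "pcstopnurse_af:S": 70.84,
    }


def _default_genetic_growth() -> dict[str, float]:
    # ADG offsets by piglet genetic type (dam/sire), reference LW/MS.
    return {"LW/MS": 0.0, "LW/LW": -38.42, "MS/LW": -110.80, "MS/MS": -102.55}


def _default_birth_weights() -> dict[str, float]:
    return {"MS/MS": 875.0, "MS/LW": 1063.0, "LW/LW": 1292.0, "LW/MS": 1283.0}


@dataclass
class SimConfig:
    """Full specification of a synthetic peripartum study."""

    n_sows: int = 43
    seed: int = 0
    breeds: dict[str, dict[str, Any]] = field(default_factory=_default_breeds)
    day_grid: tuple[int, ...] = DAY_GRID
    tick_s: int = 5
    posture_rates: dict[str, np.ndarray] = field(default_factory=_default_rates)
    activity_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_ACTIVITY_PROBS)
    )
    restlessness_multiplier: dict[int, float] = field(
        default_factory=lambda: dict(_RESTLESSNESS)
    )
    #: multiplicative log-normal between-sow restlessness (sigma on log scale)
    sow_sigma: float = 0.55
    #: extra log-normal restlessness variation per sow x period, so activity
    #: levels are repeatable but not identical across the three periods
    sow_period_sigma: float = 0.30
    #: log-normal per-sow preference for lying with the udder exposed
    #: (column bias on rates into LLU); drives within-breed budget variation
    sow_posture_sigma: float = 0.25
    #: probability that a tick receives a spurious single-tick label
    noise_rate: float = 0.01
    #: probability that a whole sow-day of video is lost
    missing_day_rate: float = 0.0
    litter_size_range: tuple[int, int] = (12, 21)
    survival_betas: dict[str, float] = field(default_factory=_default_survival_betas)
    #: centring constants so the baseline hazard refers to an average dam
    trait_centers: dict[str, float] = field(
        default_factory=lambda: {"pcall_af": 246.0, "llu_h_af": 17.5}
    )
    baseline_hazard: np.ndarray = field(default_factory=_default_baseline_hazard)
    follow_up_days: int = 28
    growth_intercept: float = 229.5
    growth_effects: dict[str, float] = field(default_factory=_default_growth_effects)
    growth_genetic_effects: dict[str, float] = field(default_factory=_default_genetic_growth)
    growth_sd: float = 55.0
    birth_weight_means: dict[str, float] = field(default_factory=_default_birth_weights)
    birth_weight_sd: float = 230.0

    def __post_init__(self) -> None:
        self.day_grid = tuple(int(d) for d in self.day_grid)
        self.posture_rates = {
            p: np.asarray(m, dtype=float) for p, m in self.posture_rates.items()
        }
        self.baseline_hazard = np.asarray(self.baseline_hazard, dtype=float)

    # -- validation -----------------------------------------------------------
    def validate(self) -> "SimConfig":
        if self.n_sows < 0:
            raise ConfigError("n_sows must be non-negative")
        if self.tick_s <= 0 or SECONDS_PER_DAY % self.tick_s != 0:
            raise ConfigError("tick_s must divide 86,400 seconds")
        n = len(eth.POSTURES)
        for p, q in self.posture_rates.items():
            if q.shape != (n, n):
                raise ConfigError(f"rate matrix for period {p!r} must be {n}x{n}")
            if np.any(q < 0):
                raise ConfigError(f"rate matrix for period {p!r} has a negative entry")
            if np.any(np.diag(q) != 0):
                raise ConfigError(f"rate matrix for period {p!r} must have a zero diagonal")
        for p, probs in self.activity_probs.items():
            a = np.asarray(probs, dtype=float)
            if a.size != len(eth.ACTIVITIES) or np.any(a < 0) or not math.isclose(
                a.sum(), 1.0, abs_tol=1e-9
            ):
                raise ConfigError(f"activity_probs for period {p!r} must sum to 1")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ConfigError("noise_rate must lie in [0, 1]")
        if not 0.0 <= self.missing_day_rate <= 1.0:
            raise ConfigError("missing_day_rate must lie in [0, 1]")
        lo, hi = self.litter_size_range
        if not (0 < lo <= hi):
            raise ConfigError("litter_size_range must satisfy 0 < lo <= hi")
        if self.baseline_hazard.size != self.follow_up_days or np.any(
            self.baseline_hazard < 0
        ):
            raise ConfigError("baseline_hazard must be non-negative with one entry per day")
        fr = sum(b.get("fraction", 0.0) for b in self.breeds.values())
        if self.breeds and not math.isclose(fr, 1.0, abs_tol=1e-9):
            raise ConfigError("breed fractions must sum to 1")
        return self

    @property
    def ticks_per_day(self) -> int:
        return SECONDS_PER_DAY // self.tick_s

    # -- (de)serialisation ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["posture_rates"] = {p: m.tolist() for p, m in self.posture_rates.items()}
        d["baseline_hazard"] = self.baseline_hazard.tolist()
        d["day_grid"] = list(self.day_grid)
        d["litter_size_range"] = list(self.litter_size_range)
        d["activity_probs"] = {p: list(v) for p, v in self.activity_probs.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimConfig":
        d = dict(d)
        if "restlessness_multiplier" in d:
            d["restlessness_multiplier"] = {
                int(k): float(v) for k, v in d["restlessness_multiplier"].items()
            }
        if "day_grid" in d:
            d["day_grid"] = tuple(d["day_grid"])
        if "litter_size_range" in d:
            d["litter_size_range"] = tuple(d["litter_size_range"])
        if "activity_probs" in d:
            d["activity_probs"] = {k: tuple(v) for k, v in d["activity_probs"].items()}
        return cls(**d)


def default_sim_config(**overrides: Any) -> SimConfig:
    """A validated :class:`SimConfig` at the study's default calibration."""
    return SimConfig(**overrides).validate()


@dataclass
class AnalysisConfig:
    """Knobs of the trait-extraction / clustering / association stages."""

    merge_map: dict[str, str] = field(
        default_factory=lambda: dict(eth.DEFAULT_MERGE_MAP)
    )
    #: count posture changes after merging the ambiguous classes (default)
    count_after_merge: bool = True
    #: multiplicative zero replacement before the ILR: half a tick's share
    delta: float = 1.0 / (2 * 17_280)
    k_range: tuple[int, int] = (1, 6)
    n_init: int = 50
    alpha: float = 0.05
    #: head-distance radii (same spatial units as head coordinates)
    r_drink: float = 0.5
    r_eat: float = 0.5

    def validate(self) -> "AnalysisConfig":
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0 < self.delta < 1:
            raise ConfigError("delta must lie in (0, 1)")
        if self.k_range[0] < 1 or self.k_range[1] < self.k_range[0]:
            raise ConfigError("k_range must be an increasing pair of positive ints")
        return self


@dataclass
class RunConfig:
    """Top-level pipeline configuration (paths + simulation + analysis)."""

    out_dir: str = "runs/demo"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self) -> "RunConfig":
        self.sim.validate()
        self.analysis.validate()
        return self

    def to_dict(self) -> dict[str, Any]:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "simulation": self.sim.to_dict(),
            "analysis": asdict(self.analysis),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        sim = d.get("simulation", {})
        sim = SimConfig.from_dict(sim) if not isinstance(sim, SimConfig) else sim
        ana = d.get("analysis", {})
        if not isinstance(ana, AnalysisConfig):
            ana = AnalysisConfig(**ana)
        cfg = cls(
            out_dir=d.get("out_dir", "runs/demo"),
            seed=int(d.get("seed", 0)),
            sim=sim,
            analysis=ana,
        )
        cfg.sim.seed = cfg.sim.seed or cfg.seed
        return cfg.validate()


def load_run_config(path: str) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)


def save_run_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: "RunConfig | SimConfig") -> str:
    """Short stable hash of a configuration, recorded in artifact headers."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
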