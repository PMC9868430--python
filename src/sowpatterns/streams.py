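"""Daily behavioural traits from 5-second posture/activity streams.

This module turns a raw labelled stream (one posture per 5-s tick, plus a
standing activity while the sow is upright) into the five daily traits used
throughout the analysis:

* the postural budget (proportion of time per posture class),
* the standing-activity budget (eat / drink / other shares of standing time),
* PCAll -- the daily number of posture changes (restlessness),
* PCRiskCrush -- changes that put piglets at risk of crushing
  (standing straight into a lying posture, sternal-to-lateral rolls),
* PCStopNurse -- changes that can end a nursing bout (any exit from
  lateral lying with the udder exposed).

The fixed processing order is despike -> merge -> budgets/counts.  Despiking
replaces single-tick posture runs (treated as classifier errors) with the
posture of the previous observation, in a single left-to-right pass over the
raw stream; a leading singleton has no previous observation and is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import ethogram as eth
from .config import PERIOD_DAYS, PERIODS
from .errors import InputDataError

__all__ = [
    "PostureStream",
    "TickLabel",
    "PeriodDataset",
    "despike",
    "merge_postures",
    "classify_standing_activity",
    "daily_postural_budget",
    "daily_standing_budget",
    "count_posture_changes",
    "compute_daily_traits",
    "assemble_period_dataset",
    "sow_period_covariates",
]


class TickLabel(NamedTuple):
    """A single 5-s observation: posture, plus an activity iff standing."""

    posture: str
    activity: str | None = None


@dataclass
class PostureStream:
    """One sow-day of tick labels at fixed 5-s spacing.

    Postures and activities are stored as small integer codes into ``vocab``
    and :data:`ethogram.ACTIVITIES`; ``-1`` marks "no activity" on ticks
    where the sow is not standing.
    """

    sow_id: str
    day: int
    postures: np.ndarray
    activities: np.ndarray
    vocab: tuple[str, ...] = eth.POSTURES

    def __post_init__(self) -> None:
        self.postures = np.asarray(self.postures, dtype=np.int8)
        self.activities = np.asarray(self.activities, dtype=np.int8)
        if self.postures.shape != self.activities.shape:
            raise InputDataError("postures and activities must have equal length")
        if self.postures.size and (
            self.postures.min() < 0 or self.postures.max() >= len(self.vocab)
        ):
            raise InputDataError("posture code outside vocabulary")

    # -- convenience ----------------------------------------------------------
    @property
    def n_ticks(self) -> int:
        return int(self.postures.size)

    def posture_labels(self) -> np.ndarray:
        return np.asarray(self.vocab, dtype=object)[self.postures]

    def tick(self, i: int) -> TickLabel:
        act = self.activities[i]
        return TickLabel(
            self.vocab[self.postures[i]],
            eth.ACTIVITIES[act] if act >= 0 else None,
        )

    def copy(self) -> "PostureStream":
        return PostureStream(
            self.sow_id, self.day, self.postures.copy(), self.activities.copy(), self.vocab
        )

    @classmethod
    def from_labels(
        cls,
        labels: Sequence[str],
        activities: Sequence[str | None] | None = None,
        sow_id: str = "S000",
        day: int = 0,
        vocab: tuple[str, ...] = eth.POSTURES,
    ) -> "PostureStream":
        codes = np.array([vocab.index(p) for p in labels], dtype=np.int8)
        if activities is None:
            acts = np.full(codes.shape, eth.NO_ACTIVITY, dtype=np.int8)
        else:
            acts = np.array(
                [eth.ACTIVITIES.index(a) if a else eth.NO_ACTIVITY for a in activities],
                dtype=np.int8,
            )
        return cls(sow_id, day, codes, acts, vocab)


def _runs(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start index and length of each maximal constant run."""
    starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
    lengths = np.diff(np.r_[starts, codes.size])
    return starts, lengths


def despike(stream: PostureStream) -> PostureStream:
    """Replace single-tick posture runs with the previous observation's posture.

    Run lengths are measured on the raw stream and the pass is causal
    (left-to-right), so a chain of adjacent singletons collapses onto the
    nearest preceding run of length >= 2 (or the leading run).  A replaced
    tick's activity is recomputed to stay consistent with its new posture:
    it inherits the previous tick's activity when the new posture is ST and
    becomes "none" otherwise.
    """
    if stream.n_ticks == 0:
        raise InputDataError("cannot despike an empty stream")
    codes = stream.postures
    starts, lengths = _runs(codes)
    anchor = lengths >= 2
    anchor[0] = True  # a leading singleton has no previous observation
    run_idx = np.arange(starts.size)
    last_anchor = np.maximum.accumulate(np.where(anchor, run_idx, -1))
    new_run_post = codes[starts][last_anchor]
    new_codes = np.repeat(new_run_post, lengths).astype(np.int8)

    new_acts = stream.activities.copy()
    replaced = np.flatnonzero(~anchor)  # all length-1, never index 0
    if replaced.size:
        pos = starts[replaced]
        src = starts[last_anchor[replaced]] + lengths[last_anchor[replaced]] - 1
        try:
            st_code = stream.vocab.index("ST")
        except ValueError:
            st_code = -2
        new_acts[pos] = np.where(
            new_codes[pos] == st_code, stream.activities[src], eth.NO_ACTIVITY
        )
    return PostureStream(stream.sow_id, stream.day, new_codes, new_acts, stream.vocab)


def merge_postures(
    stream: PostureStream, merge_map: Mapping[str, str] = eth.DEFAULT_MERGE_MAP
) -> PostureStream:
    """Relabel ethogram postures onto analysis classes.

    The default map pools the two visually confusable upright classes
    (sitting and kneeling) into ``SI+K``.  The merged vocabulary preserves
    the order of first appearance in the source vocabulary.
    """
    missing = [lab for lab in stream.vocab if lab not in merge_map]
    if missing:
        raise InputDataError(f"merge map does not cover label(s): {missing}")
    new_vocab: list[str] = []
    remap = np.empty(len(stream.vocab), dtype=np.int8)
    for i, lab in enumerate(stream.vocab):
        target = merge_map[lab]
        if target not in new_vocab:
            new_vocab.append(target)
        remap[i] = new_vocab.index(target)
    return PostureStream(
        stream.sow_id,
        stream.day,
        remap[stream.postures],
        stream.activities.copy(),
        tuple(new_vocab),
    )


def classify_standing_activity(
    head_xy: Sequence[float] | np.ndarray,
    trough_xy: Sequence[float],
    feeder_xy: Sequence[float],
    r_drink: float,
    r_eat: float,
) -> "str | np.ndarray":
    """Head-distance rule for standing ticks: DRINK / EAT / OTHER.

    A sow with her head within ``r_drink`` of the drinking trough is
    drinking; otherwise within ``r_eat`` of the feeder she is eating;
    otherwise she is doing something other.  Drinking takes precedence when
    both radii are satisfied.  Accepts a single ``(x, y)`` pair or an
    ``(n, 2)`` array.
    """
    if r_drink <= 0 or r_eat <= 0:
        raise InputDataError("activity radii must be positive")
    head = np.atleast_2d(np.asarray(head_xy, dtype=float))
    d_tr = np.hypot(*(head - np.asarray(trough_xy, dtype=float)).T)
    d_fe = np.hypot(*(head - np.asarray(feeder_xy, dtype=float)).T)
    out = np.where(d_tr <= r_drink, "DRINK", np.where(d_fe <= r_eat, "EAT", "OTHER"))
    return out[0] if np.asarray(head_xy).ndim == 1 else out


def daily_postural_budget(stream: PostureStream) -> pd.Series:
    """Proportion of ticks in each posture class (sums to 1)."""
    if stream.n_ticks == 0:
        raise InputDataError("postural budget undefined for an empty day")
    counts = np.bincount(stream.postures, minlength=len(stream.vocab))
    return pd.Series(counts / stream.n_ticks, index=list(stream.vocab))


def daily_standing_budget(stream: PostureStream) -> pd.Series | None:
    """EAT/DRINK/OTHER shares of standing time; ``None`` if never standing.

    A day without a single standing tick has no defined standing-activity
    composition (a structural absence, not a zero composition).
    """
    if "ST" not in stream.vocab:
        return None
    st_mask = stream.postures == stream.vocab.index("ST")
    if not st_mask.any():
        return None
    acts = stream.activities[st_mask]
    counts = np.bincount(acts[acts >= 0], minlength=len(eth.ACTIVITIES))
    total = counts.sum()
    if total == 0:
        return None
    return pd.Series(counts / total, index=list(eth.ACTIVITIES))


def _transition_masks(vocab: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean lookup tables (V x V) for crush-risk and stop-nurse transitions."""
    v = len(vocab)
    risk = np.zeros((v, v), dtype=bool)
    for a, b in eth.RISK_CRUSH_TRANSITIONS:
        if a in vocab and b in vocab:
            risk[vocab.index(a), vocab.index(b)] = True
    stop = np.zeros((v, v), dtype=bool)
    if eth.STOP_NURSE_SOURCE in vocab:
        i = vocab.index(eth.STOP_NURSE_SOURCE)
        stop[i, :] = True
        stop[i, i] = False
    return risk, stop


def count_posture_changes(stream: PostureStream) -> tuple[int, int, int]:
    """(PCAll, PCRiskCrush, PCStopNurse) from adjacent tick pairs.

    PCAll counts every adjacent pair with differing postures; PCRiskCrush the
    standing-to-lying and sternal-to-lateral subsets; PCStopNurse every exit
    from lateral lying with the udder exposed.  Streams are expected to be
    despiked first (single-tick runs otherwise inflate all three counts).
    """
    codes = stream.postures
    if codes.size < 2:
        return (0, 0, 0)
    a, b = codes[:-1], codes[1:]
    risk, stop = _transition_masks(stream.vocab)
    pc_all = int(np.count_nonzero(a != b))
    pc_risk = int(np.count_nonzero(risk[a, b]))
    pc_stop = int(np.count_nonzero(stop[a, b]))
    return (pc_all, pc_risk, pc_stop)


def compute_daily_traits(
    streams: Iterable[PostureStream],
    *,
    despike_first: bool = True,
    merge_map: Mapping[str, str] | None = eth.DEFAULT_MERGE_MAP,
    count_after_merge: bool = True,
) -> pd.DataFrame:
    """One row of daily traits per sow-day.

    Columns: ``prop_<class>`` postural budget, ``act_<EAT|DRINK|OTHER>``
    standing budget (NaN on days without standing), the three posture-change
    counts, and ``total_ticks``.
    """
    rows = []
    for raw in streams:
        s = despike(raw) if despike_first else raw
        merged = merge_postures(s, merge_map) if merge_map is not None else s
        counted = merged if count_after_merge else s
        pc_all, pc_risk, pc_stop = count_posture_changes(counted)
        row: dict[str, object] = {
            "sow_id": raw.sow_id,
            "day": raw.day,
            "total_ticks": merged.n_ticks,
            "pcall": pc_all,
            "pcriskcrush": pc_risk,
            "pcstopnurse": pc_stop,
        }
        for lab, v in daily_postural_budget(merged).items():
            row[f"prop_{lab}"] = v
        standing = daily_standing_budget(merged)
        for lab in eth.ACTIVITIES:
            row[f"act_{lab}"] = np.nan if standing is None else standing[lab]
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["sow_id", "day"]).reset_index(drop=True)
    return df


@dataclass
class PeriodDataset:
    """Daily traits of one peripartum period plus per-sow completeness."""

    period: str
    days: tuple[int, ...]
    traits: pd.DataFrame
    complete: pd.Series  # indexed by sow_id, True if every day is present

    @property
    def complete_sows(self) -> list[str]:
        return list(self.complete.index[self.complete])


def assemble_period_dataset(traits: pd.DataFrame, period: str) -> PeriodDataset:
    """Restrict a trait table to one period and flag complete sows.

    Downstream clustering uses complete sows only; a sow missing any day of
    the period is flagged incomplete.
    """
    if period not in PERIODS:
        raise InputDataError(f"unknown period {period!r}")
    days = PERIOD_DAYS[period]
    sub = traits[traits["day"].isin(days)].copy()
    sows = traits["sow_id"].unique()
    present = sub.groupby("sow_id")["day"].nunique()
    complete = pd.Series(
        [present.get(s, 0) == len(days) for s in sows], index=pd.Index(sows, name="sow_id")
    )
    return PeriodDataset(period, days, sub.reset_index(drop=True), complete)


def sow_period_covariates(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-sow period summaries of the daily traits.

    For each period ``p`` produces period means of the counts
    (``pcall_p``, ``pcriskcrush_p``, ``pcstopnurse_p``) and hours/day
    spent per posture class (``st_h_p``, ``llu_h_p``, ...) and per standing
    activity (``eat_h_p``, ``drink_h_p``, ``other_h_p``).  Days with no
    standing contribute zero activity hours.  Sows missing every day of a
    period get NaN for that period's columns.
    """
    out: dict[str, pd.Series] = {}
    hour_cols = {
        c: c.replace("prop_", "").replace("+", "").lower() + "_h"
        for c in traits.columns
        if c.startswith("prop_")
    }
    for period in PERIODS:
        sub = traits[traits["day"].isin(PERIOD_DAYS[period])]
        g = sub.groupby("sow_id")
        for col in ("pcall", "pcriskcrush", "pcstopnurse"):
            out[f"{col}_{period}"] = g[col].mean()
        for col, name in hour_cols.items():
            out[f"{name}_{period}"] = g[col].mean() * 24.0
        if "prop_ST" in sub.columns:
            for act in eth.ACTIVITIES:
                hours = (sub[f"act_{act}"].fillna(0.0) * sub["prop_ST"] * 24.0).groupby(
                    sub["sow_id"]
                ).mean()
                out[f"{act.lower()}_h_{period}"] = hours
    df = pd.DataFrame(out)
    df.index.name = "sow_id"
    return df
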