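"""File formats: long stream CSV, trait/cluster tables, model reports.

Streams are stored in a long CSV with one row per 5-s tick
(``sow_id, day, tick_index, posture, activity``); the activity field is
empty on non-standing ticks.  Missing sow-days are encoded by absence, not
by NA rows.  Every artifact starts with a comment header recording the
configuration hash, so a result file can always be matched to the exact
run that produced it.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import ethogram as eth
from .errors import InputDataError
from .streams import PostureStream

__all__ = [
    "write_streams_csv",
    "read_stream_csv",
    "StreamCollection",
    "write_table",
    "read_table",
]

_STREAM_COLUMNS = ("sow_id", "day", "tick_index", "posture", "activity")


def _opener(path: "str | Path", mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_streams_csv(
    streams: Iterable[PostureStream], path: "str | Path", config_hash: str | None = None
) -> None:
    """Write streams in the long tick-per-row format (optionally gzipped)."""
    frames = []
    for s in streams:
        acts = np.where(
            s.activities >= 0,
            np.asarray(eth.ACTIVITIES, dtype=object)[np.clip(s.activities, 0, None)],
            "",
        )
        frames.append(
            pd.DataFrame(
                {
                    "sow_id": s.sow_id,
                    "day": s.day,
                    "tick_index": np.arange(s.n_ticks),
                    "posture": s.posture_labels(),
                    "activity": acts,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(_STREAM_COLUMNS))
    )
    with _opener(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


@dataclass
class StreamCollection:
    """Streams read back from disk plus data-quality findings."""

    streams: list[PostureStream]
    missing_ticks: pd.DataFrame  # sow_id, day, n_missing
    config_hash: str | None = None

    def __iter__(self):
        return iter(self.streams)

    def __len__(self) -> int:
        return len(self.streams)


def read_stream_csv(
    path: "str | Path", vocab: tuple[str, ...] = eth.POSTURES
) -> StreamCollection:
    """Read and validate a long stream CSV.

    Unknown posture codes are rejected with the offending line numbers;
    gaps in ``tick_index`` within a sow-day are reported (not errors) as
    missing ticks.
    """
    with _opener(path, "r") as fh:
        first = fh.readline()
        cfg_hash = None
        offset = 1  # header line
        if first.startswith("#"):
            cfg_hash = first.strip().lstrip("# ").split("=", 1)[-1]
            offset = 2
            header = fh.readline()
        else:
            header = first
        cols = [c.strip() for c in header.strip().split(",")]
        if cols != list(_STREAM_COLUMNS):
            raise InputDataError(
                f"unexpected stream header {cols!r}; expected {list(_STREAM_COLUMNS)}"
            )
        df = pd.read_csv(
            fh,
            names=cols,
            dtype={"sow_id": str, "day": int, "tick_index": int, "posture": str},
            keep_default_na=False,
        )
    if df.empty:
        raise InputDataError(f"stream file {path} contains no observations")
    bad = ~df["posture"].isin(vocab)
    if bad.any():
        lines = (df.index[bad] + offset + 1).tolist()[:10]
        raise InputDataError(
            f"unknown posture code(s) {sorted(df.loc[bad, 'posture'].unique())} "
            f"at line(s) {lines}"
        )
    bad_act = ~df["activity"].isin(list(eth.ACTIVITIES) + [""])
    if bad_act.any():
        lines = (df.index[bad_act] + offset + 1).tolist()[:10]
        raise InputDataError(f"unknown activity code at line(s) {lines}")

    post_code = {p: i for i, p in enumerate(vocab)}
    act_code = {a: i for i, a in enumerate(eth.ACTIVITIES)}
    act_code[""] = eth.NO_ACTIVITY
    streams: list[PostureStream] = []
    gaps = []
    for (sow, day), sub in df.groupby(["sow_id", "day"], sort=True):
        ticks = sub["tick_index"].to_numpy()
        if np.any(np.diff(ticks) <= 0):
            raise InputDataError(
                f"tick_index not strictly increasing for sow {sow} day {day}"
            )
        n_missing = int(ticks[-1] - ticks[0] + 1 - ticks.size)
        if n_missing:
            gaps.append({"sow_id": sow, "day": int(day), "n_missing": n_missing})
        streams.append(
            PostureStream(
                sow_id=str(sow),
                day=int(day),
                postures=sub["posture"].map(post_code).to_numpy(dtype=np.int8),
                activities=sub["activity"].map(act_code).to_numpy(dtype=np.int8),
                vocab=vocab,
            )
        )
    missing = pd.DataFrame(gaps, columns=["sow_id", "day", "n_missing"])
    return StreamCollection(streams, missing, cfg_hash)


def write_table(
    df: pd.DataFrame, path: "str | Path", config_hash: str | None = None, index: bool = False
) -> None:
    """CSV writer with the standard config-hash comment header."""
    with _opener(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=index)


def read_table(path: "str | Path", **kwargs) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (skips comment headers)."""
    if not Path(path).exists():
        raise InputDataError(f"missing table {path}")
    return pd.read_csv(path, comment="#", **kwargs)


def write_json(payload: dict, path: "str | Path") -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
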