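"""Ethogram vocabulary for sow posture and standing-activity labels.

Six postures are distinguished: standing (ST), sitting (SI), kneeling (K),
sternal lying (SL), lateral lying with the udder hidden (LL) and lateral
lying with the udder exposed (LLU, the nursing-accessible posture).  While
standing, a sow is additionally classified as eating (head in the feeder),
drinking (head in the drinking trough) or doing something other.

The sitting and kneeling classes are hard to tell apart on overhead video,
so the default analysis merges them into a single ``SI+K`` class.
"""

from __future__ import annotations

POSTURES: tuple[str, ...] = ("ST", "SI", "K", "SL", "LL", "LLU")
ACTIVITIES: tuple[str, ...] = ("EAT", "DRINK", "OTHER")

#: activity code used on ticks where the sow is not standing
NO_ACTIVITY: int = -1

#: default analysis relabelling: sitting and kneeling pooled
DEFAULT_MERGE_MAP: dict[str, str] = {
    "ST": "ST",
    "SI": "SI+K",
    "K": "SI+K",
    "SL": "SL",
    "LL": "LL",
    "LLU": "LLU",
}

#: postures counted as lying
LYING: tuple[str, ...] = ("SL", "LL", "LLU")

#: transitions that put piglets at risk of crushing: standing straight down
#: into any lying posture, and sternal-to-lateral rolls
RISK_CRUSH_TRANSITIONS: frozenset[tuple[str, str]] = frozenset(
    {("ST", "LL"), ("ST", "LLU"), ("ST", "SL"), ("SL", "LL"), ("SL", "LLU")}
)

#: source posture whose exits can terminate a nursing bout (udder hidden)
STOP_NURSE_SOURCE: str = "LLU"


def posture_code(label: str, vocab: tuple[str, ...] = POSTURES) -> int:
    """Integer code of ``label`` within ``vocab`` (raises ValueError if absent)."""
    return vocab.index(label)
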