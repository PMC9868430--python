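"""Compositional geometry for daily time budgets.

Daily postural and standing-activity budgets are compositions: non-negative
parts that sum to one.  Euclidean operations on raw proportions are
ill-behaved (spurious correlations, boundary effects), so budgets are mapped
to unconstrained coordinates with an isometric log-ratio (ILR) transform
before clustering.  The ILR is an isometry of the Aitchison geometry:
Aitchison distances between compositions equal Euclidean distances between
their coordinates, for any orthonormal basis, which makes downstream
cluster assignments basis-invariant.

Bases are built from a sequential binary partition (SBP): an ordered list of
splits of the parts into a +group and a -group.  The default postural basis
contrasts lying vs upright first, then splits within each block; the default
activity basis contrasts "other" vs the two maintenance activities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, InputDataError

__all__ = [
    "IlrBasis",
    "default_postural_basis",
    "default_activity_basis",
    "zero_replace",
    "ilr_transform",
    "ilr_inverse",
    "clr",
    "aitchison_distance",
    "closure",
]

#: default zero replacement: half of one 5-s tick's share of a day
DEFAULT_DELTA = 1.0 / (2 * 17_280)


def closure(x: np.ndarray) -> np.ndarray:
    """Rescale rows to sum to one."""
    x = np.asarray(x, dtype=float)
    return x / x.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class IlrBasis:
    """Orthonormal ILR contrast matrix derived from a sequential binary partition."""

    parts: tuple[str, ...]
    contrast: np.ndarray  # (D-1, D), rows orthonormal and orthogonal to 1

    def __post_init__(self) -> None:
        d = len(self.parts)
        c = np.asarray(self.contrast, dtype=float)
        if c.shape != (d - 1, d):
            raise ConfigError("contrast matrix must be (D-1) x D")
        if not np.allclose(c @ c.T, np.eye(d - 1), atol=1e-10):
            raise ConfigError("contrast rows must be orthonormal")
        if not np.allclose(c.sum(axis=1), 0.0, atol=1e-10):
            raise ConfigError("contrast rows must be orthogonal to the ones vector")
        object.__setattr__(self, "contrast", c)

    @classmethod
    def from_sbp(
        cls,
        parts: Sequence[str],
        splits: Sequence[tuple[Sequence[str], Sequence[str]]],
    ) -> "IlrBasis":
        """Build the basis from ``D - 1`` ordered (+group, -group) splits.

        Each split contributes the balance coordinate
        ``sqrt(r s / (r + s)) * log(g_plus / g_minus)`` where ``g`` are
        geometric means and ``r``, ``s`` the group sizes.
        """
        parts = tuple(parts)
        d = len(parts)
        if len(splits) != d - 1:
            raise ConfigError(f"need {d - 1} splits for {d} parts, got {len(splits)}")
        rows = []
        for plus, minus in splits:
            plus, minus = set(plus), set(minus)
            if plus & minus:
                raise ConfigError("split groups must be disjoint")
            if not (plus | minus) <= set(parts):
                raise ConfigError("split references unknown part labels")
            r, s = len(plus), len(minus)
            if r == 0 or s == 0:
                raise ConfigError("both groups of a split must be non-empty")
            row = np.zeros(d)
            for j, p in enumerate(parts):
                if p in plus:
                    row[j] = np.sqrt(s / (r * (r + s)))
                elif p in minus:
                    row[j] = -np.sqrt(r / (s * (r + s)))
            rows.append(row)
        return cls(parts, np.vstack(rows))

    @property
    def n_coords(self) -> int:
        return len(self.parts) - 1


def default_postural_basis(
    parts: Sequence[str] = ("ST", "SI+K", "SL", "LL", "LLU"),
) -> IlrBasis:
    """Lying-vs-upright first, then within-lying and within-upright splits."""
    parts = tuple(parts)
    lying = [p for p in parts if p in ("SL", "LL", "LLU")]
    upright = [p for p in parts if p not in lying]
    splits: list[tuple[Sequence[str], Sequence[str]]] = [(lying, upright)]
    # within lying: udder exposed vs hidden, then lateral vs sternal
    if "LLU" in lying:
        rest = [p for p in lying if p != "LLU"]
        splits.append((["LLU"], rest))
        if len(rest) == 2:
            splits.append(([rest[1]], [rest[0]]))
    # within upright
    if len(upright) == 2:
        splits.append(([upright[0]], [upright[1]]))
    return IlrBasis.from_sbp(parts, splits)


def default_activity_basis(
    parts: Sequence[str] = ("EAT", "DRINK", "OTHER"),
) -> IlrBasis:
    """Other-activity vs maintenance (eat + drink), then eat vs drink."""
    return IlrBasis.from_sbp(parts, [ (["OTHER"], ["EAT", "DRINK"]), (["EAT"], ["DRINK"]) ])


def zero_replace(c: np.ndarray, delta: float = DEFAULT_DELTA) -> np.ndarray:
    """Multiplicative replacement of zero parts.

    Zero parts are set to ``delta`` and the non-zero parts of the same row
    are shrunk by ``(1 - z * delta)`` where ``z`` is that row's number of
    zeros, preserving closure.  ``delta`` must be positive and smaller than
    every non-zero part.
    """
    x = np.asarray(c, dtype=float)
    if np.any(x < 0):
        raise InputDataError("composition parts must be non-negative")
    if delta <= 0:
        raise InputDataError("delta must be positive")
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    nz_min = np.where(x > 0, x, np.inf).min()
    if delta >= nz_min:
        raise InputDataError("delta must be smaller than the smallest non-zero part")
    z = (x == 0).sum(axis=1, keepdims=True)
    out = np.where(x == 0, delta, x * (1.0 - z * delta))
    return out[0] if one_d else out


def ilr_transform(c: np.ndarray, basis: IlrBasis) -> np.ndarray:
    """ILR coordinates ``contrast @ log(parts)`` (rows for 2-D input).

    Parts must be strictly positive; apply :func:`zero_replace` first when a
    budget contains structural zeros.
    """
    x = np.asarray(c, dtype=float)
    if x.shape[-1] != len(basis.parts):
        raise InputDataError("composition dimension does not match basis")
    if np.any(x <= 0):
        raise InputDataError("ILR requires strictly positive parts (zero_replace first)")
    return np.log(x) @ basis.contrast.T


def ilr_inverse(y: np.ndarray, basis: IlrBasis) -> np.ndarray:
    """Exact inverse of :func:`ilr_transform`: a strictly positive closed composition."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise InputDataError("ILR coordinates must be finite")
    logx = y @ basis.contrast
    x = np.exp(logx - logx.max(axis=-1, keepdims=True))
    return closure(x)


def clr(c: np.ndarray) -> np.ndarray:
    """Centred log-ratio transform (basis-free)."""
    x = np.asarray(c, dtype=float)
    lx = np.log(x)
    return lx - lx.mean(axis=-1, keepdims=True)


def aitchison_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Aitchison distance between compositions (Euclidean norm of clr difference)."""
    return np.linalg.norm(clr(a) - clr(b), axis=-1)
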