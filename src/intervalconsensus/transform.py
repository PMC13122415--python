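"""Link function between bounded interval responses and the unbounded plane.

An interval response ``[lower, upper]`` on the closed unit scale is equivalent
to a three-part composition ``(lower, upper - lower, 1 - upper)``: the gap to
the left of the interval, the interval width, and the gap to the right.  The
composition lives on the 2-simplex, so an isometric log-ratio (ILR) transform
maps it to an unbounded bivariate point whose first coordinate is an interval
*location* (log-ratio of left vs right gap) and whose second coordinate is an
interval *width* (log-ratio of the width against the geometric mean of the two
gaps).  Because boundary-touching responses put zeros in the composition, an
optional padding constant ``c`` is added to all three parts (and renormalised)
before taking logs; the padding is undone after back-transforming.

All functions are vectorised over leading axes: bounds are arrays of shape
``(...)``, compositions ``(..., 3)`` and bivariate points ``(..., 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "K1",
    "K2",
    "IntervalResponse",
    "Composition3",
    "BivariatePoint",
    "PaddingConfig",
    "to_composition",
    "pad",
    "unpad",
    "ilr",
    "ilr_inverse",
    "to_interval",
    "interval_to_unbounded",
    "unbounded_to_interval",
    "transform_table",
]

#: Orthonormal ILR basis constants for a 3-part composition.
K1 = 1.0 / np.sqrt(2.0)
K2 = np.sqrt(2.0 / 3.0)

_SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class IntervalResponse:
    """One observed interval on the bounded [0, 1] response scale."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("interval bounds must be finite")
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError(
                f"invalid interval ({self.lower}, {self.upper}): "
                "need 0 <= lower <= upper <= 1"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.lower, self.upper])


@dataclass(frozen=True)
class Composition3:
    """Three-part simplex representation (left gap, width, right gap)."""

    x1: float
    x2: float
    x3: float

    def __post_init__(self) -> None:
        parts = np.array([self.x1, self.x2, self.x3])
        if np.any(parts < 0):
            raise ValueError(f"composition parts must be non-negative, got {parts}")
        if abs(parts.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"composition must sum to 1, got sum {parts.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3])


@dataclass(frozen=True)
class BivariatePoint:
    """A (location, width) pair on the unbounded transformed scale."""

    loc: float
    wid: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.loc) and np.isfinite(self.wid)):
            raise ValueError("bivariate point must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.loc, self.wid])


@dataclass(frozen=True)
class PaddingConfig:
    """Padding constant added to all composition parts before renormalising."""

    c: float = 0.01

    def __post_init__(self) -> None:
        if not np.isfinite(self.c) or self.c < 0:
            raise ValueError(f"padding constant must be >= 0, got {self.c}")


def _validate_bounds(lower: np.ndarray, upper: np.ndarray) -> None:
    bad = (lower < 0) | (upper > 1) | (lower > upper) | ~np.isfinite(lower) | ~np.isfinite(upper)
    if np.any(bad):
        idx = np.argwhere(np.atleast_1d(bad))[0]
        lo = np.atleast_1d(lower)[tuple(idx)]
        up = np.atleast_1d(upper)[tuple(idx)]
        raise ValueError(
            f"invalid interval ({lo}, {up}): need 0 <= lower <= upper <= 1"
        )


def to_composition(lower, upper) -> np.ndarray:
    """Map interval bounds to the 3-part composition (left gap, width, right gap)."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    _validate_bounds(lower, upper)
    return np.stack([lower, upper - lower, 1.0 - upper], axis=-1)


def pad(comp, c: float) -> np.ndarray:
    """Add the padding constant to every part and renormalise to the simplex."""
    comp = np.asarray(comp, dtype=float)
    if c < 0:
        raise ValueError(f"padding constant must be >= 0, got {c}")
    return (comp + c) / (1.0 + 3.0 * c)


def unpad(comp, c: float) -> np.ndarray:
    """Exact inverse of :func:`pad`; tiny negative parts (< 1e-9) are clamped to 0."""
    comp = np.asarray(comp, dtype=float)
    out = comp * (1.0 + 3.0 * c) - c
    if np.any(out < -1e-9):
        raise ValueError(
            "unpad produced a negative component; padding constant inconsistent "
            "with the composition"
        )
    return np.clip(out, 0.0, None)


def ilr(comp, k1: float = K1, k2: float = K2) -> np.ndarray:
    """ILR transform of a strictly positive 3-part composition.

    Returns ``(loc, wid)`` with ``loc = k1 * ln(x1/x3)`` and
    ``wid = k2 * ln(x2 / sqrt(x1 * x3))``.  Right-shifted intervals have
    ``loc > 0``; intervals wider than the geometric mean of the two gaps have
    ``wid > 0``.
    """
    comp = np.asarray(comp, dtype=float)
    if np.any(comp <= 0):
        raise ValueError(
            "composition has a zero (or negative) part; apply padding with c > 0 "
            "before the ILR transform"
        )
    logs = np.log(comp)
    loc = k1 * (logs[..., 0] - logs[..., 2])
    wid = k2 * (logs[..., 1] - 0.5 * (logs[..., 0] + logs[..., 2]))
    return np.stack([loc, wid], axis=-1)


def ilr_inverse(z, k1: float = K1, k2: float = K2) -> np.ndarray:
    """Inverse ILR: map an unbounded (loc, wid) point back to the simplex."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("bivariate point must be finite")
    u = z[..., 0] / k1
    v = z[..., 1] / k2
    # softmax of (u/2, v, -u/2), stabilised
    logits = np.stack([u / 2.0, v, -u / 2.0], axis=-1)
    logits = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=-1, keepdims=True)


def to_interval(comp) -> np.ndarray:
    """Read interval bounds off a composition: ``(x1, x1 + x2)``."""
    comp = np.asarray(comp, dtype=float)
    lower = comp[..., 0]
    upper = comp[..., 0] + comp[..., 1]
    return np.stack([lower, np.minimum(upper, 1.0)], axis=-1)


def interval_to_unbounded(lower, upper, c: float = 0.0) -> np.ndarray:
    """Full forward pipeline: bounds -> composition -> pad -> ILR."""
    return ilr(pad(to_composition(lower, upper), c))


def unbounded_to_interval(z, c: float = 0.0) -> np.ndarray:
    """Full inverse pipeline: ILR point -> composition -> unpad -> bounds."""
    return to_interval(unpad(ilr_inverse(z), c))


def transform_table(
    table: pd.DataFrame, c: float = 0.01, scale_max: float = 1.0
) -> pd.DataFrame:
    """Augment a long-format response table with composition and ILR columns.

    Expects columns ``respondent_id, item_id, lower, upper``; bounds are divided
    by ``scale_max`` first (e.g. 100 for percentage sliders).  Padding is
    skipped (c treated as 0) when no response touches a scale boundary, since
    all log-ratios are then already defined.
    """
    out = table.copy()
    lower = out["lower"].to_numpy(dtype=float) / scale_max
    upper = out["upper"].to_numpy(dtype=float) / scale_max
    comp = to_composition(lower, upper)
    c_eff = c if np.any(comp == 0) else 0.0
    z = ilr(pad(comp, c_eff))
    out["x1"], out["x2"], out["x3"] = comp[:, 0], comp[:, 1], comp[:, 2]
    out["loc"], out["wid"] = z[:, 0], z[:, 1]
    return out
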