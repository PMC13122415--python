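"""Descriptive competitor aggregators: means and medians on the ILR scale.

The "wisdom of crowds" baselines transform every response to the unbounded
(location, width) scale, take the componentwise mean or median per item, and
back-transform the aggregate to a bounded interval.  Medians are marginal
(per dimension), with the usual midpoint convention for even counts.  Note
that because the link is non-linear, the mean on the unbounded scale is *not*
the mean of the observed bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transform import (
    BivariatePoint,
    IntervalResponse,
    ilr,
    pad,
    to_composition,
    unbounded_to_interval,
)

__all__ = ["BaselineEstimate", "aggregate"]


@dataclass(frozen=True)
class BaselineEstimate:
    """Aggregated consensus estimate for one item."""

    item_id: str
    method: str
    unbounded: BivariatePoint
    bounded: IntervalResponse


def aggregate(data: pd.DataFrame, method: str = "median", c: float = 0.01) -> pd.DataFrame:
    """Per-item mean or median of ILR-transformed responses.

    ``data`` is a long-format table with columns ``respondent_id, item_id,
    lower, upper`` on [0, 1].  Padding ``c`` is applied only if some response
    touches a scale boundary.  Returns one row per item with both scales.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"method must be 'mean' or 'median', got {method!r}")
    if len(data) == 0:
        raise ValueError("cannot aggregate an empty response table")
    comp = to_composition(
        data["lower"].to_numpy(dtype=float), data["upper"].to_numpy(dtype=float)
    )
    c_eff = c if np.any(comp == 0) else 0.0
    z = ilr(pad(comp, c_eff))
    frame = pd.DataFrame(
        {"item_id": data["item_id"].to_numpy(), "loc": z[:, 0], "wid": z[:, 1]}
    )
    agg = frame.groupby("item_id", sort=True).agg(method)
    est = agg[["loc", "wid"]].to_numpy()
    bounds = unbounded_to_interval(est, c=c_eff)
    return pd.DataFrame(
        {
            "item_id": agg.index.to_numpy(),
            "method": method,
            "loc": est[:, 0],
            "wid": est[:, 1],
            "lower": bounds[:, 0],
            "upper": bounds[:, 1],
        }
    )


def aggregate_estimates(data: pd.DataFrame, method: str = "median", c: float = 0.01):
    """Like :func:`aggregate` but returning :class:`BaselineEstimate` objects."""
    table = aggregate(data, method=method, c=c)
    return [
        BaselineEstimate(
            item_id=str(r.item_id),
            method=method,
            unbounded=BivariatePoint(r.loc, r.wid),
            bounded=IntervalResponse(r.lower, r.upper),
        )
        for r in table.itertuples(index=False)
    ]
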