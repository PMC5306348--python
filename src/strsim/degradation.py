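"""Closed-form DNA degradation model.

Degradation is random cleavage with a constant per-base-pair probability
``p_deg``; a fragment of x bases survives (and can amplify) only if none
of its bases is cleaved, so

    P(intact) = (1 - p_deg)**x

and concentration falls log-linearly with target length,

    ln c(x) = ln H + x * ln(1 - p_deg).

Dual-target qPCR kits measure c(x) at two amplicon lengths, which fixes
both the degradation index DI = c_small / c_large (kit-dependent, since
it depends on the two target lengths) and the per-bp parameter p_deg
(kit-independent).  This module implements those closed forms plus the
drop-out probability for n copies and the cells-per-aliquot planner.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QuantPair",
    "DegradationModel",
    "DegradationWarning",
    "degradation_index",
    "estimate_p_deg",
    "p_intact",
    "p_dropout_n",
    "intact_curve",
    "cells_required",
]


class DegradationWarning(UserWarning):
    """Signals a quantification pair violating the decay model."""


@dataclass(frozen=True)
class QuantPair:
    """Dual-target qPCR result for one sample.

    Concentrations in ng/µl of the small and large autosomal targets,
    with their amplicon lengths in bp (e.g. 80/214 for Quantifiler Trio,
    84/294 for PowerQuant).
    """

    c_small: float
    c_large: float
    x_small: float
    x_large: float

    def __post_init__(self) -> None:
        if self.c_small <= 0 or self.c_large <= 0:
            raise ValueError("concentrations must be > 0")
        if not (self.x_small < self.x_large):
            raise ValueError("x_small must be < x_large")


@dataclass(frozen=True)
class DegradationModel:
    """Fitted per-bp degradation probability and decay intercept H (ng/µl)."""

    p_deg: float
    intercept: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_deg < 1.0):
            raise ValueError("p_deg must be in [0, 1)")

    def concentration(self, x: float) -> float:
        """Model concentration at target length x (requires ``intercept``)."""
        if self.intercept is None:
            raise ValueError("model has no intercept")
        return self.intercept * (1.0 - self.p_deg) ** x


def degradation_index(q: QuantPair) -> float:
    """Degradation index DI = c_small / c_large (dimensionless)."""
    return q.c_small / q.c_large


def estimate_p_deg(q: QuantPair) -> DegradationModel:
    """Per-bp degradation probability from a dual-target quant pair.

    Solves the two-point log-linear decay for the slope:

        p_deg = 1 - exp[(ln c_large - ln c_small) / (x_large - x_small)]

    and the intercept H = c_small / (1 - p_deg)**x_small.  A pair with
    c_large > c_small has no valid decay slope; p_deg is clamped to 0
    with a :class:`DegradationWarning`.
    """
    if q.c_large > q.c_small:
        warnings.warn(
            "c_large > c_small violates the decay model; clamping p_deg to 0",
            DegradationWarning,
            stacklevel=2,
        )
        return DegradationModel(p_deg=0.0, intercept=q.c_small)
    slope = math.log(q.c_large / q.c_small) / (q.x_large - q.x_small)
    p_deg = -math.expm1(slope)  # 1 - e^slope, well conditioned near 0
    intercept = q.c_small / (1.0 - p_deg) ** q.x_small
    return DegradationModel(p_deg=p_deg, intercept=intercept)


def p_intact(p_deg: float, x: float) -> float:
    """Probability that a fragment of x bases carries no cleavage."""
    if not (0.0 <= p_deg < 1.0):
        raise ValueError(f"p_deg must be in [0, 1), got {p_deg!r}")
    if x < 0:
        raise ValueError(f"fragment length must be >= 0, got {x!r}")
    return (1.0 - p_deg) ** x


def p_dropout_n(p_drop1: float, n: int) -> float:
    """Drop-out probability for n copies: 1 - (1 - p_drop1)**n."""
    if not (0.0 <= p_drop1 <= 1.0):
        raise ValueError(f"p_drop1 must be in [0, 1], got {p_drop1!r}")
    if n < 0:
        raise ValueError("n must be >= 0")
    return 1.0 - (1.0 - p_drop1) ** n


def intact_curve(
    p_deg_values: list[float],
    x_range: tuple[float, float] = (0.0, 500.0),
    n_points: int = 201,
) -> pd.DataFrame:
    """Tabulate P(intact) against fragment length, one series per p_deg.

    Long-format frame with columns ``p_deg``, ``size_bp``, ``p_intact``;
    every series is monotone non-increasing in length.
    """
    for p in p_deg_values:
        if not (0.0 <= p < 1.0):
            raise ValueError(f"p_deg values must be in [0, 1), got {p!r}")
    xs = np.linspace(x_range[0], x_range[1], n_points)
    frames = []
    for p in p_deg_values:
        frames.append(pd.DataFrame({"p_deg": p, "size_bp": xs, "p_intact": (1.0 - p) ** xs}))
    return pd.concat(frames, ignore_index=True)


def cells_required(
    amount_pg: float,
    aliquot: float,
    pg_per_cell: float = 6.0,
) -> int:
    """Cells needed in the extract so an aliquot carries ``amount_pg``.

    ``ceil(amount_pg / (pg_per_cell * aliquot))`` — the planner behind
    "how many cells must the stain contain" tables.  ``pg_per_cell`` is
    an explicit parameter (6 pg/cell reproduces the printed planning
    grid exactly; 6.6 pg/diploid cell is the value used to convert pg to
    cells in the simulation experiments).
    """
    if not (0.0 < aliquot <= 1.0):
        raise ValueError(f"aliquot must be in (0, 1], got {aliquot!r}")
    if pg_per_cell <= 0:
        raise ValueError("pg_per_cell must be > 0")
    if amount_pg < 0:
        raise ValueError("amount_pg must be >= 0")
    return math.ceil(amount_pg / (pg_per_cell * aliquot))
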