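"""Natural cubic spline basis and constrained internal-knot candidate enumeration.

The longitudinal intake submodel represents each child's trajectory as a
natural cubic spline of age: piecewise cubic, twice continuously
differentiable at the internal knots, and constrained to be linear at and
beyond the boundary knots.  With two boundary knots and K internal knots the
basis (including the intercept column) has K + 2 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = ["SplineSpec", "natural_cubic_basis", "candidate_knot_sets"]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout of a natural cubic spline.

    Parameters
    ----------
    boundary_knots : (low, high) ages in years.
    internal_knots : strictly increasing ages inside the boundary.
    include_intercept : whether the basis carries a constant column.
    """

    boundary_knots: tuple[float, float]
    internal_knots: tuple[float, ...]
    include_intercept: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        knots = (lo, *self.internal_knots, hi)
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError(
                f"knots must be strictly increasing with internal knots inside "
                f"the boundary, got boundary={self.boundary_knots} "
                f"internal={self.internal_knots}"
            )

    @property
    def all_knots(self) -> np.ndarray:
        return np.array([self.boundary_knots[0], *self.internal_knots,
                         self.boundary_knots[1]], dtype=float)

    @property
    def n_basis(self) -> int:
        return len(self.internal_knots) + 1 + int(self.include_intercept)


def natural_cubic_basis(ages, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``ages``.

    Returns an ``(n, K+2)`` design matrix (intercept column first when
    requested).  Evaluation outside the boundary knots extrapolates linearly,
    which is the defining property of the natural spline.

    The construction is the standard truncated-power one: with knots
    ``xi_1 < ... < xi_K`` (boundary knots included),

        d_k(t) = [ (t - xi_k)^3_+ - (t - xi_K)^3_+ ] / (xi_K - xi_k)

    and the basis is ``{1, t, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1}}``.
    """
    ages = np.asarray(ages, dtype=float)
    t = np.atleast_1d(ages)
    xi = spec.all_knots
    K = len(xi)

    def d(k: int) -> np.ndarray:
        num = np.maximum(t - xi[k], 0.0) ** 3 - np.maximum(t - xi[K - 1], 0.0) ** 3
        return num / (xi[K - 1] - xi[k])

    cols = [np.ones_like(t), t] if spec.include_intercept else [t]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    X = np.column_stack(cols)
    if ages.ndim == 0:
        return X[0]
    return X


def candidate_knot_sets(
    observation_ages: Sequence[float],
    n_knots: int = 3,
    min_records_outside: int = 2,
    min_gap: float = 1.0,
) -> list[tuple[float, ...]]:
    """Enumerate feasible internal-knot sets on the observed-age grid.

    A candidate is an ``n_knots``-subset of the distinct observation ages such
    that at least ``min_records_outside`` distinct ages lie strictly below the
    first knot and strictly above the last, and consecutive knots are at least
    ``min_gap`` years apart.  Returned in ascending lexicographic order.
    """
    grid = np.unique(np.asarray(list(observation_ages), dtype=float))
    if grid.size < n_knots + 2 * min_records_outside:
        raise ValueError(
            f"need at least {n_knots + 2 * min_records_outside} distinct "
            f"observation ages, got {grid.size}"
        )
    out: list[tuple[float, ...]] = []
    for triple in combinations(grid, n_knots):
        lo, hi = triple[0], triple[-1]
        if np.sum(grid < lo) < min_records_outside:
            continue
        if np.sum(grid > hi) < min_records_outside:
            continue
        gaps = np.diff(triple)
        # tolerance guards float grids like 0.25/0.5; gap test is >= min_gap
        if np.any(gaps < min_gap - 1e-9):
            continue
        out.append(tuple(float(k) for k in triple))
    if not out:
        raise ValueError(
            "no feasible internal-knot set: the boundary-record and "
            f"minimum-gap ({min_gap} y) constraints exclude every "
            f"{n_knots}-subset of the {grid.size}-age grid"
        )
    return sorted(out)
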