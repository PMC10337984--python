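"""Grid censuses of the adaptive dynamics and seeded random fixtures.

The censuses evaluate the strategy cube on an evenly spaced grid of interior
points (k/(n+1) for k = 1..n per axis; 9 points per axis puts the grid at
0.1, ..., 0.9).  Interior placement matters: on boundary faces several field
components vanish identically, so an endpoint-inclusive grid would drown the
sign census in structural zeros and start trajectories where dynamics have
already ceased.

Sign classification is exact: any component whose floating-point value falls
below ``zero_tol`` is re-evaluated in rational arithmetic to decide whether
it is a true zero or merely small; grid coordinates and payoff parameters
are carried as exact fractions for that purpose.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .counting import counting_field, counting_field_exact
from .engine import payoff_batch
from .game import GamePayoffs
from .memone import memone_field, memone_field_exact, sign_pattern
from .trajectories import IntegrationSettings, integrate_batch


@dataclass(frozen=True)
class GridSpec:
    """Evenly spaced interior grid: coordinates k/(n_per_axis+1), k=1..n."""

    n_per_axis: int = 9
    dims: int = 4

    def __post_init__(self) -> None:
        if self.dims not in (3, 4):
            raise ValueError("dims must be 3 (counting) or 4 (memory-one)")
        if self.n_per_axis < 1:
            raise ValueError("n_per_axis must be positive")

    @property
    def size(self) -> int:
        return self.n_per_axis**self.dims

    @property
    def axis(self) -> np.ndarray:
        n = self.n_per_axis
        return np.arange(1, n + 1) / (n + 1)

    @property
    def axis_exact(self) -> list[Fraction]:
        n = self.n_per_axis
        return [Fraction(k, n + 1) for k in range(1, n + 1)]

    def points(self) -> np.ndarray:
        """All grid points as an (size, dims) array, lexicographic order."""
        mesh = np.meshgrid(*([self.axis] * self.dims), indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def points_exact(self):
        """Iterator of grid points as tuples of Fractions (same order)."""
        return itertools.product(self.axis_exact, repeat=self.dims)


@dataclass
class CensusResult:
    """Per-point census records and the category tally."""

    records: pd.DataFrame
    tally: dict[str, int]
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False, float_format="%.17g")

    def tally_json(self) -> dict:
        return {"tally": self.tally, **self.meta}


def _exact_bc(game: GamePayoffs) -> tuple[Fraction, Fraction]:
    b, c = game.bc
    return Fraction(str(b)), Fraction(str(c))


def sign_census(
    grid: GridSpec, game: GamePayoffs, zero_tol: float = 1e-12
) -> CensusResult:
    """Sign pattern of the field at every grid point, with exact zeros.

    Components smaller than ``zero_tol`` in floating point are re-evaluated
    in exact rational arithmetic; '0' is assigned only to true zeros.
    """
    pts = grid.points()
    if grid.dims == 4:
        F = memone_field(pts, game)
        exact_eval = memone_field_exact
        cols = ["p_cc", "p_cd", "p_dc", "p_dd"]
    else:
        F = counting_field(pts, game)
        exact_eval = counting_field_exact
        cols = ["q2", "q1", "q0"]

    patterns = []
    near_zero_rows = np.flatnonzero((np.abs(F) < zero_tol).any(axis=1))
    exact_cache: dict[int, tuple] = {}
    if near_zero_rows.size:
        bF, cF = _exact_bc(game)
        exact_pts = grid.points_exact()
        want = set(near_zero_rows.tolist())
        for idx, pt in enumerate(exact_pts):
            if idx in want:
                exact_cache[idx] = exact_eval(pt, bF, cF)
                want.remove(idx)
                if not want:
                    break

    for idx, row in enumerate(F):
        if idx in exact_cache:
            ex = exact_cache[idx]
            pat = "".join(
                "0" if v == 0 else ("+" if v > 0 else "-") for v in ex
            )
        else:
            pat = sign_pattern(row, zero_tol)
        patterns.append(pat)

    df = pd.DataFrame(pts, columns=cols)
    for j, cname in enumerate(cols):
        df[f"d_{cname}"] = F[:, j]
    df["pattern"] = patterns
    tally = dict(Counter(patterns).most_common())
    return CensusResult(
        records=df,
        tally=tally,
        meta={"grid": grid.size, "dims": grid.dims, "b": game.benefit, "c": game.cost},
    )


def endpoint_census(
    grid: GridSpec,
    game: GamePayoffs,
    settings: IntegrationSettings | None = None,
) -> CensusResult:
    """Long-time limit class of the trajectory from every grid point."""
    space = "memone" if grid.dims == 4 else "counting"
    pts = grid.points()
    endpoints, classes = integrate_batch(pts, space, game, settings)
    cols = (
        ["p_cc", "p_cd", "p_dc", "p_dd"] if grid.dims == 4 else ["q2", "q1", "q0"]
    )
    df = pd.DataFrame(pts, columns=cols)
    for j, cname in enumerate(cols):
        df[f"end_{cname}"] = endpoints[:, j]
    df["endpoint_class"] = classes
    tally = dict(Counter(classes).most_common())
    return CensusResult(
        records=df,
        tally=tally,
        meta={"grid": grid.size, "dims": grid.dims, "b": game.benefit, "c": game.cost},
    )


def cooperative_region_census(
    grid: GridSpec,
    game: GamePayoffs,
    h: float = 1e-6,
    zero_tol: float = 1e-12,
) -> CensusResult:
    """Where the self-cooperation rate is locally increasing along the flow.

    At each 4-cube grid point, the directional derivative of C(p) =
    A(p, p)/(b - c) along the field is the inner product of the field with
    the central-difference gradient of C (step ``h``).  Points where the
    field itself vanishes identically are the census's 'critical' category.
    """
    if grid.dims != 4:
        raise ValueError("the cooperative-region census is defined on the 4-cube")
    b, c = game.bc
    pts = grid.points()
    F = memone_field(pts, game)

    grad = np.empty_like(pts)
    for i in range(4):
        hi = pts.copy()
        lo = pts.copy()
        hi[:, i] += h
        lo[:, i] -= h
        chi = payoff_batch(hi, hi, game) / (b - c)
        clo = payoff_batch(lo, lo, game) / (b - c)
        grad[:, i] = (chi - clo) / (2 * h)

    inner = np.sum(F * grad, axis=1)
    critical = (np.abs(F) < zero_tol).all(axis=1)
    labels = np.where(critical, "critical", np.where(inner > 0, "increasing", "decreasing"))

    df = pd.DataFrame(pts, columns=["p_cc", "p_cd", "p_dc", "p_dd"])
    df["coop_derivative"] = inner
    df["category"] = labels
    tally = dict(Counter(labels).most_common())
    return CensusResult(
        records=df,
        tally=tally,
        meta={"grid": grid.size, "dims": grid.dims, "b": game.benefit, "c": game.cost},
    )


def random_strategies(n: int, dims: int, seed: int) -> np.ndarray:
    """Seeded uniform i.i.d. strategies in the open cube, shape (n, dims)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    out = rng.random((n, dims))
    mask = out == 0.0
    while mask.any():  # open cube: resample the measure-zero exact zeros
        out[mask] = rng.random(int(mask.sum()))
        mask = out == 0.0
    return out
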