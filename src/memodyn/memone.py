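"""Closed-form adaptive dynamics on the 4-cube of memory-one strategies.

Adaptive dynamics moves a homogeneous resident population along the gradient
of the invader payoff, evaluated at the resident.  For the donation game the
gradient, multiplied by the positive factor ``(1 - p_CD + p_DC) * r(p)**2``,
is a polynomial vector field.  That rescaling changes only the timescale in
the interior, and the polynomial form is total on the closed cube, which is
what makes boundary analysis and grid censuses well defined.

Each component factors as ``f_i * (b * g_i + c * h_i)``; the i = 3, 4
auxiliary polynomials are argument-reversal substitutions of the i = 1, 2
ones, which makes the forward/backward orbit duality (sigma below) structural
rather than coincidental.

All polynomial evaluators use plain arithmetic only, so they work elementwise
on numpy arrays and exactly on ``fractions.Fraction`` inputs (the sign census
uses the latter to resolve zero components without floating-point ties).
"""

from __future__ import annotations

import enum

import numpy as np

from .engine import payoff_batch
from .errors import NotOnBoundaryError
from .game import GamePayoffs
from .strategies import as_memone_array


# ---------------------------------------------------------------------------
# Auxiliary polynomials of the rescaled field
# ---------------------------------------------------------------------------

def r_denominator(x, y, z, w):
    """The rescaling polynomial r; positive on the open 4-cube."""
    return (
        w * w * (-1 + 2 * x - y - z)
        + w * (2 - 2 * x * x + 2 * y * z)
        + (-1 + x) * (-1 + y + z - 2 * y * z + x * (-1 + y + z))
    )


def f1(y, z, w):
    return w * (2 * y * z + w - y * w - z * w)


def g1(x, y, z, w):
    return (
        -w + w * x - w * w * x + x * x + w * x * x + w * w * y - x * y
        - w * x * y - x * x * y + x * y * y + z - x * z + w * x * z
        - w * y * z + x * y * z - y * y * z - x * z * z + y * z * z
    )


def h1(x, y, z, w):
    return (
        -1 - w + w * w - w * x - w * w * x + w * x * x + y + x * y
        + w * x * y - x * y * y + w * w * z + x * z - w * x * z - x * x * z
        - 2 * y * z - w * y * z + x * y * z + y * y * z + x * z * z - y * z * z
    )


def f2(x, w):
    return -w * (1 - w + x) * (1 - x)


def g2(x, y, z, w):
    return (
        w + w * w * x - w * x * x - w * w * y - z - w * z - x * z
        + x * x * z + y * z + 2 * w * y * z + z * z - w * z * z - x * z * z
        - y * z * z + z * z * z
    )


def h2(x, y, z, w):
    return (
        1 + w - w * w + w * w * x - x * x - w * x * x - y + x * x * y
        + w * z - w * w * z + x * z + y * z - 2 * x * y * z - z * z
        + w * z * z + x * z * z + y * z * z - z * z * z
    )


# The i = 3, 4 functions are substitutions of the i = 1, 2 ones.  All three
# of g3, h3, g4, h4 share the argument pattern (1-w, 1-z, 1-y, 1-x): the
# components and the outcome axes are both reversed.

def f3(x, w):
    return f2(1 - w, 1 - x)


def g3(x, y, z, w):
    return g2(1 - w, 1 - z, 1 - y, 1 - x)


def h3(x, y, z, w):
    return h2(1 - w, 1 - z, 1 - y, 1 - x)


def f4(x, y, z):
    return f1(1 - z, 1 - y, 1 - x)


def g4(x, y, z, w):
    return g1(1 - w, 1 - z, 1 - y, 1 - x)


def h4(x, y, z, w):
    return h1(1 - w, 1 - z, 1 - y, 1 - x)


def memone_field(p, game: GamePayoffs) -> np.ndarray:
    """Rescaled adaptive-dynamics field on [0, 1]^4 for the donation game.

    Accepts a single strategy or a stack of shape (..., 4) and returns the
    matching shape.  Equals the raw payoff gradient times the positive factor
    ``(1 - p_CD + p_DC) * r(p)**2`` in the interior.
    """
    b, c = game.bc
    arr = p if isinstance(p, np.ndarray) else as_memone_array(p)
    arr = np.asarray(arr, dtype=float)
    x, y, z, w = arr[..., 0], arr[..., 1], arr[..., 2], arr[..., 3]
    out = np.empty_like(arr)
    out[..., 0] = f1(y, z, w) * (b * g1(x, y, z, w) + c * h1(x, y, z, w))
    out[..., 1] = f2(x, w) * (b * g2(x, y, z, w) + c * h2(x, y, z, w))
    out[..., 2] = f3(x, w) * (b * g3(x, y, z, w) + c * h3(x, y, z, w))
    out[..., 3] = f4(x, y, z) * (b * g4(x, y, z, w) + c * h4(x, y, z, w))
    return out


def memone_field_exact(p, b, c):
    """Field components for exact (e.g. Fraction) coordinates and payoffs."""
    x, y, z, w = p
    return (
        f1(y, z, w) * (b * g1(x, y, z, w) + c * h1(x, y, z, w)),
        f2(x, w) * (b * g2(x, y, z, w) + c * h2(x, y, z, w)),
        f3(x, w) * (b * g3(x, y, z, w) + c * h3(x, y, z, w)),
        f4(x, y, z) * (b * g4(x, y, z, w) + c * h4(x, y, z, w)),
    )


def rescale_factor(p) -> float:
    """The positive factor relating the raw gradient to the polynomial field."""
    arr = np.asarray(as_memone_array(p) if not isinstance(p, np.ndarray) else p, float)
    x, y, z, w = arr[..., 0], arr[..., 1], arr[..., 2], arr[..., 3]
    return (1 - y + z) * r_denominator(x, y, z, w) ** 2


# ---------------------------------------------------------------------------
# Sign patterns
# ---------------------------------------------------------------------------

def sign_pattern(field_value, zero_tol: float = 1e-12) -> str:
    """One symbol per component: '+', '-', or '0' for |value| < zero_tol."""
    return "".join(
        "0" if abs(v) < zero_tol else ("+" if v > 0 else "-") for v in field_value
    )


# ---------------------------------------------------------------------------
# Duality
# ---------------------------------------------------------------------------

def sigma(p):
    """The orbit-pairing reflection (a, b, c, d) -> (1-d, 1-c, 1-b, 1-a).

    An involution of the cube; its fixed plane is p_CC + p_DD = 1,
    p_CD + p_DC = 1.  It maps forward-time orbits to backward-time orbits in
    any game with equal gains from switching.
    """
    arr = np.asarray(p if isinstance(p, np.ndarray) else as_memone_array(p), float)
    return 1.0 - arr[..., ::-1]


def duality_check(p, game: GamePayoffs) -> float:
    """Max-norm residual of the orbit-pairing identity at ``p``.

    The field at sigma(p) equals the component-reversed field at p (the
    reflection's derivative is minus the reversal, so this is exactly the
    time-reversal conjugacy); returns the max-norm of the difference,
    which is structurally ~0 because the i = 3, 4 auxiliary polynomials
    are the corresponding substitutions of the i = 1, 2 ones.
    """
    F_p = memone_field(p, game)
    F_sp = memone_field(sigma(p), game)
    return float(np.max(np.abs(F_sp - F_p[..., ::-1])))


# ---------------------------------------------------------------------------
# Counting subspace
# ---------------------------------------------------------------------------

def counting_distance_derivative(p, game: GamePayoffs) -> float:
    """Time derivative of d = p_CD - p_DC under the rescaled dynamics.

    Closed form: f2(p_CC, p_DD) * (b - c) * (1 - p_CD + p_DC)
    * (p_CD - p_DC) * (p_CC - p_CD - p_DC + p_DD).  Exactly zero on the
    counting subspace p_CD = p_DC, which is therefore invariant; off the
    subspace, d shrinks iff p_CC + p_DD > p_CD + p_DC.
    """
    b, c = game.bc
    x, y, z, w = as_memone_array(p)
    return float(f2(x, w) * (b - c) * (1 - y + z) * (y - z) * (x - y - z + w))


# ---------------------------------------------------------------------------
# Critical points and equalizers
# ---------------------------------------------------------------------------

def critical_plane_point(p_cd: float, p_dc: float, game: GamePayoffs):
    """Interior critical point with the given (p_CD, p_DC), if one exists.

    The interior critical set is the plane  b(p_CC - p_CD) = c(1 - p_CC +
    p_DC),  p_CC + p_DD = p_CD + p_DC; solving for the remaining coordinates
    gives  p_CC = (c + b p_CD + c p_DC)/(b + c)  and  p_DD = (c(p_CD - 1) +
    b p_DC)/(b + c).  Returns None when either falls outside (0, 1).
    """
    b, c = game.bc
    if not (0 < p_cd < 1 and 0 < p_dc < 1):
        return None
    p_cc = (c + b * p_cd + c * p_dc) / (b + c)
    p_dd = (c * (p_cd - 1) + b * p_dc) / (b + c)
    if not (0 < p_cc < 1 and 0 < p_dd < 1):
        return None
    return np.array([p_cc, p_cd, p_dc, p_dd])


def is_critical(p, game: GamePayoffs, tol: float = 1e-9) -> bool:
    """Whether an interior point satisfies the critical-plane conditions."""
    b, c = game.bc
    x, y, z, w = as_memone_array(p)
    return bool(
        abs(b * (x - y) - c * (1 - x + z)) < tol and abs(x + w - y - z) < tol
    )


def is_equalizer(
    p,
    game: GamePayoffs,
    n_opponents: int = 100,
    tol: float = 1e-8,
    seed: int = 0,
) -> bool:
    """Whether ``p`` forces every opponent to the same payoff.

    Samples random opponents and checks that the payoff range of A(p', p)
    stays below ``tol``.  In the interior this coincides with the critical
    points of the adaptive dynamics.
    """
    pa = as_memone_array(p)
    rng = np.random.default_rng(seed)
    opponents = rng.random((n_opponents, 4))
    vals = payoff_batch(opponents, np.broadcast_to(pa, opponents.shape), game)
    return float(np.ptp(vals)) < tol


# ---------------------------------------------------------------------------
# Boundary saturation and cooperative Nash set
# ---------------------------------------------------------------------------

class SaturationStatus(enum.Enum):
    STRICTLY_SATURATED = "strictly_saturated"
    SATURATED = "saturated"
    UNSATURATED = "unsaturated"
    DEGENERATE = "degenerate"

    @property
    def is_saturated(self) -> bool:
        return self in (SaturationStatus.SATURATED, SaturationStatus.STRICTLY_SATURATED)


def _saturation_pcc1_fraction(p_cd, p_dc, p_dd):
    """Numerator and denominator of the p_CC = 1 saturation quotient."""
    y, z, w = p_cd, p_dc, p_dd
    num = (1 - y) * (1 - (1 - z) * (y - w) - (z - w) ** 2)
    den = (
        (1 - y) ** 2 * (1 - z)
        + z * w * (2 - w)
        + (1 - y) * (1 - z) * (z + w)
    )
    return num, den


def saturation_pCC1(p_cd: float, p_dc: float, p_dd: float, game: GamePayoffs) -> SaturationStatus:
    """Saturation of a point on the fully-cooperative face p_CC = 1.

    On that face the tangential field components vanish and the point is
    saturated iff the outward component is nonnegative, which reduces to a
    quotient of two polynomials in (p_CD, p_DC, p_DD) exceeding c/b.  The
    comparison is made in fraction-free cross-multiplied form; the 0/0 locus
    (e.g. the tit-for-tat tail) is reported as DEGENERATE.
    """
    b, c = game.bc
    num, den = _saturation_pcc1_fraction(p_cd, p_dc, p_dd)
    if num == 0.0 and den == 0.0:
        return SaturationStatus.DEGENERATE
    s = b * num - c * den
    if s > 0:
        return SaturationStatus.STRICTLY_SATURATED
    if s == 0:
        return SaturationStatus.SATURATED
    return SaturationStatus.UNSATURATED


def is_cooperative_nash(p_cd: float, p_dc: float, p_dd: float, game: GamePayoffs) -> bool:
    """Whether (1, p_CD, p_DC, p_DD) is a cooperative Nash equilibrium.

    The known characterisation:  (1 - p_CD)/p_DD >= c/(b - c)  and
    (1 - p_CD)/p_DC >= c/b,  evaluated here cross-multiplied so the face
    coordinates may be zero.  The Nash set is a strict subset of the
    saturated set: a point can be a local payoff maximum against itself
    without being a global one.
    """
    b, c = game.bc
    return bool(
        (1 - p_cd) * (b - c) >= c * p_dd and (1 - p_cd) * b >= c * p_dc
    )


def boundary_saturation(p, game: GamePayoffs) -> SaturationStatus:
    """Saturation of a point on any boundary face, via the polynomial field.

    The point must have exactly one coordinate in {0, 1}.  Saturated means
    the field does not point into the interior: the component normal to the
    face is <= 0 on a 0-face and >= 0 on a 1-face.
    """
    arr = as_memone_array(p)
    extreme = (arr == 0.0) | (arr == 1.0)
    if extreme.sum() != 1:
        raise NotOnBoundaryError(
            f"expected exactly one coordinate in {{0, 1}}, got {arr}"
        )
    i = int(np.argmax(extreme))
    comp = memone_field(arr, game)[i]
    outward = comp if arr[i] == 1.0 else -comp
    if outward > 0:
        return SaturationStatus.STRICTLY_SATURATED
    if outward == 0:
        return SaturationStatus.SATURATED
    return SaturationStatus.UNSATURATED
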