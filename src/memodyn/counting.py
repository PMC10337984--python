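"""Closed-form adaptive dynamics on the 3-cube of counting strategies.

Counting strategies (q2, q1, q0) react only to the number of cooperators in
the previous round.  Their adaptive dynamics is taken in [0, 1]^3 with the
payoff gradient computed there; within the counting subspace of the
memory-one cube the middle component of the raw gradient differs by a factor
of 2, so this system is a space in its own right, not a restriction.

The gradient multiplied by r(q)**2 (with r the 3-variable rescaling
polynomial, nonzero on the open cube) is again polynomial and total on the
closed cube.  Interior critical points form the straight line segment
(t + c/(b+c), t, t - c/(b+c)) for t in (c/(b+c), b/(b+c)); its direction is
neutral for the linearisation, and stability is read off the two transverse
eigenvalues of the analytic Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NotOnBoundaryError, OutOfRangeError
from .game import GamePayoffs
from .memone import SaturationStatus
from .strategies import as_counting_array


# ---------------------------------------------------------------------------
# Auxiliary polynomials; (x, y, z) = (q2, q1, q0)
# ---------------------------------------------------------------------------

def r_counting(x, y, z):
    """3-variable rescaling polynomial; nonzero on the open cube."""
    return (
        (-1 + x) * (-1 + y + (1 - 2 * y) * (y - x))
        + (2 - 2 * x * x + 2 * y * y) * z
        + (-1 + 2 * x - 2 * y) * z * z
    )


def cf2(y, z):
    return -z * (2 * y * (y - z) + z)


def cg2(x, y, z):
    return (
        -x * x - y + 2 * x * y + x * x * y - x * y * y + z - x * z
        - x * x * z + y * y * z + x * z * z - y * z * z
    )


def ch2(x, y, z):
    return (
        1 - y - 2 * x * y + x * x * y + 2 * y * y - x * y * y + z + x * z
        - x * x * z + y * y * z - z * z + x * z * z - y * z * z
    )


def cf1(x, z):
    return -2 * z * (-1 + x) * (1 + x - z)


def cg1(x, y, z):
    return (
        y + x * y - x * x * y - 2 * y * y + x * y * y - z + x * x * z
        + y * z - y * y * z - x * z * z + y * z * z
    )


def ch1(x, y, z):
    return (
        -1 + x * x + y - x * y - x * x * y + x * y * y - z + x * x * z
        - y * z - y * y * z + z * z - x * z * z + y * z * z
    )


def cf0(x, y):
    return cf2(1 - y, 1 - x)


def cg0(x, y, z):
    return cg2(1 - z, 1 - y, 1 - x)


def ch0(x, y, z):
    return ch2(1 - z, 1 - y, 1 - x)


def counting_field(q, game: GamePayoffs) -> np.ndarray:
    """Rescaled adaptive-dynamics field on [0, 1]^3 for the donation game.

    Accepts a single strategy or a stack (..., 3); equals the raw gradient
    times r(q)**2 in the interior and is total on the closed cube.
    """
    b, c = game.bc
    arr = np.asarray(q, dtype=float) if isinstance(q, np.ndarray) else as_counting_array(q)
    x, y, z = arr[..., 0], arr[..., 1], arr[..., 2]
    out = np.empty_like(arr, dtype=float)
    out[..., 0] = cf2(y, z) * (b * cg2(x, y, z) + c * ch2(x, y, z))
    out[..., 1] = cf1(x, z) * (b * cg1(x, y, z) + c * ch1(x, y, z))
    out[..., 2] = cf0(x, y) * (b * cg0(x, y, z) + c * ch0(x, y, z))
    return out


def counting_field_exact(q, b, c):
    """Field components for exact (e.g. Fraction) coordinates and payoffs."""
    x, y, z = q
    return (
        cf2(y, z) * (b * cg2(x, y, z) + c * ch2(x, y, z)),
        cf1(x, z) * (b * cg1(x, y, z) + c * ch1(x, y, z)),
        cf0(x, y) * (b * cg0(x, y, z) + c * ch0(x, y, z)),
    )


def sigma_counting(q):
    """Orbit-pairing rotation (q2, q1, q0) -> (1-q0, 1-q1, 1-q2)."""
    arr = np.asarray(q, float) if isinstance(q, np.ndarray) else as_counting_array(q)
    return 1.0 - arr[..., ::-1]


# ---------------------------------------------------------------------------
# Analytic Jacobian (product rule over hand-coded polynomial partials)
# ---------------------------------------------------------------------------

def _d_cf2(y, z):
    return (-4 * y * z + 2 * z * z, -2 * y * y + 4 * y * z - 2 * z)


def _d_cf1(x, z):
    return (-2 * z * (2 * x - z), -2 * (x - 1) * (1 + x - 2 * z))


def _d_cg2(x, y, z):
    return (
        -2 * x + 2 * y + 2 * x * y - y * y - z - 2 * x * z + z * z,
        -1 + 2 * x + x * x - 2 * x * y + 2 * y * z - z * z,
        1 - x - x * x + y * y + 2 * x * z - 2 * y * z,
    )


def _d_ch2(x, y, z):
    return (
        -2 * y + 2 * x * y - y * y + z - 2 * x * z + z * z,
        -1 - 2 * x + x * x + 4 * y - 2 * x * y + 2 * y * z - z * z,
        1 + x - x * x + y * y - 2 * z + 2 * x * z - 2 * y * z,
    )


def _d_cg1(x, y, z):
    return (
        y - 2 * x * y + y * y + 2 * x * z - z * z,
        1 + x - x * x - 4 * y + 2 * x * y + z - 2 * y * z + z * z,
        -1 + x * x + y - y * y - 2 * x * z + 2 * y * z,
    )


def _d_ch1(x, y, z):
    return (
        2 * x - y - 2 * x * y + y * y + 2 * x * z - z * z,
        1 - x - x * x + 2 * x * y - z - 2 * y * z + z * z,
        -1 + x * x - y - y * y + 2 * z - 2 * x * z + 2 * y * z,
    )


def counting_jacobian(q, game: GamePayoffs) -> np.ndarray:
    """3x3 Jacobian of the rescaled counting field, from analytic partials.

    Assembled by the product rule from hand-coded partial derivatives of the
    auxiliary polynomials; the third row uses the chain rule through the
    argument-reversal substitutions.  Verified against finite differences in
    the test suite.
    """
    b, c = game.bc
    x, y, z = as_counting_array(q)
    J = np.empty((3, 3))

    # row 0: d/dq of cf2(y, z) * (b cg2 + c ch2)(x, y, z)
    A = b * cg2(x, y, z) + c * ch2(x, y, z)
    dg = _d_cg2(x, y, z)
    dh = _d_ch2(x, y, z)
    df_y, df_z = _d_cf2(y, z)
    f = cf2(y, z)
    J[0, 0] = f * (b * dg[0] + c * dh[0])
    J[0, 1] = df_y * A + f * (b * dg[1] + c * dh[1])
    J[0, 2] = df_z * A + f * (b * dg[2] + c * dh[2])

    # row 1: d/dq of cf1(x, z) * (b cg1 + c ch1)(x, y, z)
    A = b * cg1(x, y, z) + c * ch1(x, y, z)
    dg = _d_cg1(x, y, z)
    dh = _d_ch1(x, y, z)
    df_x, df_z = _d_cf1(x, z)
    f = cf1(x, z)
    J[1, 0] = df_x * A + f * (b * dg[0] + c * dh[0])
    J[1, 1] = f * (b * dg[1] + c * dh[1])
    J[1, 2] = df_z * A + f * (b * dg[2] + c * dh[2])

    # row 2: cf0(x, y) = cf2(1-y, 1-x); (cg0, ch0)(x, y, z) = (cg2, ch2)(1-z, 1-y, 1-x)
    u, v, s = 1 - z, 1 - y, 1 - x  # substituted arguments of cg2/ch2
    A = b * cg2(u, v, s) + c * ch2(u, v, s)
    dg = _d_cg2(u, v, s)
    dh = _d_ch2(u, v, s)
    df_y, df_z = _d_cf2(1 - y, 1 - x)  # partials wrt its own two slots
    f = cf2(1 - y, 1 - x)
    # d/dx: cf2 slot-2 arg is 1-x (deriv -df_z); cg2/ch2 slot-3 arg is 1-x
    J[2, 0] = -df_z * A + f * (b * dg[2] + c * dh[2]) * (-1)
    # d/dy: cf2 slot-1 arg is 1-y; cg2/ch2 slot-2 arg is 1-y
    J[2, 1] = -df_y * A + f * (b * dg[1] + c * dh[1]) * (-1)
    # d/dz: cg2/ch2 slot-1 arg is 1-z
    J[2, 2] = f * (b * dg[0] + c * dh[0]) * (-1)
    return J


# ---------------------------------------------------------------------------
# The interior critical line and its classification
# ---------------------------------------------------------------------------

def critical_line(t: float, game: GamePayoffs) -> np.ndarray:
    """Point (t + c/(b+c), t, t - c/(b+c)) of the interior critical line."""
    b, c = game.bc
    lo, hi = c / (b + c), b / (b + c)
    if not (lo < t < hi):
        raise OutOfRangeError(
            f"critical-line parameter t={t} outside the open interval ({lo}, {hi})"
        )
    d = c / (b + c)
    return np.array([t + d, t, t - d])


def critical_line_endpoints(game: GamePayoffs) -> tuple[np.ndarray, np.ndarray]:
    """Closure endpoints (2c/(b+c), c/(b+c), 0) and (1, b/(b+c), (b-c)/(b+c))."""
    b, c = game.bc
    return (
        np.array([2 * c / (b + c), c / (b + c), 0.0]),
        np.array([1.0, b / (b + c), (b - c) / (b + c)]),
    )


def critical_line_length(game: GamePayoffs) -> float:
    """sqrt(3) * (b - c) / (b + c): cube diagonal as c -> 0, zero as c -> b."""
    b, c = game.bc
    return float(np.sqrt(3.0) * (b - c) / (b + c))


@dataclass(frozen=True)
class CriticalPointClass:
    """Eigenvalues of the linearisation at a critical-line point and a label.

    One eigenvalue is structurally zero (the direction along the line of
    critical points is neutral); ``label`` classifies the two transverse
    eigenvalues: source / spiral source / sink / spiral sink / saddle, or
    non-hyperbolic when a transverse real part vanishes at tolerance.
    """

    eigenvalues: tuple[complex, complex, complex]
    label: str


def classify_critical(
    t: float, game: GamePayoffs, tol: float = 1e-10
) -> CriticalPointClass:
    """Stability type of the interior critical point at line parameter ``t``."""
    q = critical_line(t, game)
    eig = np.linalg.eigvals(counting_jacobian(q, game))
    order = np.argsort(np.abs(eig))
    neutral, trans = eig[order[0]], eig[order[1:]]
    re = np.real(trans)
    im = np.imag(trans)
    spiral = bool(np.any(np.abs(im) > tol))
    if np.any(np.abs(re) < tol) or abs(neutral) > 1e-6:
        label = "non-hyperbolic"
    elif np.all(re > 0):
        label = "spiral source" if spiral else "source"
    elif np.all(re < 0):
        label = "spiral sink" if spiral else "sink"
    else:
        label = "saddle"
    return CriticalPointClass(eigenvalues=tuple(eig[order]), label=label)


# ---------------------------------------------------------------------------
# Boundary critical points and saturation
# ---------------------------------------------------------------------------

_FACES = {"q2=1", "q0=0"}


def _normal_component(face: str, a: float, b_: float, game: GamePayoffs) -> float:
    """Field component normal to the face at in-face coordinates (a, b_).

    For face q2=1 the in-face coordinates are (q1, q0); for q0=0 they are
    (q2, q1).  The tangential components vanish identically on both faces.
    """
    if face == "q2=1":
        return float(counting_field(np.array([1.0, a, b_]), game)[0])
    return float(counting_field(np.array([a, b_, 0.0]), game)[2])


def boundary_critical_counting(
    face: str, game: GamePayoffs, resolution: int = 200, include_edge: bool = True
) -> np.ndarray:
    """Grid-resolved critical curve on a boundary face, as (N, 3) points.

    On the faces q2=1 and q0=0 the two tangential field components vanish
    identically, so boundary critical points are the zero set of the normal
    component.  Zeros are located by sign-change bisection along grid lines
    in both in-face directions.  The shared edge q0=0, q2=1 is critical in
    its entirety and is appended when ``include_edge``.
    """
    if face not in _FACES:
        raise ValueError(f"face must be one of {_FACES}, got {face!r}")
    ticks = np.linspace(0.0, 1.0, resolution)
    pts: list[tuple[float, float]] = []

    def scan(fixed: float, along_second: bool) -> None:
        coords = [
            (fixed, s) if along_second else (s, fixed) for s in ticks
        ]
        vals = [_normal_component(face, a, b_, game) for a, b_ in coords]
        for i in range(len(ticks) - 1):
            v0, v1 = vals[i], vals[i + 1]
            if v0 == 0.0:
                pts.append(coords[i])
            if v0 * v1 < 0:
                lo, hi = ticks[i], ticks[i + 1]
                flo = v0
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    fm = _normal_component(
                        face,
                        fixed if along_second else mid,
                        mid if along_second else fixed,
                        game,
                    )
                    if fm == 0.0:
                        lo = hi = mid
                        break
                    if (fm > 0) == (flo > 0):
                        lo, flo = mid, fm
                    else:
                        hi = mid
                root = 0.5 * (lo + hi)
                pts.append((fixed, root) if along_second else (root, fixed))
        if vals[-1] == 0.0:
            pts.append(coords[-1])

    for tick in ticks:
        scan(tick, along_second=True)
        scan(tick, along_second=False)

    def lift(a: float, b_: float) -> tuple[float, float, float]:
        return (1.0, a, b_) if face == "q2=1" else (a, b_, 0.0)

    out = {lift(a, b_) for a, b_ in pts}
    if include_edge:
        out.update((1.0, s, 0.0) for s in ticks)
    if not out:
        return np.empty((0, 3))
    return np.array(sorted(out))


def counting_boundary_saturation(q, game: GamePayoffs) -> SaturationStatus:
    """Saturation of a counting strategy on a boundary face of the 3-cube.

    Every point with q1 = 0 is saturated and every point with q1 = 1 is
    unsaturated; on q2 = 1 and q0 = 0 the status follows the sign of the
    normal field component.
    """
    arr = as_counting_array(q)
    extreme = (arr == 0.0) | (arr == 1.0)
    if extreme.sum() != 1:
        raise NotOnBoundaryError(
            f"expected exactly one coordinate in {{0, 1}}, got {arr}"
        )
    i = int(np.argmax(extreme))
    comp = counting_field(arr, game)[i]
    outward = comp if arr[i] == 1.0 else -comp
    if outward > 0:
        return SaturationStatus.STRICTLY_SATURATED
    if outward == 0:
        return SaturationStatus.SATURATED
    return SaturationStatus.UNSATURATED
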