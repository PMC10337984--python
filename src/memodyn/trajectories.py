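"""Numerical integration of the adaptive dynamics with endpoint classing.

Dynamics are integrated under the rescaled polynomial fields (identical
orbits to the raw gradient flow, up to timescale) and cease at the boundary
of the strategy cube.  A trajectory's long-time limit is classified as

* ``full_cooperation``  -- it reached the face p_CC = 1 (resp. q2 = 1),
* ``full_defection``    -- it reached the face p_DD = 0 (resp. q0 = 0),
* ``other_boundary``    -- it reached any other part of the boundary,
* ``interior_critical`` -- it converged in the open cube to a point of the
  critical plane / line (an equalizer),
* ``undecided``         -- the time cap elapsed first.

When several face conditions hold simultaneously (edges and corners),
full cooperation is checked before full defection; this tie-break is a
convention of this package.

The integrator is an adaptive Dormand-Prince RK45 with per-trajectory step
control, vectorised over a batch of starting points so the grid censuses
stay cheap; a single trajectory is just a batch of one with its path
recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .counting import counting_field
from .engine import payoff_batch
from .game import GamePayoffs
from .memone import is_critical, memone_field

ENDPOINT_CLASSES = (
    "full_cooperation",
    "full_defection",
    "other_boundary",
    "interior_critical",
    "undecided",
)


@dataclass(frozen=True)
class IntegrationSettings:
    """Tolerances and caps for trajectory integration.

    boundary_tol: distance to a face at which dynamics are declared to have
      ceased.  conv_tol: field max-norm below which, sustained for ``dwell``
      accepted steps, the trajectory counts as converged in the interior.
      t_max: cap for the explicit batch phase, in rescaled time units.
      t_max_stiff: extended cap for the implicit finishing phase applied to
      trajectories still undecided at t_max (orbits crawling along the
      critical line toward one of its closure endpoints have transverse
      rates as small as ~1e-4 and need horizons far beyond t_max).
      rtol/atol: local error control.  critical_tol: residual tolerance for
      the interior-critical test at the endpoint.
    """

    boundary_tol: float = 1e-6
    conv_tol: float = 1e-10
    dwell: int = 50
    t_max: float = 1e4
    t_max_stiff: float = 1e8
    rtol: float = 1e-8
    atol: float = 1e-10
    critical_tol: float = 1e-5
    h_max: float = 100.0

    def halved(self) -> "IntegrationSettings":
        """Same settings with all tolerances halved (robustness guard)."""
        return replace(
            self,
            boundary_tol=self.boundary_tol / 2,
            conv_tol=self.conv_tol / 2,
            rtol=self.rtol / 2,
            atol=self.atol / 2,
            critical_tol=self.critical_tol / 2,
        )


@dataclass
class TrajectoryOutcome:
    """Integrated path, its endpoint, and the endpoint class."""

    times: np.ndarray
    path: np.ndarray  # (n_samples, dims)
    endpoint: np.ndarray
    endpoint_class: str
    space: str
    coop_series: np.ndarray | None = field(default=None, repr=False)


# Dormand-Prince RK45 tableau
_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = [
    np.array([]),
    np.array([1 / 5]),
    np.array([3 / 40, 9 / 40]),
    np.array([44 / 45, -56 / 15, 32 / 9]),
    np.array([19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729]),
    np.array([9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656]),
    np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84]),
]
_DP_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_DP_B4 = np.array(
    [5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200, 187 / 2100, 1 / 40]
)


def _field_fn(space: str, game: GamePayoffs):
    if space == "memone":
        return lambda Y: memone_field(Y, game)
    if space == "counting":
        return lambda Y: counting_field(Y, game)
    raise ValueError(f"space must be 'memone' or 'counting', got {space!r}")


def integrate_batch(
    starts: np.ndarray,
    space: str,
    game: GamePayoffs,
    settings: IntegrationSettings | None = None,
    record_paths: bool = False,
):
    """Integrate many trajectories at once; returns (endpoints, classes[, paths]).

    ``starts`` is (N, dims).  Classes follow ENDPOINT_CLASSES.  Paths (one
    list of (t, y) samples per trajectory) are recorded only on request.
    """
    st = settings or IntegrationSettings()
    F = _field_fn(space, game)
    Y = np.array(starts, dtype=float)
    n, dims = Y.shape
    t = np.zeros(n)
    h = np.full(n, 1e-2)
    done = np.zeros(n, dtype=bool)
    hit_boundary = np.zeros(n, dtype=bool)
    converged = np.zeros(n, dtype=bool)
    dwell_count = np.zeros(n, dtype=int)
    paths = [[(0.0, Y[i].copy())] for i in range(n)] if record_paths else None

    # Starts on (or within tolerance of) the boundary cease at t = 0 unless
    # the field points strictly into the cube at every extreme coordinate,
    # in which case the orbit immediately re-enters the interior and is
    # integrated like any other.
    # Tangential components vanish identically on the invariant faces, so the
    # inward test is made a small nudge inside the cube: the orbit of an
    # unsaturated boundary point enters the interior immediately.
    lo0 = Y <= st.boundary_tol
    hi0 = Y >= 1.0 - st.boundary_tol
    on_boundary0 = (lo0 | hi0).any(axis=1)
    if on_boundary0.any():
        eps = 2.0 * st.boundary_tol
        Yn = np.clip(Y, eps, 1.0 - eps)
        Fn = F(Yn)
        inward = on_boundary0 & np.all(
            (~lo0 | (Fn > 0)) & (~hi0 | (Fn < 0)), axis=1
        )
        Y[inward] = Yn[inward]
        initial_boundary = on_boundary0 & ~inward
        done |= initial_boundary
        hit_boundary |= initial_boundary

    max_iter = 1_000_000
    for _ in range(max_iter):
        if done.all():
            break
        act = np.flatnonzero(~done)
        y = Y[act]
        ha = np.minimum(np.minimum(h[act], st.h_max), st.t_max - t[act])
        k = np.empty((7, len(act), dims))
        k[0] = F(y)
        for s in range(1, 7):
            incr = np.tensordot(_DP_A[s], k[:s], axes=(0, 0))
            k[s] = F(y + ha[:, None] * incr)
        y5 = y + ha[:, None] * np.tensordot(_DP_B5, k, axes=(0, 0))
        err_vec = ha[:, None] * np.tensordot(_DP_B5 - _DP_B4, k, axes=(0, 0))
        scale = st.atol + st.rtol * np.maximum(np.abs(y), np.abs(y5))
        err = np.sqrt(np.mean((err_vec / scale) ** 2, axis=1))
        accept = err <= 1.0

        # step-size update (PI-free basic controller, clipped)
        with np.errstate(divide="ignore"):
            fac = np.where(err > 0, 0.9 * err ** -0.2, 5.0)
        h[act] = ha * np.clip(fac, 0.2, 5.0)

        # Localize boundary contact: a long accepted step may hop across the
        # contact band even though the true orbit only grazes the face and
        # returns (spirals near the critical plane do).  Such steps are
        # re-taken with a halved step until contact happens within a short
        # step, which pins the first true crossing.
        crossing = accept & (
            (y5 <= st.boundary_tol) | (y5 >= 1.0 - st.boundary_tol)
        ).any(axis=1)
        retry = crossing & (ha > 1e-4)
        if retry.any():
            h[act[retry]] = ha[retry] / 2.0
            accept = accept & ~retry

        if not accept.any():
            continue
        ai = act[accept]
        ya = y5[accept]
        t[ai] += ha[accept]
        Y[ai] = ya
        if record_paths:
            for j, i in enumerate(ai):
                paths[i].append((t[i], ya[j].copy()))

        # boundary contact: dynamics cease
        outside = (ya <= st.boundary_tol) | (ya >= 1.0 - st.boundary_tol)
        contact = outside.any(axis=1)
        if contact.any():
            ci = ai[contact]
            Y[ci] = np.clip(Y[ci], 0.0, 1.0)
            done[ci] = True
            hit_boundary[ci] = True

        # interior convergence: small field norm sustained for `dwell` steps
        live = ai[~contact]
        if live.size:
            norms = np.max(np.abs(F(Y[live])), axis=1)
            small = norms < st.conv_tol
            dwell_count[live[small]] += 1
            dwell_count[live[~small]] = 0
            conv = live[dwell_count[live] >= st.dwell]
            done[conv] = True
            converged[conv] = True
            timeout = live[t[live] >= st.t_max]
            done[timeout] = True

    # Finish stragglers implicitly: orbits still moving at t_max are usually
    # crawling along the near-critical slow manifold, where the explicit
    # stepper is stability-limited by the fast transverse eigenvalue.  LSODA
    # switches to BDF there and clears the remaining horizon cheaply.
    if st.t_max_stiff <= st.t_max:
        stragglers = np.empty(0, dtype=int)  # plain time-cap semantics
    else:
        stragglers = np.flatnonzero(~hit_boundary & ~converged & (t >= st.t_max))
    for i in stragglers:
        if np.max(np.abs(F(Y[i][None, :]))) < st.conv_tol:
            converged[i] = True
            continue
        y_end, t_end, kind = _finish_stiff(Y[i], F, st, dims)
        Y[i] = y_end
        if record_paths:
            paths[i].append((t[i] + t_end, y_end.copy()))
        if kind == "boundary":
            hit_boundary[i] = True
        elif kind == "converged":
            converged[i] = True

    classes = np.array(
        [
            _classify_point(Y[i], space, game, st, hit_boundary[i], converged[i])
            for i in range(n)
        ]
    )
    if record_paths:
        return Y, classes, paths
    return Y, classes


def _finish_stiff(y0, F, st: IntegrationSettings, dims: int):
    """Integrate one slow trajectory with LSODA until boundary or convergence."""
    from scipy.integrate import solve_ivp

    def rhs(_t, y):
        return F(y.reshape(1, dims)).ravel()

    def boundary_event(_t, y):
        return float(np.min(np.minimum(y - st.boundary_tol, 1.0 - st.boundary_tol - y)))

    boundary_event.terminal = True

    def conv_event(_t, y):
        return float(np.max(np.abs(rhs(_t, y)))) - st.conv_tol

    conv_event.terminal = True

    sol = solve_ivp(
        rhs,
        (0.0, st.t_max_stiff),
        np.asarray(y0, float),
        method="LSODA",
        events=[boundary_event, conv_event],
        rtol=st.rtol,
        atol=st.atol,
    )
    y_end = np.clip(sol.y[:, -1], 0.0, 1.0)
    if sol.t_events[0].size:
        return y_end, float(sol.t[-1]), "boundary"
    if sol.t_events[1].size or np.max(np.abs(rhs(0.0, y_end))) < st.conv_tol:
        return y_end, float(sol.t[-1]), "converged"
    return y_end, float(sol.t[-1]), "timeout"


def _q_is_critical(q: np.ndarray, game: GamePayoffs, tol: float) -> bool:
    """Whether a counting strategy lies on the interior critical line."""
    b, c = game.bc
    return bool(
        abs(q[0] + q[2] - 2 * q[1]) < tol
        and abs(q[0] - q[2] - 2 * c / (b + c)) < tol
    )


def _classify_point(
    y: np.ndarray,
    space: str,
    game: GamePayoffs,
    st: IntegrationSettings,
    on_boundary: bool,
    converged: bool,
) -> str:
    tol = st.boundary_tol
    if on_boundary or (y <= tol).any() or (y >= 1.0 - tol).any():
        if y[0] >= 1.0 - tol:
            return "full_cooperation"
        if y[-1] <= tol:
            return "full_defection"
        return "other_boundary"
    if space == "memone":
        crit = is_critical(y, game, tol=st.critical_tol)
    else:
        crit = _q_is_critical(y, game, st.critical_tol)
    if crit:
        return "interior_critical"
    return "interior_critical" if converged else "undecided"


def integrate(
    start,
    space: str,
    game: GamePayoffs,
    settings: IntegrationSettings | None = None,
) -> TrajectoryOutcome:
    """Integrate a single trajectory with its path recorded."""
    st = settings or IntegrationSettings()
    y0 = np.atleast_2d(np.asarray(start, dtype=float))
    endpoints, classes, paths = integrate_batch(
        y0, space, game, st, record_paths=True
    )
    times = np.array([s[0] for s in paths[0]])
    path = np.array([s[1] for s in paths[0]])
    return TrajectoryOutcome(
        times=times,
        path=path,
        endpoint=endpoints[0],
        endpoint_class=str(classes[0]),
        space=space,
    )


def classify_endpoint(outcome: TrajectoryOutcome, game: GamePayoffs,
                      settings: IntegrationSettings | None = None) -> str:
    """Re-derive the endpoint class of a finished trajectory from its endpoint."""
    st = settings or IntegrationSettings()
    y = np.asarray(outcome.endpoint, dtype=float)
    on_boundary = bool(((y <= st.boundary_tol) | (y >= 1 - st.boundary_tol)).any())
    return _classify_point(y, outcome.space, game, st, on_boundary, converged=True)


def cooperation_series(
    outcome: TrajectoryOutcome, game: GamePayoffs, eps: float = 1e-9
) -> np.ndarray:
    """Self-cooperation rate C(p(t)) along the recorded path.

    Computed as A(p, p)/(b - c) via the vectorised determinant payoff; exact
    corner points are evaluated one-sidedly by an eps-perturbation.
    """
    b, c = game.bc
    P = outcome.path
    if outcome.space == "counting":
        P = np.column_stack([P[:, 0], P[:, 1], P[:, 1], P[:, 2]])
    P = np.clip(P, eps, 1.0 - eps)
    vals = payoff_batch(P, P, game) / (b - c)
    series = np.clip(vals, 0.0, 1.0)
    outcome.coop_series = series
    return series
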