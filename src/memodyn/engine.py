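"""Exact payoff computation for repeated 2x2 games.

Two memory-one players generate a Markov chain over the four joint outcomes
(CC, CD, DC, DD).  Payoffs are long-run averages under the chain's stationary
distribution and can be computed two ways: by solving the linear stationary
system directly, or in closed form via the Press-Dyson determinant quotient.
Both are implemented; they agree to ~1e-10 wherever the chain is ergodic and
the tests hold them to that.

The same machinery generalises to memory-n strategies over the 4**n histories
of the last n rounds (used for the invariance checks of the counting
subspace), with a cap on n to keep the state space small.
"""

from __future__ import annotations

import numpy as np

from .errors import CapExceededError, DegenerateChainError, NonUniqueStationaryError
from .game import GamePayoffs
from .strategies import (
    SWAP,
    MemoryNStrategy,
    StationaryDistribution,
    as_counting_array,
    as_memone_array,
)

_SINGULAR_TOL = 1e-9


def transition_matrix(p, p2) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix of the joint-outcome chain.

    Row/column order is (CC, CD, DC, DD) from the focal player's perspective;
    the co-player's cooperation probability in state s is read from the
    perspective-swapped state (CD and DC exchanged).
    """
    pa = as_memone_array(p)
    pb = as_memone_array(p2)[SWAP]
    M = np.empty((4, 4))
    M[:, 0] = pa * pb
    M[:, 1] = pa * (1.0 - pb)
    M[:, 2] = (1.0 - pa) * pb
    M[:, 3] = (1.0 - pa) * (1.0 - pb)
    return M


def _stationary_of_matrix(M: np.ndarray, tol: float = _SINGULAR_TOL) -> np.ndarray:
    """Unique left fixed vector of a row-stochastic matrix, or raise.

    Solves (M^T - I) v = 0 with the normalisation row sum(v) = 1 appended;
    uniqueness is checked via the singular values of M^T - I.
    """
    n = M.shape[0]
    A = M.T - np.eye(n)
    sv = np.linalg.svd(A, compute_uv=False)
    if np.sum(sv < tol * max(1.0, sv[0])) > 1:
        raise NonUniqueStationaryError(
            "the eigenvalue-1 eigenspace has dimension > 1; the long-run "
            "outcome frequencies are not unique for this strategy pair"
        )
    B = np.vstack([A, np.ones((1, n))])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    v, *_ = np.linalg.lstsq(B, rhs, rcond=None)
    v = np.where(np.abs(v) < 1e-15, 0.0, v)
    if np.any(v < -1e-9):
        raise NonUniqueStationaryError(f"stationary solve produced negative mass: {v}")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def stationary_distribution(p, p2) -> StationaryDistribution:
    """Stationary distribution of the joint-outcome chain of ``p`` vs ``p2``."""
    v = _stationary_of_matrix(transition_matrix(p, p2))
    return StationaryDistribution(*v)


# ---------------------------------------------------------------------------
# Determinant (Press-Dyson) payoff
# ---------------------------------------------------------------------------

def _det_columns(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """First three columns of the Press-Dyson matrix, shape (..., 4, 3)."""
    x1, y1, z1, w1 = pa[..., 0], pa[..., 1], pa[..., 2], pa[..., 3]
    x2, y2, z2, w2 = pb[..., 0], pb[..., 1], pb[..., 2], pb[..., 3]
    out = np.empty(pa.shape[:-1] + (4, 3))
    out[..., 0, 0] = -1.0 + x1 * x2
    out[..., 0, 1] = -1.0 + x1
    out[..., 0, 2] = -1.0 + x2
    out[..., 1, 0] = y1 * z2
    out[..., 1, 1] = -1.0 + y1
    out[..., 1, 2] = z2
    out[..., 2, 0] = z1 * y2
    out[..., 2, 1] = z1
    out[..., 2, 2] = -1.0 + y2
    out[..., 3, 0] = w1 * w2
    out[..., 3, 1] = w1
    out[..., 3, 2] = w2
    return out


def _det_quotient(pa: np.ndarray, pb: np.ndarray, last_col: np.ndarray):
    """Numerator and denominator of the determinant payoff formula."""
    cols = _det_columns(pa, pb)
    mat = np.concatenate([cols, np.broadcast_to(last_col, cols.shape[:-1])[..., None]], axis=-1)
    ones = np.concatenate(
        [cols, np.ones(cols.shape[:-1])[..., None]], axis=-1
    )
    return np.linalg.det(mat), np.linalg.det(ones)


def _perturbed(pa: np.ndarray, eps: float) -> np.ndarray:
    """Pull deterministic entries off the boundary: 0 -> eps, 1 -> 1 - eps."""
    return np.clip(pa, eps, 1.0 - eps)


def payoff(p, p2, game: GamePayoffs, *, perturb: float | None = None) -> float:
    """Long-run payoff of the ``p``-player against the ``p2``-player.

    Uses the determinant quotient.  For degenerate strategy pairs (periodic
    or reducible chains) where the quotient is 0/0, a DegenerateChainError is
    raised unless ``perturb`` is given, in which case each deterministic entry
    is replaced by eps / 1 - eps and the result is the corresponding limit
    approximation.
    """
    pa = as_memone_array(p)
    pb = as_memone_array(p2)
    if perturb is not None:
        pa, pb = _perturbed(pa, perturb), _perturbed(pb, perturb)
    last = np.array(game.as_tuple())
    num, den = _det_quotient(pa, pb, last)
    if abs(den) < 1e-14:
        if perturb is None:
            raise DegenerateChainError(
                "determinant payoff is 0/0 for this strategy pair; pass "
                "perturb=eps to evaluate the epsilon-perturbed limit"
            )
        pa, pb = _perturbed(pa, 10 * perturb), _perturbed(pb, 10 * perturb)
        num, den = _det_quotient(pa, pb, last)
    return float(num / den)


def payoff_via_stationary(p, p2, game: GamePayoffs) -> float:
    """Payoff computed as R v_CC + S v_CD + T v_DC + P v_DD (the oracle form)."""
    v = stationary_distribution(p, p2).as_array()
    return float(np.dot(np.array(game.as_tuple()), v))


def payoff_batch(P: np.ndarray, P2: np.ndarray, game: GamePayoffs) -> np.ndarray:
    """Vectorised determinant payoff for stacks of strategy vectors (..., 4)."""
    last = np.array(game.as_tuple())
    num, den = _det_quotient(np.asarray(P, float), np.asarray(P2, float), last)
    return num / den


def payoff_counting(q, q2, game: GamePayoffs, *, perturb: float | None = None) -> float:
    """Payoff of a counting-strategy player against another.

    Evaluates the determinant quotient on the three-variable matrix obtained
    by identifying the CD and DC rows of the memory-one formula, i.e. on the
    embedded strategies (q2, q1, q1, q0).
    """
    qa = as_counting_array(q)
    qb = as_counting_array(q2)
    emb = lambda v: np.array([v[0], v[1], v[1], v[2]])
    return payoff(emb(qa), emb(qb), game, perturb=perturb)


# ---------------------------------------------------------------------------
# Memory-n payoffs
# ---------------------------------------------------------------------------

def _swap_history_index(n: int) -> np.ndarray:
    """Index permutation expressing each history from the co-player's view."""
    idx = np.arange(4**n)
    out = np.zeros_like(idx)
    rem = idx.copy()
    for k in range(n):
        digit = rem % 4
        out += SWAP[digit] * 4**k
        rem //= 4
    return out


def memory_n_transition(s: MemoryNStrategy, s2: MemoryNStrategy) -> np.ndarray:
    """Sparse-structured 4**n x 4**n transition matrix over histories."""
    if s.n != s2.n:
        raise ValueError("both players must have the same memory length")
    n = s.n
    size = 4**n
    pa = s.table
    pb = s2.table[_swap_history_index(n)]
    M = np.zeros((size, size))
    hist = np.arange(size)
    # new history: drop the oldest round (most significant digit), append the
    # new outcome as the least significant digit
    base = (hist % 4 ** (n - 1)) * 4
    probs = np.stack(
        [pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)], axis=1
    )
    for outcome in range(4):
        M[hist, base + outcome] = probs[:, outcome]
    return M


def payoff_memory_n(
    s: MemoryNStrategy, s2: MemoryNStrategy, game: GamePayoffs, *, cap: int = 4
) -> float:
    """Long-run payoff between two memory-n players.

    Averages the last-round payoff over the stationary distribution of the
    history chain.  Falls back to power iteration when the direct linear
    solve flags the chain as near-degenerate.
    """
    if s.n > cap:
        raise CapExceededError(f"memory length {s.n} exceeds cap {cap}")
    M = memory_n_transition(s, s2)
    try:
        v = _stationary_of_matrix(M)
    except NonUniqueStationaryError:
        v = _power_iteration(M)
    last_outcome = np.arange(4**s.n) % 4
    per_round = np.array(game.as_tuple())[last_outcome]
    return float(np.dot(v, per_round))


def _power_iteration(M: np.ndarray, iters: int = 100000, tol: float = 1e-13) -> np.ndarray:
    v = np.full(M.shape[0], 1.0 / M.shape[0])
    for _ in range(iters):
        nxt = v @ M
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - v)) < tol:
            return nxt
        v = nxt
    raise NonUniqueStationaryError("power iteration did not converge")


# ---------------------------------------------------------------------------
# Gradients and cooperation rate
# ---------------------------------------------------------------------------

def numeric_gradient(p, game: GamePayoffs, h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of the invader payoff A(p', p) at p' = p.

    This is the raw adaptive-dynamics velocity (no rescaling); it serves as
    the independent oracle for the closed-form polynomial fields.  The
    determinant payoff is a rational function, so evaluation a half-step
    outside the cube is well defined.
    """
    pa = as_memone_array(p)
    last = np.array(game.as_tuple())
    grad = np.empty(4)
    for i in range(4):
        hi, lo = pa.copy(), pa.copy()
        hi[i] += h
        lo[i] -= h
        num_h, den_h = _det_quotient(hi, pa, last)
        num_l, den_l = _det_quotient(lo, pa, last)
        grad[i] = (num_h / den_h - num_l / den_l) / (2.0 * h)
    return grad


def numeric_gradient_counting(q, game: GamePayoffs, h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of A(q', q) at q' = q in the 3-cube."""
    qa = as_counting_array(q)
    emb = lambda v: np.array([v[0], v[1], v[1], v[2]])
    last = np.array(game.as_tuple())
    grad = np.empty(3)
    for i in range(3):
        hi, lo = qa.copy(), qa.copy()
        hi[i] += h
        lo[i] -= h
        num_h, den_h = _det_quotient(emb(hi), emb(qa), last)
        num_l, den_l = _det_quotient(emb(lo), emb(qa), last)
        grad[i] = (num_h / den_h - num_l / den_l) / (2.0 * h)
    return grad


def self_play_outcome_frequencies(p, *, perturb: float | None = None) -> np.ndarray:
    """Stationary outcome frequencies of a homogeneous ``p`` population."""
    pa = as_memone_array(p)
    if perturb is not None:
        pa = _perturbed(pa, perturb)
    return _stationary_of_matrix(transition_matrix(pa, pa))


def cooperation_rate(p, game: GamePayoffs | None = None, *, perturb: float | None = None) -> float:
    """Long-run rate of own cooperation in self-play: v_CC + (v_CD + v_DC)/2.

    For the donation game this equals A(p, p) / (b - c).  The ``game``
    argument is accepted for interface symmetry but the rate itself is
    payoff-independent.
    """
    v = self_play_outcome_frequencies(p, perturb=perturb)
    return float(v[0] + 0.5 * (v[1] + v[2]))


def self_payoff_batch(P: np.ndarray, game: GamePayoffs) -> np.ndarray:
    """Vectorised self-play payoff A(p, p) for a stack of strategies (..., 4)."""
    P = np.asarray(P, float)
    return payoff_batch(P, P, game)
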