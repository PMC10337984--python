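"""Strategy containers for repeated 2x2 games.

A memory-one strategy is a point ``p = (p_CC, p_CD, p_DC, p_DD)`` in the unit
4-cube: the probability of cooperating after each of the four joint outcomes
of the previous round, with the focal player's move listed first.  A counting
strategy only reacts to how many players cooperated last round and is written
``q = (q2, q1, q0)``; it embeds into the memory-one cube as
``(q2, q1, q1, q0)``.  Memory-n strategies condition on the joint outcomes of
the last ``n`` rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Fixed ordering of joint outcomes; first letter is the focal player's move.
STATES = ("CC", "CD", "DC", "DD")
# Index permutation that re-expresses a joint outcome from the co-player's
# perspective (CD and DC swap, CC and DD are symmetric).
SWAP = np.array([0, 2, 1, 3])


def _check_unit(values, label: str) -> None:
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{label} entries must lie in [0, 1], got {values}")


@dataclass(frozen=True)
class MemoryOneStrategy:
    """Conditional cooperation probabilities after CC, CD, DC, DD."""

    p_cc: float
    p_cd: float
    p_dc: float
    p_dd: float

    def __post_init__(self) -> None:
        _check_unit(self.as_array(), "memory-one strategy")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_cc, self.p_cd, self.p_dc, self.p_dd], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "MemoryOneStrategy":
        a = np.asarray(arr, dtype=float)
        if a.shape != (4,):
            raise ValueError(f"expected 4 entries, got shape {a.shape}")
        return cls(*a)

    @property
    def is_counting(self) -> bool:
        """True when p_CD = p_DC (responds only to the number of cooperators)."""
        return self.p_cd == self.p_dc

    @property
    def is_interior(self) -> bool:
        a = self.as_array()
        return bool(np.all((a > 0.0) & (a < 1.0)))


@dataclass(frozen=True)
class CountingStrategy:
    """Cooperation probabilities after 2, 1, or 0 cooperators last round."""

    q2: float
    q1: float
    q0: float

    def __post_init__(self) -> None:
        _check_unit(self.as_array(), "counting strategy")

    def as_array(self) -> np.ndarray:
        return np.array([self.q2, self.q1, self.q0], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "CountingStrategy":
        a = np.asarray(arr, dtype=float)
        if a.shape != (3,):
            raise ValueError(f"expected 3 entries, got shape {a.shape}")
        return cls(*a)

    def embed(self) -> MemoryOneStrategy:
        """The corresponding memory-one strategy (q2, q1, q1, q0)."""
        return MemoryOneStrategy(self.q2, self.q1, self.q1, self.q0)

    @property
    def is_interior(self) -> bool:
        a = self.as_array()
        return bool(np.all((a > 0.0) & (a < 1.0)))


@dataclass(frozen=True)
class MemoryNStrategy:
    """Cooperation probability for each length-n history of joint outcomes.

    Histories are ordered with the most recent round last; the flat table is
    indexed lexicographically in that order, i.e. the most recent outcome is
    the least significant base-4 digit (CC=0, CD=1, DC=2, DD=3).
    """

    n: int
    table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("memory length n must be a positive integer")
        tab = np.asarray(self.table, dtype=float)
        if tab.shape != (4**self.n,):
            raise ValueError(
                f"memory-{self.n} table must have {4 ** self.n} entries, "
                f"got shape {tab.shape}"
            )
        _check_unit(tab, f"memory-{self.n} strategy")
        object.__setattr__(self, "table", tab)

    @classmethod
    def from_memory_one(cls, p, n: int) -> "MemoryNStrategy":
        """Lift a memory-one strategy: condition only on the last outcome."""
        p4 = as_memone_array(p)
        idx = np.arange(4**n) % 4  # least significant digit = most recent round
        return cls(n=n, table=p4[idx])


@dataclass(frozen=True)
class StationaryDistribution:
    """Long-run frequencies of the four joint outcomes."""

    v_cc: float
    v_cd: float
    v_dc: float
    v_dd: float

    def __post_init__(self) -> None:
        a = self.as_array()
        if np.any(a < -1e-12):
            raise ValueError(f"stationary distribution has negative entries: {a}")
        if abs(a.sum() - 1.0) > 1e-12:
            raise ValueError(f"stationary distribution must sum to 1, got {a.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.v_cc, self.v_cd, self.v_dc, self.v_dd], dtype=float)


def as_memone_array(p) -> np.ndarray:
    """Coerce a strategy-like object to a length-4 float array.

    Accepts MemoryOneStrategy, CountingStrategy (embedded), or any sequence
    of four probabilities.
    """
    if isinstance(p, MemoryOneStrategy):
        return p.as_array()
    if isinstance(p, CountingStrategy):
        return p.embed().as_array()
    a = np.asarray(p, dtype=float)
    if a.shape != (4,):
        raise ValueError(f"expected a memory-one strategy (4 entries), got {p!r}")
    return a


def as_counting_array(q) -> np.ndarray:
    """Coerce to a length-3 float array of counting probabilities."""
    if isinstance(q, CountingStrategy):
        return q.as_array()
    if isinstance(q, MemoryOneStrategy):
        if not q.is_counting:
            raise ValueError(f"{q} is not a counting strategy (p_CD != p_DC)")
        return np.array([q.p_cc, q.p_cd, q.p_dd], dtype=float)
    a = np.asarray(q, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a counting strategy (3 entries), got {q!r}")
    return a


# Canonical named strategies.
ALLC = MemoryOneStrategy(1, 1, 1, 1)
ALLD = MemoryOneStrategy(0, 0, 0, 0)
TFT = MemoryOneStrategy(1, 0, 1, 0)
WSLS = MemoryOneStrategy(1, 0, 0, 1)
GRIM = MemoryOneStrategy(1, 0, 0, 0)
RANDOM = MemoryOneStrategy(0.5, 0.5, 0.5, 0.5)


def gtft(b: float, c: float) -> MemoryOneStrategy:
    """Generous tit-for-tat (1, x, 1, x) with the canonical x = 1 - c/b."""
    x = 1.0 - c / b
    return MemoryOneStrategy(1, x, 1, x)
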