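"""Payoff parameters for symmetric 2x2 games.

The donation game is the prisoner's dilemma variant in which cooperation
costs the donor ``c`` and confers a benefit ``b`` on the recipient, so the
one-shot payoff matrix is ``(R, S, T, P) = (b - c, -c, b, 0)`` with
``b > c > 0``.  It satisfies "equal gains from switching", ``R + P = T + S``,
which is the structural condition behind the forward/backward orbit duality
exploited throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GamePayoffs:
    """One-round payoffs (R, S, T, P) of a symmetric 2x2 game.

    R: reward for mutual cooperation; S: sucker's payoff (cooperate against
    defection); T: temptation (defect against cooperation); P: punishment for
    mutual defection.  ``benefit``/``cost`` are set by the donation-game
    constructor and are ``None`` for a general game.
    """

    R: float
    S: float
    T: float
    P: float
    benefit: float | None = None
    cost: float | None = None

    @classmethod
    def donation(cls, b: float, c: float) -> "GamePayoffs":
        """Donation game with benefit ``b`` and cost ``c`` (``b > c > 0``)."""
        if not (b > c > 0):
            raise ValueError(f"donation game requires b > c > 0, got b={b}, c={c}")
        return cls(R=b - c, S=-c, T=b, P=0.0, benefit=float(b), cost=float(c))

    @property
    def equal_gains(self) -> bool:
        """Whether R + P = T + S ('equal gains from switching')."""
        return abs((self.R + self.P) - (self.T + self.S)) < 1e-12

    @property
    def is_donation(self) -> bool:
        return self.benefit is not None and self.cost is not None

    @property
    def bc(self) -> tuple[float, float]:
        """(benefit, cost); raises for games without a donation-game form."""
        if not self.is_donation:
            raise ValueError(
                "this operation needs donation-game parameters (b, c); "
                "construct the game with GamePayoffs.donation(b, c)"
            )
        return self.benefit, self.cost  # type: ignore[return-value]

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.R, self.S, self.T, self.P)
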