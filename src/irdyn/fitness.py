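"""Payoffs in the donation game and reputation-averaged fitness.

In each encounter the donor may pay a cost c to confer a benefit b > c on
the recipient.  At reputation state (h, h') the expected one-interaction
payoff of a p-strategist is

    f_p(k, h, h') = b R_p(h, h') - c D_p(h, h')

where R_p is the probability that a random co-player donates to the focal
p-strategist (the focal is Good with probability h/k) and D_p the
probability that the focal donates to a random co-player; co-players are
drawn from the Z-1 others.  Averaging f_p over the stationary reputation
distribution gives the frequency-dependent fitness fbar_p(k) driving
imitation.  The average runs over the full inclusive grid
0 <= h <= k, 0 <= h' <= Z-k, the support of the stationary distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .strategies import InteractionProbs

__all__ = [
    "PayoffParams",
    "receive_prob",
    "donate_prob",
    "state_payoff",
    "average_fitness",
]


@dataclass(frozen=True)
class PayoffParams:
    """Donation-game benefit b and cost c, with b > c > 0."""

    b: float = 5.0
    c: float = 1.0

    def __post_init__(self) -> None:
        if not self.b > self.c > 0:
            raise ValueError(f"donation game requires b > c > 0, got b={self.b}, c={self.c}")


def receive_prob(h, hp, k: int, Z: int, probs_p: InteractionProbs, probs_pp: InteractionProbs):
    """Probability R_p(h, h') that a p-strategist receives a donation.

    The focal is Good with probability h/k; the co-playing donor is one of
    the Z-1 others (k-1 of them p-strategists) and donates according to its
    own cooperation probability toward the focal's reputation.  Accepts
    scalars or arrays for (h, hp).
    """
    if k == 0:
        raise ValueError("receive_prob undefined for k=0 (no p-strategist present)")
    h = np.asarray(h, dtype=float)
    w_p, w_pp = (k - 1) / (Z - 1), (Z - k) / (Z - 1)
    toward_good = w_p * probs_p.c_g + w_pp * probs_pp.c_g
    toward_bad = w_p * probs_p.c_b + w_pp * probs_pp.c_b
    return h / k * toward_good + (k - h) / k * toward_bad


def donate_prob(h, hp, k: int, Z: int, probs_p: InteractionProbs):
    """Probability D_p(h, h') that a p-strategist donates.

    A Good focal sees h-1+h' Good co-players among the Z-1 others; a Bad
    focal sees h+h'.  Accepts scalars or arrays for (h, hp).
    """
    if k == 0:
        raise ValueError("donate_prob undefined for k=0 (no p-strategist present)")
    h = np.asarray(h, dtype=float)
    hp = np.asarray(hp, dtype=float)
    good_if_good = (h - 1 + hp) / (Z - 1)
    good_if_bad = (h + hp) / (Z - 1)
    d_good = good_if_good * probs_p.c_g + (1 - good_if_good) * probs_p.c_b
    d_bad = good_if_bad * probs_p.c_g + (1 - good_if_bad) * probs_p.c_b
    return h / k * d_good + (k - h) / k * d_bad


def state_payoff(h, hp, k: int, Z: int, probs_p, probs_pp, payoff: PayoffParams):
    """f_p(k, h, h') = b R_p - c D_p."""
    return payoff.b * receive_prob(h, hp, k, Z, probs_p, probs_pp) - payoff.c * donate_prob(
        h, hp, k, Z, probs_p
    )


def average_fitness(
    k: int,
    Z: int,
    sigma: np.ndarray,
    probs_p: InteractionProbs,
    probs_pp: InteractionProbs,
    payoff: PayoffParams,
) -> tuple[float, float, float]:
    """Reputation-averaged fitness (fbar_p, fbar_p', delta = fbar_p - fbar_p').

    ``sigma`` is the stationary distribution of the (h, h') chain at
    composition k, in the linear order h*(Z-k+1)+h'.  The p' quantities are
    obtained from the same formulas with k -> Z-k, h <-> h', p <-> p'.
    """
    if not 1 <= k <= Z - 1:
        raise ValueError(f"average fitness needs both strategies present (1 <= k <= Z-1), got k={k}")
    width = Z - k + 1
    if sigma.shape != ((k + 1) * width,):
        raise ValueError(
            f"sigma has length {sigma.size}, expected (k+1)(Z-k+1) = {(k + 1) * width}"
        )
    h, hp = np.meshgrid(np.arange(k + 1), np.arange(width), indexing="ij")
    f_p = state_payoff(h, hp, k, Z, probs_p, probs_pp, payoff)
    f_pp = state_payoff(hp, h, Z - k, Z, probs_pp, probs_p, payoff)
    w = sigma.reshape(k + 1, width)
    fbar_p = float((w * f_p).sum())
    fbar_pp = float((w * f_pp).sum())
    return fbar_p, fbar_pp, fbar_p - fbar_pp
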