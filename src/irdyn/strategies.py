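"""Behavioral rules (strategies) and error-adjusted interaction probabilities.

A strategy is a duple p = (p_G, p_B): the probability of cooperating with an
opponent perceived as Good, respectively Bad.  The four pure strategies are
AllC=(1,1), AllD=(0,0), the discriminator Disc=(1,0) and the paradoxical
discriminator pDisc=(0,1).

Three error rates perturb play:

* ``epsilon`` — execution error: an intended donation fails (p -> (1-eps)p).
  By default errors are one-sided; a symmetric variant in which defectors
  also cooperate involuntarily is available via ``symmetric=True``.
* ``alpha`` — assignment error, folded into the norm (see :mod:`irdyn.norms`).
* ``chi`` — private assessment error: an individual privately misperceives
  an opponent's public reputation, independently per observation.

Folding epsilon into p and alpha into d first, the probability that a
p-strategist cooperates with a truly-Good opponent is
``C_G = (1-chi) p_G + chi p_B`` (and symmetrically for C_B), and the
probability that a bystander assigns Good after watching an interaction with
a truly-Good recipient is

    G_G = (1-chi) [C_G d_GC + (1-C_G) d_GD] + chi [C_G d_BC + (1-C_G) d_BD]

i.e. the bystander independently misreads the recipient with probability chi
while the donor's own misperception is already inside C_G.
"""

from __future__ import annotations

from dataclasses import dataclass

from .norms import Norm, apply_assignment_error

__all__ = [
    "Strategy",
    "ErrorRates",
    "InteractionProbs",
    "NAMED_STRATEGIES",
    "STRATEGY_ORDER",
    "named_strategy",
    "parse_strategy",
    "apply_execution_error",
    "cooperation_probs",
    "good_assignment_probs",
    "interaction_probs",
]


@dataclass(frozen=True)
class Strategy:
    """Cooperation probabilities toward perceived-Good / perceived-Bad opponents."""

    p_g: float
    p_b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_g <= 1.0 and 0.0 <= self.p_b <= 1.0):
            raise ValueError(f"strategy entries must be probabilities, got {(self.p_g, self.p_b)}")

    def as_tuple(self) -> tuple[float, float]:
        return (self.p_g, self.p_b)

    def __str__(self) -> str:
        for name, vec in NAMED_STRATEGIES.items():
            if self.as_tuple() == vec:
                return name
        return ",".join(format(v, "g") for v in self.as_tuple())


NAMED_STRATEGIES: dict[str, tuple[float, float]] = {
    "AllC": (1.0, 1.0),
    "AllD": (0.0, 0.0),
    "Disc": (1.0, 0.0),
    "pDisc": (0.0, 1.0),
}

#: Canonical ordering of the monomorphic states in the evolutionary analysis.
STRATEGY_ORDER: tuple[str, ...] = ("AllC", "AllD", "Disc", "pDisc")


def named_strategy(name: str) -> Strategy:
    """Look up AllC / AllD / Disc / pDisc (case-insensitive)."""
    lookup = {k.lower(): v for k, v in NAMED_STRATEGIES.items()}
    try:
        return Strategy(*lookup[name.strip().lower()])
    except KeyError:
        raise KeyError(
            f"unknown strategy name {name!r}; valid names are {sorted(NAMED_STRATEGIES)}"
        ) from None


def parse_strategy(text: str) -> Strategy:
    """Parse a strategy from a name or two comma-separated floats."""
    if text.strip().lower() in {k.lower() for k in NAMED_STRATEGIES}:
        return named_strategy(text)
    parts = text.split(",")
    if len(parts) != 2:
        raise ValueError(
            f"cannot parse strategy {text!r}: expected a name in "
            f"{sorted(NAMED_STRATEGIES)} or 2 comma-separated probabilities"
        )
    return Strategy(float(parts[0]), float(parts[1]))


@dataclass(frozen=True)
class ErrorRates:
    """Assignment (alpha), execution (epsilon) and private assessment (chi) errors."""

    alpha: float = 0.0
    epsilon: float = 0.0
    chi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "epsilon", "chi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"error rate {name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class InteractionProbs:
    """Effective per-encounter probabilities for one strategy under one norm.

    ``c_g`` / ``c_b``: probability the strategist cooperates with a
    truly-Good / truly-Bad opponent.  ``g_g`` / ``g_b``: probability a
    bystander assigns Good after witnessing the strategist interact with a
    truly-Good / truly-Bad recipient.
    """

    c_g: float
    c_b: float
    g_g: float
    g_b: float


def apply_execution_error(p: Strategy, epsilon: float, symmetric: bool = False) -> Strategy:
    """Fold the execution error into the strategy.

    One-sided (default): intended cooperation fails with probability epsilon,
    p -> (1-eps) p.  Symmetric variant: the realized action is flipped with
    probability epsilon, p -> (1-eps) p + eps (1-p).
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"execution error epsilon must be in [0, 1], got {epsilon}")
    if symmetric:
        return Strategy(
            (1 - epsilon) * p.p_g + epsilon * (1 - p.p_g),
            (1 - epsilon) * p.p_b + epsilon * (1 - p.p_b),
        )
    return Strategy((1 - epsilon) * p.p_g, (1 - epsilon) * p.p_b)


def cooperation_probs(p_eff: Strategy, chi: float) -> tuple[float, float]:
    """(C_G, C_B): cooperation probabilities toward truly-Good / truly-Bad
    opponents, given the donor misperceives the opponent with probability chi."""
    c_g = (1 - chi) * p_eff.p_g + chi * p_eff.p_b
    c_b = chi * p_eff.p_g + (1 - chi) * p_eff.p_b
    return c_g, c_b


def good_assignment_probs(p_eff: Strategy, d_eff: Norm, chi: float) -> tuple[float, float]:
    """(G_G, G_B): probabilities that the bystander assigns a Good reputation
    after an interaction with a truly-Good / truly-Bad recipient.

    ``p_eff`` must already include the execution error and ``d_eff`` the
    assignment error; the donor's and bystander's chi-misperceptions are
    independent.
    """
    c_g, c_b = cooperation_probs(p_eff, chi)
    g_g = (1 - chi) * (c_g * d_eff.d_gc + (1 - c_g) * d_eff.d_gd) + chi * (
        c_g * d_eff.d_bc + (1 - c_g) * d_eff.d_bd
    )
    g_b = chi * (c_b * d_eff.d_gc + (1 - c_b) * d_eff.d_gd) + (1 - chi) * (
        c_b * d_eff.d_bc + (1 - c_b) * d_eff.d_bd
    )
    return g_g, g_b


def interaction_probs(
    strategy: Strategy,
    norm: Norm,
    errors: ErrorRates,
    symmetric_execution: bool = False,
) -> InteractionProbs:
    """Fold all three error rates and return the four effective probabilities
    (C_G, C_B, G_G, G_B) that drive the reputation chain."""
    p_eff = apply_execution_error(strategy, errors.epsilon, symmetric=symmetric_execution)
    d_eff = apply_assignment_error(norm, errors.alpha)
    c_g, c_b = cooperation_probs(p_eff, errors.chi)
    g_g, g_b = good_assignment_probs(p_eff, d_eff, errors.chi)
    return InteractionProbs(c_g=c_g, c_b=c_b, g_g=g_g, g_b=g_b)
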