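"""Strategy evolution in the small-mutation limit and the cooperation index.

Strategies spread by pairwise-comparison imitation (Fermi rule): a learner
copies a model with probability 1/(1 + exp(-beta * delta_f)), where delta_f
is the model's fitness advantage and beta the selection strength.  In the
small-mutation approximation (SMA) at most two strategies ever coexist, so
the long-run dynamics reduce to a Markov chain over the four monomorphic
states (AllC, AllD, Disc, pDisc) whose transitions are single-mutant
fixation probabilities

    rho_{p' -> p} = [ 1 + sum_{i=1}^{Z-1} prod_{j=1}^{i} exp(-beta df(j)) ]^{-1}

with df(j) the fitness difference of p over p' when j individuals play p
(each evaluated under the stationary reputation distribution at that
composition).  The embedded chain T has T_ij = rho_{i->j}/3 off the
diagonal; its stationary distribution lambda weights the per-state donation
rates into the cooperation index

    eta = sum_i lambda_i sum_j D_{p_i}(j, 0) sigma^d(p_i, j)

where sigma^d(p_i, .) is the stationary distribution of Good counts in the
monomorphic p_i population under norm d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import expit, logsumexp

from .fitness import PayoffParams, average_fitness, donate_prob
from .norms import Norm
from .reputation import build_transition_matrix, stationary_distribution
from .strategies import (
    STRATEGY_ORDER,
    ErrorRates,
    InteractionProbs,
    Strategy,
    interaction_probs,
    named_strategy,
)

__all__ = [
    "ModelParams",
    "MonomorphicStats",
    "EvolutionResult",
    "fermi_prob",
    "delta_fitness_profile",
    "fixation_probability",
    "pairwise_fixation_matrix",
    "embedded_chain",
    "monomorphic_stats",
    "cooperation_index",
    "transition_graph",
]


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of one model evaluation."""

    Z: int
    norm: Norm
    payoff: PayoffParams = PayoffParams()
    errors: ErrorRates = ErrorRates(alpha=0.01, epsilon=0.08, chi=0.01)
    beta: float = 1.0
    symmetric_execution: bool = False

    def __post_init__(self) -> None:
        if self.Z < 2:
            raise ValueError(f"population size Z must be >= 2, got {self.Z}")
        if self.beta < 0:
            raise ValueError(f"selection strength beta must be >= 0, got {self.beta}")

    def interaction_probs(self, strategy: Strategy) -> InteractionProbs:
        return interaction_probs(
            strategy, self.norm, self.errors, symmetric_execution=self.symmetric_execution
        )


@dataclass(frozen=True)
class MonomorphicStats:
    """Stationary reputation summary of a single-strategy population."""

    strategy: str
    sigma: np.ndarray = field(repr=False)  # distribution of the Good count, length Z+1
    good_fraction: float
    donation_fraction: float


@dataclass(frozen=True)
class EvolutionResult:
    """Output of the SMA pipeline for one parameter set."""

    params: ModelParams
    rho: np.ndarray  # 4x4, rho[i, j] = fixation prob. of a p_j mutant among p_i residents
    T: np.ndarray  # embedded 4-state chain
    lam: np.ndarray  # stationary distribution over STRATEGY_ORDER
    eta: float
    monomorphic: tuple[MonomorphicStats, ...]

    @property
    def strategy_names(self) -> tuple[str, ...]:
        return STRATEGY_ORDER


def fermi_prob(delta_f: float, beta: float) -> float:
    """Imitation probability 1/(1 + exp(-beta * delta_f)); overflow-safe."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    return float(expit(beta * np.asarray(delta_f, dtype=float)))


def delta_fitness_profile(
    mutant: Strategy, resident: Strategy, params: ModelParams
) -> np.ndarray:
    """df(k) = fbar_mutant(k) - fbar_resident(k) for k = 1..Z-1 mutants.

    Each entry requires solving the reputation chain at that composition;
    this is the expensive inner loop of the SMA and the natural caching unit.
    """
    probs_m = params.interaction_probs(mutant)
    probs_r = params.interaction_probs(resident)
    out = np.empty(params.Z - 1)
    for k in range(1, params.Z):
        chain = build_transition_matrix(k, params.Z, probs_m, probs_r)
        sigma = stationary_distribution(chain)
        _, _, delta = average_fitness(k, params.Z, sigma, probs_m, probs_r, params.payoff)
        out[k - 1] = delta
    return out


def _fixation_from_deltas(deltas: np.ndarray, beta: float, Z: int) -> float:
    # rho = 1 / (1 + sum_i exp(-beta * cumsum_i)); evaluated in log space
    s = -beta * np.cumsum(deltas)
    if not s.any():
        return 1.0 / Z  # neutral drift, exactly (log-space would lose exactness)
    log_denominator = logsumexp(np.concatenate(([0.0], s)))
    return float(np.exp(-log_denominator))


def fixation_probability(resident: Strategy, mutant: Strategy, params: ModelParams) -> float:
    """Probability that a single mutant fixates in a resident population.

    Closed form of the one-dimensional birth-death chain under the Fermi
    rule, with the fitness difference re-evaluated at every intermediate
    mutant count via the reputation chain.  At beta=0 this is the neutral
    value 1/Z.
    """
    if resident == mutant:
        raise ValueError("resident and mutant strategies must differ")
    deltas = delta_fitness_profile(mutant, resident, params)
    return _fixation_from_deltas(deltas, params.beta, params.Z)


def pairwise_fixation_matrix(params: ModelParams) -> np.ndarray:
    """All 12 ordered fixation probabilities rho[i, j] (mutant j in resident i).

    Only the 6 unordered pairs are solved: the chain at composition k for the
    pair (a, b) also yields the reversed profile df_{b,a}(k) = -df_{a,b}(Z-k).
    Diagonal entries are NaN (no mutant).
    """
    strategies = [named_strategy(s) for s in STRATEGY_ORDER]
    n = len(strategies)
    rho = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            deltas = delta_fitness_profile(strategies[j], strategies[i], params)
            rho[i, j] = _fixation_from_deltas(deltas, params.beta, params.Z)
            rho[j, i] = _fixation_from_deltas(-deltas[::-1], params.beta, params.Z)
    return rho


def embedded_chain(rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Embedded monomorphic-state chain T and its stationary distribution lambda.

    T_ij = rho_ij / 3 for i != j (a mutant picks one of the 3 other
    strategies uniformly), diagonal as the residual.  lambda solves
    lambda T = lambda, normalized to sum 1.
    """
    n = rho.shape[0]
    T = rho / (n - 1)
    np.fill_diagonal(T, 0.0)
    np.fill_diagonal(T, 1.0 - T.sum(axis=1))
    if np.any(~np.isfinite(T)):
        raise ValueError("fixation matrix contains non-finite off-diagonal entries")
    A = T.T - np.eye(n)
    A[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    lam = np.linalg.solve(A, rhs)
    if lam.min() < -1e-12:
        raise RuntimeError("embedded chain appears reducible: negative stationary mass")
    lam = np.clip(lam, 0.0, None)
    return T, lam / lam.sum()


def monomorphic_stats(strategy_name: str, params: ModelParams) -> MonomorphicStats:
    """Stationary reputation distribution and donation rate of the all-p_i state.

    The two-strategy chain at k=Z degenerates to a one-dimensional chain on
    the Good count h = 0..Z; the second camp is empty and irrelevant.
    """
    strategy = named_strategy(strategy_name)
    probs = params.interaction_probs(strategy)
    chain = build_transition_matrix(params.Z, params.Z, probs, probs)
    sigma = stationary_distribution(chain)
    h = np.arange(params.Z + 1)
    donations = donate_prob(h, np.zeros_like(h), params.Z, params.Z, probs)
    return MonomorphicStats(
        strategy=strategy_name,
        sigma=sigma,
        good_fraction=float((sigma * h).sum() / params.Z),
        donation_fraction=float((sigma * donations).sum()),
    )


def cooperation_index(params: ModelParams) -> tuple[float, EvolutionResult]:
    """Cooperation index eta and the full SMA result bundle.

    eta is the lambda-weighted average, over the four monomorphic states, of
    the stationary fraction of realized donations in that state.
    """
    rho = pairwise_fixation_matrix(params)
    T, lam = embedded_chain(rho)
    mono = tuple(monomorphic_stats(name, params) for name in STRATEGY_ORDER)
    eta = float(sum(l * m.donation_fraction for l, m in zip(lam, mono)))
    result = EvolutionResult(params=params, rho=rho, T=T, lam=lam, eta=eta, monomorphic=mono)
    return eta, result


def transition_graph(result: EvolutionResult, Z: int | None = None) -> nx.DiGraph:
    """Directed graph of above-neutral transitions between monomorphic states.

    An edge i -> j is drawn iff rho_{i->j} > 1/Z (strictly above neutral
    drift), weighted by rho * Z (so every drawn edge has weight > 1).  Nodes
    carry the stationary prevalence lambda and the per-state donation and
    Good fractions.
    """
    Z = Z if Z is not None else result.params.Z
    g = nx.DiGraph()
    for name, l, m in zip(STRATEGY_ORDER, result.lam, result.monomorphic):
        g.add_node(
            name,
            stationary_probability=float(l),
            donation_fraction=m.donation_fraction,
            good_fraction=m.good_fraction,
        )
    for i, src in enumerate(STRATEGY_ORDER):
        for j, dst in enumerate(STRATEGY_ORDER):
            if i != j and result.rho[i, j] > 1.0 / Z:
                g.add_edge(src, dst, weight=float(result.rho[i, j] * Z))
    return g
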