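"""Agent-based simulation of co-evolving reputations and strategies.

The analytic pipeline rests on two approximations: at most two strategies
coexist (small-mutation limit) and reputations equilibrate between strategy
updates (time-scale separation).  This simulator drops both.  All four pure
strategies co-evolve under a finite exploration rate mu, and each
strategy-update event is preceded by ``g_rep`` donation/reputation events,
so the separation of time scales becomes a tunable knob.

Event types
-----------
Reputation event: a random donor meets a random distinct recipient; the
donor misreads the recipient's public reputation with probability chi, then
cooperates according to its strategy with execution failure epsilon; an
observing bystander independently misreads the recipient (chi) and assigns
the donor's new reputation per the norm, flipped with probability alpha.

Strategy event: with probability mu a random individual adopts a uniformly
random strategy; otherwise a learner imitates a random model with the Fermi
probability, using exact expected payoffs given the current configuration
(the same R/D expressions as the analytic model) rather than noisy one-shot
payoffs — matching the quantity the Fermi rule compares analytically.

The main observable is the time-averaged donation rate (the simulated
counterpart of the cooperation index eta), with block-averaged standard
errors; strategy occupancies and per-strategy Good fractions are also
tracked.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .evolution import ModelParams
from .norms import apply_assignment_error
from .strategies import (
    NAMED_STRATEGIES,
    STRATEGY_ORDER,
    Strategy,
    apply_execution_error,
    cooperation_probs,
)

__all__ = ["SimulationConfig", "SimulationSummary", "PopulationState", "run", "step_reputation", "step_strategy"]

_N_BLOCKS = 20


@dataclass(frozen=True)
class SimulationConfig:
    """Run configuration; ``n_steps`` counts strategy-update events."""

    params: ModelParams
    mu: float = 1e-3
    g_rep: int | None = None  # reputation events per strategy event; default 10*Z
    n_steps: int = 200_000
    burn_in: float = 0.1
    seed: int = 0
    sample_every: int = 0  # if > 0, record strategy counts every so many strategy events
    initial_strategy: str | None = None  # monomorphic start; default uniform random

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mutation rate mu must be in [0, 1], got {self.mu}")
        if self.g_rep is not None and self.g_rep < 1:
            raise ValueError(f"g_rep must be >= 1, got {self.g_rep}")
        if not 0.0 <= self.burn_in < 1.0:
            raise ValueError(f"burn_in must be a fraction in [0, 1), got {self.burn_in}")

    @property
    def resolved_g_rep(self) -> int:
        return self.g_rep if self.g_rep is not None else 10 * self.params.Z


@dataclass(frozen=True)
class SimulationSummary:
    """Time-averaged observables of one run (post burn-in)."""

    eta: float  # fraction of reputation events in which a donation occurred
    eta_stderr: float
    strategy_occupancy: np.ndarray  # mean frequency of each strategy, STRATEGY_ORDER
    good_fraction_by_strategy: np.ndarray  # occupancy-weighted Good fraction per strategy
    good_fraction: float
    n_strategy_events: int
    n_reputation_events: int
    trace: np.ndarray | None = None  # optional (n_samples, 4) strategy-count series
    n_blocks: int = _N_BLOCKS


@dataclass
class PopulationState:
    """Mutable population: per-individual strategy index (STRATEGY_ORDER) and
    reputation (True = Good)."""

    strategies: np.ndarray
    reputations: np.ndarray

    @classmethod
    def initial(cls, Z: int, rng: np.random.Generator) -> "PopulationState":
        # everyone starts Good; strategies uniformly random
        return cls(
            strategies=rng.integers(0, 4, size=Z).astype(np.int64),
            reputations=np.ones(Z, dtype=bool),
        )


def _effective_tables(params: ModelParams):
    """Per-strategy effective probabilities and the error-folded norm table."""
    p_eff = np.empty((4, 2))
    c_eff = np.empty((4, 2))  # (C_G, C_B) with chi folded, for exact payoffs
    for s, name in enumerate(STRATEGY_ORDER):
        pe = apply_execution_error(
            Strategy(*NAMED_STRATEGIES[name]),
            params.errors.epsilon,
            symmetric=params.symmetric_execution,
        )
        p_eff[s] = pe.as_tuple()
        c_eff[s] = cooperation_probs(pe, params.errors.chi)
    d_eff = np.array(apply_assignment_error(params.norm, params.errors.alpha).as_tuple())
    return p_eff, c_eff, d_eff


def step_reputation(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> bool:
    """One donation/reputation event, in place; returns whether a donation
    occurred.  Reference single-event implementation (the batch runner uses a
    compiled equivalent)."""
    Z = params.Z
    p_eff, _, d_eff = _effective_tables(params)
    donor = int(rng.integers(Z))
    recipient = int(rng.integers(Z - 1))
    if recipient >= donor:
        recipient += 1
    rep_true = bool(state.reputations[recipient])
    seen_by_donor = rep_true ^ (rng.random() < params.errors.chi)
    coop_prob = p_eff[state.strategies[donor], 0 if seen_by_donor else 1]
    donated = rng.random() < coop_prob
    seen_by_bystander = rep_true ^ (rng.random() < params.errors.chi)
    # norm table order: (G,C), (G,D), (B,C), (B,D)
    col = (0 if seen_by_bystander else 2) + (0 if donated else 1)
    state.reputations[donor] = rng.random() < d_eff[col]
    return bool(donated)


def _exact_payoff(
    idx: int, state: PopulationState, c_eff: np.ndarray, b: float, c: float
) -> float:
    Z = state.strategies.size
    s = state.strategies[idx]
    good_mask = state.reputations.copy()
    good_mask[idx] = False
    n_good_others = int(good_mask.sum())
    donate = (
        n_good_others * c_eff[s, 0] + (Z - 1 - n_good_others) * c_eff[s, 1]
    ) / (Z - 1)
    col = 0 if state.reputations[idx] else 1
    receive = 0.0
    for other_s in range(4):
        n_s = int((state.strategies == other_s).sum()) - (1 if other_s == s else 0)
        receive += n_s * c_eff[other_s, col]
    receive /= Z - 1
    return b * receive - c * donate


def step_strategy(
    state: PopulationState, params: ModelParams, mu: float, rng: np.random.Generator
) -> None:
    """One strategy-update event in place: exploration with probability mu,
    otherwise Fermi imitation of a random model using exact expected payoffs."""
    Z = params.Z
    learner = int(rng.integers(Z))
    if rng.random() < mu:
        state.strategies[learner] = rng.integers(4)
        return
    model = int(rng.integers(Z - 1))
    if model >= learner:
        model += 1
    _, c_eff, _ = _effective_tables(params)
    f_l = _exact_payoff(learner, state, c_eff, params.payoff.b, params.payoff.c)
    f_m = _exact_payoff(model, state, c_eff, params.payoff.b, params.payoff.c)
    if rng.random() < 1.0 / (1.0 + np.exp(-params.beta * (f_m - f_l))):
        state.strategies[learner] = state.strategies[model]


_BUF = 1 << 16


@njit(cache=True)
def _run_core(Z, b, c, beta, chi, mu, p_eff, c_eff, d_eff, g_rep, n_steps, burn_in_steps, seed, sample_every, init_strategy):  # pragma: no cover - compiled
    np.random.seed(seed)
    if init_strategy >= 0:
        strat = np.full(Z, init_strategy, dtype=np.int64)
    else:
        strat = np.random.randint(0, 4, Z)
    rep = np.ones(Z, dtype=np.bool_)
    n_s = np.zeros(4, dtype=np.int64)  # individuals per strategy
    g_s = np.zeros(4, dtype=np.int64)  # Good individuals per strategy
    for i in range(Z):
        n_s[strat[i]] += 1
        g_s[strat[i]] += 1

    measured = n_steps - burn_in_steps
    block = max(1, measured // _N_BLOCKS)
    block_don = np.zeros(_N_BLOCKS)
    block_events = np.zeros(_N_BLOCKS)
    occupancy = np.zeros(4)
    good_time = np.zeros(4)
    donations = 0
    rep_events = 0
    n_samples = n_steps // sample_every if sample_every > 0 else 0
    trace = np.zeros((n_samples, 4), dtype=np.int16)

    # uniforms are drawn from a refillable buffer (vectorized generation is
    # several times cheaper than per-call draws); at most 6 per event
    buf = np.random.random(_BUF)
    ptr = 0
    chi2 = chi * chi
    chi_hi = 2 * chi - chi2
    pairs = Z * (Z - 1)
    for step in range(n_steps):
        in_window = step >= burn_in_steps
        bi = min((step - burn_in_steps) // block, _N_BLOCKS - 1) if in_window else 0
        for _ in range(g_rep):
            if ptr > _BUF - 8:
                buf = np.random.random(_BUF)
                ptr = 0
            pair = int(buf[ptr] * pairs)
            ptr += 1
            donor = pair // (Z - 1)
            recipient = pair % (Z - 1)
            if recipient >= donor:
                recipient += 1
            rep_true = rep[recipient]
            # one uniform encodes the two independent Bernoulli(chi) misreads:
            # donor flip iff u < chi, bystander flip iff u < chi^2 or chi <= u < 2chi - chi^2
            u = buf[ptr]
            ptr += 1
            seen_donor = rep_true != (u < chi)
            flip_by = u < chi2 or (chi <= u < chi_hi)
            cp = p_eff[strat[donor], 0] if seen_donor else p_eff[strat[donor], 1]
            if cp <= 0.0:
                donated = False
            elif cp >= 1.0:
                donated = True
            else:
                donated = buf[ptr] < cp
                ptr += 1
            seen_by = rep_true != flip_by
            col = (0 if seen_by else 2) + (0 if donated else 1)
            new_rep = buf[ptr] < d_eff[col]
            ptr += 1
            if rep[donor] != new_rep:
                g_s[strat[donor]] += 1 if new_rep else -1
                rep[donor] = new_rep
            if in_window:
                rep_events += 1
                if donated:
                    donations += 1
                    block_don[bi] += 1.0
        if in_window:
            block_events[bi] += g_rep
            for s in range(4):
                occupancy[s] += n_s[s]
                good_time[s] += g_s[s]
        if sample_every > 0 and step % sample_every == 0 and step // sample_every < n_samples:
            for s in range(4):
                trace[step // sample_every, s] = np.int16(n_s[s])

        if ptr > _BUF - 8:
            buf = np.random.random(_BUF)
            ptr = 0
        learner = int(buf[ptr] * Z)
        ptr += 1
        if buf[ptr] < mu:
            ptr += 1
            new_s = int(buf[ptr] * 4)
            ptr += 1
            old_s = strat[learner]
            if new_s != old_s:
                n_s[old_s] -= 1
                n_s[new_s] += 1
                if rep[learner]:
                    g_s[old_s] -= 1
                    g_s[new_s] += 1
                strat[learner] = new_s
        else:
            ptr += 1
            model = int(buf[ptr] * (Z - 1))
            ptr += 1
            if model >= learner:
                model += 1
            if strat[model] != strat[learner]:
                n_good = np.int64(0)
                for i in range(Z):
                    if rep[i]:
                        n_good += 1
                f = np.zeros(2)
                who = (learner, model)
                for t in range(2):
                    idx = who[t]
                    s = strat[idx]
                    good_others = n_good - (1 if rep[idx] else 0)
                    donate = (good_others * c_eff[s, 0] + (Z - 1 - good_others) * c_eff[s, 1]) / (Z - 1)
                    col2 = 0 if rep[idx] else 1
                    receive = 0.0
                    for os in range(4):
                        cnt = n_s[os] - (1 if os == s else 0)
                        receive += cnt * c_eff[os, col2]
                    receive /= Z - 1
                    f[t] = b * receive - c * donate
                x = -beta * (f[1] - f[0])
                if x > 0:
                    fermi = np.exp(-x) / (1.0 + np.exp(-x))
                else:
                    fermi = 1.0 / (1.0 + np.exp(x))
                if buf[ptr] < fermi:
                    ptr += 1
                    old_s = strat[learner]
                    new_s = strat[model]
                    n_s[old_s] -= 1
                    n_s[new_s] += 1
                    if rep[learner]:
                        g_s[old_s] -= 1
                        g_s[new_s] += 1
                    strat[learner] = new_s
                else:
                    ptr += 1

    return donations, rep_events, block_don, block_events, occupancy, good_time, measured, trace


def run(config: SimulationConfig) -> SimulationSummary:
    """Run the simulation and return time-averaged observables.

    Deterministic given ``config.seed``.  Standard errors come from
    splitting the post-burn-in window into equal blocks.
    """
    params = config.params
    p_eff, c_eff, d_eff = _effective_tables(params)
    burn_in_steps = int(config.burn_in * config.n_steps)
    donations, rep_events, block_don, block_events, occupancy, good_time, measured, trace = _run_core(
        params.Z,
        params.payoff.b,
        params.payoff.c,
        params.beta,
        params.errors.chi,
        config.mu,
        p_eff,
        c_eff,
        d_eff,
        config.resolved_g_rep,
        config.n_steps,
        burn_in_steps,
        int(config.seed) % 2**31,
        config.sample_every,
        STRATEGY_ORDER.index(config.initial_strategy) if config.initial_strategy else -1,
    )
    eta = donations / rep_events if rep_events else 0.0
    rates = block_don[block_events > 0] / block_events[block_events > 0]
    stderr = float(rates.std(ddof=1) / np.sqrt(rates.size)) if rates.size > 1 else float("nan")
    occ = occupancy / (measured * params.Z)
    with np.errstate(invalid="ignore", divide="ignore"):
        good_by_s = np.where(occupancy > 0, good_time / occupancy, np.nan)
    return SimulationSummary(
        eta=float(eta),
        eta_stderr=stderr,
        strategy_occupancy=occ,
        good_fraction_by_strategy=good_by_s,
        good_fraction=float(good_time.sum() / (measured * params.Z)),
        n_strategy_events=measured,
        n_reputation_events=int(rep_events),
        trace=trace if config.sample_every > 0 else None,
    )
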