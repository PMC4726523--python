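"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: the chain sampler
re-draws events from the one-step probabilities instead of solving an
eigenproblem, and the fixation sampler simulates the birth-death walk
instead of evaluating the closed form.
"""

import numpy as np
from numba import njit

from irdyn.reputation import ReputationChain, birth_death_probs


def chain_occupancy(
    chain: ReputationChain, n_steps: int, seed: int, start: tuple[int, int] | None = None
) -> np.ndarray:
    """Empirical state occupancy of a direct Monte Carlo run of the chain."""
    Z, k = chain.Z, chain.k
    width = Z - k + 1
    probs = np.zeros(((k + 1) * width, 4))
    for h in range(k + 1):
        for hp in range(width):
            probs[h * width + hp] = birth_death_probs(
                h, hp, k, Z, chain.probs_p, chain.probs_pp
            )
    if start is None:
        start = (k, Z - k)
    return _walk(probs, width, start[0] * width + start[1], n_steps, seed)


@njit(cache=True)
def _walk(probs, width, state, n_steps, seed):  # pragma: no cover - compiled
    np.random.seed(seed)
    counts = np.zeros(probs.shape[0])
    for _ in range(n_steps):
        u = np.random.random()
        up_p, down_p, up_pp, down_pp = probs[state]
        if u < up_p:
            state += width
        elif u < up_p + down_p:
            state -= width
        elif u < up_p + down_p + up_pp:
            state += 1
        elif u < up_p + down_p + up_pp + down_pp:
            state -= 1
        counts[state] += 1.0
    return counts / n_steps


def sample_fixation(deltas: np.ndarray, beta: float, Z: int, n_runs: int, seed: int) -> float:
    """Empirical fixation frequency of a single mutant under the
    pairwise-comparison process, using the same per-k fitness differences.

    Simulates the embedded jump chain of the mutant count: from k the next
    move is up with probability F(+df)/(F(+df)+F(-df)) = F(+df), with F the
    Fermi probability (the selection-free pair-sampling factors cancel and
    F(+x)+F(-x)=1), which is the conditional jump law of the birth-death walk.
    """
    rng = np.random.default_rng(seed)
    p_up = np.zeros(Z + 1)
    p_up[1:Z] = 1.0 / (1.0 + np.exp(-beta * deltas))
    k = np.ones(n_runs, dtype=np.int64)
    active = np.ones(n_runs, dtype=bool)
    while active.any():
        u = rng.random(active.sum())
        ks = k[active]
        ks = np.where(u < p_up[ks], ks + 1, ks - 1)
        k[active] = ks
        active[active] = (ks > 0) & (ks < Z)
    return float((k == Z).mean())
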