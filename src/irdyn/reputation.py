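"""The two-dimensional Markov chain of reputations at fixed strategy counts.

With ``k`` individuals playing strategy p and ``Z-k`` playing p', and at most
one reputation updated per donation event, the numbers (h, h') of Good
individuals in the two camps form a Markov chain on the
``S = (k+1)(Z-k+1)`` states ``0 <= h <= k``, ``0 <= h' <= Z-k``.  Per event a
random donor meets a random distinct recipient and a bystander re-assigns the
donor's reputation, so h (or h') moves by at most one:

    H_p^+(h,h') = (k-h)/Z * [ (h+h')/(Z-1) G_G^p + (Z-h-h'-1)/(Z-1) G_B^p ]
    H_p^-(h,h') = h/Z     * [ (h+h'-1)/(Z-1) (1-G_G^p) + (Z-h-h')/(Z-1) (1-G_B^p) ]

with the p' expressions obtained by swapping k <-> Z-k, h <-> h', p <-> p'.
The residual probability is a lazy self-loop.  The stationary distribution
sigma solves sigma H = sigma; with all error rates strictly inside (0, 1) the
chain is irreducible and sigma is its unique, strictly positive stationary
law.  In error-free corner cases the chain can be reducible (e.g. an
absorbing all-Good state); the limiting distribution started from the
all-Good state is returned instead, matching the convention that everyone
starts with a Good reputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .strategies import InteractionProbs

__all__ = [
    "ReputationChain",
    "birth_death_probs",
    "build_transition_matrix",
    "stationary_distribution",
    "stationary_frame",
]

# Below this state count a dense representation is used for the solve.
_DENSE_CUTOFF = 200


@dataclass
class ReputationChain:
    """Reputation chain for a fixed composition (k strategists of p, Z-k of p')."""

    Z: int
    k: int
    probs_p: InteractionProbs
    probs_pp: InteractionProbs
    H: sp.csr_matrix = field(repr=False)

    @property
    def n_states(self) -> int:
        return (self.k + 1) * (self.Z - self.k + 1)

    def state_index(self, h: int, hp: int) -> int:
        """Linear index of state (h, h'): h*(Z-k+1) + h'."""
        if not (0 <= h <= self.k and 0 <= hp <= self.Z - self.k):
            raise ValueError(f"state ({h}, {hp}) out of bounds for Z={self.Z}, k={self.k}")
        return h * (self.Z - self.k + 1) + hp

    def state_of(self, index: int) -> tuple[int, int]:
        width = self.Z - self.k + 1
        return divmod(index, width)


def birth_death_probs(
    h: int,
    hp: int,
    k: int,
    Z: int,
    probs_p: InteractionProbs,
    probs_pp: InteractionProbs,
) -> tuple[float, float, float, float]:
    """One-event transition probabilities (H_p^+, H_p^-, H_p'^+, H_p'^-).

    H_p^+ is the probability that the event turns one Bad p-strategist Good
    (the donor is a Bad p-strategist and the bystander assigns Good), and
    H_p^- the reverse; primes refer to the p' camp.  Their sum is at most 1;
    the remainder is the probability that the reputation profile is unchanged.
    """
    if not (0 <= k <= Z and 0 <= h <= k and 0 <= hp <= Z - k):
        raise ValueError(f"state (h={h}, h'={hp}) out of bounds for Z={Z}, k={k}")

    def up(n_good_own: int, n_own: int, n_good_other: int, g: InteractionProbs) -> float:
        # a Bad member of this camp donates; recipient Good w.p. (h+h')/(Z-1)
        n_good = n_good_own + n_good_other
        return (n_own - n_good_own) / Z * (
            n_good / (Z - 1) * g.g_g + (Z - n_good - 1) / (Z - 1) * g.g_b
        )

    def down(n_good_own: int, n_own: int, n_good_other: int, g: InteractionProbs) -> float:
        if n_good_own == 0:
            return 0.0
        n_good = n_good_own + n_good_other
        return n_good_own / Z * (
            (n_good - 1) / (Z - 1) * (1 - g.g_g) + (Z - n_good) / (Z - 1) * (1 - g.g_b)
        )

    return (
        up(h, k, hp, probs_p),
        down(h, k, hp, probs_p),
        up(hp, Z - k, h, probs_pp),
        down(hp, Z - k, h, probs_pp),
    )


def build_transition_matrix(
    k: int,
    Z: int,
    probs_p: InteractionProbs,
    probs_pp: InteractionProbs,
) -> ReputationChain:
    """Assemble the sparse row-stochastic transition matrix H over the
    (h, h') grid; at most five nonzeros per row (the four +-1 moves and the
    lazy self-loop)."""
    if not 0 <= k <= Z or Z < 2:
        raise ValueError(f"need Z >= 2 and 0 <= k <= Z, got Z={Z}, k={k}")
    width = Z - k + 1
    S = (k + 1) * width
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for h in range(k + 1):
        for hp in range(width):
            i = h * width + hp
            up_p, down_p, up_pp, down_pp = birth_death_probs(h, hp, k, Z, probs_p, probs_pp)
            stay = 1.0 - up_p - down_p - up_pp - down_pp
            for j, v in (
                (i + width, up_p),
                (i - width, down_p),
                (i + 1, up_pp),
                (i - 1, down_pp),
                (i, stay),
            ):
                if v != 0.0:
                    rows.append(i)
                    cols.append(j)
                    vals.append(v)
    H = sp.csr_matrix((vals, (rows, cols)), shape=(S, S))
    return ReputationChain(Z=Z, k=k, probs_p=probs_p, probs_pp=probs_pp, H=H)


def _possibly_reducible(chain: ReputationChain) -> bool:
    # exact 0/1 assignment probabilities can create absorbing boundary states
    g = (chain.probs_p.g_g, chain.probs_p.g_b, chain.probs_pp.g_g, chain.probs_pp.g_b)
    return any(v in (0.0, 1.0) for v in g)


def _limit_from_all_good(chain: ReputationChain, tol: float, max_iter: int) -> np.ndarray:
    """Limiting distribution started from (h, h') = (k, Z-k).

    For small chains the limit is reached by repeated squaring of H
    (H^(2^m), double-exponential convergence); larger chains fall back to
    plain power iteration.
    """
    S = chain.n_states
    start = chain.state_index(chain.k, chain.Z - chain.k)
    if S < _DENSE_CUTOFF:
        M = chain.H.toarray()
        for _ in range(60):
            M2 = M @ M
            if np.abs(M2 - M).max() < tol:
                M = M2
                break
            M = M2
        sigma = M[start]
    else:
        sigma = np.zeros(S)
        sigma[start] = 1.0
        Ht = chain.H.T.tocsr()
        for it in range(max_iter):
            nxt = Ht @ sigma
            if np.abs(nxt - sigma).sum() < tol:
                sigma = nxt
                break
            sigma = nxt
        else:
            raise RuntimeError(
                f"power iteration did not converge after {max_iter} iterations "
                f"(Z={chain.Z}, k={chain.k})"
            )
    return _clean(sigma)


def _clean(sigma: np.ndarray) -> np.ndarray:
    if sigma.min() < -1e-9:
        raise RuntimeError(f"stationary solve produced negative mass ({sigma.min():.3e})")
    sigma = np.clip(sigma, 0.0, None)
    return sigma / sigma.sum()


def stationary_distribution(
    chain: ReputationChain,
    tol: float = 1e-12,
    max_iter: int = 2_000_000,
) -> np.ndarray:
    """Stationary distribution sigma of the reputation chain (sigma H = sigma).

    Solves the linear system (H^T - I) sigma = 0 with a normalization row;
    when the chain may be reducible (an interaction probability exactly 0 or
    1) the limiting distribution from the all-Good state is computed instead.
    """
    if _possibly_reducible(chain):
        return _limit_from_all_good(chain, tol, max_iter)

    S = chain.n_states
    if S < _DENSE_CUTOFF:
        A = chain.H.toarray().T - np.eye(S)
        A[-1, :] = 1.0
        rhs = np.zeros(S)
        rhs[-1] = 1.0
        sigma = _clean(np.linalg.solve(A, rhs))
    else:
        try:
            sigma = _clean(_banded_pinned_solve(chain))
        except RuntimeError:
            sigma = None
    residual = np.inf if sigma is None else np.abs(sigma @ chain.H - sigma).max()
    if residual > 1e-10:
        # pinned solve was ill-conditioned here; use the ones-row sparse solve
        A = (chain.H.T - sp.identity(S, format="csr")).tolil()
        A[-1, :] = 1.0
        rhs = np.zeros(S)
        rhs[-1] = 1.0
        sigma = _clean(spla.spsolve(A.tocsc(), rhs))
        residual = np.abs(sigma @ chain.H - sigma).max()
        if residual > 1e-10:
            return _limit_from_all_good(chain, tol, max_iter)
    return sigma


def _banded_pinned_solve(chain: ReputationChain, n_warm: int = 200) -> np.ndarray:
    """Solve sigma (H - I) = 0 exploiting the banded structure.

    States couple only to index offsets {0, +-1, +-(Z-k+1)}, so H^T - I is
    banded with bandwidth Z-k+1.  The singular system is made definite by
    pinning sigma at one high-mass state (located by a short power
    iteration) to 1 and deleting that row and column, which preserves the
    band; pinning near the mode keeps the relative scale of the unknowns
    moderate and the solve numerically accurate.
    """
    S = chain.n_states
    width = chain.Z - chain.k + 1
    Ht = chain.H.T.tocsr()
    est = np.full(S, 1.0 / S)
    for _ in range(n_warm):
        est = Ht @ est
    pin = int(np.argmax(est))

    coo = chain.H.tocoo()
    i, j, v = coo.col, coo.row, coo.data  # A[i, j] = H[j, i] - delta_ij
    keep = (i != pin) & (j != pin)
    ikeep = i[keep] - (i[keep] > pin)
    jkeep = j[keep] - (j[keep] > pin)
    ab = np.zeros((2 * width + 1, S - 1))
    np.add.at(ab, (width + ikeep - jkeep, jkeep), v[keep])
    ab[width, :] -= 1.0
    rhs = np.zeros(S - 1)
    m = (j == pin) & (i != pin)
    np.subtract.at(rhs, i[m] - (i[m] > pin), v[m])
    y = sla.solve_banded((width, width), ab, rhs)
    return np.insert(y, pin, 1.0)


def stationary_frame(chain: ReputationChain, sigma: np.ndarray) -> pd.DataFrame:
    """Tabulate sigma as columns (h, h_prime, probability), e.g. for heat maps."""
    width = chain.Z - chain.k + 1
    idx = np.arange(chain.n_states)
    return pd.DataFrame(
        {"h": idx // width, "h_prime": idx % width, "probability": sigma}
    )
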