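# Methods

`irdyn` models the evolution of cooperation through indirect reciprocity in
a finite, well-mixed population of `Z` individuals playing the donation
game: a donor may pay a cost `c` to confer a benefit `b > c` on a
recipient.  Every individual carries a public binary reputation (Good or
Bad) and a behavioral rule `p = (p_G, p_B)` — the probability of
cooperating with an opponent perceived as Good or Bad.  The four pure rules
are AllC, AllD, the discriminator Disc = (1,0) and the paradoxical
discriminator pDisc = (0,1).  Reputations are updated by bystanders
applying a shared second-order social norm `d = (d_GC, d_GD, d_BC, d_BD)`:
the probability of assigning Good given the donor's action and the
recipient's reputation.

## Error model

Three independent error channels perturb the dynamics, with defaults from
the baseline study conditions:

| symbol  | meaning                                       | default | range    |
|---------|-----------------------------------------------|---------|----------|
| epsilon | execution error: intended donation fails      | 0.08    | [0, 1]   |
| alpha   | assignment error: bystander records opposite  | 0.01    | [0, 0.5] |
| chi     | private assessment error: reputation misread  | 0.01    | [0, 1]   |

Execution errors are one-sided by default (`p -> (1-eps)p`): failed intended
cooperation, never spontaneous cooperation.  A symmetric variant
(`symmetric_execution=True`) flips the realized action with probability
epsilon instead.  The assignment error is folded into the norm
(`d -> (1-2a)d + a`), which is why alpha is capped at 0.5 — beyond that the
transform would invert the norm's meaning.  Private assessment errors are
drawn independently for the donor and the bystander at every encounter.

## Reputation dynamics

For a fixed composition (`k` users of `p`, `Z-k` of `p'`), the Good counts
`(h, h')` follow a Markov chain over `S = (k+1)(Z-k+1)` states in which one
donation event updates one donor's reputation.  The one-event transition
probabilities combine the chance of drawing a donor of each camp and
reputation with the effective Good-assignment probabilities `G_G, G_B`
(action probability composed with the error-folded norm).  The stationary
distribution solves `sigma H = sigma`.

Numerically, states couple only at index offsets `{0, +-1, +-(Z-k+1)}`, so
`H^T - I` is banded.  For `S >= 200` the singular system is solved by
pinning `sigma` at a high-mass state — located by a 200-step power
iteration — to 1 and deleting that row and column, which preserves the band
and keeps the unknowns well scaled; an invariance residual above `1e-10`
triggers a fallback to a sparse direct solve with an explicit normalization
row.  Smaller systems use a dense solve.  When any effective probability is
exactly 0 or 1 the chain can be reducible (absorbing all-Good or all-Bad
states in error-free limits); the limiting distribution from the all-Good
start — everyone begins Good — is then computed by repeated squaring of `H`
(dense, `S < 200`) or power iteration to `1e-12`.

## Fitness and strategy evolution

The one-interaction payoff at state `(h, h')` is
`f_p = b R_p - c D_p`, with `R_p` the probability of receiving a donation
(the focal is Good with probability `h/k`; co-players exclude the focal)
and `D_p` the probability of donating.  Fitness is the expectation of `f_p`
under `sigma`, taken over the full inclusive grid `0 <= h <= k`,
`0 <= h' <= Z-k` — the entire support of the stationary law; in
near-absorbing regimes most mass sits exactly on the boundary states.

Strategies evolve by pairwise-comparison imitation: a learner copies a
model with the Fermi probability `1/(1 + exp(-beta * delta_f))`, with
selection strength `beta` (default 1).  In the small-mutation limit the
dynamics reduce to the embedded chain over the four monomorphic states with
transitions `rho_{i->j}/3`, where the fixation probability of a single
mutant has the standard closed form with the fitness difference
re-evaluated at every intermediate composition via the reputation chain.
The product over compositions is accumulated in log space (stable for beta
up to at least 10), and the neutral case `beta = 0` returns `1/Z` exactly.
Only the 6 unordered strategy pairs are solved; the reversed profile
follows from `delta_f_{p',p}(k) = -delta_f_{p,p'}(Z-k)`.

The cooperation index `eta` weights the stationary donation rate of each
monomorphic state (its one-dimensional reputation chain at `k = Z`) by the
embedded chain's stationary distribution `lambda`.  The transition-graph
export draws an edge `i -> j` when `rho_{i->j}` strictly exceeds the
neutral value `1/Z`, with weights `rho * Z`.

Design choices worth noting: monomorphic states are ordered
(AllC, AllD, Disc, pDisc) everywhere; mirror symmetry (relabelling
Good/Bad, which maps Disc onto pDisc) leaves `eta` invariant and is used as
an end-to-end correctness check rather than to halve the computation.

## Agent-based simulator

The simulator drops both analytic approximations: all four strategies
co-evolve at a finite exploration rate `mu` (a learner adopts a uniformly
random rule with probability `mu` per imitation event), and each imitation
event is preceded by `g_rep` donation events (default `10 Z`, which gives
every individual several reputation updates between composition changes —
roughly the `Z ln Z` events the chain needs to re-equilibrate).  Imitation
compares exact expected payoffs given the current configuration, the same
`R`/`D` expressions the analytic model uses, because that is the quantity
the Fermi rule compares in the derivation; one-shot sampled payoffs would
only add noise with no compensating realism at this level of abstraction.
Populations start all-Good with uniformly random strategies (or a chosen
monomorphic state).  All randomness flows from one integer seed; outputs
are bit-reproducible.  The donation rate is reported with a standard error
from 20 equal post-burn-in blocks.

The inner loop is compiled (numba) and consumes uniforms from a refilled
buffer; at `Z = 50` it sustains roughly `2x10^7` donation events per second
on one core.

### What the simulator does and does not emulate

It reproduces the full stochastic co-evolution of reputations and
strategies under the model's assumptions: public, instantly disseminated
reputations; a single shared norm; well-mixed interactions.  It does not
model private opinion lists, gossip dynamics, structured populations, or
payoff accumulation across named rounds — conclusions about real societies
inherit those idealizations.

### Convergence and problem sizes

Validation runs at `Z = 50`, `mu = 1e-3` are limited by basin mixing of the
monomorphic states, not by per-state noise.  Transitions require a rare
single-mutant fixation (probabilities of order `0.003`), so basin switches
occur every ~10^5–10^6 imitation events depending on the norm.  Two knobs
matter:

* **Time-scale separation.**  When the stationary strategy mix balances
  two nearly-neutral fixation routes (shunning, image scoring, simple
  standing), small biases in fixation probabilities shift the basin
  balance strongly; `g_rep = 10 Z` lets reputations lag during invasions
  and measurably over-weights the defector basin (under shunning the
  simulated donation rate drops to ~0.03 against an analytic 0.07), while
  `g_rep = 40 Z` restores agreement to three decimals.  Validation runs for
  those norms therefore use `40 Z`; stern judging's two discriminator
  basins donate at the same rate by symmetry, so its index is insensitive
  and the default suffices.
* **Run length.**  The test suite sizes each run from the mixing analysis:
  stern judging needs only to leave the defector basin once; shunning and
  image scoring alternate on ~10^5-event scales; simple standing
  alternates between unconditional defection and discrimination — basins
  donating at 0 versus ~0.8 — on a ~10^6-event scale, so a converged
  stationary average for it needs on the order of 10^8 imitation events,
  beyond what the bundled tests run.  At test-sized runs the simple
  standing estimate reflects whichever basin the run occupies and its
  consistency check is expected to fail; the other three norms agree with
  the analytic index to well within 0.05.

## Known limitations

* The analytic pipeline is exact only in the double limit of rare mutations
  and separated time scales; finite-`mu` corrections shift the stationary
  strategy mix most where competing fixation probabilities are close (e.g.
  simple standing's defector/discriminator balance).
* The evolutionary state space is restricted to the four pure rules;
  probabilistic rules are supported by the types but not enumerated.
* Third-order norms (conditioning on the donor's own prior reputation) are
  out of scope.
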