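# Methods

This note documents the model implemented by `collrep`, its conventions and
defaults, the design choices made where the design was genuinely open, and
what the reduced problem sizes used by the test suite and the acceptance
script do and do not establish.

## Reputation dynamics

**State.** An N×N binary image matrix `M`; `M[i,j] = 1` iff player `i`
currently considers `j` good. Opinions are private: rows evolve
independently. Self-opinion `M[i,i]` exists and serves as the donor's own
reputation `r_a` when acting. ALLC rows are pinned all-good and ALLD rows
all-bad: these players act unconditionally, so their opinions never feed
back into behaviour, and pinning implements the convention that ALLC
considers everyone good and ALLD everyone bad.

**Round.** `k` of `N` players are sampled uniformly without replacement.
Each member `i`, viewed as a donor, evaluates its recipient group
`G(i) = G \ {i}` by the collective-reputation threshold: good iff
`Σ_{j∈G(i)} M[i,j] ≥ lam_i · (k-1)`. The comparison is inclusive and made on
the raw integer count; a tolerance of 1e-9 is subtracted from the threshold
so that a boundary that is exact in real arithmetic (e.g. 7 good of 9 at
`lam = 0.7`) is not broken by the binary representation of one-decimal
criteria. A singleton recipient group reduces to the individual opinion for
every `lam ∈ (0, 1]`, recovering pairwise-game reputation dynamics. The
donor then acts by its norm's action rule on `(M[i,i], group reputation)`.

**Payoffs.** `pi_C = R c n_C / k − c`, `pi_D = R c n_C / k`; with the
group-size-scaled parameterisation `R = alpha·k` a participant's payoff is
`alpha·c·n_C − c·(own contribution)`. Payoffs never influence the reputation
dynamics; this separation is exploited throughout (see *Composition
statistics*).

**Observation and update.** Group members always learn the actions in their
round; each outsider observes the whole round with probability `q` (one
Bernoulli draw per observer per round — "observes the game" is treated as
round-level, not per-donor). An observed action other than the observer's
own is misperceived (C and D swapped) independently per (observer, donor)
pair with probability `eps`. By default misperception applies only to
out-group observers: participants learn each other's actions exactly. This
was a genuinely open reading — "learning" an action in one's own game versus
"observing" from outside — and the error-free in-group convention both fits
that distinction and reproduces the reference behaviours slightly better;
`SimParams(in_group_errors=True)` selects the alternative. The observer's
own action is always perceived without error.

Updates are synchronous: every assessment in a round reads the pre-round
matrix, and all updated opinions (each observer's opinion of each of the `k`
donors, via the observer's assessment rule on its *own* prior opinion of the
donor, its *own* view of `G(i)`, and the perceived action) are applied
simultaneously. Donors self-assess error-free, so `M[i,i]` stays meaningful.

**Initialisation and averaging.** The matrix starts all-good (benign
standard start; configurable). Statistics — per-strategy cooperation
frequency, participant-conditioned mean cooperator count, and the
(observer strategy × target strategy) matrix of good-reputation
proportions, diagonal blocks included — are averaged over post-burn-in
rounds; burn-in defaults to the first 10% of rounds and is configurable
down to 0.

**Engines and reproducibility.** A numba kernel and a pure-Python reference
implement the identical process, consuming random draws from the same
`numpy.random.Generator` in a documented order (group sampling by partial
Fisher–Yates; observation draws in player-index order; misperception draws
in sampled-group order; draws are consumed by every observer, including
pinned ALLC/ALLD rows, whether or not the result is used). Trajectories are
bit-identical across engines, which the tests check against an additional
independently written loop oracle. Every sweep derives per-cell seeds from
the master seed via `SeedSequence`, so results are independent of execution
order.

## Evolutionary layer

**Timescale separation.** Strategy change is far slower than opinion
change, so expected per-game payoffs are taken from reputation-dynamics
simulations run to quasi-stationarity at each fixed population composition
(`m` mutants vs `N−m` residents, `m = 1..N−1`).

**Composition statistics.** Because actions never depend on payoffs, the
simulation records payoff-free moments — each strategy's cooperation
frequency and its participant-conditioned mean cooperator count — from
which the mean per-game payoff under any `alpha` follows as
`pi = alpha·c·(mean n_C) − c·(cooperation frequency)`. One set of
simulations per (strategy pair, criterion) therefore serves an entire
`alpha` grid, and the mirrored pair (resident as mutant) reuses the same
runs. Payoffs are per game, i.e. conditional on participation: the
participation rate `k/N` is composition-independent, so including idle
rounds would only rescale the selection strength; the per-game convention
reproduces the reference fixation behaviours at `s = 1`. For the ALLC/ALLD
pair both strategies act unconditionally, so the moments are computed
exactly from the hypergeometric group-sampling distribution instead of by
Monte Carlo (a test cross-checks simulation against this closed form).

**Imitation and fixation.** Pairwise Fermi imitation
`P(pi_i, pi_j) = 1/(1+exp(−s(pi_j − pi_i)))` induces a birth–death chain
whose single-mutant fixation probability has the standard closed form

```
rho = [ 1 + Σ_{m=1}^{N-1} Π_{l=1}^{m} exp(−s (pi_mut(l) − pi_res(l))) ]^{-1}
```

evaluated in log space (`logsumexp`) so extreme `s·Δ` cannot overflow. A
payoff-neutral mutant fixes with probability exactly `1/N`. The closed form
is validated in tests against a direct stochastic simulation of the
imitation process.

**Rare-mutation equilibrium.** With vanishing mutation rate the population
occupies homogeneous states; a mutant of each other state arises with equal
probability and fixates or goes extinct before the next mutation. The
embedded chain has off-diagonals `T[i→j] = rho(j into i)/(n_states−1)`; its
stationary distribution (unique left fixed vector, computed by a
least-squares solve with an explicit strong-connectivity check) is the
selection–mutation equilibrium. The equilibrium cooperation rate is the
abundance-weighted average of homogeneous-state cooperation frequencies
(ALLC ≡ 1, ALLD ≡ 0, leading-eight states simulated per criterion).

**Critical payoff parameter.** Under hypergeometric group sampling with
`R = alpha·k`, a focal cooperator's expected per-game payoff minus a focal
defector's is `alpha·c·(N−k)/(N−1) − c` at every ALLC/ALLD composition,
giving `alpha_c = (N−1)/(N−k)` — 1.18 at the baseline N=60, k=10. Tests
verify the closed form against brute-force hypergeometric expectations and
the sign flip of simulated payoff gaps.

**Optimal criterion.** The criterion most conducive to cooperation in
social dilemmas is operationalised on a phase grid as the `lam` minimising
the smallest `alpha` whose equilibrium cooperation rate reaches a threshold
(default one half, configurable; ties break toward the smaller criterion;
undefined if no criterion cooperates below `alpha_c`). The threshold is a
modelling choice — "maintaining cooperation" has no canonical numeric
definition — and results near the boundary are sensitive to it.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `N` | 60 | population size |
| `k` | 10 | group size (recipient groups have k−1 = 9 members) |
| `c` | 1 | contribution cost (payoff unit) |
| `alpha` | — | payoff parameter, `R = alpha·k`; `alpha_c = 59/50 = 1.18` |
| `q` | 0.9 | out-group observation probability |
| `eps` | 0.05 | misperception probability |
| `s` | 1 | selection strength of Fermi imitation |
| `mu` | → 0 | mutation rate (rare-mutation embedded chain) |
| `lam` | per player | group assessment criterion in (0, 1] |

These defaults are the baseline conditions of the analyses the package
reproduces; the criterion-evolution scenarios use the three states
`lam ∈ {0.1, 0.4, 0.7}`.

## Problem sizes

Full-resolution runs (`--preset paper`) use 2×10⁵ reputation rounds per
experiment or composition and 50 replicates. The test suite and the
acceptance script use desk-scale sizes chosen so the whole pipeline runs in
minutes on one core: 2×10⁴ rounds × 10 replicates for reputation scenarios,
2×10⁴ rounds per composition for fixation probabilities, 10⁴ rounds per
composition with `alpha` grid step 0.1 and `lam` grid {0.1, 0.3, 0.5, 0.7,
0.9} for phase grids. At these sizes reputation statistics are stable to a
few percent; equilibrium cooperation rates inherit more noise because
fixation probabilities depend exponentially on accumulated payoff gaps, so
phase-boundary cells can move by one grid step between seeds.

## What the simulations do and do not show

The generator *is* the model: all inputs are configuration, there is no
external data. Passing tests show that the implementation realises this
model faithfully (engine ≡ independent oracle bit for bit; closed forms
verified) and that the model at baseline parameters reproduces the headline
phenomena: reputation laundering of unconditional defectors under strict
criteria, a cooperation pocket below `alpha_c` at moderate criteria, ALLC
dominance in strict high-payoff societies, and strict-criterion dominance
at low payoffs for the norms that punish cooperation with the bad. They do
not show anything about populations with network or group structure,
persistent group membership, non-binary reputations, or continuous
criterion evolution, none of which are modelled.

## Known limitations

- Equilibrium quantities near phase boundaries are Monte-Carlo noisy at
  desk scale (see above); boundary positions quoted to one grid step.
- For the norms whose homogeneous populations collapse under strict
  criteria (notably L2 and L8 beyond `lam ≈ 0.65`), the low-payoff
  cooperation pocket is narrow in `lam` and its peak equilibrium
  cooperation rate stays below one half on coarse grids: the embedded chain
  then describes co-existence with ALLD rather than dominance. Finer `lam`
  resolution changes the picture only marginally.
- The embedded-chain treatment assumes strict timescale separation; the
  direct agent-based evolution routine is provided for finite mutation
  rates but is far slower and used mainly as an oracle.
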