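"""Evolutionary layer: imitation dynamics on top of the reputation dynamics.

Strategy change happens on a much slower timescale than opinion change, so
expected per-game payoffs at each mixed population composition are estimated
by running the reputation dynamics to (quasi-)stationarity, and the
evolutionary process is then treated analytically:

* pairwise imitation with the Fermi rule ``P = 1/(1 + exp(-s (pi_j - pi_i)))``;
* the closed-form fixation probability of the resulting birth–death chain;
* in the rare-mutation limit, an embedded Markov chain over homogeneous
  states whose stationary distribution is the selection–mutation equilibrium;
* the critical payoff parameter ``alpha_c = (N-1)/(N-k)`` at which a
  cooperator's and a defector's expected per-game payoffs coincide under
  hypergeometric group sampling with ``R(k) = alpha*k``;
* an operational optimal criterion ``lambda_c`` read off an (alpha, lambda)
  phase grid.

Because actions depend only on reputations, the reputation dynamics are
independent of the payoff parameters; composition statistics are therefore
collected once per strategy pair (as :class:`CompositionMoments`) and turned
into payoffs for any ``alpha`` afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

from .dynamics import SimParams, simulate_reputation_dynamics
from .norms import Player

__all__ = [
    "EvoParams",
    "CompositionMoments",
    "CompositionPayoffs",
    "FixationResult",
    "TransitionMatrix",
    "EquilibriumResult",
    "fermi_prob",
    "composition_moments",
    "unconditional_composition_moments",
    "composition_payoffs",
    "fixation_probability",
    "embedded_chain",
    "stationary_distribution",
    "equilibrium_cooperation_rate",
    "selection_mutation_equilibrium",
    "critical_alpha",
    "find_lambda_c",
    "agent_based_evolution",
]

Label = Tuple[str, float]


@dataclass(frozen=True)
class EvoParams:
    """Evolutionary-process configuration.

    ``comp_steps`` is the number of reputation-dynamics rounds run per
    population composition when estimating expected payoffs; ``reps``
    replicates are averaged (replicate r shifts the seed stream).
    """

    s: float = 1.0
    mu: float = 0.0
    comp_steps: int = 20_000
    reps: int = 1
    burn_in: float = 0.1

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError(f"selection strength s must be >= 0, got {self.s}")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mutation rate mu must lie in [0, 1], got {self.mu}")


def fermi_prob(pi_i: float, pi_j: float, s: float) -> float:
    """Probability that player i imitates role model j (Fermi rule)."""
    if s < 0:
        raise ValueError(f"selection strength must be >= 0, got {s}")
    # expit form is overflow-safe for large |s * (pi_j - pi_i)|
    x = s * (pi_j - pi_i)
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    ex = np.exp(x)
    return ex / (1.0 + ex)


@dataclass
class CompositionMoments:
    """Payoff-free composition statistics for a mutant/resident pair.

    For every mutant count ``m = 1..N-1``: the mean number of cooperators in
    games a focal player participated in (``nc_mut``/``nc_res``) and that
    player's own cooperation frequency (``act_mut``/``act_res``).  The mean
    per-game payoff of a focal player under ``R = alpha*k`` is then
    ``pi = alpha*c*nc_mean - c*act_mean`` for any ``alpha``.
    """

    mutant: Label
    resident: Label
    N: int
    k: int
    nc_mut: np.ndarray
    act_mut: np.ndarray
    nc_res: np.ndarray
    act_res: np.ndarray

    def payoffs(self, alpha: float, c: float = 1.0) -> "CompositionPayoffs":
        return CompositionPayoffs(
            mutant=self.mutant,
            resident=self.resident,
            N=self.N,
            pi_mut=alpha * c * self.nc_mut - c * self.act_mut,
            pi_res=alpha * c * self.nc_res - c * self.act_res,
        )


@dataclass
class CompositionPayoffs:
    """Expected per-game payoffs at every mixed composition m = 1..N-1."""

    mutant: Label
    resident: Label
    N: int
    pi_mut: np.ndarray
    pi_res: np.ndarray

    def __post_init__(self) -> None:
        if len(self.pi_mut) != self.N - 1 or len(self.pi_res) != self.N - 1:
            raise ValueError("payoff arrays must cover m = 1..N-1")


@dataclass(frozen=True)
class FixationResult:
    rho: float
    direction: Tuple[Label, Label]  # (mutant, resident)

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"fixation probability out of [0,1]: {self.rho}")


def composition_moments(
    mutant: Player,
    resident: Player,
    params: SimParams,
    *,
    evo: Optional[EvoParams] = None,
    seed: Optional[int] = None,
    engine: str = "numba",
) -> CompositionMoments:
    """Estimate composition statistics by simulating every mixture.

    For each mutant count ``m`` the reputation dynamics of ``m`` mutants and
    ``N-m`` residents run for ``evo.comp_steps`` rounds (times ``evo.reps``
    replicates, averaged).  Each (m, replicate) cell uses an independent
    stream derived from ``seed`` so results do not depend on execution order.
    """
    if mutant.label == resident.label:
        raise ValueError("mutant and resident must be distinct (strategy, lam) states")
    evo = evo or EvoParams(comp_steps=params.steps, burn_in=params.burn_in)
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    N = params.N
    nc_mut = np.empty(N - 1)
    act_mut = np.empty(N - 1)
    nc_res = np.empty(N - 1)
    act_res = np.empty(N - 1)
    run_params = SimParams(
        N=N, k=params.k, c=params.c, alpha=params.alpha, R=params.R,
        q=params.q, eps=params.eps, steps=evo.comp_steps, burn_in=evo.burn_in,
    )
    for m in range(1, N):
        players = [mutant] * m + [resident] * (N - m)
        nc_m = act_m = nc_r = act_r = 0.0
        for r in range(evo.reps):
            rng_seed = np.random.SeedSequence([seed, m, r])
            stats = simulate_reputation_dynamics(
                players, run_params, engine=engine, seed=rng_seed
            )
            nc_m += stats.nc_mean[mutant.label]
            act_m += stats.coop_freq[mutant.label]
            nc_r += stats.nc_mean[resident.label]
            act_r += stats.coop_freq[resident.label]
        nc_mut[m - 1] = nc_m / evo.reps
        act_mut[m - 1] = act_m / evo.reps
        nc_res[m - 1] = nc_r / evo.reps
        act_res[m - 1] = act_r / evo.reps
    return CompositionMoments(
        mutant=mutant.label, resident=resident.label, N=N, k=params.k,
        nc_mut=nc_mut, act_mut=act_mut, nc_res=nc_res, act_res=act_res,
    )


def unconditional_composition_moments(N: int, k: int) -> CompositionMoments:
    """Exact ALLC-mutant / ALLD-resident composition statistics.

    Both strategies act independently of reputations, so the cooperator count
    in a group is hypergeometric and the expectations are closed-form: a
    focal cooperator at composition m sees ``1 + (k-1)(m-1)/(N-1)``
    cooperators on average, a focal defector ``(k-1) m / (N-1)``.
    """
    m = np.arange(1, N, dtype=float)
    return CompositionMoments(
        mutant=("ALLC", 1.0), resident=("ALLD", 1.0), N=N, k=k,
        nc_mut=1.0 + (k - 1) * (m - 1) / (N - 1),
        act_mut=np.ones(N - 1),
        nc_res=(k - 1) * m / (N - 1),
        act_res=np.zeros(N - 1),
    )


def composition_payoffs(
    mutant: Player,
    resident: Player,
    params: SimParams,
    *,
    evo: Optional[EvoParams] = None,
    seed: Optional[int] = None,
    engine: str = "numba",
) -> CompositionPayoffs:
    """Simulated expected per-game payoffs at every composition.

    Requires ``params`` to carry a payoff parameterisation (``alpha`` or
    ``R``).  Convenience wrapper over :func:`composition_moments`.
    """
    moments = composition_moments(
        mutant, resident, params, evo=evo, seed=seed, engine=engine
    )
    alpha = params.alpha if params.alpha is not None else params.synergy / params.k
    return moments.payoffs(alpha, params.c)


def fixation_probability(cp: CompositionPayoffs, s: float, N: Optional[int] = None) -> FixationResult:
    """Fixation probability of a single mutant under pairwise imitation.

    Standard closed form for the birth–death chain induced by Fermi
    imitation:

        rho = [1 + sum_{m=1}^{N-1} prod_{l=1}^{m} exp(-s (pi_mut(l) - pi_res(l)))]^{-1}

    evaluated in log space so large ``s * delta`` cannot overflow.
    A payoff-neutral mutant has rho = 1/N exactly.
    """
    if s < 0:
        raise ValueError(f"selection strength must be >= 0, got {s}")
    if N is None:
        N = cp.N
    if N != cp.N:
        raise ValueError(f"N={N} does not match payoff table N={cp.N}")
    log_terms = np.concatenate(
        [[0.0], np.cumsum(-s * (cp.pi_mut - cp.pi_res))]
    )
    rho = float(np.exp(-logsumexp(log_terms)))
    return FixationResult(rho=rho, direction=(cp.mutant, cp.resident))


@dataclass
class TransitionMatrix:
    """Embedded Markov chain over homogeneous population states."""

    states: List[Label]
    probs: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.states)
        if self.probs.shape != (n, n):
            raise ValueError("transition matrix shape mismatch")
        if (self.probs < -1e-12).any():
            raise ValueError("negative transition probability")
        if not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValueError("rows of the transition matrix must sum to 1")


def embedded_chain(
    states: Sequence[Label],
    fixation: Dict[Tuple[Label, Label], float],
) -> TransitionMatrix:
    """Rare-mutation embedded chain from pairwise fixation probabilities.

    In the rare-mutation limit the population hops between homogeneous
    states: from resident state i, a mutant of each other state j arises
    with equal probability ``1/(n-1)`` and fixates with probability
    ``fixation[(j, i)]``.
    """
    states = list(states)
    n = len(states)
    if n < 2:
        raise ValueError("need at least two homogeneous states")
    T = np.zeros((n, n))
    for i, res in enumerate(states):
        for j, mut in enumerate(states):
            if i == j:
                continue
            T[i, j] = fixation[(mut, res)] / (n - 1)
        T[i, i] = 1.0 - T[i].sum()
    return TransitionMatrix(states=states, probs=T)


def stationary_distribution(T: TransitionMatrix) -> np.ndarray:
    """Unique left fixed vector of an irreducible row-stochastic matrix."""
    P = T.probs
    n = P.shape[0]
    off = P.copy()
    np.fill_diagonal(off, 0.0)
    n_comp, _ = connected_components(off > 0, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError(
            f"embedded chain is reducible ({n_comp} strongly connected "
            "components); stationary distribution is not unique"
        )
    # Solve v (P - I) = 0 with sum(v) = 1 as an overdetermined linear system.
    A = np.vstack([(P - np.eye(n)).T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    v, *_ = np.linalg.lstsq(A, b, rcond=None)
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def equilibrium_cooperation_rate(
    abundance: np.ndarray, coop_rates: Sequence[float]
) -> float:
    """Abundance-weighted cooperation rate across homogeneous states."""
    abundance = np.asarray(abundance, dtype=float)
    coop = np.asarray(coop_rates, dtype=float)
    if abundance.shape != coop.shape:
        raise ValueError("abundance and cooperation-rate vectors differ in length")
    return float(abundance @ coop)


@dataclass
class EquilibriumResult:
    """Selection–mutation equilibrium of one strategy set."""

    states: List[Label]
    abundance: np.ndarray
    coop_rate: float


def selection_mutation_equilibrium(
    states: Sequence[Label],
    fixation: Dict[Tuple[Label, Label], float],
    coop_rates: Dict[Label, float],
) -> EquilibriumResult:
    """Rare-mutation equilibrium from pairwise fixation probabilities.

    Convenience composition of :func:`embedded_chain`,
    :func:`stationary_distribution` and
    :func:`equilibrium_cooperation_rate`.
    """
    chain = embedded_chain(states, fixation)
    abundance = stationary_distribution(chain)
    coop = equilibrium_cooperation_rate(
        abundance, [coop_rates[lab] for lab in chain.states]
    )
    return EquilibriumResult(states=chain.states, abundance=abundance, coop_rate=coop)


def critical_alpha(N: int, k: int) -> float:
    """Critical payoff parameter for unconditional cooperation.

    With ``R(k) = alpha*k`` and groups sampled without replacement, a focal
    cooperator's expected payoff minus a focal defector's is
    ``alpha*c*(N-k)/(N-1) - c`` at every ALLC/ALLD composition, which
    vanishes at ``alpha_c = (N-1)/(N-k)``.  For N=60, k=10 this is 1.18.
    """
    if not (2 <= k < N):
        raise ValueError(f"need 2 <= k < N, got k={k}, N={N}")
    return (N - 1) / (N - k)


def find_lambda_c(
    grid: pd.DataFrame,
    *,
    threshold: float = 0.5,
    alpha_c: Optional[float] = None,
) -> Optional[float]:
    """Operational optimal assessment criterion from a phase grid.

    ``grid`` holds columns ``alpha``, ``lam`` and ``coop_rate``.  For each
    criterion the smallest alpha whose equilibrium cooperation rate reaches
    ``threshold`` is found; ``lambda_c`` is the criterion minimising that
    alpha (ties broken toward the smaller criterion).  If ``alpha_c`` is
    given and no criterion sustains cooperation below it, the optimum is
    undefined and None is returned.
    """
    required = {"alpha", "lam", "coop_rate"}
    if not required.issubset(grid.columns):
        raise ValueError(f"grid must have columns {sorted(required)}")
    best_lam: Optional[float] = None
    best_alpha = np.inf
    for lam, sub in grid.groupby("lam"):
        ok = sub[sub["coop_rate"] >= threshold]
        if ok.empty:
            continue
        a = ok["alpha"].min()
        if a < best_alpha - 1e-12 or (
            abs(a - best_alpha) <= 1e-12 and (best_lam is None or lam < best_lam)
        ):
            best_alpha = a
            best_lam = float(lam)
    if best_lam is None:
        return None
    if alpha_c is not None and best_alpha >= alpha_c:
        return None
    return best_lam


def agent_based_evolution(
    n_states: int,
    payoff_fn: Callable[[np.ndarray], np.ndarray],
    N: int,
    *,
    s: float = 1.0,
    mu: float = 0.0,
    steps: int = 10_000,
    init_counts: Optional[Sequence[int]] = None,
    seed: Optional[int] = None,
    record_every: int = 1,
) -> np.ndarray:
    """Direct stochastic simulation of the mutation–imitation chain.

    Each elementary step selects a random player; with probability ``mu`` it
    mutates to a uniformly random *other* state, otherwise it picks a random
    other player as role model and imitates with the Fermi probability, where
    ``payoff_fn(counts)`` supplies per-state expected payoffs for the current
    composition.  Returns the recorded trajectory of state counts, shape
    ``(n_records, n_states)``.  Serves as a stochastic oracle for the
    closed-form fixation probability and for high-mutation scenarios.
    """
    rng = np.random.default_rng(seed)
    if init_counts is None:
        base = N // n_states
        counts = np.full(n_states, base, dtype=np.int64)
        counts[: N - base * n_states] += 1
    else:
        counts = np.array(init_counts, dtype=np.int64)
        if counts.sum() != N or (counts < 0).any():
            raise ValueError("init_counts must be nonnegative and sum to N")
    out = [counts.copy()]
    for t in range(steps):
        # select focal player uniformly -> its state, weighted by counts
        u = rng.random()
        i_state = int(np.searchsorted(np.cumsum(counts), u * N, side="right"))
        if mu > 0 and rng.random() < mu:
            j_state = int(rng.integers(n_states - 1))
            if j_state >= i_state:
                j_state += 1
            counts[i_state] -= 1
            counts[j_state] += 1
        else:
            # role model uniform among the other N-1 players
            r = rng.random() * (N - 1)
            cum = 0.0
            j_state = i_state
            for st in range(n_states):
                c = counts[st] - (1 if st == i_state else 0)
                cum += c
                if r < cum:
                    j_state = st
                    break
            if j_state != i_state:
                pi = payoff_fn(counts)
                if rng.random() < fermi_prob(pi[i_state], pi[j_state], s):
                    counts[i_state] -= 1
                    counts[j_state] += 1
        if (t + 1) % record_every == 0:
            out.append(counts.copy())
    return np.array(out)
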