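"""Agent-based collective-reputation dynamics in public goods games.

A well-mixed population of ``N`` players holds private binary opinions of one
another, recorded in an N×N image matrix ``M`` (entry ``M[i, j] = 1`` iff
player ``i`` currently considers ``j`` good).  Each round, ``k`` players are
sampled without replacement to play a public goods game: every group member,
viewed as a donor, faces the remaining ``k − 1`` members as its recipient
group, judges that group collectively — good iff the fraction of its members
the donor deems good reaches the donor's assessment criterion ``lam`` — and
cooperates or defects according to its norm's action rule.  Contributions of
cost ``c`` are scaled by a synergy factor ``R`` and shared equally, so a
round with ``n_C`` cooperators pays ``R·c·n_C/k − c`` to each cooperator and
``R·c·n_C/k`` to each defector.

Opinions then update synchronously: group members always learn each other's
actions; outsiders observe the whole round with probability ``q``; an
observed action other than one's own is misperceived (C↔D flipped)
independently with probability ``eps``.  By default misperception applies to
out-group observers only — participants learn the actions in their own game
exactly — but ``in_group_errors=True`` extends it to fellow group members.
Each observer re-assesses every donor from its own pre-round opinions.  ALLC
and ALLD players keep fixed all-good / all-bad opinion rows.

Two interchangeable engines run the same process: readable pure-Python
reference operations (:func:`play_round`, :func:`update_reputations`) and a
numba-compiled kernel.  Both consume random draws in an identical documented
order from the same ``numpy.random.Generator`` stream, so their image-matrix
trajectories agree bit for bit.

Random draw contract (per round, in order):
  1. group sampling — ``k`` partial Fisher–Yates draws, ``j = t + int(u·(N−t))``;
  2. actions — no draws (deterministic given the matrix);
  3. for each player ``h = 0..N−1`` in index order: one observation draw
     (``u < q``) iff ``h`` is outside the group; if ``h`` observes, one
     misperception draw per group member in sampled order, skipping ``h``
     itself (the flip threshold is ``eps`` or 0 depending on membership and
     ``in_group_errors``, but the draw is always consumed).  Draws are
     consumed by every observer, including ALLC/ALLD players whose rows are
     pinned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .norms import Player

__all__ = [
    "SimParams",
    "GroupSample",
    "RoundRecord",
    "RepStats",
    "population",
    "initial_image_matrix",
    "collective_reputation",
    "pg_payoffs",
    "play_round",
    "update_reputations",
    "simulate_reputation_dynamics",
]

#: Tolerance added to the threshold comparison so that a mathematically exact
#: boundary (e.g. lam=0.7 with 10 members needing exactly 7 good) is judged
#: inclusively despite the binary representation of one-decimal criteria.
THRESHOLD_TOL = 1e-9

Label = Tuple[str, float]


@dataclass(frozen=True)
class SimParams:
    """Configuration of one reputation-dynamics run.

    Exactly one of ``alpha`` (payoff parameter, with synergy ``R = alpha*k``)
    or ``R`` may be given; neither is needed if payoffs are not requested.
    The group assessment and opinion dynamics never depend on payoffs.
    """

    N: int
    k: int
    c: float = 1.0
    alpha: Optional[float] = None
    R: Optional[float] = None
    q: float = 0.9
    eps: float = 0.05
    in_group_errors: bool = False
    steps: int = 20_000
    burn_in: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (2 <= self.k <= self.N):
            raise ValueError(f"need 2 <= k <= N, got k={self.k}, N={self.N}")
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        if not (0.0 <= self.eps <= 0.5):
            raise ValueError(f"eps must lie in [0, 0.5], got {self.eps}")
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")
        if not (0.0 <= self.burn_in < 1.0):
            raise ValueError(f"burn_in fraction must lie in [0, 1), got {self.burn_in}")
        if self.alpha is not None and self.R is not None:
            raise ValueError("give either alpha or R, not both")

    @property
    def synergy(self) -> float:
        """The synergy factor R, resolving ``R = alpha*k`` if alpha was given."""
        if self.R is not None:
            return self.R
        if self.alpha is not None:
            return self.alpha * self.k
        raise ValueError("neither alpha nor R was configured")

    @property
    def burn_in_steps(self) -> int:
        return int(round(self.burn_in * self.steps))


@dataclass(frozen=True)
class GroupSample:
    """An ordered sample of k distinct players; member i faces the rest."""

    members: Tuple[int, ...]

    def recipient_group(self, i: int) -> Tuple[int, ...]:
        if i not in self.members:
            raise ValueError(f"player {i} is not in the group")
        return tuple(j for j in self.members if j != i)


@dataclass(frozen=True)
class RoundRecord:
    """Outcome of one public goods round."""

    group: GroupSample
    actions: Tuple[int, ...]
    n_C: int
    payoffs: Tuple[float, ...]


def population(spec: Sequence[Tuple[int, str, float]]) -> List[Player]:
    """Build a player list from ``(count, strategy_id, lam)`` blocks."""
    players: List[Player] = []
    for count, sid, lam in spec:
        players.extend(Player(sid, lam) for _ in range(count))
    return players


def initial_image_matrix(players: Sequence[Player], init: str = "all_good") -> np.ndarray:
    """Initial image matrix with ALLC/ALLD rows pinned to their constants.

    ``init`` is ``"all_good"`` (the default benign start), ``"all_bad"`` or
    ``"random"`` is not offered here — pass an explicit matrix to the
    simulator instead.  Rows of ALLC players are forced to all-ones and rows
    of ALLD players to all-zeros regardless of ``init``.
    """
    N = len(players)
    if init == "all_good":
        M = np.ones((N, N), dtype=np.int8)
    elif init == "all_bad":
        M = np.zeros((N, N), dtype=np.int8)
    else:
        raise ValueError(f"unknown init {init!r}")
    _pin_unconditional_rows(M, players)
    return M


def _pin_unconditional_rows(M: np.ndarray, players: Sequence[Player]) -> None:
    for i, p in enumerate(players):
        if p.strategy_id == "ALLC":
            M[i, :] = 1
        elif p.strategy_id == "ALLD":
            M[i, :] = 0


def collective_reputation(opinion_row: Sequence[int], group: Sequence[int], lam: float) -> int:
    """Collective reputation of a group in one observer's eyes.

    Returns 1 (good) iff the number of group members the observer considers
    good is at least ``lam`` times the group size; the comparison is
    inclusive and performed on the raw count (no rounding of ``lam·|G'|``).
    A singleton group therefore reduces to the individual opinion for every
    ``lam`` in (0, 1], recovering two-player reputation dynamics.
    """
    if len(group) == 0:
        raise ValueError("collective reputation of an empty group is undefined")
    if not (0.0 < lam <= 1.0):
        raise ValueError(f"lam must lie in (0, 1], got {lam}")
    row = np.asarray(opinion_row)
    good = int(sum(int(row[j]) for j in group))
    return 1 if good >= lam * len(group) - THRESHOLD_TOL else 0


def pg_payoffs(k: int, n_C: int, c: float, R: float) -> Tuple[float, float]:
    """Public goods payoffs ``(pi_C, pi_D)`` for a round with n_C cooperators.

    ``pi_C = R·c·n_C/k − c`` and ``pi_D = R·c·n_C/k``; defectors always earn
    exactly ``c`` more than cooperators in the same round.
    """
    if not (0 <= n_C <= k):
        raise ValueError(f"need 0 <= n_C <= k, got n_C={n_C}, k={k}")
    share = R * c * n_C / k
    return share - c, share


def _sample_group(N: int, k: int, rng: np.random.Generator) -> List[int]:
    # Partial Fisher–Yates; draw order is part of the engine contract.
    perm = list(range(N))
    for t in range(k):
        u = rng.random()
        j = t + int(u * (N - t))
        perm[t], perm[j] = perm[j], perm[t]
    return perm[:k]


def _group_is_good(good_count: int, size: int, lam: float) -> int:
    return 1 if good_count >= lam * size - THRESHOLD_TOL else 0


def play_round(
    matrix: np.ndarray,
    players: Sequence[Player],
    params: SimParams,
    rng: np.random.Generator,
) -> RoundRecord:
    """Sample a group and let each member act on its view of the others.

    Donor ``i`` acts on ``(M[i,i], collective reputation of G(i) in row i)``
    via its norm's action rule.  Payoffs use the configured synergy if one
    was given, otherwise they are reported as NaN (the dynamics do not need
    them).
    """
    N = len(players)
    if params.k > N:
        raise ValueError(f"group size k={params.k} exceeds population N={N}")
    members = _sample_group(N, params.k, rng)
    actions = []
    for i in members:
        good = sum(int(matrix[i, j]) for j in members if j != i)
        rp = _group_is_good(good, params.k - 1, players[i].lam)
        actions.append(players[i].table.act(int(matrix[i, i]), rp))
    n_C = sum(actions)
    try:
        pi_C, pi_D = pg_payoffs(params.k, n_C, params.c, params.synergy)
        payoffs = tuple(pi_C if a == 1 else pi_D for a in actions)
    except ValueError:
        payoffs = tuple(float("nan") for _ in actions)
    return RoundRecord(
        group=GroupSample(tuple(members)),
        actions=tuple(actions),
        n_C=n_C,
        payoffs=payoffs,
    )


def update_reputations(
    matrix: np.ndarray,
    record: RoundRecord,
    players: Sequence[Player],
    params: SimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synchronous opinion update after one round; returns a new matrix.

    Every assessment reads the pre-round matrix.  Group members observe with
    certainty, outsiders with probability ``q``; a perceived action other
    than the observer's own is flipped with probability ``eps`` (out-group
    observers always; in-group observers only if ``in_group_errors``).  Rows
    of ALLC/ALLD players stay pinned, though those players still consume
    their observation and misperception draws (part of the draw contract).
    """
    N = len(players)
    members = record.group.members
    member_set = set(members)
    new = matrix.copy()
    for h in range(N):
        if h in member_set:
            observes = True
        else:
            observes = rng.random() < params.q
        if not observes:
            continue
        eps_h = params.eps if (h not in member_set or params.in_group_errors) else 0.0
        rowsum = sum(int(matrix[h, j]) for j in members)
        updates = []
        for idx, i in enumerate(members):
            b = record.actions[idx]
            if i != h:
                if rng.random() < eps_h:
                    b = 1 - b
            ra = int(matrix[h, i])
            rp = _group_is_good(rowsum - ra, params.k - 1, players[h].lam)
            updates.append(players[h].table.assess(ra, rp, b))
        if players[h].strategy_id not in ("ALLC", "ALLD"):
            for idx, i in enumerate(members):
                new[h, i] = updates[idx]
    return new


@dataclass
class RepStats:
    """Summary statistics of one reputation-dynamics run.

    All per-strategy quantities are keyed by ``(strategy_id, lam)`` labels
    and averaged over post-burn-in rounds.  ``nc_mean`` is the mean number of
    cooperators in games a player of that label took part in; together with
    ``coop_freq`` it determines the mean per-game payoff for any payoff
    parameterisation: ``pi = alpha·c·nc_mean − c·coop_freq``.
    """

    labels: List[Label]
    coop_freq: Dict[Label, float]
    nc_mean: Dict[Label, float]
    mean_payoff: Dict[Label, float]
    good_rep: pd.DataFrame
    participation: Dict[Label, int]
    steps: int
    burn_in_steps: int
    seed: Optional[int]

    def payoff(self, label: Label, alpha: float, c: float = 1.0) -> float:
        """Mean per-game payoff under synergy R = alpha·k."""
        return alpha * c * self.nc_mean[label] - c * self.coop_freq[label]


def _strategy_arrays(players: Sequence[Player]):
    N = len(players)
    assess_arr = np.empty((N, 2, 2, 2), dtype=np.int8)
    act_arr = np.empty((N, 2, 2), dtype=np.int8)
    pinned = np.zeros(N, dtype=np.int8)
    lam = np.empty(N, dtype=np.float64)
    for i, p in enumerate(players):
        table = p.table
        assess_arr[i] = table.assessment_array()
        act_arr[i] = table.action_array()
        pinned[i] = 1 if p.strategy_id in ("ALLC", "ALLD") else 0
        lam[i] = p.lam
    return assess_arr, act_arr, pinned, lam


def _aggregate_stats(
    players: Sequence[Player],
    m_acc: np.ndarray,
    part: np.ndarray,
    act_sum: np.ndarray,
    nc_sum: np.ndarray,
    n_avg: int,
    params: SimParams,
    seed: Optional[int],
) -> RepStats:
    labels: List[Label] = []
    idx_by_label: Dict[Label, List[int]] = {}
    for i, p in enumerate(players):
        if p.label not in idx_by_label:
            idx_by_label[p.label] = []
            labels.append(p.label)
        idx_by_label[p.label].append(i)

    coop_freq: Dict[Label, float] = {}
    nc_mean: Dict[Label, float] = {}
    mean_payoff: Dict[Label, float] = {}
    participation: Dict[Label, int] = {}
    try:
        R = params.synergy
    except ValueError:
        R = None
    for lab, idx in idx_by_label.items():
        n_part = int(part[idx].sum())
        participation[lab] = n_part
        if n_part > 0:
            coop_freq[lab] = float(act_sum[idx].sum() / n_part)
            nc_mean[lab] = float(nc_sum[idx].sum() / n_part)
        else:
            coop_freq[lab] = float("nan")
            nc_mean[lab] = float("nan")
        if R is not None and n_part > 0:
            mean_payoff[lab] = R * params.c * nc_mean[lab] / params.k - params.c * coop_freq[lab]
        else:
            mean_payoff[lab] = float("nan")

    # Time-averaged good-reputation proportions per (observer, target) label.
    names = [f"{sid}@{lam:g}" for sid, lam in labels]
    good = np.zeros((len(labels), len(labels)))
    if n_avg > 0:
        for a, la in enumerate(labels):
            rows = idx_by_label[la]
            for b, lb in enumerate(labels):
                cols = idx_by_label[lb]
                block = m_acc[np.ix_(rows, cols)]
                good[a, b] = block.sum() / (len(rows) * len(cols) * n_avg)
    good_rep = pd.DataFrame(good, index=names, columns=names)
    return RepStats(
        labels=labels,
        coop_freq=coop_freq,
        nc_mean=nc_mean,
        mean_payoff=mean_payoff,
        good_rep=good_rep,
        participation=participation,
        steps=params.steps,
        burn_in_steps=params.burn_in_steps,
        seed=seed,
    )


def simulate_reputation_dynamics(
    players: Sequence[Player],
    params: SimParams,
    *,
    engine: str = "numba",
    init: Union[str, np.ndarray] = "all_good",
    seed: Optional[int] = None,
    record_trajectory: bool = False,
):
    """Iterate the reputation dynamics and accumulate summary statistics.

    Runs ``params.steps`` rounds of group sampling, action and synchronous
    opinion update from an all-good initial matrix (configurable), then
    averages cooperation frequencies, participant-conditioned cooperator
    counts and good-reputation proportions over the post-burn-in rounds.

    ``engine`` selects the numba kernel (default) or the pure-Python
    reference loop; both produce identical trajectories for the same seed.
    If ``record_trajectory`` is true, also returns the (steps+1, N, N) int8
    matrix trajectory (small runs only).
    """
    N = len(players)
    if params.N != N:
        raise ValueError(f"params.N={params.N} but {N} players were given")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    if isinstance(init, str):
        M = initial_image_matrix(players, init)
    else:
        M = np.array(init, dtype=np.int8, copy=True)
        if M.shape != (N, N) or not np.isin(M, (0, 1)).all():
            raise ValueError("init matrix must be binary and N x N")
        _pin_unconditional_rows(M, players)

    burn = params.burn_in_steps
    if engine == "numba":
        from ._engine import run_simulation

        assess_arr, act_arr, pinned, lam = _strategy_arrays(players)
        m_acc = np.zeros((N, N), dtype=np.int64)
        part = np.zeros(N, dtype=np.int64)
        act_sum = np.zeros(N, dtype=np.int64)
        nc_sum = np.zeros(N, dtype=np.int64)
        if record_trajectory:
            traj = np.empty((params.steps + 1, N, N), dtype=np.int8)
        else:
            traj = np.empty((1, 1, 1), dtype=np.int8)
        ig_eps = params.eps if params.in_group_errors else 0.0
        run_simulation(
            M, assess_arr, act_arr, pinned, lam,
            params.k, params.q, params.eps, ig_eps, params.steps, burn,
            rng, m_acc, part, act_sum, nc_sum, traj, record_trajectory,
        )
    elif engine == "python":
        m_acc = np.zeros((N, N), dtype=np.int64)
        part = np.zeros(N, dtype=np.int64)
        act_sum = np.zeros(N, dtype=np.int64)
        nc_sum = np.zeros(N, dtype=np.int64)
        traj_list = [M.copy()] if record_trajectory else None
        for t in range(params.steps):
            record = play_round(M, players, params, rng)
            M = update_reputations(M, record, players, params, rng)
            if t >= burn:
                m_acc += M
                for idx, i in enumerate(record.group.members):
                    part[i] += 1
                    act_sum[i] += record.actions[idx]
                    nc_sum[i] += record.n_C
            if traj_list is not None:
                traj_list.append(M.copy())
        if traj_list is not None:
            traj = np.stack(traj_list)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    n_avg = params.steps - burn
    stats = _aggregate_stats(players, m_acc, part, act_sum, nc_sum, n_avg, params, seed)
    if record_trajectory:
        return stats, traj
    return stats
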