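"""Experiment orchestration: scenario configs, sweeps and result writers.

Three experiment families mirror the analyses the framework is built for:

* ``reputation`` — fixed-strategy populations (one leading-eight norm, ALLC,
  ALLD in equal thirds) swept over the group assessment criterion; outputs
  time-averaged good-reputation proportions and cooperation frequencies.
* ``phase_grid`` — selection–mutation equilibria of {Li, ALLC, ALLD} over an
  (alpha, lambda) grid: composition payoffs -> fixation probabilities ->
  embedded chain -> stationary abundances and equilibrium cooperation rate.
* ``criterion_evolution`` — a single norm with three assessment criteria
  (0.1 / 0.4 / 0.7 by default) competing over a range of alpha; also covers
  the five-state co-evolution scenario (three criteria + ALLC + ALLD).

All sweeps derive per-cell RNG streams from the master seed, so results are
independent of execution order and bit-reproducible from the manifest.
Composition statistics are payoff-free and cached per (pair, lambda), which
lets a whole alpha grid reuse one set of simulations.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .dynamics import SimParams, population, simulate_reputation_dynamics
from .evolution import (
    CompositionMoments,
    EvoParams,
    composition_moments,
    critical_alpha,
    fixation_probability,
    selection_mutation_equilibrium,
    unconditional_composition_moments,
)
from .norms import Player

__all__ = [
    "ScenarioConfig",
    "RunManifest",
    "DEFAULT_LAMBDA_STATES",
    "run_reputation_scenario",
    "run_phase_grid",
    "run_criterion_evolution",
    "run_coevolution",
    "make_fixture",
]

logger = logging.getLogger("collrep.runner")

#: The three assessment-criterion states used in criterion evolution.
DEFAULT_LAMBDA_STATES = (0.1, 0.4, 0.7)

_FAMILIES = ("reputation", "phase_grid", "criterion_evolution", "coevolution")

#: Preset problem sizes: ``desk`` for quick exploration, ``paper`` for
#: full-resolution runs (2e5 steps per experiment, 50 replicates).
PRESETS = {
    "desk": dict(steps=20_000, reps=5),
    "paper": dict(steps=200_000, reps=50),
}


@dataclass
class ScenarioConfig:
    """One experiment family plus everything needed to reproduce it.

    Defaults follow the baseline parameterisation used throughout the
    analyses: N=60, k=10, q=0.9, eps=0.05, s=1, rare mutations.
    """

    family: str
    strategy: str = "L1"
    lambdas: Tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    lambda_states: Tuple[float, ...] = DEFAULT_LAMBDA_STATES
    alpha_grid: Tuple[float, ...] = tuple(np.round(np.arange(0.1, 2.01, 0.1), 10))
    N: int = 60
    k: int = 10
    c: float = 1.0
    q: float = 0.9
    eps: float = 0.05
    s: float = 1.0
    mu: float = 0.0
    steps: int = 20_000
    burn_in: float = 0.1
    reps: int = 5
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; valid: {_FAMILIES}")
        self.lambdas = tuple(float(x) for x in self.lambdas)
        self.lambda_states = tuple(float(x) for x in self.lambda_states)
        self.alpha_grid = tuple(float(x) for x in self.alpha_grid)

    def sim_params(self, **overrides) -> SimParams:
        kw = dict(
            N=self.N, k=self.k, c=self.c, q=self.q, eps=self.eps,
            steps=self.steps, burn_in=self.burn_in,
        )
        kw.update(overrides)
        return SimParams(**kw)

    def evo_params(self) -> EvoParams:
        return EvoParams(
            s=self.s, mu=self.mu, comp_steps=self.steps,
            reps=1, burn_in=self.burn_in,
        )

    @classmethod
    def with_preset(cls, family: str, preset: str = "desk", **kw) -> "ScenarioConfig":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; valid: {sorted(PRESETS)}")
        merged = dict(PRESETS[preset])
        merged.update(kw)
        return cls(family=family, **merged)

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path: Union[str, Path, None] = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "ScenarioConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        for key in ("lambdas", "lambda_states", "alpha_grid"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunManifest:
    """Reproducibility metadata written beside every result CSV."""

    config: dict
    seed: int
    code_version: str
    outputs: Dict[str, str] = field(default_factory=dict)

    def add_output(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1) + "\n")


def _code_version() -> str:
    from . import __version__

    return __version__


def _write_outputs(cfg: ScenarioConfig, frames: Dict[str, pd.DataFrame]) -> None:
    if cfg.out_dir is None:
        return
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(cfg), seed=cfg.seed, code_version=_code_version())
    for name, df in frames.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest.add_output(path)
    manifest.write(out / "manifest.json")


def _thirds(N: int) -> Tuple[int, int, int]:
    base = N // 3
    extra = N - 3 * base
    counts = [base, base, base]
    for i in range(extra):
        counts[i] += 1
    return tuple(counts)


# ---------------------------------------------------------------------------
# reputation family
# ---------------------------------------------------------------------------

def run_reputation_scenario(cfg: ScenarioConfig) -> pd.DataFrame:
    """Sweep the assessment criterion for a fixed {Li, ALLC, ALLD} population.

    Emits one long-format row per (lambda, replicate, statistic): cooperation
    frequency and mean payoff per strategy, and the good-reputation
    proportion for every (observer strategy, target strategy) pair.
    If N is not divisible by 3, the leftover players go to the leading-eight
    and then the ALLC block (nearest split).
    """
    if cfg.family != "reputation":
        raise ValueError("config family must be 'reputation'")
    n_li, n_c, n_d = _thirds(cfg.N)
    rows = []
    for lam in cfg.lambdas:
        logger.info("reputation scenario %s: lam=%g, %d replicates, seed=%d",
                    cfg.strategy, lam, cfg.reps, cfg.seed)
        players = population(
            [(n_li, cfg.strategy, lam), (n_c, "ALLC", lam), (n_d, "ALLD", lam)]
        )
        for rep in range(cfg.reps):
            seed = np.random.SeedSequence([cfg.seed, int(round(lam * 1000)), rep])
            stats = simulate_reputation_dynamics(players, cfg.sim_params(), seed=seed)
            meta = dict(
                scenario=f"reputation-{cfg.strategy}", lam=lam, rep=rep,
                seed_root=cfg.seed, steps=cfg.steps,
            )
            for label in stats.labels:
                sid = label[0]
                rows.append(dict(meta, statistic="coop_freq", strategy=sid,
                                 target="", value=stats.coop_freq[label]))
            for (obs_id, _), obs_name in zip(stats.labels, stats.good_rep.index):
                for (tgt_id, _), tgt_name in zip(stats.labels, stats.good_rep.columns):
                    rows.append(dict(meta, statistic="good_rep", strategy=obs_id,
                                     target=tgt_id,
                                     value=stats.good_rep.loc[obs_name, tgt_name]))
    df = pd.DataFrame(rows)
    _write_outputs(cfg, {"reputation": df})
    return df


# ---------------------------------------------------------------------------
# shared equilibrium machinery
# ---------------------------------------------------------------------------

def _pair_moments(
    a: Player,
    b: Player,
    cfg: ScenarioConfig,
    cache: Dict[tuple, CompositionMoments],
    stream: int,
) -> CompositionMoments:
    """Composition moments for mutant a vs resident b, memoised.

    The ALLC/ALLD pair has reputation-independent actions, so its moments are
    exact hypergeometric expectations rather than Monte Carlo estimates.
    """
    key = (a.label, b.label)
    if key in cache:
        logger.debug("composition moments cache hit: %s vs %s", a.label, b.label)
        return cache[key]
    if {a.strategy_id, b.strategy_id} == {"ALLC", "ALLD"}:
        base = unconditional_composition_moments(cfg.N, cfg.k)
        if a.strategy_id == "ALLD":  # exact table stores ALLC as mutant; mirror
            mom = CompositionMoments(
                mutant=a.label, resident=b.label, N=cfg.N, k=cfg.k,
                nc_mut=base.nc_res[::-1].copy(), act_mut=base.act_res[::-1].copy(),
                nc_res=base.nc_mut[::-1].copy(), act_res=base.act_mut[::-1].copy(),
            )
        else:
            mom = CompositionMoments(
                mutant=a.label, resident=b.label, N=cfg.N, k=cfg.k,
                nc_mut=base.nc_mut, act_mut=base.act_mut,
                nc_res=base.nc_res, act_res=base.act_res,
            )
    else:
        logger.info(
            "simulating composition moments: %s vs %s (stream %d, %d steps)",
            a.label, b.label, stream, cfg.steps,
        )
        mom = composition_moments(
            a, b, cfg.sim_params(), evo=cfg.evo_params(),
            seed=int(np.random.SeedSequence([cfg.seed, stream]).generate_state(1)[0] % (2**31)),
        )
    cache[key] = mom
    # The reverse direction reuses the same simulations mirrored: the payoff
    # of b as resident at mutant count m equals b's mutant payoff at N-m.
    cache[(b.label, a.label)] = CompositionMoments(
        mutant=b.label, resident=a.label, N=cfg.N, k=cfg.k,
        nc_mut=mom.nc_res[::-1].copy(), act_mut=mom.act_res[::-1].copy(),
        nc_res=mom.nc_mut[::-1].copy(), act_res=mom.act_mut[::-1].copy(),
    )
    return mom


def _homogeneous_coop_rate(player: Player, cfg: ScenarioConfig, stream: int) -> float:
    if player.strategy_id == "ALLC":
        return 1.0
    if player.strategy_id == "ALLD":
        return 0.0
    seed = np.random.SeedSequence([cfg.seed, stream])
    stats = simulate_reputation_dynamics(
        [player] * cfg.N, cfg.sim_params(), seed=seed
    )
    return stats.coop_freq[player.label]


def _equilibrium_over_alpha(
    states: List[Player],
    cfg: ScenarioConfig,
    moments: Dict[tuple, CompositionMoments],
    coop_rates: Dict[Tuple[str, float], float],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Fixation table + stationary abundances for every alpha in the grid."""
    eq_rows, fix_rows = [], []
    labels = [p.label for p in states]
    ids = [lab[0] for lab in labels]
    # column names drop the criterion when strategy ids already disambiguate,
    # so phase-grid rows across lambda values share a schema
    names = ids if len(set(ids)) == len(ids) else [
        f"{sid}@{lam:g}" for sid, lam in labels
    ]
    for alpha in cfg.alpha_grid:
        fix: Dict[Tuple[tuple, tuple], float] = {}
        for a in states:
            for b in states:
                if a.label == b.label:
                    continue
                cp = moments[(a.label, b.label)].payoffs(alpha, cfg.c)
                rho = fixation_probability(cp, cfg.s).rho
                fix[(a.label, b.label)] = rho
                fix_rows.append(dict(
                    alpha=alpha, mutant=f"{a.strategy_id}@{a.lam:g}",
                    resident=f"{b.strategy_id}@{b.lam:g}", rho=rho,
                    neutral=1.0 / cfg.N,
                ))
        eq = selection_mutation_equilibrium(labels, fix, coop_rates)
        row = dict(alpha=alpha, coop_rate=eq.coop_rate)
        for name, x in zip(names, eq.abundance):
            row[f"abundance[{name}]"] = x
        eq_rows.append(row)
    return pd.DataFrame(eq_rows), pd.DataFrame(fix_rows)


# ---------------------------------------------------------------------------
# phase_grid family
# ---------------------------------------------------------------------------

def run_phase_grid(cfg: ScenarioConfig) -> pd.DataFrame:
    """Equilibrium cooperation over an (alpha, lambda) grid for {Li, ALLC, ALLD}.

    Per lambda, the three pairwise composition-moment tables and the
    homogeneous Li cooperation rate are simulated once; every alpha on the
    grid is then evaluated analytically from them.  Returns one row per
    (alpha, lambda) with stationary abundances and the equilibrium
    cooperation rate.
    """
    if cfg.family != "phase_grid":
        raise ValueError("config family must be 'phase_grid'")
    all_rows = []
    for li, lam in enumerate(cfg.lambdas):
        logger.info("phase grid %s: lam=%g (%d/%d), seed=%d",
                    cfg.strategy, lam, li + 1, len(cfg.lambdas), cfg.seed)
        states = [
            Player(cfg.strategy, lam), Player("ALLC", lam), Player("ALLD", lam)
        ]
        cache: Dict[tuple, CompositionMoments] = {}
        for pi, (a, b) in enumerate(
            [(0, 1), (0, 2), (1, 2)]
        ):
            _pair_moments(states[a], states[b], cfg, cache, stream=1000 + 10 * li + pi)
        coop_rates = {
            s.label: _homogeneous_coop_rate(s, cfg, stream=2000 + li)
            for s in states
        }
        eq, _ = _equilibrium_over_alpha(states, cfg, cache, coop_rates)
        eq.insert(1, "lam", lam)
        eq.insert(0, "strategy", cfg.strategy)
        all_rows.append(eq)
    df = pd.concat(all_rows, ignore_index=True)
    df["alpha_c"] = critical_alpha(cfg.N, cfg.k)
    _write_outputs(cfg, {"phase_grid": df})
    return df


# ---------------------------------------------------------------------------
# criterion_evolution / coevolution families
# ---------------------------------------------------------------------------

def _run_state_contest(
    states: List[Player], cfg: ScenarioConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    cache: Dict[tuple, CompositionMoments] = {}
    stream = 3000
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            _pair_moments(states[i], states[j], cfg, cache, stream=stream)
            stream += 1
    coop_rates = {
        s.label: _homogeneous_coop_rate(s, cfg, stream=4000 + i)
        for i, s in enumerate(states)
    }
    abundances, fixation = _equilibrium_over_alpha(states, cfg, cache, coop_rates)
    for lab in [s.label for s in states]:
        abundances[f"coop_rate[{lab[0]}@{lab[1]:g}]"] = coop_rates[lab]
    return abundances, fixation


def run_criterion_evolution(cfg: ScenarioConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Contest of assessment criteria within a single leading-eight norm.

    The homogeneous states are one norm equipped with each criterion in
    ``cfg.lambda_states`` (default 0.1 / 0.4 / 0.7).  Returns (abundances
    per alpha, fixation table per alpha); the fixation table carries the
    neutral reference 1/N in a ``neutral`` column.
    """
    if cfg.family != "criterion_evolution":
        raise ValueError("config family must be 'criterion_evolution'")
    states = [Player(cfg.strategy, lam) for lam in cfg.lambda_states]
    abundances, fixation = _run_state_contest(states, cfg)
    abundances.insert(0, "strategy", cfg.strategy)
    fixation.insert(0, "strategy", cfg.strategy)
    _write_outputs(cfg, {"criterion_abundance": abundances,
                         "criterion_fixation": fixation})
    return abundances, fixation


def run_coevolution(cfg: ScenarioConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Co-evolution of strategy and criterion: Li at three criteria + ALLC + ALLD."""
    if cfg.family != "coevolution":
        raise ValueError("config family must be 'coevolution'")
    states = [Player(cfg.strategy, lam) for lam in cfg.lambda_states]
    states += [Player("ALLC", 0.5), Player("ALLD", 0.5)]
    abundances, fixation = _run_state_contest(states, cfg)
    abundances.insert(0, "strategy", cfg.strategy)
    fixation.insert(0, "strategy", cfg.strategy)
    _write_outputs(cfg, {"coevolution_abundance": abundances,
                         "coevolution_fixation": fixation})
    return abundances, fixation


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, seed: int = 0):
    """Small deterministic instances for unit tests and worked examples.

    ``tiny-population``: an N=6, k=3 mixed population, its SimParams and the
    recorded 100-step trajectory.  ``worked-example``: a 5-player group where
    the in-group donor and an outside observer disagree about the recipient
    group (the donor sees 3 of 4 members as good, the observer only 2), so at
    criterion 0.7 the donor judges the group good and the observer judges it
    bad.  ``oracle-pair``: the tiny population run through both engines.
    """
    if kind == "tiny-population":
        players = population([(2, "L6", 0.5), (2, "ALLC", 0.5), (2, "ALLD", 0.5)])
        params = SimParams(N=6, k=3, steps=100, burn_in=0.0, seed=seed)
        stats, traj = simulate_reputation_dynamics(
            players, params, record_trajectory=True
        )
        return dict(players=players, params=params, stats=stats, trajectory=traj)
    if kind == "worked-example":
        # Group of 5: donor i = player 0, recipients 1..4.  Donor deems
        # {1,2,3} good; outside observer h deems {2,3} good (disagreeing on
        # players 1 and 4).
        donor_row = np.array([1, 1, 1, 1, 0], dtype=np.int8)
        observer_row = np.array([1, 0, 1, 1, 0], dtype=np.int8)
        return dict(
            group=[0, 1, 2, 3, 4],
            recipients=[1, 2, 3, 4],
            donor_row=donor_row,
            observer_row=observer_row,
            lam=0.7,
        )
    if kind == "oracle-pair":
        players = population([(2, "L3", 0.5), (2, "ALLC", 0.5), (2, "ALLD", 0.5)])
        params = SimParams(N=6, k=3, steps=100, burn_in=0.0, seed=seed)
        _, t_fast = simulate_reputation_dynamics(
            players, params, engine="numba", record_trajectory=True
        )
        _, t_ref = simulate_reputation_dynamics(
            players, params, engine="python", record_trajectory=True
        )
        return dict(players=players, params=params, fast=t_fast, reference=t_ref)
    raise ValueError(
        f"unknown fixture kind {kind!r}; valid: tiny-population, "
        "worked-example, oracle-pair"
    )
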