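"""Social norms as explicit assessment/action tables.

A third-order social norm consists of an assessment rule — how an observer
judges a donor given the donor's current reputation ``r_a``, the (collective)
reputation of the recipient group ``r_p`` and the observed action ``b`` — and
an action rule prescribing cooperation or defection given the donor's own
reputation and the recipient group's reputation.  Reputations and actions are
binary throughout: 1 = good / cooperate, 0 = bad / defect.

This module ships the leading-eight norms L1–L8 (the eight third-order norms
known to stabilise cooperation under reputation dynamics) together with the
unconditional strategies ALLC and ALLD.  Tables are stored as explicit
12-entry records rather than computed rules so that arbitrary norms remain
pluggable; the canonical set is loaded from a versioned JSON data file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping, Tuple

import numpy as np

__all__ = [
    "GOOD",
    "BAD",
    "COOPERATE",
    "DEFECT",
    "STRATEGY_IDS",
    "LEADING_EIGHT_IDS",
    "ALIASES",
    "StrategyTable",
    "Player",
    "leading_eight_table",
    "assess",
    "act",
    "load_strategy_catalog",
]

#: Binary reputation / action values.
GOOD, BAD = 1, 0
COOPERATE, DEFECT = 1, 0

LEADING_EIGHT_IDS = tuple(f"L{i}" for i in range(1, 9))
STRATEGY_IDS = LEADING_EIGHT_IDS + ("ALLC", "ALLD")

#: Conventional names for the leading-eight norms that have them.
ALIASES: Dict[str, str] = {
    "Consistent Standing": "L2",
    "Simple Standing": "L3",
    "Stern Judging": "L6",
    "Staying": "L7",
    "Judging": "L8",
}

_REP_CHAR = {GOOD: "G", BAD: "B"}
_ACT_CHAR = {COOPERATE: "C", DEFECT: "D"}
_CHAR_REP = {"G": GOOD, "B": BAD}
_CHAR_ACT = {"C": COOPERATE, "D": DEFECT}


def _assessment_key(ra: int, rp: int, b: int) -> str:
    return f"ra{_REP_CHAR[ra]}|rp{_REP_CHAR[rp]}|b{_ACT_CHAR[b]}"


def _action_key(ra: int, rp: int) -> str:
    return f"ra{_REP_CHAR[ra]}|rp{_REP_CHAR[rp]}"


@dataclass(frozen=True)
class StrategyTable:
    """A complete social norm: 8 assessment entries + 4 action entries.

    ``assessment`` maps ``(r_a, r_p, b)`` — donor reputation, recipient-group
    reputation, observed action — to the donor's new reputation.  ``action``
    maps ``(r_a, r_p)`` — the donor's self-image and its view of the recipient
    group — to the prescribed action.
    """

    id: str
    assessment: Mapping[Tuple[int, int, int], int]
    action: Mapping[Tuple[int, int], int]

    def __post_init__(self) -> None:
        binary = (0, 1)
        for ra in binary:
            for rp in binary:
                for b in binary:
                    v = self.assessment.get((ra, rp, b))
                    if v not in binary:
                        raise ValueError(
                            f"{self.id}: assessment entry ({ra},{rp},{b}) "
                            f"missing or non-binary: {v!r}"
                        )
                v = self.action.get((ra, rp))
                if v not in binary:
                    raise ValueError(
                        f"{self.id}: action entry ({ra},{rp}) missing or "
                        f"non-binary: {v!r}"
                    )

    def assess(self, donor_rep: int, group_rep: int, observed: int) -> int:
        """New reputation the norm assigns to a donor in the given context."""
        return self.assessment[(donor_rep, group_rep, observed)]

    def act(self, self_rep: int, group_rep: int) -> int:
        """Action the norm prescribes to a donor."""
        return self.action[(self_rep, group_rep)]

    def assessment_array(self) -> np.ndarray:
        """Assessment rule as an int8 array indexed ``[r_a, r_p, b]``."""
        arr = np.empty((2, 2, 2), dtype=np.int8)
        for (ra, rp, b), v in self.assessment.items():
            arr[ra, rp, b] = v
        return arr

    def action_array(self) -> np.ndarray:
        """Action rule as an int8 array indexed ``[r_a, r_p]``."""
        arr = np.empty((2, 2), dtype=np.int8)
        for (ra, rp), v in self.action.items():
            arr[ra, rp] = v
        return arr

    def to_dict(self) -> dict:
        """Plain-JSON representation (keys like ``"raG|rpB|bC"``)."""
        return {
            "id": self.id,
            "assessment": {
                _assessment_key(*key): _REP_CHAR[v]
                for key, v in sorted(self.assessment.items(), reverse=True)
            },
            "action": {
                _action_key(*key): _ACT_CHAR[v]
                for key, v in sorted(self.action.items(), reverse=True)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StrategyTable":
        assessment = {}
        for key, v in d["assessment"].items():
            ra, rp, b = key.split("|")
            assessment[(_CHAR_REP[ra[2]], _CHAR_REP[rp[2]], _CHAR_ACT[b[1]])] = _CHAR_REP[v]
        action = {}
        for key, v in d["action"].items():
            ra, rp = key.split("|")
            action[(_CHAR_REP[ra[2]], _CHAR_REP[rp[2]])] = _CHAR_ACT[v]
        return cls(id=d["id"], assessment=assessment, action=action)


@dataclass(frozen=True)
class Player:
    """A population member: a norm plus a personal group assessment criterion.

    ``lam`` is the threshold fraction of good members required for this player
    to judge a recipient group as good; it must lie in (0, 1].
    """

    strategy: str
    lam: float = 0.5

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGY_IDS and self.strategy not in ALIASES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; valid: "
                f"{sorted(STRATEGY_IDS) + sorted(ALIASES)}"
            )
        if not (0.0 < self.lam <= 1.0):
            raise ValueError(f"lam must lie in (0, 1], got {self.lam}")

    @property
    def strategy_id(self) -> str:
        return ALIASES.get(self.strategy, self.strategy)

    @property
    def label(self) -> Tuple[str, float]:
        """Aggregation key: (canonical strategy id, criterion)."""
        return (self.strategy_id, self.lam)

    @property
    def table(self) -> StrategyTable:
        return leading_eight_table(self.strategy_id)


def _build_catalog() -> Dict[str, StrategyTable]:
    """Construct the canonical 10-strategy catalog in code.

    The leading eight share every entry that involves a good recipient group
    (cooperation with the good is good, defection against the good is bad, and
    everyone cooperates with a good group when in good standing) as well as
    the entry that justified defection — a good donor defecting against a bad
    group — preserves good standing.  They differ in three assessment cells
    (how to judge cooperation with a bad group by good and by bad donors, and
    defection between bad parties) and in one action cell (whether a bad donor
    cooperates with a bad group); the three variable assessment cells
    enumerate all eight binary combinations across L1–L8.
    """
    G, B, C, D = GOOD, BAD, COOPERATE, DEFECT

    # Variable cells per norm: (assess(G,B,C), assess(B,B,C), assess(B,B,D), action(B,B))
    variable = {
        "L1": (G, G, B, C),
        "L2": (B, G, B, C),
        "L3": (G, G, G, D),
        "L4": (G, B, G, D),
        "L5": (B, G, G, D),
        "L6": (B, B, G, D),
        "L7": (G, B, B, D),
        "L8": (B, B, B, D),
    }

    catalog: Dict[str, StrategyTable] = {}
    for sid, (d_gbc, d_bbc, d_bbd, a_bb) in variable.items():
        assessment = {
            (G, G, C): G, (B, G, C): G,   # cooperation with the good is good
            (G, G, D): B, (B, G, D): B,   # defection against the good is bad
            (G, B, D): G,                 # justified defection
            (G, B, C): d_gbc,
            (B, B, C): d_bbc,
            (B, B, D): d_bbd,
        }
        action = {(G, G): C, (B, G): C, (G, B): D, (B, B): a_bb}
        catalog[sid] = StrategyTable(id=sid, assessment=assessment, action=action)

    allc_assessment = {(ra, rp, b): G for ra in (0, 1) for rp in (0, 1) for b in (0, 1)}
    alld_assessment = {(ra, rp, b): B for ra in (0, 1) for rp in (0, 1) for b in (0, 1)}
    catalog["ALLC"] = StrategyTable(
        id="ALLC",
        assessment=allc_assessment,
        action={(ra, rp): C for ra in (0, 1) for rp in (0, 1)},
    )
    catalog["ALLD"] = StrategyTable(
        id="ALLD",
        assessment=alld_assessment,
        action={(ra, rp): D for ra in (0, 1) for rp in (0, 1)},
    )
    return catalog


def load_strategy_catalog() -> Dict[str, StrategyTable]:
    """Load the canonical strategy catalog from the shipped JSON data file."""
    path = resources.files("collrep.data").joinpath("strategies.json")
    payload = json.loads(path.read_text())
    return {d["id"]: StrategyTable.from_dict(d) for d in payload["strategies"]}


_CATALOG: Dict[str, StrategyTable] = _build_catalog()


def leading_eight_table(id: str) -> StrategyTable:
    """Return the full table for a leading-eight norm, ALLC or ALLD.

    Accepts canonical ids (``"L1"``..``"L8"``, ``"ALLC"``, ``"ALLD"``) and the
    conventional aliases (e.g. ``"Stern Judging"`` for L6).
    """
    sid = ALIASES.get(id, id)
    try:
        return _CATALOG[sid]
    except KeyError:
        raise KeyError(
            f"unknown strategy id {id!r}; valid ids: {sorted(STRATEGY_IDS)}"
            f" plus aliases {sorted(ALIASES)}"
        ) from None


def assess(table: StrategyTable, donor_rep: int, group_rep: int, observed: int) -> int:
    """Pure table lookup: the new reputation assigned to the donor."""
    return table.assess(donor_rep, group_rep, observed)


def act(table: StrategyTable, self_rep: int, group_rep: int) -> int:
    """Pure table lookup: the action prescribed to the donor."""
    return table.act(self_rep, group_rep)
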