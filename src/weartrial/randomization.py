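"""Covariate-adaptive allocation by minimization (Pocock–Simon).

Each incoming participant is hypothetically added to every arm in turn;
for each prognostic factor, the spread of the factor-level marginal
counts across arms (range ``max − min`` by default, or population
variance) is computed on the hypothetical table, and the weighted sum
over factors is that arm's imbalance score. A biased coin then picks the
score-minimizing arm with probability ``assignment_prob`` (ties broken
by a fair draw from the same seeded stream, never by arm order), and
otherwise draws uniformly among the remaining arms. ``assignment_prob=1``
gives deterministic minimization.

The allocator never looks at outcomes or at anything beyond the factor
levels; with one factor and a deterministic coin it degenerates to
marginal balancing with ``|n_A − n_B| ≤ 1`` inside every level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator


class AllocationConfig(BaseModel):
    """Factors, weights, imbalance metric, and biased-coin probability."""

    factors: dict[str, list[str]]
    factor_weights: dict[str, float] = Field(default_factory=dict)
    imbalance_method: Literal["range", "variance"] = "range"
    assignment_prob: float = 0.8
    arms: list[str] = Field(default_factory=lambda: ["sm_only", "sm_feedback"])
    seed: int = 0

    @field_validator("assignment_prob")
    @classmethod
    def _coin_biased_toward_minimizer(cls, v: float) -> float:
        if not (0.5 < v <= 1.0):
            raise ValueError("assignment_prob must be in (0.5, 1]")
        return v

    @field_validator("factor_weights")
    @classmethod
    def _weights_positive(cls, w: dict[str, float]) -> dict[str, float]:
        if any(x <= 0 for x in w.values()):
            raise ValueError("factor weights must be positive")
        return w

    def weight(self, factor: str) -> float:
        return self.factor_weights.get(factor, 1.0)


class AllocationError(Exception):
    pass


@dataclass
class AllocationState:
    """Per-arm marginal counts by prognostic-factor level; append-only."""

    arms: list[str]
    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    total_per_arm: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in self.arms:
            self.total_per_arm.setdefault(a, 0)

    def count(self, factor: str, level: str, arm: str) -> int:
        return self.counts.get((factor, level, arm), 0)

    def add(self, levels: dict[str, str], arm: str) -> None:
        if arm not in self.arms:
            raise AllocationError(f"unknown arm {arm}")
        for f, l in levels.items():
            key = (f, l, arm)
            self.counts[key] = self.counts.get(key, 0) + 1
        self.total_per_arm[arm] += 1

    @property
    def n(self) -> int:
        return sum(self.total_per_arm.values())


def _spread(values: Sequence[int], method: str) -> float:
    if method == "range":
        return float(max(values) - min(values))
    if method == "variance":
        return float(np.var(values))  # population variance
    raise AllocationError(f"unknown imbalance method {method}")


def imbalance(
    state: AllocationState,
    config: AllocationConfig,
    participant_levels: dict[str, str],
    candidate_arm: str,
) -> float:
    """Imbalance score if the participant joined ``candidate_arm``.

    Weighted sum, over factors, of the across-arm spread of the marginal
    count at the participant's level after the hypothetical addition.
    """
    for f in config.factors:
        if f not in participant_levels:
            raise AllocationError(f"participant missing factor {f}")
        if participant_levels[f] not in config.factors[f]:
            raise AllocationError(
                f"unknown level {participant_levels[f]!r} for factor {f}"
            )
    score = 0.0
    for f in config.factors:
        l = participant_levels[f]
        hypo = [
            state.count(f, l, a) + (1 if a == candidate_arm else 0)
            for a in state.arms
        ]
        score += config.weight(f) * _spread(hypo, config.imbalance_method)
    return score


@dataclass
class AllocationRecord:
    order: int
    study_id: str
    levels: dict[str, str]
    scores: dict[str, float]
    arm: str
    coin: Optional[float]  # None when all arms tied (pure fair draw)


class Minimizer:
    """Stateful allocator: seeded stream + allocation state + audit log.

    Replaying the same ordered participant stream with the same seed
    reproduces the identical arm sequence.
    """

    def __init__(self, config: AllocationConfig, seed: Optional[int] = None) -> None:
        self.config = config
        self.state = AllocationState(arms=list(config.arms))
        self.rng = np.random.default_rng(config.seed if seed is None else seed)
        self.log: list[AllocationRecord] = []
        self._allocated: set[str] = set()

    def allocate(self, study_id: str, participant_levels: dict[str, str]) -> str:
        """Assign an arm and update the marginal-count state."""
        if study_id in self._allocated:
            raise AllocationError(f"{study_id} already allocated")
        scores = {
            a: imbalance(self.state, self.config, participant_levels, a)
            for a in self.state.arms
        }
        best = min(scores.values())
        minimizers = [a for a in self.state.arms if scores[a] == best]
        coin: Optional[float] = None
        if len(minimizers) == len(self.state.arms):
            # complete tie (e.g. the very first participant): fair draw
            arm = minimizers[int(self.rng.integers(len(minimizers)))]
        else:
            coin = float(self.rng.random())
            if coin < self.config.assignment_prob:
                arm = minimizers[int(self.rng.integers(len(minimizers)))]
            else:
                rest = [a for a in self.state.arms if a not in minimizers]
                arm = rest[int(self.rng.integers(len(rest)))]
        self.state.add({f: participant_levels[f] for f in self.config.factors}, arm)
        self._allocated.add(study_id)
        self.log.append(
            AllocationRecord(
                order=len(self.log) + 1,
                study_id=study_id,
                levels=dict(participant_levels),
                scores=scores,
                arm=arm,
                coin=coin,
            )
        )
        return arm

    def log_frame(self):
        """Allocation audit log as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for r in self.log:
            row = {"order": r.order, "study_id": r.study_id, "arm": r.arm,
                   "coin": r.coin}
            row.update({f"level_{f}": l for f, l in r.levels.items()})
            row.update({f"score_{a}": s for a, s in r.scores.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def simple_randomization(
    n: int, arms: Sequence[str], rng: np.random.Generator
) -> list[str]:
    """Unrestricted equal-probability randomization (comparison baseline)."""
    return [arms[int(k)] for k in rng.integers(len(arms), size=n)]


def max_marginal_imbalance(
    state: AllocationState, config: AllocationConfig
) -> int:
    """Largest ``|n_A − n_B|`` over all factor levels (2-arm) — or, for
    k arms, the largest across-arm range of any level's marginal counts."""
    worst = 0
    for f, levels in config.factors.items():
        for l in levels:
            counts = [state.count(f, l, a) for a in state.arms]
            worst = max(worst, max(counts) - min(counts))
    return worst
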