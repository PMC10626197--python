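"""Acquisition scoring and constrained batch selection.

Four strategies score unlabeled candidates from their predictive
distribution: brute force (seeded noise, i.e. random querying), greedy
(exploitation, mu), pure exploration (sigma), and the upper confidence bound
UCB = mu + kappa * sigma (default kappa = 1).  Batches are then drawn down
the score ranking under one of the experimental-round regimes: unconstrained
top-k, drug-disjoint (each drug at most once per batch), diversity-first
(every queried combination must introduce a drug not yet used), or per-drug
capped (a drug appears at most ``cap`` times per batch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .uncertainty import PredictiveDistribution

__all__ = [
    "Strategy",
    "AcquisitionSpec",
    "BatchConstraints",
    "acquisition_scores",
    "rank_candidates",
    "select_batch_topk",
    "select_batch_diverse",
    "select_batch_capped",
    "select_batch",
]


class Strategy(str, Enum):
    brute_force = "brute_force"
    greedy = "greedy"
    pure_exploration = "pure_exploration"
    ucb = "ucb"


@dataclass
class AcquisitionSpec:
    strategy: str | Strategy = Strategy.ucb
    kappa: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.strategy = Strategy(self.strategy)
        if not np.isfinite(self.kappa):
            raise ValueError("kappa must be finite")


@dataclass
class BatchConstraints:
    regime: str = "unconstrained"  # unconstrained | drug_disjoint | diversity_first | per_drug_cap
    batch_size: int = 30
    cap: int = 5
    used_drugs: set = field(default_factory=set)
    cumulative_cap: bool = False

    def __post_init__(self):
        if self.batch_size < 1 or self.cap < 1:
            raise ValueError("batch_size and cap must be >= 1")
        if self.regime not in ("unconstrained", "drug_disjoint",
                               "diversity_first", "per_drug_cap"):
            raise ValueError(f"unknown constraint regime '{self.regime}'")


def acquisition_scores(pred: PredictiveDistribution, spec: AcquisitionSpec) -> np.ndarray:
    """Score each candidate under the chosen strategy."""
    if len(pred) == 0:
        return np.zeros(0)
    strategy = Strategy(spec.strategy)
    if strategy is Strategy.brute_force:
        return np.random.default_rng(spec.seed).uniform(size=len(pred))
    if strategy is Strategy.greedy:
        return pred.mu.copy()
    if strategy is Strategy.pure_exploration:
        return pred.sigma.copy()
    return pred.mu + spec.kappa * pred.sigma


def rank_candidates(scores: np.ndarray, seed: int = 0) -> np.ndarray:
    """Indices in descending score order; equal scores broken by a seeded
    random key so rankings are reproducible."""
    scores = np.asarray(scores, dtype=float)
    tiebreak = np.random.default_rng(seed).random(len(scores))
    return np.lexsort((tiebreak, -scores))


def select_batch_topk(
    scores: np.ndarray,
    candidates: list[tuple],
    batch_size: int,
    drug_disjoint: bool = False,
    seed: int = 0,
) -> tuple[list[int], bool]:
    """Greedy descending-score selection; optionally skip a candidate when
    either of its drugs already appears in the batch.  Returns the selected
    indices and a warning flag set when fewer eligible candidates than
    ``batch_size`` were available."""
    order = rank_candidates(scores, seed)
    selected: list[int] = []
    batch_drugs: set = set()
    for i in order:
        if len(selected) == batch_size:
            break
        a, b = candidates[i][0], candidates[i][1]
        if drug_disjoint and (a in batch_drugs or b in batch_drugs):
            continue
        selected.append(int(i))
        batch_drugs.update((a, b))
    return selected, len(selected) < batch_size


def select_batch_diverse(
    scores: np.ndarray,
    candidates: list[tuple],
    used_drugs: set,
    batch_size: int = 30,
    seed: int = 0,
) -> tuple[list[int], bool]:
    """Diversity-first selection: walk down the ranking and add each
    candidate that involves at least one drug absent from
    ``used_drugs`` and the current batch, until the batch is full."""
    order = rank_candidates(scores, seed)
    seen = set(used_drugs)
    selected: list[int] = []
    for i in order:
        if len(selected) == batch_size:
            break
        a, b = candidates[i][0], candidates[i][1]
        if a not in seen or b not in seen:
            selected.append(int(i))
            seen.update((a, b))
    return selected, len(selected) < batch_size


def select_batch_capped(
    scores: np.ndarray,
    candidates: list[tuple],
    cap: int = 5,
    batch_size: int = 30,
    seed: int = 0,
    prior_counts: dict | None = None,
) -> tuple[list[int], bool]:
    """Descending-score selection skipping any candidate that would push
    either drug's appearance count above ``cap``.  Counts are per batch by
    default; pass ``prior_counts`` (appearances in earlier rounds) for the
    cumulative-history variant."""
    order = rank_candidates(scores, seed)
    counts: dict = dict(prior_counts or {})
    selected: list[int] = []
    for i in order:
        if len(selected) == batch_size:
            break
        a, b = candidates[i][0], candidates[i][1]
        if counts.get(a, 0) + 1 > cap or counts.get(b, 0) + 1 > cap:
            continue
        selected.append(int(i))
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    return selected, len(selected) < batch_size


def select_batch(
    scores: np.ndarray,
    candidates: list[tuple],
    constraints: BatchConstraints,
    seed: int = 0,
    prior_counts: dict | None = None,
) -> tuple[list[int], bool]:
    """Dispatch to the regime-specific selector."""
    if constraints.regime == "unconstrained":
        return select_batch_topk(scores, candidates, constraints.batch_size, seed=seed)
    if constraints.regime == "drug_disjoint":
        return select_batch_topk(scores, candidates, constraints.batch_size,
                                 drug_disjoint=True, seed=seed)
    if constraints.regime == "diversity_first":
        return select_batch_diverse(scores, candidates, constraints.used_drugs,
                                    constraints.batch_size, seed=seed)
    return select_batch_capped(
        scores, candidates, constraints.cap, constraints.batch_size, seed=seed,
        prior_counts=(prior_counts if constraints.cumulative_cap else None),
    )
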