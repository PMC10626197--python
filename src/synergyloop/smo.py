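"""The sequential-model-optimization loop and the fine-tuning ensemble.

Each round: split the visible (labeled) set 80/20 into train/validation,
train a fresh model ensemble from scratch with early stopping, score the
hidden pool with an acquisition function, select a batch under the round's
constraints, query the oracle, and move the batch into the visible set.
Retraining from scratch every round avoids overfitting to early
acquisitions.  The trajectory records every round's queries, observations,
scores and seeds and serialises to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionSpec, BatchConstraints, Strategy, acquisition_scores, select_batch
from .dose_response import SynergyRecord
from .featurization import CellLineFeatures, DrugFeatureMatrix
from .model import RecoverConfig, RecoverModel, train_model
from .uncertainty import (Ensemble, PredictiveDistribution, ensemble_predict,
                          train_deup_pair, train_ensemble)

__all__ = ["SMOState", "SMOTrajectory", "run_smo", "fine_tune_ensemble"]


@dataclass
class SMOState:
    """Visible (labeled) and hidden candidate indices at round t."""

    visible: list[int]
    hidden: list[int]
    round_index: int = 0
    failed: list[int] = field(default_factory=list)

    def __post_init__(self):
        if set(self.visible) & set(self.hidden):
            raise ValueError("visible and hidden pools must be disjoint")


@dataclass
class RoundRecord:
    round_index: int
    queried: list[tuple]
    observed: list[float]
    failed: list[tuple]
    strategy: str
    metrics: dict = field(default_factory=dict)


@dataclass
class SMOTrajectory:
    """Audit trail of one simulated campaign."""

    pool: list[tuple]
    rounds: list[RoundRecord]
    seed: int
    config: dict = field(default_factory=dict)

    def queried_per_round(self) -> list[list[tuple]]:
        return [r.queried for r in self.rounds]

    def all_queried(self) -> list[tuple]:
        return [p for r in self.rounds for p in r.queried]

    def observed_synergies(self) -> np.ndarray:
        return np.asarray([y for r in self.rounds for y in r.observed])

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "config": self.config,
            "pool": [list(p) for p in self.pool],
            "rounds": [
                {
                    "round_index": r.round_index,
                    "queried": [list(p) for p in r.queried],
                    "observed": list(map(float, r.observed)),
                    "failed": [list(p) for p in r.failed],
                    "strategy": r.strategy,
                    "metrics": r.metrics,
                }
                for r in self.rounds
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "SMOTrajectory":
        try:
            payload = json.loads(path_or_text)
        except (json.JSONDecodeError, TypeError):
            with open(path_or_text) as fh:
                payload = json.load(fh)
        rounds = [
            RoundRecord(r["round_index"], [tuple(p) for p in r["queried"]],
                        r["observed"], [tuple(p) for p in r["failed"]],
                        r["strategy"], r.get("metrics", {}))
            for r in payload["rounds"]
        ]
        return cls([tuple(p) for p in payload["pool"]], rounds,
                   payload["seed"], payload.get("config", {}))


def _query(oracle, pair):
    if callable(oracle):
        return float(oracle(pair))
    key = tuple(sorted(pair[:2]))
    if key in oracle:
        return float(oracle[key])
    return float(oracle[tuple(pair[:2])])


def run_smo(
    pool: list[tuple],
    oracle,
    drug_features: DrugFeatureMatrix,
    cell_features: CellLineFeatures | None = None,
    init_size: int = 30,
    spec: AcquisitionSpec | None = None,
    constraints: BatchConstraints | None = None,
    config: RecoverConfig | None = None,
    uncertainty_method: str = "ensemble",
    n_ensemble: int = 5,
    n_rounds: int = 10,
    seed: int = 0,
    cell_line: str = "",
) -> SMOTrajectory:
    """Simulate a sequential campaign over a candidate pool.

    ``oracle`` maps a pair to its measured synergy (callable or dict keyed by
    the sorted pair); an oracle exception marks the candidate failed: it is
    logged, removed from the pool and never retried.  Round 0 seeds the
    visible set with ``init_size`` uniformly random candidates; each of the
    ``n_rounds`` subsequent rounds retrains from scratch, scores the hidden
    pool, selects ``constraints.batch_size`` candidates and queries them.

    Rounds whose strategy is brute force skip the (irrelevant) model
    retraining; their scores are seeded noise either way.
    """
    spec = spec or AcquisitionSpec()
    constraints = constraints or BatchConstraints()
    config = config or RecoverConfig()
    if len(pool) < init_size:
        raise ValueError(f"pool of {len(pool)} smaller than init_size={init_size}")
    rng = np.random.default_rng(seed)
    pool = [tuple(p) for p in pool]

    visible: list[int] = []
    records: list[SynergyRecord] = []
    rounds: list[RoundRecord] = []
    failed_pairs: list[tuple] = []

    def acquire(indices: list[int], round_index: int, strategy: str, metrics: dict):
        queried, observed, failed = [], [], []
        for i in indices:
            pair = pool[i]
            try:
                yv = _query(oracle, pair)
            except Exception:
                failed.append(pair)
                failed_pairs.append(pair)
                continue
            queried.append(pair)
            observed.append(yv)
            visible.append(i)
            records.append(SynergyRecord(pair[0], pair[1], cell_line, yv))
        rounds.append(RoundRecord(round_index, queried, observed, failed,
                                  strategy, metrics))

    init_idx = rng.choice(len(pool), size=init_size, replace=False).tolist()
    acquire(init_idx, 0, "random_init", {})
    hidden = [i for i in range(len(pool))
              if i not in set(visible) and pool[i] not in set(failed_pairs)]

    drug_counts: dict = {}
    for t in range(1, n_rounds + 1):
        if not hidden:
            break
        hidden_pairs = [pool[i] for i in hidden]
        round_seed = int(rng.integers(2 ** 31 - 1))
        round_spec = AcquisitionSpec(spec.strategy, spec.kappa, seed=round_seed)
        metrics: dict = {}
        if Strategy(spec.strategy) is Strategy.brute_force:
            pred = PredictiveDistribution(np.zeros(len(hidden)), np.zeros(len(hidden)),
                                          method="none", pairs=hidden_pairs)
        elif uncertainty_method == "deup":
            deup = train_deup_pair(records, config, drug_features, cell_features,
                                   seed=round_seed)
            pred = deup.predict(hidden_pairs)
        else:
            ens = train_ensemble(records, config, drug_features, cell_features,
                                 n_members=n_ensemble, base_seed=round_seed)
            pred = ensemble_predict(ens, hidden_pairs)
            metrics["val_mse"] = [r.best_validation_mse for r in ens.reports]
        scores = acquisition_scores(pred, round_spec)
        constraints.used_drugs = {d for i in visible for d in pool[i][:2]}
        sel, _ = select_batch(scores, hidden_pairs, constraints, seed=round_seed,
                              prior_counts=drug_counts)
        batch = [hidden[j] for j in sel]
        acquire(batch, t, Strategy(spec.strategy).value, metrics)
        for i in batch:
            for d in pool[i][:2]:
                drug_counts[d] = drug_counts.get(d, 0) + 1
        taken = set(batch) | {i for i in hidden if pool[i] in set(failed_pairs)}
        hidden = [i for i in hidden if i not in taken]

    return SMOTrajectory(pool, rounds, seed, config.to_dict())


def fine_tune_ensemble(
    pretrained: list[RecoverModel],
    new_data: list[SynergyRecord],
    config: RecoverConfig,
    drug_features: DrugFeatureMatrix,
    cell_features: CellLineFeatures | None = None,
    n_finetune_seeds: int = 12,
    base_seed: int = 0,
) -> Ensemble:
    """Fine-tune each pretrained model on the new study only, once per seed.

    All weights are updated (no frozen layers); early stopping as in
    training.  The result is an ensemble of ``len(pretrained) *
    n_finetune_seeds`` members -- 3 pretrained x 12 fine-tune seeds = 36 in
    the recommendation configuration.
    """
    if not pretrained:
        raise ValueError("no pretrained models supplied")
    if not new_data:
        raise ValueError("no fine-tuning data supplied")
    if n_finetune_seeds < 1:
        raise ValueError("n_finetune_seeds must be >= 1 (an empty ensemble is forbidden)")
    members, reports = [], []
    s = base_seed
    for parent in pretrained:
        for _ in range(n_finetune_seeds):
            m, rep = train_model(new_data, config, drug_features, cell_features,
                                 seed=s, warm_start=parent)
            members.append(m)
            reports.append(rep)
            s += 1
    return Ensemble(members, reports)
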