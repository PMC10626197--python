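"""Evaluation harness: out-of-distribution splits, metrics, enrichment
curves, discovery rates, and replicate-noise performance bounds.

The split tasks probe increasingly hard generalisation: (default) test pairs
drawn from the training distribution, (one_unseen_drug) test pairs joining a
seen drug with one of a held-out 30% of drugs, (two_unseen_drugs) test pairs
of two held-out drugs, and (shuffled_labels) the default split after the
drug representations have been permuted among drugs -- a control that
measures how much signal identity alone carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dose_response import SynergyRecord

__all__ = [
    "SplitSpec",
    "MetricReport",
    "make_task_split",
    "regression_metrics",
    "reversed_cdf",
    "enrichment_ratio",
    "discovery_rate_curve",
    "noise_upper_bound",
    "SYNERGY_THRESHOLD",
]

# a combination counts as "synergistic" above this max-Bliss score; 40 is the
# stricter alternative used when summarising prospective hits
SYNERGY_THRESHOLD = 30.0


@dataclass
class SplitSpec:
    task: str = "default"  # default | one_unseen_drug | two_unseen_drugs | shuffled_labels
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    unseen_drug_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not 0 < self.unseen_drug_fraction < 1:
            raise ValueError("unseen_drug_fraction must be in (0, 1)")
        if self.task not in ("default", "one_unseen_drug", "two_unseen_drugs",
                             "shuffled_labels"):
            raise ValueError(f"unknown task '{self.task}'")


@dataclass
class MetricReport:
    r2: float
    spearman: float
    weighted_explained_variance: float | None = None
    n: int = 0
    degenerate: bool = False


def make_task_split(
    records: list[SynergyRecord], spec: SplitSpec
) -> tuple[list[SynergyRecord], list[SynergyRecord], list[SynergyRecord]]:
    """Split combination records into (train, validation, test) per task.

    ``default`` and ``shuffled_labels`` split uniformly by the stated
    fractions (the label-shuffling itself acts on the feature matrix via
    ``featurization.randomize_features(fraction=1)`` and is applied by the
    caller).  The unseen-drug tasks hold out ``unseen_drug_fraction`` of the
    drugs; the test set is the pairs with exactly one (or both) held-out
    drugs and the remaining seen-seen pairs are split 80/20 into
    train/validation.  Pairs that match neither side of the definition
    (e.g. both-unseen pairs in the one-unseen task) are ineligible and
    dropped.
    """
    if not records:
        raise ValueError("no records to split")
    rng = np.random.default_rng(spec.seed)
    n = len(records)
    if spec.task in ("default", "shuffled_labels"):
        order = rng.permutation(n)
        n_train = int(np.floor(spec.fractions[0] * n))
        n_val = int(np.floor(spec.fractions[1] * n))
        train = [records[i] for i in order[:n_train]]
        val = [records[i] for i in order[n_train:n_train + n_val]]
        test = [records[i] for i in order[n_train + n_val:]]
    else:
        drugs = sorted({d for r in records for d in r.pair})
        n_held = max(1, int(round(spec.unseen_drug_fraction * len(drugs))))
        held = set(rng.choice(drugs, size=n_held, replace=False).tolist())
        want_unseen = 1 if spec.task == "one_unseen_drug" else 2
        test = [r for r in records
                if sum(d in held for d in r.pair) == want_unseen]
        seen_seen = [r for r in records if all(d not in held for d in r.pair)]
        order = rng.permutation(len(seen_seen))
        n_train = int(round(0.8 * len(seen_seen)))
        train = [seen_seen[i] for i in order[:n_train]]
        val = [seen_seen[i] for i in order[n_train:]]
    if not test:
        raise ValueError(
            f"task '{spec.task}' produced an empty test set "
            f"(n_records={n}, n_train={len(train)}, n_val={len(val)})"
        )
    return train, val, test


def regression_metrics(y, yhat, sigma=None) -> MetricReport:
    """R^2, Spearman rank correlation (average ranks for ties) and, when
    per-prediction uncertainties are supplied, explained variance weighted by
    w_i = 1/sigma_i (weighted means throughout)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must share a length >= 2")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return MetricReport(r2=np.nan, spearman=np.nan, n=y.size, degenerate=True)
    r2 = float(1 - np.sum((y - yhat) ** 2) / ss_tot)
    # a constant prediction vector has no rank ordering to correlate
    rho = (float(stats.spearmanr(y, yhat).statistic)
           if np.std(yhat) > 0 else np.nan)
    ev_w = None
    if sigma is not None:
        w = 1.0 / np.asarray(sigma, dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights 1/sigma must be positive and finite")
        resid = y - yhat
        var_res = np.average((resid - np.average(resid, weights=w)) ** 2, weights=w)
        var_y = np.average((y - np.average(y, weights=w)) ** 2, weights=w)
        ev_w = float(1 - var_res / var_y) if var_y > 0 else np.nan
    return MetricReport(r2=r2, spearman=rho, weighted_explained_variance=ev_w, n=y.size)


def reversed_cdf(synergies, thresholds) -> np.ndarray:
    """P(S >= s) for each threshold s: the fraction of queried combinations
    at or above each synergy level.  Non-increasing in s."""
    synergies = np.asarray(synergies, dtype=float)
    if synergies.size == 0:
        raise ValueError("empty synergy sample")
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    return (synergies[None, :] >= thresholds[:, None]).mean(axis=1)


def enrichment_ratio(strategy_synergies, random_synergies, thresholds) -> np.ndarray:
    """Elementwise ratio of the strategy's reversed CDF to random's; NaN
    marks thresholds where the random density is 0 (undefined ratio)."""
    num = reversed_cdf(strategy_synergies, thresholds)
    den = reversed_cdf(random_synergies, thresholds)
    out = np.full_like(num, np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def discovery_rate_curve(trajectory, top_set: set) -> np.ndarray:
    """Per-round fraction of the top-synergy set already unblinded.

    ``trajectory`` is an :class:`~synergyloop.smo.SMOTrajectory`;
    ``top_set`` the candidate pairs (canonical order) in the true top 1%.
    Entry 0 is the random initial set; the curve is non-decreasing and
    reaches 1 exactly when every top candidate has been queried.
    """
    if not top_set:
        raise ValueError("empty top set")
    top = {tuple(sorted(p[:2])) for p in top_set}
    curve = []
    found: set = set()
    for batch in trajectory.queried_per_round():
        found |= {tuple(sorted(p[:2])) for p in batch}
        curve.append(len(found & top) / len(top))
    return np.asarray(curve)


def noise_upper_bound(
    true_synergies,
    eta: float,
    metric: str = "spearman",
    n_sims: int = 100,
    seed: int = 0,
) -> float:
    """Performance ceiling implied by replicate noise.

    Corrupt the true synergies with Gaussian noise of level ``eta``, imagine
    a perfect regressor that fits the noisy observations exactly, and score
    it against the true values; the average over ``n_sims`` simulations
    bounds what any model evaluated on noisy labels can achieve.
    """
    y = np.asarray(true_synergies, dtype=float)
    if eta < 0 or n_sims < 1:
        raise ValueError("eta must be >= 0 and n_sims >= 1")
    if y.std() == 0:
        raise ValueError("degenerate (constant) synergy distribution")
    if metric not in ("r2", "spearman"):
        raise ValueError(f"unknown metric '{metric}'")
    if eta == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    vals = []
    ss_tot = np.sum((y - y.mean()) ** 2)
    for _ in range(n_sims):
        noisy = y + rng.normal(0.0, eta, size=y.shape)
        if metric == "r2":
            vals.append(1 - np.sum((noisy - y) ** 2) / ss_tot)
        else:
            vals.append(stats.spearmanr(y, noisy).statistic)
    return float(np.mean(vals))
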