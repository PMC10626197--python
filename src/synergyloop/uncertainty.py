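"""Predictive-distribution estimation.

Two estimators of the predictive distribution p(s | {d1, d2}) are provided:

* **Deep ensembles** -- several networks trained on identical data differing
  only in their initialisation seed; the member mean is the predicted synergy
  and the member standard deviation (population convention: the ensemble *is*
  the predictive sample) is the uncertainty.
* **Direct (DEUP-style) estimation** -- a frozen MSE-trained *mean predictor*
  plus a second *uncertainty predictor* of the same architecture trained
  against the mean predictor's residuals with the Gaussian negative
  log-likelihood  NLL = log(sigma^2)/2 + (y - mu)^2 / (2 sigma^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import SynergyRecord
from .featurization import CellLineFeatures, DrugFeatureMatrix
from .model import RecoverConfig, RecoverModel, TrainReport, _design_matrices, _fit, train_model

__all__ = [
    "PredictiveDistribution",
    "Ensemble",
    "train_ensemble",
    "ensemble_predict",
    "nll_loss",
    "DeupPredictor",
    "train_deup_pair",
    "SIGMA_FLOOR",
]

SIGMA_FLOOR = 1e-3  # NLL diverges as sigma -> 0; predictions are floored here


@dataclass
class PredictiveDistribution:
    """Per-candidate predictive mean and uncertainty."""

    mu: np.ndarray
    sigma: np.ndarray
    method: str = "ensemble"
    pairs: list = field(default_factory=list)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("mu must be finite")

    def __len__(self) -> int:
        return len(self.mu)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.mu)):
            p = self.pairs[i] if self.pairs else ("", "", "")
            rows.append((p[0], p[1], p[2] if len(p) > 2 else "",
                         self.mu[i], self.sigma[i], self.method))
        return pd.DataFrame(rows, columns=["drug_a", "drug_b", "cell_line",
                                           "mu", "sigma", "method"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class Ensemble:
    """Networks trained with distinct seeds on identical data."""

    members: list[RecoverModel]
    reports: list[TrainReport] = field(default_factory=list)

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValueError("an ensemble needs at least one member")

    @property
    def size(self) -> int:
        return len(self.members)


def train_ensemble(
    dataset: list[SynergyRecord],
    config: RecoverConfig,
    drug_features: DrugFeatureMatrix,
    cell_features: CellLineFeatures | None = None,
    n_members: int = 5,
    base_seed: int = 0,
) -> Ensemble:
    """Train ``n_members`` networks with seeds base_seed..base_seed+n-1."""
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    members, reports = [], []
    for i in range(n_members):
        m, rep = train_model(dataset, config, drug_features, cell_features,
                             seed=base_seed + i)
        members.append(m)
        reports.append(rep)
    return Ensemble(members, reports)


def ensemble_predict(ensemble: Ensemble, pairs) -> PredictiveDistribution:
    """Member-mean and member population standard deviation per candidate."""
    preds = np.stack([m.predict(pairs) for m in ensemble.members])
    return PredictiveDistribution(
        mu=preds.mean(axis=0),
        sigma=preds.std(axis=0, ddof=0),
        method="ensemble",
        pairs=list(pairs),
    )


def nll_loss(y, mu, sigma):
    """Gaussian negative log-likelihood (up to the constant log(2 pi)/2).

    ``NLL = log(sigma^2)/2 + (y - mu)^2 / (2 sigma^2)``.  With sigma fixed at
    1 this reduces to half the squared error, i.e. the MSE criterion.
    Elementwise on array input.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    out = 0.5 * np.log(sigma ** 2) + (y - mu) ** 2 / (2.0 * sigma ** 2)
    return float(out) if out.ndim == 0 else out


class DeupPredictor:
    """Frozen mean predictor + trained uncertainty predictor."""

    def __init__(self, mean_model: RecoverModel, sigma_model: RecoverModel):
        self.mean_model = mean_model
        self.sigma_model = sigma_model

    def predict(self, pairs) -> PredictiveDistribution:
        mu = self.mean_model.predict(pairs)
        log_var = self.sigma_model.predict(pairs)
        sigma = np.maximum(np.exp(0.5 * np.clip(log_var, -40, 40)), SIGMA_FLOOR)
        return PredictiveDistribution(mu=mu, sigma=sigma, method="deup",
                                      pairs=list(pairs))


def train_deup_pair(
    dataset: list[SynergyRecord],
    config: RecoverConfig,
    drug_features: DrugFeatureMatrix,
    cell_features: CellLineFeatures | None = None,
    seed: int | None = None,
    sigma_config: RecoverConfig | None = None,
    n_folds: int = 5,
) -> DeupPredictor:
    """Train the mean predictor (MSE), freeze it, then train the uncertainty
    predictor on its residuals with the Gaussian NLL.

    The residual targets are computed *out of fold*: ``n_folds`` auxiliary
    mean predictors, each trained with the same configuration on the
    complementary folds, supply the residual for every record.  In-sample
    residuals of a flexible network understate (and destructure) the
    predictive spread it actually has on unqueried candidates, which is what
    the uncertainty predictor is for.  The uncertainty predictor mirrors the
    main architecture but its scalar output parameterises log(sigma^2);
    predictions are floored at ``SIGMA_FLOOR`` so sigma is always strictly
    positive.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    seed = config.seed if seed is None else seed
    mean_model, _ = train_model(dataset, config, drug_features, cell_features,
                                seed=seed)
    y = np.array([r.synergy for r in dataset])
    pairs = [(r.drug_a, r.drug_b, r.cell_line) for r in dataset]
    resid = np.empty(len(dataset))
    if n_folds >= 2 and len(dataset) >= 2 * n_folds:
        folds = np.random.default_rng(seed).permutation(len(dataset)) % n_folds
        for f in range(n_folds):
            held = np.where(folds == f)[0]
            rest = [dataset[i] for i in np.where(folds != f)[0]]
            aux, _ = train_model(rest, config, drug_features, cell_features,
                                 seed=seed + 100 + f)
            resid[held] = y[held] - aux.predict([pairs[i] for i in held])
    else:
        resid = y - mean_model.predict(pairs)
    sigma_config = sigma_config or config
    rng = np.random.default_rng(seed + 1)
    sigma_model = RecoverModel(
        sigma_config, l_D=drug_features.l_D,
        l_C=(cell_features.X.shape[1] if cell_features is not None else 0),
        seed=seed + 1,
    )
    # start the log-variance head at the marginal residual variance so the
    # NLL optimisation begins in the right scale
    last = sigma_model.n_head_layers - 1
    sigma_model.params[f"head.b{last}"][:] = np.log(max(np.mean(resid ** 2), 1e-6))
    X1, X2, C, _ = _design_matrices(dataset, drug_features, cell_features)
    _fit(sigma_model, X1, X2, C, resid, sigma_config, rng, loss="nll_logvar")
    sigma_model.drug_features = drug_features
    sigma_model.cell_features = cell_features
    return DeupPredictor(mean_model, sigma_model)
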