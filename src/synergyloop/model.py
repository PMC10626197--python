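"""Permutation-invariant synergy regression.

The architecture has two parts.  A *single-drug encoder* ``E`` (an MLP,
optionally FiLM-conditioned on cell-line features) maps each drug's raw
feature row to an embedding in ``R^{k_D}``.  A *combination module* pairs two
embeddings through a bilinear tensor ``B`` in ``R^{k_D x k_D x k}`` whose
slices are symmetrised at evaluation time, ``z_i = e1' (W_i + W_i')/2 e2``,
making the prediction exactly invariant to drug order; a small MLP head then
maps ``z`` to the scalar synergy.  Training minimises mean squared error
with Adam and early stopping on a held-out validation split.

The module is presented statsmodels-style: :class:`SynergyRegression` is
built from a records table plus feature matrices, and ``fit()`` returns a
:class:`SynergyRegressionResults` carrying the trained network, diagnostics
and a ``summary()``.  The functional wrappers (``train_model``,
``predict_synergy``, ...) expose the same operations for pipeline code.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import _nn
from .dose_response import SynergyRecord
from .featurization import CellLineFeatures, DrugFeatureMatrix

__all__ = [
    "RecoverConfig",
    "RecoverModel",
    "TrainReport",
    "SynergyRegression",
    "SynergyRegressionResults",
    "film_modulate",
    "encode_drug",
    "combine_pair",
    "train_model",
    "predict_synergy",
    "DeepSynergyBaseline",
    "deepsynergy_baseline",
]


@dataclass
class RecoverConfig:
    """Hyperparameters of the synergy-regression network.

    Defaults: batch size 128, embedding 128, encoder hidden [1024], head
    hidden [64]; learning rate and weight decay default to 1e-4 (both worth
    tuning per dataset; see docs/methods.md for the searched grids).
    """

    single_hidden_dims: list[int] = field(default_factory=lambda: [1024])
    drug_embedding_dim: int = 128
    bilinear_dim: int = 64
    combination_hidden_dims: list[int] = field(default_factory=lambda: [64])
    batch_size: int = 128
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    max_epochs: int = 500
    patience: int = 20
    seed: int = 0

    def __post_init__(self):
        dims = ([self.drug_embedding_dim, self.bilinear_dim, self.batch_size]
                + list(self.single_hidden_dims) + list(self.combination_hidden_dims))
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RecoverConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RecoverConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class TrainReport:
    epochs_run: int
    best_validation_mse: float
    train_loss_trace: list[float]
    criterion: str = "mse"

    def __post_init__(self):
        # the Gaussian NLL criterion is legitimately negative; MSE is not
        if self.criterion == "mse" and self.best_validation_mse < 0:
            raise ValueError("validation MSE cannot be negative")


class RecoverModel:
    """The trained (or freshly initialised) network: parameters + geometry."""

    def __init__(self, config: RecoverConfig, l_D: int, l_C: int = 0, seed: int | None = None):
        self.config = config
        self.l_D = l_D
        self.l_C = l_C
        rng = np.random.default_rng(config.seed if seed is None else seed)
        kD, k = config.drug_embedding_dim, config.bilinear_dim
        enc_dims = [l_D] + list(config.single_hidden_dims) + [kD]
        head_dims = [k] + list(config.combination_hidden_dims) + [1]
        self.n_enc_layers = len(enc_dims) - 1
        self.n_head_layers = len(head_dims) - 1
        self.params: dict[str, np.ndarray] = {}
        for name, val in _nn.init_mlp(rng, enc_dims).items():
            self.params[f"enc.{name}"] = val
        self.params["B"] = rng.normal(0.0, 1.0 / np.sqrt(kD), size=(k, kD, kD))
        for name, val in _nn.init_mlp(rng, head_dims).items():
            self.params[f"head.{name}"] = val
        if l_C > 0:
            for name, val in _nn.init_film(rng, l_C, list(config.single_hidden_dims)).items():
                self.params[f"encfilm.{name}"] = val
            for name, val in _nn.init_film(rng, l_C, list(config.combination_hidden_dims)).items():
                self.params[f"headfilm.{name}"] = val
        # feature matrices bound at fit time so id-based prediction works
        self.drug_features: DrugFeatureMatrix | None = None
        self.cell_features: CellLineFeatures | None = None

    # -- parameter views ----------------------------------------------------
    def _sub(self, prefix: str) -> dict[str, np.ndarray]:
        plen = len(prefix) + 1
        return {k[plen:]: v for k, v in self.params.items() if k.startswith(prefix + ".")}

    def copy(self) -> "RecoverModel":
        clone = copy.copy(self)
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone

    # -- forward / backward -------------------------------------------------
    def forward(self, X1: np.ndarray, X2: np.ndarray, C: np.ndarray | None = None):
        enc, encf = self._sub("enc"), (self._sub("encfilm") or None)
        head, headf = self._sub("head"), (self._sub("headfilm") or None)
        e1, c1 = _nn.mlp_forward(enc, self.n_enc_layers, X1, film=encf, cell=C)
        e2, c2 = _nn.mlp_forward(enc, self.n_enc_layers, X2, film=encf, cell=C)
        z = _nn.sym_bilinear_forward(self.params["B"], e1, e2)
        y, ch = _nn.mlp_forward(head, self.n_head_layers, z, film=headf, cell=C)
        cache = {"c1": c1, "c2": c2, "ch": ch, "e1": e1, "e2": e2, "C": C}
        return y[:, 0], cache

    def backward(self, cache: dict, dy: np.ndarray) -> dict[str, np.ndarray]:
        enc, encf = self._sub("enc"), (self._sub("encfilm") or None)
        head, headf = self._sub("head"), (self._sub("headfilm") or None)
        C = cache["C"]
        grads: dict[str, np.ndarray] = {}
        hg: dict[str, np.ndarray] = {}
        hfg: dict[str, np.ndarray] = {}
        dz = _nn.mlp_backward(head, self.n_head_layers, cache["ch"], dy[:, None],
                              hg, film=headf, film_grads=hfg, cell=C)
        dB, de1, de2 = _nn.sym_bilinear_backward(
            self.params["B"], cache["e1"], cache["e2"], dz)
        eg: dict[str, np.ndarray] = {}
        efg: dict[str, np.ndarray] = {}
        _nn.mlp_backward(enc, self.n_enc_layers, cache["c1"], de1, eg,
                         film=encf, film_grads=efg, cell=C)
        _nn.mlp_backward(enc, self.n_enc_layers, cache["c2"], de2, eg,
                         film=encf, film_grads=efg, cell=C)
        grads["B"] = dB
        for name, g in eg.items():
            grads[f"enc.{name}"] = g
        for name, g in hg.items():
            grads[f"head.{name}"] = g
        for name, g in efg.items():
            grads[f"encfilm.{name}"] = g
        for name, g in hfg.items():
            grads[f"headfilm.{name}"] = g
        return grads

    # -- id-based prediction -------------------------------------------------
    def _rows_for_pairs(self, pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        if self.drug_features is None:
            raise ValueError("model has no bound drug features; fit it or set drug_features")
        idx = self.drug_features.index
        unknown = sorted({d for p in pairs for d in p[:2] if d not in idx})
        if unknown:
            raise KeyError(f"unknown drug ids: {unknown}")
        X1 = np.stack([self.drug_features.X[idx[p[0]]] for p in pairs])
        X2 = np.stack([self.drug_features.X[idx[p[1]]] for p in pairs])
        C = None
        if self.l_C > 0:
            if self.cell_features is None:
                raise ValueError("model is cell-conditioned but has no bound cell features")
            cidx = self.cell_features.index
            cells = [p[2] if len(p) > 2 else self.cell_features.cell_lines[0] for p in pairs]
            C = np.stack([self.cell_features.X[cidx[c]] for c in cells])
        return X1, X2, C

    def predict(self, pairs) -> np.ndarray:
        if len(pairs) == 0:
            return np.zeros(0)
        X1, X2, C = self._rows_for_pairs(pairs)
        y, _ = self.forward(X1, X2, C)
        return y

    # -- serialization -------------------------------------------------------
    def save(self, path) -> None:
        meta = {"config": self.config.to_dict(), "l_D": self.l_D, "l_C": self.l_C}
        np.savez(path, __meta__=json.dumps(meta),
                 **{k.replace(".", "__"): v for k, v in self.params.items()})

    @classmethod
    def load(cls, path) -> "RecoverModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            model = cls(RecoverConfig.from_dict(meta["config"]), meta["l_D"], meta["l_C"])
            model.params = {k.replace("__", "."): data[k] for k in data.files
                            if k != "__meta__"}
        return model


def film_modulate(hidden: np.ndarray, cell: np.ndarray, film_params: dict) -> np.ndarray:
    """Feature-wise linear modulation: ``gamma(cell) * hidden + beta(cell)``.

    ``film_params`` holds the linear maps {Wg, bg, Wb, bb}; applied after an
    affine layer and before its nonlinearity.
    """
    was_1d = np.asarray(hidden).ndim == 1
    hidden = np.atleast_2d(np.asarray(hidden, dtype=float))
    cell = np.atleast_2d(np.asarray(cell, dtype=float))
    gamma = cell @ film_params["Wg"] + film_params["bg"]
    beta = cell @ film_params["Wb"] + film_params["bb"]
    if gamma.shape[1] != hidden.shape[1]:
        raise ValueError(f"FiLM width {gamma.shape[1]} does not match hidden "
                         f"width {hidden.shape[1]}")
    out = gamma * hidden + beta
    return out[0] if (was_1d and out.shape[0] == 1) else out


def encode_drug(model: RecoverModel, x: np.ndarray, cell: np.ndarray | None = None) -> np.ndarray:
    """Embed one drug feature row (optionally FiLM-conditioned)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.l_D:
        raise ValueError(f"expected drug feature length {model.l_D}, got {x.shape[1]}")
    C = None if cell is None else np.atleast_2d(np.asarray(cell, dtype=float))
    e, _ = _nn.mlp_forward(model._sub("enc"), model.n_enc_layers, x,
                           film=(model._sub("encfilm") or None), cell=C)
    return e[0]


def combine_pair(model: RecoverModel, e1: np.ndarray, e2: np.ndarray,
                 cell: np.ndarray | None = None) -> float:
    """Predict synergy from two drug embeddings via the symmetric pairing."""
    e1 = np.atleast_2d(np.asarray(e1, dtype=float))
    e2 = np.atleast_2d(np.asarray(e2, dtype=float))
    kD = model.config.drug_embedding_dim
    if e1.shape[1] != kD or e2.shape[1] != kD:
        raise ValueError(f"embeddings must have length {kD}")
    z = _nn.sym_bilinear_forward(model.params["B"], e1, e2)
    C = None if cell is None else np.atleast_2d(np.asarray(cell, dtype=float))
    y, _ = _nn.mlp_forward(model._sub("head"), model.n_head_layers, z,
                           film=(model._sub("headfilm") or None), cell=C)
    return float(y[0, 0])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _design_matrices(dataset: list[SynergyRecord],
                     drug_features: DrugFeatureMatrix,
                     cell_features: CellLineFeatures | None):
    idx = drug_features.index
    X1 = np.stack([drug_features.X[idx[r.drug_a]] for r in dataset])
    X2 = np.stack([drug_features.X[idx[r.drug_b]] for r in dataset])
    y = np.array([r.synergy for r in dataset], dtype=float)
    C = None
    if cell_features is not None:
        cidx = cell_features.index
        C = np.stack([cell_features.X[cidx[r.cell_line]] for r in dataset])
    return X1, X2, C, y


def _fit(model: RecoverModel, X1, X2, C, y, config: RecoverConfig,
         rng: np.random.Generator, val_fraction: float = 0.2,
         loss: str = "mse") -> TrainReport:
    """Shared optimisation loop (MSE, or Gaussian NLL on a log-variance head)."""
    n = len(y)
    order = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        tr_idx = order
    opt = _nn.Adam(model.params, lr=config.learning_rate, weight_decay=config.weight_decay)

    def subset(idx):
        return (X1[idx], X2[idx], None if C is None else C[idx], y[idx])

    def batch_loss_grad(idx):
        x1, x2, c, yy = subset(idx)
        pred, cache = model.forward(x1, x2, c)
        if loss == "mse":
            resid = pred - yy
            L = float(np.mean(resid ** 2))
            dy = 2.0 * resid / len(idx)
        else:  # Gaussian NLL with the network output s = log(sigma^2)
            s = pred
            L = float(np.mean(0.5 * s + 0.5 * (yy ** 2) * np.exp(-s)))
            dy = (0.5 - 0.5 * (yy ** 2) * np.exp(-s)) / len(idx)
        grads = model.backward(cache, dy)
        return L, grads

    def step_fn(idx):
        L, grads = batch_loss_grad(idx)
        opt.step(model.params, grads)
        return L

    def val_fn():
        x1, x2, c, yy = subset(val_idx if n_val else tr_idx)
        pred, _ = model.forward(x1, x2, c)
        if loss == "mse":
            return float(np.mean((pred - yy) ** 2))
        return float(np.mean(0.5 * pred + 0.5 * (yy ** 2) * np.exp(-pred)))

    _, rep = _nn.train_loop(model.params, step_fn, val_fn, len(tr_idx),
                            config.batch_size, config.max_epochs, config.patience, rng)
    return TrainReport(rep["epochs_run"], rep["best_validation_mse"],
                       rep["train_loss_trace"], criterion=loss)


def train_model(
    dataset: list[SynergyRecord],
    config: RecoverConfig,
    drug_features: DrugFeatureMatrix,
    cell_features: CellLineFeatures | None = None,
    seed: int | None = None,
    val_fraction: float = 0.2,
    warm_start: RecoverModel | None = None,
) -> tuple[RecoverModel, TrainReport]:
    """Train a fresh network (or fine-tune ``warm_start``) with early stopping.

    The dataset is split 80/20 into train/validation; optimisation stops when
    validation MSE fails to improve for ``config.patience`` epochs and the
    best-validation weights are restored.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if warm_start is not None:
        model = warm_start.copy()
    else:
        model = RecoverModel(config, l_D=drug_features.l_D,
                             l_C=(cell_features.X.shape[1] if cell_features is not None else 0),
                             seed=seed)
    X1, X2, C, y = _design_matrices(dataset, drug_features, cell_features)
    report = _fit(model, X1, X2, C, y, config, rng, val_fraction=val_fraction)
    model.drug_features = drug_features
    model.cell_features = cell_features
    return model, report


def predict_synergy(model: RecoverModel, pairs) -> np.ndarray:
    """Predict synergy for (drug_a, drug_b[, cell_line]) tuples; order-invariant."""
    return model.predict(pairs)


# ---------------------------------------------------------------------------
# statsmodels-style surface
# ---------------------------------------------------------------------------

class SynergyRegression:
    """Synergy regression model bound to data.

    Parameters
    ----------
    records : list of SynergyRecord
        Combination-level training labels.
    drug_features, cell_features : feature matrices for every referenced id.
    config : RecoverConfig, optional.
    """

    def __init__(self, records: list[SynergyRecord],
                 drug_features: DrugFeatureMatrix,
                 cell_features: CellLineFeatures | None = None,
                 config: RecoverConfig | None = None):
        if not records:
            raise ValueError("no training records")
        self.records = list(records)
        self.drug_features = drug_features
        self.cell_features = cell_features
        self.config = config or RecoverConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, drug_features: DrugFeatureMatrix,
                       cell_features: CellLineFeatures | None = None,
                       config: RecoverConfig | None = None) -> "SynergyRegression":
        records = [
            SynergyRecord(str(r.drug_a), str(r.drug_b),
                          str(getattr(r, "cell_line", "")), float(r.synergy))
            for r in df.itertuples(index=False)
        ]
        return cls(records, drug_features, cell_features, config)

    def fit(self, seed: int | None = None) -> "SynergyRegressionResults":
        model, report = train_model(self.records, self.config, self.drug_features,
                                    self.cell_features, seed=seed)
        return SynergyRegressionResults(self, model, report)


class SynergyRegressionResults:
    """Fit results: trained network, diagnostics, and a summary table."""

    def __init__(self, spec: SynergyRegression, model: RecoverModel, report: TrainReport):
        self.model_spec = spec
        self.network = model
        self.report = report
        self._fitted: np.ndarray | None = None

    @property
    def fittedvalues(self) -> np.ndarray:
        if self._fitted is None:
            pairs = [(r.drug_a, r.drug_b, r.cell_line) for r in self.model_spec.records]
            self._fitted = self.network.predict(pairs)
        return self._fitted

    @property
    def resid(self) -> np.ndarray:
        y = np.array([r.synergy for r in self.model_spec.records])
        return y - self.fittedvalues

    @property
    def rsquared(self) -> float:
        y = np.array([r.synergy for r in self.model_spec.records])
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            return np.nan
        return float(1 - np.sum(self.resid ** 2) / ss_tot)

    def predict(self, pairs) -> np.ndarray:
        return self.network.predict(pairs)

    def summary(self) -> str:
        y = np.array([r.synergy for r in self.model_spec.records])
        rho = stats.spearmanr(y, self.fittedvalues).statistic if len(y) > 2 else np.nan
        cfg = self.model_spec.config
        lines = [
            "Synergy Regression Results",
            "=" * 46,
            f"{'No. observations':<28}{len(y):>18}",
            f"{'Drug feature dim (l_D)':<28}{self.network.l_D:>18}",
            f"{'Embedding dim (k_D)':<28}{cfg.drug_embedding_dim:>18}",
            f"{'Bilinear dim (k)':<28}{cfg.bilinear_dim:>18}",
            f"{'Cell conditioning (FiLM)':<28}{str(self.network.l_C > 0):>18}",
            f"{'Epochs run':<28}{self.report.epochs_run:>18}",
            f"{'Best validation MSE':<28}{self.report.best_validation_mse:>18.4f}",
            f"{'Training R^2':<28}{self.rsquared:>18.4f}",
            f"{'Training Spearman rho':<28}{rho:>18.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# DeepSynergy baseline
# ---------------------------------------------------------------------------

class DeepSynergyBaseline:
    """Concatenation MLP baseline with tanh-standardised inputs.

    Inputs are [drug1 | drug2 | cell] feature rows standardised to zero mean
    and unit variance (zero-variance columns map to 0) and passed through
    tanh; the network is a plain MLP with input dropout 0.2 and layer dropout
    0.5.  Order invariance is imposed explicitly by averaging the predictions
    on (d1, d2) and (d2, d1).
    """

    def __init__(self, hidden_dims: tuple[int, int] = (8182, 4096),
                 input_dropout: float = 0.2, layer_dropout: float = 0.5):
        self.hidden_dims = tuple(hidden_dims)
        self.dropout = (input_dropout, layer_dropout)
        self.params: dict[str, np.ndarray] | None = None
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None
        self.drug_features: DrugFeatureMatrix | None = None
        self.cell_features: CellLineFeatures | None = None
        self.n_layers = len(self.hidden_dims) + 1

    def _raw_rows(self, pairs) -> np.ndarray:
        idx = self.drug_features.index
        rows = []
        for p in pairs:
            x = [self.drug_features.X[idx[p[0]]], self.drug_features.X[idx[p[1]]]]
            if self.cell_features is not None:
                cidx = self.cell_features.index
                cell = p[2] if len(p) > 2 else self.cell_features.cell_lines[0]
                x.append(self.cell_features.X[cidx[cell]])
            rows.append(np.concatenate(x))
        return np.stack(rows)

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return np.tanh((X - self.mean_) / self.std_)

    def fit(self, dataset: list[SynergyRecord], config: RecoverConfig,
            drug_features: DrugFeatureMatrix,
            cell_features: CellLineFeatures | None = None,
            seed: int | None = None) -> TrainReport:
        if not dataset:
            raise ValueError("empty training dataset")
        self.drug_features = drug_features
        self.cell_features = cell_features
        rng = np.random.default_rng(config.seed if seed is None else seed)
        Xr = self._raw_rows([(r.drug_a, r.drug_b, r.cell_line) for r in dataset])
        self.mean_ = Xr.mean(axis=0)
        std = Xr.std(axis=0)
        self.std_ = np.where(std > 0, std, 1.0)  # zero-variance columns -> 0
        X = self._normalize(Xr)
        Xs = self._normalize(self._raw_rows([(r.drug_b, r.drug_a, r.cell_line)
                                             for r in dataset]))
        y = np.array([r.synergy for r in dataset])
        dims = [X.shape[1], *self.hidden_dims, 1]
        self.params = _nn.init_mlp(rng, dims)
        n = len(y)
        order = rng.permutation(n)
        n_val = max(1, int(round(0.2 * n))) if n > 1 else 0
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if len(tr_idx) == 0:
            tr_idx = order
        opt = _nn.Adam(self.params, lr=config.learning_rate,
                       weight_decay=config.weight_decay)

        def step_fn(idx):
            # symmetrised training: each minibatch sees both drug orders
            xb = np.vstack([X[idx], Xs[idx]])
            yb = np.concatenate([y[idx], y[idx]])
            pred, cache = _nn.mlp_forward(self.params, self.n_layers, xb,
                                          dropout=self.dropout, rng=rng)
            resid = pred[:, 0] - yb
            L = float(np.mean(resid ** 2))
            grads: dict[str, np.ndarray] = {}
            _nn.mlp_backward(self.params, self.n_layers, cache,
                             (2 * resid / len(yb))[:, None], grads)
            opt.step(self.params, grads)
            return L

        def val_fn():
            idx = val_idx if n_val else tr_idx
            pred, _ = _nn.mlp_forward(self.params, self.n_layers, X[idx])
            return float(np.mean((pred[:, 0] - y[idx]) ** 2))

        _, rep = _nn.train_loop(self.params, step_fn, val_fn, len(tr_idx),
                                config.batch_size, config.max_epochs,
                                config.patience, rng)
        return TrainReport(rep["epochs_run"], rep["best_validation_mse"],
                           rep["train_loss_trace"])

    def predict(self, pairs) -> np.ndarray:
        if len(pairs) == 0:
            return np.zeros(0)
        X12 = self._normalize(self._raw_rows(pairs))
        X21 = self._normalize(self._raw_rows([(p[1], p[0], *p[2:]) for p in pairs]))
        p12, _ = _nn.mlp_forward(self.params, self.n_layers, X12)
        p21, _ = _nn.mlp_forward(self.params, self.n_layers, X21)
        return 0.5 * (p12[:, 0] + p21[:, 0])


def deepsynergy_baseline(
    dataset: list[SynergyRecord],
    config: RecoverConfig,
    drug_features: DrugFeatureMatrix,
    cell_features: CellLineFeatures | None = None,
    hidden_dims: tuple[int, int] = (8182, 4096),
    seed: int | None = None,
) -> tuple[DeepSynergyBaseline, np.ndarray]:
    """Train the baseline and return it with its training-set predictions."""
    baseline = DeepSynergyBaseline(hidden_dims=hidden_dims)
    baseline.fit(dataset, config, drug_features, cell_features, seed=seed)
    preds = baseline.predict([(r.drug_a, r.drug_b, r.cell_line) for r in dataset])
    return baseline, preds
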