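"""Model reduction: feed-forward surrogates of the PTA simulator.

The Monte-Carlo PTA engine is expensive to query across regimen space, so
it is reduced to small multilayer perceptrons that map regimen and
covariate inputs to PTA directly:

* model 1 — inputs (DD, II, Tinf, eGFR, log2 MIC), one output: PTA of
  AUC24/MIC >= 400;
* model 2 — inputs (DD, II, Tinf, eGFR), two outputs: PTA of CminSS in
  [15, 20] mg/L and PTA of AUC24 in [400, 600] mg.h/L.

Training data are PTA labels computed by the simulator on regimens drawn
from DD ~ U(1000, 4000) mg/day, eGFR ~ U(80, 150), II ~ U(2, 24) h,
Tinf ~ U(1.5, II) h and log2 MIC ~ U(-2, 2).  Four architectures are
considered (hidden layers A=[5], B=[10], C=[10,10], D=[10,10,10]; ReLU
hidden units, sigmoid output so predictions live in (0, 1)).  Training
uses Adam on a mean-absolute-error loss, batch size 256, at most 1000
epochs, early stop after 30 epochs without improvement beyond 1e-10.
Inputs are standardized with mean/SD of the complete dataset (before the
train/test split — a deliberate fidelity choice, see the methods note).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exposure import TargetSpec, _evaluate_target_arrays, _exposure_batch
from .pk import DosingRegimen, PopulationParameters
from .population import RandomEffectsSpec, individual_parameters, sample_eta

__all__ = [
    "ARCHITECTURES",
    "PRIMARY_FEATURES",
    "SECONDARY_FEATURES",
    "PTASurrogate",
    "generate_surrogate_dataset",
    "split_and_normalize",
    "train_surrogate",
    "evaluate_surrogate",
    "select_architecture",
    "predict_pta",
]

ARCHITECTURES = {"A": (5,), "B": (10,), "C": (10, 10), "D": (10, 10, 10)}

PRIMARY_FEATURES = ["dd", "ii", "tinf", "egfr", "log2mic"]
SECONDARY_FEATURES = ["dd", "ii", "tinf", "egfr"]
PRIMARY_LABELS = ["pta_auc_mic"]
SECONDARY_LABELS = ["pta_cmin_range", "pta_auc_range"]

TRAINING_RANGES = {
    "dd": (1000.0, 4000.0),
    "egfr": (80.0, 150.0),
    "ii": (2.0, 24.0),
    "tinf": (1.5, 24.0),
    "log2mic": (-2.0, 2.0),
}


class PTASurrogate(BaseEstimator, RegressorMixin):
    """Small MLP with ReLU hidden layers and a sigmoid output.

    scikit-learn-compatible estimator trained with Adam on MAE loss.
    Outputs are probabilities in (0, 1).  Input standardization constants
    may be supplied (``norm_mean``/``norm_std``); otherwise they are
    computed from the training data passed to :meth:`fit`.

    Attributes (after fit)
    ----------------------
    coefs_, intercepts_ : per-layer weight matrices and bias vectors
    loss_curve_ : per-epoch training MAE
    n_epochs_ : epochs actually run (early stopping)
    norm_mean_, norm_std_ : input standardization constants
    """

    def __init__(
        self,
        architecture: str = "C",
        learning_rate: float = 1e-3,
        batch_size: int = 256,
        max_epochs: int = 1000,
        patience: int = 30,
        min_delta: float = 1e-10,
        norm_mean=None,
        norm_std=None,
        random_state=None,
    ):
        self.architecture = architecture
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.norm_mean = norm_mean
        self.norm_std = norm_std
        self.random_state = random_state

    # -- internals ---------------------------------------------------
    def _forward(self, x):
        acts = [x]
        for i, (w, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            z = acts[-1] @ w + b
            if i < len(self.coefs_) - 1:
                acts.append(np.maximum(z, 0.0))
            else:
                acts.append(1.0 / (1.0 + np.exp(-z)))
        return acts

    def fit(self, X, y):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {sorted(ARCHITECTURES)}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        n, n_in = X.shape
        n_out = y.shape[1]
        self.n_features_in_ = n_in
        self.n_outputs_ = n_out
        mean = np.mean(X, axis=0) if self.norm_mean is None else np.asarray(self.norm_mean, float)
        std = np.std(X, axis=0) if self.norm_std is None else np.asarray(self.norm_std, float)
        std = np.where(std > 0, std, 1.0)
        self.norm_mean_, self.norm_std_ = mean, std
        xn = (X - mean) / std

        rng = np.random.default_rng(self.random_state)
        sizes = [n_in, *ARCHITECTURES[self.architecture], n_out]
        self.coefs_ = [
            rng.standard_normal((a, b)) * np.sqrt(2.0 / a) for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.intercepts_ = [np.zeros(b) for b in sizes[1:]]

        params = self.coefs_ + self.intercepts_
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best = np.inf
        stall = 0
        self.loss_curve_ = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                acts = self._forward(xn[idx])
                pred = acts[-1]
                # d(MAE)/d(pred), then through the sigmoid
                delta = np.sign(pred - y[idx]) / (idx.size * n_out)
                delta = delta * pred * (1.0 - pred)
                grads_w, grads_b = [], []
                for layer in range(len(self.coefs_) - 1, -1, -1):
                    grads_w.append(acts[layer].T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if layer > 0:
                        delta = (delta @ self.coefs_[layer].T) * (acts[layer] > 0)
                grads = grads_w[::-1] + grads_b[::-1]
                step += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    mhat = mi / (1 - beta1**step)
                    vhat = vi / (1 - beta2**step)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            loss = float(np.mean(np.abs(self._forward(xn)[-1] - y)))
            self.loss_curve_.append(loss)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}; history={self.loss_curve_}")
            if loss < best - self.min_delta:
                best = loss
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self.n_epochs_ = len(self.loss_curve_)
        return self

    def predict(self, X):
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        out = self._forward((X - self.norm_mean_) / self.norm_std_)[-1]
        if self.n_outputs_ == 1:
            out = out[:, 0]
        return out[0] if single else out

    # -- serialization (framework-independent JSON artifact) ---------
    def to_json(self) -> str:
        check_is_fitted(self, "coefs_")
        return json.dumps(
            {
                "architecture": self.architecture,
                "coefs": [w.tolist() for w in self.coefs_],
                "intercepts": [b.tolist() for b in self.intercepts_],
                "norm_mean": self.norm_mean_.tolist(),
                "norm_std": self.norm_std_.tolist(),
                "n_outputs": self.n_outputs_,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "PTASurrogate":
        d = json.loads(payload)
        model = cls(architecture=d["architecture"])
        model.coefs_ = [np.asarray(w) for w in d["coefs"]]
        model.intercepts_ = [np.asarray(b) for b in d["intercepts"]]
        model.norm_mean_ = np.asarray(d["norm_mean"])
        model.norm_std_ = np.asarray(d["norm_std"])
        model.n_outputs_ = d["n_outputs"]
        model.n_features_in_ = model.coefs_[0].shape[0]
        model.loss_curve_ = []
        model.n_epochs_ = 0
        return model


def generate_surrogate_dataset(
    n_regimens: int = 3000,
    n_subjects: int = 1000,
    rng_seed=None,
    pop: PopulationParameters | None = None,
    grid_step: float = 0.25,
) -> pd.DataFrame:
    """Sample regimens and label them with simulator PTA for all targets.

    One row per regimen: the five sampled inputs plus PTA labels
    ``pta_auc_mic`` (uses the sampled MIC), ``pta_cmin_range`` and
    ``pta_auc_range`` (MIC-free).  Common eta draws are reused across
    regimens so differences between rows reflect the regimen, not the
    Monte-Carlo sample.
    """
    pop = pop or PopulationParameters()
    rng = np.random.default_rng(rng_seed)
    dd = rng.uniform(1000.0, 4000.0, n_regimens)
    egfr = rng.uniform(80.0, 150.0, n_regimens)
    ii = rng.uniform(2.0, 24.0, n_regimens)
    tinf = rng.uniform(1.5, ii)
    log2mic = rng.uniform(-2.0, 2.0, n_regimens)
    eta = sample_eta(RandomEffectsSpec.from_population(pop), n_subjects, rng)
    rows = []
    for i in range(n_regimens):
        regimen = DosingRegimen.from_daily_dose(dd[i], ii[i], tinf[i], horizon=96.0)
        cl, q, v1, v2 = individual_parameters(pop, egfr[i], eta)
        _, auc24, cmin, _ = _exposure_batch(regimen, cl, q, v1, v2, grid_step=grid_step)
        mic = 2.0 ** log2mic[i]
        rows.append(
            {
                "dd": dd[i],
                "ii": ii[i],
                "tinf": tinf[i],
                "egfr": egfr[i],
                "log2mic": log2mic[i],
                "pta_auc_mic": float(
                    _evaluate_target_arrays(auc24, cmin, TargetSpec.auc_mic(mic)).mean()
                ),
                "pta_cmin_range": float(
                    _evaluate_target_arrays(auc24, cmin, TargetSpec.cmin_range_t()).mean()
                ),
                "pta_auc_range": float(
                    _evaluate_target_arrays(auc24, cmin, TargetSpec.auc_range()).mean()
                ),
            }
        )
    return pd.DataFrame(rows)


def split_and_normalize(
    dataset: pd.DataFrame,
    model: int = 1,
    test_fraction: float = 0.2,
    rng_seed=None,
):
    """Split a labelled dataset and compute full-dataset normalization.

    Returns (X_train, y_train, X_test, y_test, mean, std).  The
    standardization constants are computed on the *complete* dataset
    before the split, matching the stated training protocol.
    """
    features = PRIMARY_FEATURES if model == 1 else SECONDARY_FEATURES
    labels = PRIMARY_LABELS if model == 1 else SECONDARY_LABELS
    X = dataset[features].to_numpy(float)
    y = dataset[labels].to_numpy(float)
    mean, std = X.mean(axis=0), X.std(axis=0)
    rng = np.random.default_rng(rng_seed)
    n = len(dataset)
    n_test = int(round(test_fraction * n))
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    return X[train_idx], y[train_idx], X[test_idx], y[test_idx], mean, std


def train_surrogate(
    X_train,
    y_train,
    architecture: str = "C",
    norm_mean=None,
    norm_std=None,
    rng_seed=None,
    **protocol,
) -> PTASurrogate:
    """Train one surrogate under the standard protocol."""
    model = PTASurrogate(
        architecture=architecture,
        norm_mean=norm_mean,
        norm_std=norm_std,
        random_state=rng_seed,
        **protocol,
    )
    return model.fit(X_train, y_train)


def evaluate_surrogate(model: PTASurrogate, X_test, y_test) -> dict:
    """MAE and RMSE per output (and overall) on a held-out split."""
    pred = np.atleast_2d(model.predict(X_test))
    y = np.asarray(y_test, float)
    if y.ndim == 1:
        y = y[:, None]
    if pred.shape != y.shape:
        pred = pred.reshape(y.shape)
    err = pred - y
    return {
        "mae": float(np.mean(np.abs(err))),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae_per_output": np.mean(np.abs(err), axis=0).tolist(),
        "rmse_per_output": np.sqrt(np.mean(err**2, axis=0)).tolist(),
    }


def select_architecture(
    X_train, y_train, X_test, y_test, norm_mean=None, norm_std=None, rng_seed=None, **protocol
) -> tuple[str, PTASurrogate, dict]:
    """Train all four architectures; keep the best test-set MAE."""
    results = {}
    best = None
    for arch in sorted(ARCHITECTURES):
        model = train_surrogate(
            X_train, y_train, arch, norm_mean, norm_std, rng_seed, **protocol
        )
        metrics = evaluate_surrogate(model, X_test, y_test)
        results[arch] = metrics
        if best is None or metrics["mae"] < results[best[0]]["mae"]:
            best = (arch, model)
    return best[0], best[1], results


def predict_pta(model: PTASurrogate, dd, ii, tinf, egfr, log2mic=None, warn=None):
    """Query a trained surrogate at one regimen point.

    Inputs outside the training ranges are flagged (returned in the
    second element) but not refused — extrapolation is the caller's risk.
    """
    values = {"dd": dd, "ii": ii, "tinf": tinf, "egfr": egfr}
    features = [dd, ii, tinf, egfr]
    if log2mic is not None:
        values["log2mic"] = log2mic
        features.append(log2mic)
    out_of_range = [
        k for k, x in values.items() if not TRAINING_RANGES[k][0] <= x <= TRAINING_RANGES[k][1]
    ]
    pred = model.predict(np.asarray(features, float))
    return pred, out_of_range
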