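"""Exact Kernel SHAP attribution for the PTA surrogates.

With at most five input variables, all 2^M feature coalitions can be
enumerated, so the Shapley-kernel-weighted least-squares problem is solved
exactly (no coalition sampling) and the resulting attributions are the
exact Shapley values of the coalition value function.  Missing features
are imputed by averaging the model output over a background sample drawn
from the training data — the standard Kernel SHAP marginalization, which
assumes feature independence (the Tinf <= II dependence in the training
distribution is a known caveat, see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = ["ShapExplanation", "coalition_values", "kernel_shap", "importance_ranking", "plot_shap_summary"]


@dataclass(frozen=True)
class ShapExplanation:
    """Additive feature attributions for a batch of explained instances.

    ``base_value + shap_values.sum(axis=1) == prediction`` per instance
    (local accuracy).
    """

    base_value: float
    shap_values: np.ndarray  # (n_instances, n_features)
    predictions: np.ndarray  # (n_instances,)
    instances: np.ndarray  # (n_instances, n_features)
    feature_names: tuple[str, ...]

    @property
    def feature_order(self) -> list[str]:
        """Features ranked by mean |shap|, descending."""
        mean_abs = np.mean(np.abs(self.shap_values), axis=0)
        return [self.feature_names[i] for i in np.argsort(-mean_abs)]

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for j, name in enumerate(self.feature_names):
            data[name] = self.instances[:, j]
        for j, name in enumerate(self.feature_names):
            data[f"shap_{name}"] = self.shap_values[:, j]
        data["prediction"] = self.predictions
        data["base_value"] = self.base_value
        return pd.DataFrame(data)


def _predictor(model, output: int):
    predict = model.predict if hasattr(model, "predict") else model

    def f(x):
        out = np.asarray(predict(np.atleast_2d(x)), dtype=float)
        if out.ndim == 2:
            out = out[:, output]
        return out

    return f


def coalition_values(model, background: np.ndarray, x: np.ndarray, output: int = 0):
    """Value v(S) for every coalition S of the M features.

    v(S) = E_z[f(x_S, z_{S^c})] with z drawn from the background sample.
    Returns (masks, values): masks is the (2^M, M) boolean coalition
    matrix, values the corresponding v(S).
    """
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background must be non-empty")
    x = np.asarray(x, dtype=float)
    m = x.shape[-1]
    masks = np.array(
        [[j in s for j in range(m)] for size in range(m + 1) for s in combinations(range(m), size)],
        dtype=bool,
    )
    f = _predictor(model, output)
    nbg = background.shape[0]
    # one batched prediction: for each coalition, background rows with the
    # coalition's features replaced by the explained instance's values
    batch = []
    for mask in masks:
        b = background.copy()
        b[:, mask] = x[mask]
        batch.append(b)
    preds = f(np.concatenate(batch, axis=0)).reshape(len(masks), nbg)
    return masks, preds.mean(axis=1)


def _shapley_kernel_solve(masks: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Shapley-kernel-weighted least squares over enumerated coalitions.

    The empty and full coalitions (infinite kernel weight) enter as hard
    constraints: v(empty) is the intercept and the attributions sum to
    v(full) - v(empty).
    """
    m = masks.shape[1]
    base = values[~masks.any(axis=1)][0]
    full = values[masks.all(axis=1)][0]
    interior = (masks.sum(axis=1) > 0) & (masks.sum(axis=1) < m)
    z = masks[interior].astype(float)
    y = values[interior] - base
    sizes = z.sum(axis=1).astype(int)
    w = (m - 1) / (np.array([comb(m, s) for s in sizes]) * sizes * (m - sizes))
    # eliminate the last coefficient through the sum constraint
    zt = z[:, :-1] - z[:, [-1]]
    yt = y - z[:, -1] * (full - base)
    sw = np.sqrt(w)
    phi_head, *_ = np.linalg.lstsq(zt * sw[:, None], yt * sw, rcond=None)
    phi = np.empty(m)
    phi[:-1] = phi_head
    phi[-1] = (full - base) - phi_head.sum()
    return phi


def kernel_shap(
    model,
    background: np.ndarray,
    instances: np.ndarray,
    feature_names=None,
    output: int = 0,
) -> ShapExplanation:
    """Exact Kernel SHAP explanations for a batch of instances.

    Parameters
    ----------
    model : callable or estimator with ``predict``
    background : (n_background, M) sample used for marginalizing missing
        features (the training protocol uses 400 training rows).
    instances : (n_instances, M) points to explain.
    output : which model output to attribute (for two-output surrogates).
    """
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background must be non-empty")
    instances = np.atleast_2d(np.asarray(instances, dtype=float))
    m = instances.shape[1]
    if m > 5:
        raise ValueError("exact enumeration is limited to at most 5 features")
    if feature_names is None:
        feature_names = tuple(f"x{j}" for j in range(m))
    f = _predictor(model, output)
    base = float(f(background).mean())
    shap = np.empty((len(instances), m))
    preds = np.empty(len(instances))
    for i, x in enumerate(instances):
        masks, values = coalition_values(model, background, x, output)
        shap[i] = _shapley_kernel_solve(masks, values)
        preds[i] = values[masks.all(axis=1)][0]
    return ShapExplanation(
        base_value=base,
        shap_values=shap,
        predictions=preds,
        instances=instances,
        feature_names=tuple(feature_names),
    )


def importance_ranking(explanation: ShapExplanation) -> list[str]:
    """Features in descending order of mean |shap| over the explained set."""
    if len(explanation.instances) < 1:
        raise ValueError("need at least one explained instance")
    return explanation.feature_order


def plot_shap_summary(explanation: ShapExplanation, path=None):
    """Beeswarm-style summary: per-feature shap values coloured by the
    feature value, features ordered by importance."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = explanation.feature_order
    fig, ax = plt.subplots(figsize=(7, 1.0 + 0.7 * len(order)))
    rng = np.random.default_rng(0)
    for row, name in enumerate(reversed(order)):
        j = explanation.feature_names.index(name)
        vals = explanation.shap_values[:, j]
        feat = explanation.instances[:, j]
        spread = (feat - feat.min()) / (np.ptp(feat) or 1.0)
        jitter = rng.uniform(-0.25, 0.25, len(vals))
        sc = ax.scatter(vals, row + jitter, c=spread, cmap="coolwarm", s=12, alpha=0.8)
    ax.set_yticks(range(len(order)), list(reversed(order)))
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("SHAP value (impact on predicted PTA)")
    fig.colorbar(sc, ax=ax, label="feature value (scaled)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
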