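"""Additive per-feature attributions for the feed-forward classifiers.

For every (sample, reference) pair the engine backpropagates difference
multipliers through the network (the rescale rule: a nonlinearity's
multiplier is its finite difference Delta-out / Delta-in between the sample
and the reference, affine layers contribute their weights), yielding
attributions ``phi_i = m_i * (x_i - b_i)`` that satisfy local accuracy
exactly: ``sum_i phi_i = f(x) - f(b)`` for each reference, hence
``sum_i phi_i = f(x) - mean_b f(b)`` after averaging over the reference set.

A feature's summary score is the arithmetic mean over samples of the
absolute per-sample attribution (non-negative; zero iff the model never
responds to the feature). An exhaustive coalition-enumeration Shapley oracle
is provided for cross-checking on small networks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dnn import BatchNorm, Dense, Model, ReLU, Sigmoid, TrainConfig, build_model, train

_RATIO_EPS = 1e-9
_ZERO_TOL = 1e-12


@dataclass
class ContributionTable:
    """Per-sample attribution matrix and its per-feature mean-|phi| summary."""

    per_sample: pd.DataFrame   # samples x features
    shap: pd.Series            # feature -> mean over samples of |attribution|
    expected_value: float      # mean model output over the reference set

    def zero_features(self, tol: float = _ZERO_TOL) -> list:
        return sorted(self.shap.index[self.shap.to_numpy() <= tol])


def _forward_trace(model: Model, x: np.ndarray, output: str):
    """Forward pass recording each layer's input; returns (trace, output)."""
    trace = []
    for layer in model.layers:
        if isinstance(layer, Sigmoid) and output == "logit":
            break
        trace.append(x)
        if isinstance(layer, (BatchNorm,)):
            scale, shift = layer.inference_affine()
            x = x * scale + shift
        else:
            x = layer.forward(x)
    return trace, x


def _ratio(fx, fb, zx, zb, deriv):
    delta = zx - zb
    out = np.where(np.abs(delta) > _RATIO_EPS, (fx - fb) / np.where(delta == 0, 1.0, delta), deriv)
    return out


def compute_attributions(
    model: Model,
    X,
    background,
    seed: int = 0,
    max_background: int = 100,
    output: str = "probability",
    method: str = "rescale",
    n_permutations: int = 200,
) -> ContributionTable:
    """Additive attributions of ``model`` on ``X`` against a reference set.

    Two methods are offered. ``"rescale"`` (default) backpropagates
    finite-difference multipliers in a single pass per (sample, reference)
    pair: fast, deterministic, exactly locally accurate, and exact for
    (affine) models, but only an approximation of Shapley values when the
    learned function has feature interactions. ``"permutation"`` is a
    Monte Carlo Shapley estimator: feature marginal contributions averaged
    over ``n_permutations`` random feature orderings (references cycled per
    permutation); it is also exactly locally accurate by telescoping and
    converges to the Shapley values as permutations grow, at the price of
    ``n_permutations * n_features`` forward passes.

    ``background`` is subsampled to ``max_background`` rows with ``seed`` when
    larger. ``output`` selects the probability (post-sigmoid, default) or
    logit scale.
    """
    columns = list(X.columns) if isinstance(X, pd.DataFrame) else None
    index = list(X.index) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    B = np.asarray(background, dtype=float)
    if B.ndim == 1:
        B = B[None, :]
    if B.shape[0] == 0:
        raise ValueError("background set must be non-empty")
    if X.shape[1] != B.shape[1]:
        raise ValueError(
            f"feature mismatch: X has {X.shape[1]} features, background {B.shape[1]}"
        )
    first = next(l for l in model.layers if isinstance(l, Dense))
    if first.weight.shape[0] != X.shape[1]:
        raise ValueError(
            f"feature mismatch: model expects {first.weight.shape[0]} features, X has {X.shape[1]}"
        )
    if B.shape[0] > max_background:
        rng = np.random.default_rng(seed)
        B = B[np.sort(rng.choice(B.shape[0], size=max_background, replace=False))]

    if method == "permutation":
        phi, expected = _permutation_attributions(
            model, X, B, seed, output, n_permutations
        )
        per_sample = pd.DataFrame(phi, index=index, columns=columns)
        shap = pd.Series(np.abs(phi).mean(axis=0), index=per_sample.columns, name="shap_value")
        return ContributionTable(per_sample=per_sample, shap=shap, expected_value=expected)
    if method != "rescale":
        raise ValueError(f"unknown attribution method {method!r}")

    n_s, d = X.shape
    n_b = B.shape[0]
    Xr = np.repeat(X, n_b, axis=0)
    Br = np.tile(B, (n_s, 1))
    trace_x, out_x = _forward_trace(model, Xr, output)
    trace_b, out_b = _forward_trace(model, Br, output)

    m = np.ones_like(np.atleast_2d(out_x))
    used = len(trace_x)
    for layer, zx, zb in zip(reversed(model.layers[:used]), reversed(trace_x), reversed(trace_b)):
        if isinstance(layer, Dense):
            m = m @ layer.weight.T
        elif isinstance(layer, BatchNorm):
            scale, _ = layer.inference_affine()
            m = m * scale
        elif isinstance(layer, ReLU):
            m = m * _ratio(np.maximum(zx, 0), np.maximum(zb, 0), zx, zb, (zx > 0).astype(float))
        elif isinstance(layer, Sigmoid):
            sx = 1.0 / (1.0 + np.exp(-zx))
            sb = 1.0 / (1.0 + np.exp(-zb))
            m = m * _ratio(sx, sb, zx, zb, sx * (1 - sx))
        else:  # pragma: no cover - layer set is closed
            raise TypeError(f"cannot attribute through {type(layer).__name__}")
    phi = (m * (Xr - Br)).reshape(n_s, n_b, d).mean(axis=1)

    per_sample = pd.DataFrame(phi, index=index, columns=columns)
    shap = pd.Series(
        np.abs(phi).mean(axis=0),
        index=per_sample.columns,
        name="shap_value",
    )
    expected = float(np.mean(out_b.reshape(n_s, n_b, -1)[0]))
    return ContributionTable(per_sample=per_sample, shap=shap, expected_value=expected)


def _permutation_attributions(model, X, B, seed, output, n_permutations):
    """Shapley estimation by averaging marginal contributions over random
    feature orderings; each permutation uses one reference (cycled), so the
    per-sample sums telescope exactly to f(x) - mean over used references."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    predict = model.predict_proba if output == "probability" else model.predict_logit
    n_s, d = X.shape
    n_refs = B.shape[0]
    rng = np.random.default_rng(seed)
    phi = np.zeros((n_s, d))
    ref_outputs = []
    for j in range(n_permutations):
        perm = rng.permutation(d)
        b = B[j % n_refs]
        # rows[k] flips perm[:k] from the reference to the sample
        rows = np.tile(b, (d + 1, n_s, 1))
        for k, i in enumerate(perm):
            rows[k + 1 :, :, i] = X[:, i][None, :]
        out = predict(rows.reshape(-1, d)).reshape(d + 1, n_s)
        ref_outputs.append(out[0].mean())
        deltas = np.diff(out, axis=0)          # (d, n_s)
        phi[:, perm] += deltas.T
    phi /= n_permutations
    return phi, float(np.mean(ref_outputs))


def exact_shapley(model, x, background, output: str = "probability") -> np.ndarray:
    """Exact Shapley values by coalition enumeration (n_features <= 12).

    Absent features are imputed by background means; used as a test oracle.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n > 12:
        raise ValueError(f"exact Shapley enumeration limited to 12 features, got {n}")
    b = np.asarray(background, dtype=float)
    b = b.mean(axis=0) if b.ndim == 2 else b

    masks = np.array(list(itertools.product([0, 1], repeat=n)), dtype=bool)
    inputs = np.where(masks, x[None, :], b[None, :])
    if isinstance(model, Model):
        values = model.predict_proba(inputs) if output == "probability" else model.predict_logit(inputs)
    else:
        values = np.asarray([model(row) for row in inputs], dtype=float).ravel()
    v = {tuple(np.flatnonzero(mask)): val for mask, val in zip(masks, values)}

    phi = np.zeros(n)
    features = list(range(n))
    for size in range(n):
        w = math.factorial(size) * math.factorial(n - size - 1) / math.factorial(n)
        for subset in itertools.combinations(features, size):
            base = v[subset]
            for i in features:
                if i in subset:
                    continue
                with_i = tuple(sorted(subset + (i,)))
                phi[i] += w * (v[with_i] - base)
    return phi


def prune_and_retrain(
    spec,
    X,
    y,
    contributions: ContributionTable,
    config: TrainConfig,
    seed: int = 0,
    max_background: int = 100,
    tol: float = _ZERO_TOL,
):
    """Drop zero-contribution features, rebuild the input layer and retrain.

    Returns ``(kept feature list, TrainResult or None, ContributionTable)``;
    when no feature has zero contribution the model is untouched and the
    retraining is skipped (``None``).
    """
    if isinstance(X, pd.DataFrame):
        features = list(X.columns)
    else:
        features = list(contributions.shap.index)
        X = pd.DataFrame(np.asarray(X, dtype=float), columns=features)
    if list(contributions.shap.index) != features:
        raise ValueError("contribution table does not match the feature set of X")
    zero = set(contributions.zero_features(tol))
    kept = [f for f in features if f not in zero]
    if not kept:
        raise ValueError("pruning would remove every feature")
    if not zero:
        return kept, None, contributions

    new_spec = type(spec)(
        n_features=len(kept),
        hidden_sizes=spec.hidden_sizes,
        use_regularization=spec.use_regularization,
        activation=spec.activation,
        l2=spec.l2,
    )
    Xk = X[kept]
    model = build_model(new_spec, seed=seed)
    result = train(model, Xk.to_numpy(), y, config)
    background = Xk.to_numpy()[result.train_idx]
    table = compute_attributions(
        model, Xk, background, seed=seed, max_background=max_background
    )
    return kept, result, table
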