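"""Explainability: forward-model activation patterns and Shapley attributions.

Two complementary routes. For the linear pipelines, backward-model
filters W (CSP/PCA columns or classifier weights) are converted into
forward-model activation patterns ``A = Sigma_X W``: the filter says how
to *extract* the discriminative signal, the pattern says how that signal
*projects onto* the sensors and is the object to interpret
topographically. For the tree-ensemble pipeline, per-epoch Shapley
values decompose the model's raw output additively over features.

The Shapley implementation is exact and interventional: features absent
from a coalition are replaced by values from an explicit background
sample. For a decision tree the coalition game restricted to one
background row is a sum of conjunction games (one per leaf), whose
Shapley values have a closed form; summing over leaves, trees and
background rows gives the exact interventional Shapley value with cost
linear in leaves, not exponential in features. Local accuracy
(base value + attributions = raw model output) is asserted for every
explained epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np

from .containers import FeatureMatrix
from .covariance import BandCovarianceSet, SpatialFilters


@dataclass
class PatternMap:
    """Activation patterns, same shape as the filters they explain."""

    patterns: list[np.ndarray]
    names: list[str]
    bands: list[str] | None = None

    @property
    def single(self) -> np.ndarray:
        if len(self.patterns) != 1:
            raise ValueError("pattern map holds multiple bands")
        return self.patterns[0]


def filters_to_patterns(W, sigma_x, normalize: bool = True) -> PatternMap:
    """Convert backward-model filters to forward-model activation patterns.

    ``A = Sigma_X W`` (taking the extracted-source covariance as
    identity, the usual simplification for uncorrelated components; pass
    pre-whitened filters otherwise). Columns are normalized to unit
    maximum absolute value since patterns are scale-free. Accepts either
    fitted :class:`SpatialFilters` with a per-band covariance set, or a
    plain weight vector/matrix with a feature covariance.
    """
    if isinstance(W, SpatialFilters):
        if isinstance(sigma_x, BandCovarianceSet):
            sig = sigma_x.matrices.mean(axis=0)  # (bands, N, N)
        else:
            sig = np.asarray(sigma_x, float)
        if sig.shape[0] != len(W.bands):
            raise ValueError("covariance band axis must match filters")
        pats = []
        for b, Wb in enumerate(W.filters):
            A = sig[b] @ Wb
            if normalize:
                A = A / np.max(np.abs(A), axis=0, keepdims=True)
            pats.append(A)
        return PatternMap(patterns=pats, names=list(W.ch_names), bands=list(W.bands))
    W = np.atleast_2d(np.asarray(W, float))
    if W.shape[0] == 1:
        W = W.T
    sig = np.asarray(sigma_x, float)
    if sig.shape != (W.shape[0], W.shape[0]):
        raise ValueError("covariance shape does not match weights")
    A = sig @ W
    if normalize:
        A = A / np.max(np.abs(A), axis=0, keepdims=True)
    names = [f"f{i + 1}" for i in range(W.shape[0])]
    return PatternMap(patterns=[A], names=names, bands=None)


def rank_check(W_joint: np.ndarray, rtol: float = 1e-10) -> dict:
    """Numerical column rank of a stacked multi-band filter matrix.

    A full-column-rank joint filter means no band's contribution is a
    linear combination of the others', so the concatenated feature space
    keeps every projection identifiable.
    """
    W = np.atleast_2d(np.asarray(W_joint, float))
    s = np.linalg.svd(W, compute_uv=False)
    tol = rtol * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    return {
        "rank": rank,
        "n_columns": W.shape[1],
        "full_column_rank": rank == min(W.shape),
        "singular_values": s,
        "tolerance": tol,
    }


# ------------------------------------------------------------ tree Shapley
@dataclass
class AttributionMatrix:
    """Per-epoch signed feature attributions in model-raw-output units."""

    values: np.ndarray
    base_value: float
    feature_names: list[str]
    raw_output: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def local_accuracy_error(self) -> float:
        if self.raw_output is None:
            raise ValueError("raw model output not stored")
        return float(np.max(np.abs(self.base_value + self.values.sum(axis=1) - self.raw_output)))


def _leaf_boxes(tree: dict) -> list[tuple[dict[int, tuple[float, float]], float]]:
    """Flatten a LightGBM tree into (per-feature interval box, leaf value)."""
    out = []

    def rec(node, box):
        if "leaf_value" in node and "split_feature" not in node:
            out.append((dict(box), float(node["leaf_value"])))
            return
        f = int(node["split_feature"])
        t = float(node["threshold"])
        lo, hi = box.get(f, (-np.inf, np.inf))
        # left branch: value <= threshold
        box_l = dict(box)
        box_l[f] = (lo, min(hi, t))
        rec(node["left_child"], box_l)
        box_r = dict(box)
        box_r[f] = (max(lo, t), hi)
        rec(node["right_child"], box_r)

    rec(tree["tree_structure"], {})
    return out


def _booster_of(model):
    if hasattr(model, "booster_"):
        return model.booster_
    return model


def shap_attributions(model, X_background, X_explain, feature_names=None) -> AttributionMatrix:
    """Exact interventional Shapley attributions for a LightGBM ensemble.

    The value of a coalition S is the model's raw output with features in
    S taken from the explained epoch and the rest from a background row,
    averaged over the background sample. Computed in closed form per leaf
    (see module docstring); exact, so it matches brute-force coalition
    enumeration. The base value is the mean raw output over the
    background.
    """
    booster = _booster_of(model)
    Xb = X_background.values if isinstance(X_background, FeatureMatrix) else np.asarray(X_background, float)
    Xe = X_explain.values if isinstance(X_explain, FeatureMatrix) else np.asarray(X_explain, float)
    if Xb.ndim != 2 or Xe.ndim != 2 or Xb.shape[1] != Xe.shape[1]:
        raise ValueError("background/explain must be 2-D with matching features")
    if Xb.shape[0] == 0:
        raise ValueError("background must be nonempty")
    model_names = booster.feature_name()
    generic = all(n.startswith("Column_") for n in model_names)
    if feature_names is None and isinstance(X_explain, FeatureMatrix):
        feature_names = X_explain.feature_names
    if feature_names is None:
        feature_names = model_names
    if len(feature_names) != Xe.shape[1]:
        raise ValueError("feature_names length mismatch")
    if not generic and list(feature_names) != list(model_names):
        raise ValueError("feature names do not match the fitted model")

    E, F = Xe.shape
    B = Xb.shape[0]
    dump = booster.dump_model()
    maxd = max(1, dump.get("max_depth", 64) if dump.get("max_depth", -1) > 0 else 64)
    fact = np.array([factorial(k) for k in range(maxd + 2)], float)

    phi = np.zeros((E, F))
    for tree in dump["tree_info"]:
        for box, w in _leaf_boxes(tree):
            if not box:  # stump leaf with no condition: constant
                continue
            feats = np.fromiter(box.keys(), int)
            lo = np.array([box[f][0] for f in feats])
            hi = np.array([box[f][1] for f in feats])
            xp = (Xe[:, feats] > lo) & (Xe[:, feats] <= hi)  # (E, ncf)
            zp = (Xb[:, feats] > lo) & (Xb[:, feats] <= hi)  # (B, ncf)
            P = xp[:, None, :] & ~zp[None, :, :]  # x-only pass
            Q = ~xp[:, None, :] & zp[None, :, :]  # z-only pass
            dead = (~xp[:, None, :] & ~zp[None, :, :]).any(axis=2)  # (E, B)
            p = P.sum(axis=2)
            q = Q.sum(axis=2)
            denom = fact[p + q]
            coefP = np.where((p > 0) & ~dead, w * fact[np.maximum(p - 1, 0)] * fact[q] / denom, 0.0)
            coefQ = np.where((q > 0) & ~dead, -w * fact[p] * fact[np.maximum(q - 1, 0)] / denom, 0.0)
            for k, f in enumerate(feats):
                contrib = np.where(P[:, :, k], coefP, 0.0) + np.where(Q[:, :, k], coefQ, 0.0)
                phi[:, f] += contrib.mean(axis=1)

    raw_e = booster.predict(Xe, raw_score=True)
    raw_b = booster.predict(Xb, raw_score=True)
    base = float(np.mean(raw_b))
    attr = AttributionMatrix(
        values=phi,
        base_value=base,
        feature_names=list(feature_names),
        raw_output=np.asarray(raw_e, float),
        meta={"n_background": B, "convention": "interventional"},
    )
    err = attr.local_accuracy_error()
    if err > 1e-6:
        raise AssertionError(f"local accuracy violated: max error {err:.3e}")
    return attr


def brute_force_shapley(model, X_background, x, feature_indices=None) -> np.ndarray:
    """Reference Shapley values by full coalition enumeration (test oracle).

    Feasible only for a handful of features; marginalizes absent features
    over the background rows, matching :func:`shap_attributions`'
    interventional value function. Kept independent of the closed-form
    path: it only calls the model's raw prediction on hybrid inputs.
    """
    from itertools import combinations

    booster = _booster_of(model)
    Xb = np.asarray(X_background, float)
    x = np.asarray(x, float).ravel()
    F = x.size
    idx = list(range(F)) if feature_indices is None else list(feature_indices)
    if len(idx) > 16:
        raise ValueError("brute force limited to 16 features")

    def value(S):
        Z = Xb.copy()
        Z[:, list(S)] = x[list(S)]
        return float(np.mean(booster.predict(Z, raw_score=True)))

    cachev = {}

    def v(S):
        key = frozenset(S)
        if key not in cachev:
            cachev[key] = value(key)
        return cachev[key]

    n = len(idx)
    phi = np.zeros(F)
    for i in idx:
        others = [j for j in idx if j != i]
        for r in range(n):
            for S in combinations(others, r):
                wgt = factorial(r) * factorial(n - r - 1) / factorial(n)
                phi[i] += wgt * (v(set(S) | {i}) - v(set(S)))
    return phi


def top_features(attr: AttributionMatrix, k: int = 10) -> list[tuple[str, float]]:
    """Rank features by mean absolute attribution, descending; ties by name."""
    if k > len(attr.feature_names):
        raise ValueError("k exceeds feature count")
    imp = np.mean(np.abs(attr.values), axis=0)
    order = sorted(range(len(imp)), key=lambda i: (-imp[i], attr.feature_names[i]))
    return [(attr.feature_names[i], float(imp[i])) for i in order[:k]]
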