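"""Subject-independent classification: folds, models, tuning, metrics.

Evaluation is leave-subjects-out: in every fold two unseen subjects (one
per group) are the test set, two more are the validation set used to
tune the number of spatial components J and the classifier
hyperparameters, and the rest train the feature transforms and the
classifier. Epochs are the unit of prediction; subjects are the unit of
generalization. The headline metric is balanced accuracy (chance 0.5),
with ROC-AUC alongside, and pipelines are compared fold-wise with the
Wilcoxon signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, roc_auc_score

from .containers import EpochSet, FeatureMatrix, default_bands
from .covariance import (
    csp_fit,
    csp_log_features,
    epoch_covariance,
    fit_riemann_references,
    pca_fit,
    project_covariances,
    tangent_features,
)
from .signal import apply_filter_bank, multitaper_band_power, relative_power

PIPELINES = ("supervised", "riemann", "handcrafted")

#: 20 log-spaced inverse-regularization values spanning the searched range.
DEFAULT_C_GRID = tuple(np.logspace(-10, 9, 20))

DEFAULT_GBM_GRID = tuple(
    {"learning_rate": lr, "num_leaves": nl, "min_child_samples": mc}
    for lr in (0.05, 0.1)
    for nl in (7, 15)
    for mc in (10, 20)
)

DEFAULT_J_CANDIDATES = (2, 4, 6)


@dataclass(frozen=True)
class Fold:
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.val), set(self.test)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("train/val/test subject sets must be disjoint")


@dataclass
class FoldPlan:
    folds: list[Fold]
    seed: int


def make_folds(subject_groups: dict[str, str], n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Sample leave-subjects-out folds.

    Each fold holds out one test subject per group and one validation
    subject per group; everyone else trains. Test pairs are drawn without
    replacement across folds while distinct pairs remain, then with
    replacement (with a warning).
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]] = {}
    for s, g in subject_groups.items():
        groups.setdefault(g, []).append(s)
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    (g1, s1), (g2, s2) = sorted(groups.items())
    for g, subs in ((g1, s1), (g2, s2)):
        if len(subs) < 3:
            raise ValueError(f"group {g!r} has {len(subs)} subjects; need >= 3 for train+val+test")
    pairs = [(a, b) for a in s1 for b in s2]
    order = rng.permutation(len(pairs))
    if n_folds > len(pairs):
        warnings.warn("more folds than distinct test pairs; sampling with replacement")
        extra = rng.integers(len(pairs), size=n_folds - len(pairs))
        order = np.concatenate([order, extra])
    folds = []
    for k in range(n_folds):
        test = pairs[order[k % len(order)] if k < len(order) else order[k]]
        rest1 = [s for s in s1 if s not in test]
        rest2 = [s for s in s2 if s not in test]
        val = (rest1[rng.integers(len(rest1))], rest2[rng.integers(len(rest2))])
        train = tuple(s for s in subject_groups if s not in test and s not in val)
        folds.append(Fold(train=train, val=tuple(val), test=tuple(test)))
    return FoldPlan(folds=folds, seed=seed)


# -------------------------------------------------------------------- metrics
def balanced_accuracy(y_true, y_pred) -> float:
    """(sensitivity + specificity) / 2 for binary labels."""
    y_true = np.asarray(y_true)
    classes = np.unique(y_true)
    if len(classes) != 2:
        raise ValueError(f"need both classes in y_true, got {classes}")
    return float(balanced_accuracy_score(y_true, np.asarray(y_pred)))


def roc_auc(y_true, scores, positive_label="M") -> float:
    """P(random positive outscores random negative), ties counted 1/2."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) != 2:
        raise ValueError("need both classes in y_true")
    return float(roc_auc_score(y_true == positive_label, np.asarray(scores, float)))


# ------------------------------------------------------------------- tuning
def tune_components(score_fn, candidates) -> tuple[int, float]:
    """Pick the candidate maximizing the validation score; ties -> smallest.

    ``score_fn(J)`` returns validation balanced accuracy for J components.
    """
    best_J, best = None, -np.inf
    for J in sorted(candidates):
        s = score_fn(J)
        if s > best + 1e-12:
            best, best_J = s, J
    return best_J, best


def fit_linear(
    X: np.ndarray,
    y,
    X_val: np.ndarray,
    y_val,
    C_grid=DEFAULT_C_GRID,
    positive_label: str = "M",
):
    """L2 logistic regression with validation-selected regularization.

    The grid is searched on a log scale; the C maximizing validation
    balanced accuracy is kept, ties resolved toward stronger
    regularization (smaller C). Returns ``(spec, model)`` where spec
    records the grid and tuned value and the model exposes the weight
    vector for pattern analysis.
    """
    y = np.asarray(y)
    y_val = np.asarray(y_val)
    if len(np.unique(y)) != 2:
        raise ValueError("training labels must contain two classes")
    if len(np.unique(y_val)) != 2:
        raise ValueError("validation labels must contain two classes")
    best = (-np.inf, None, None)
    for C in sorted(C_grid):
        m = LogisticRegression(C=float(C), solver="lbfgs", max_iter=2000)  # l2 default
        m.fit(X, y)
        ba = balanced_accuracy(y_val, m.predict(X_val))
        if ba > best[0] + 1e-12:
            best = (ba, C, m)
    ba, C, model = best
    spec = {
        "family": "regularized-linear",
        "grid": {"C": [float(c) for c in C_grid]},
        "tuned": {"C": float(C)},
        "val_ba": float(ba),
    }
    return spec, model


def fit_gbm(
    X: np.ndarray,
    y,
    X_val: np.ndarray,
    y_val,
    grid=DEFAULT_GBM_GRID,
    seed: int = 0,
    n_estimators: int = 300,
):
    """Gradient-boosted trees (leaf-wise growth) with validation-grid tuning.

    Each grid point is fitted with early stopping on validation log-loss;
    the point maximizing validation balanced accuracy wins. Single
    threaded and seeded for bit-reproducibility.
    """
    import lightgbm as lgb

    if not grid:
        raise ValueError("hyperparameter grid must be nonempty")
    y = np.asarray(y)
    y_val = np.asarray(y_val)
    best = (-np.inf, None, None)
    for params in grid:
        m = lgb.LGBMClassifier(
            n_estimators=n_estimators,
            random_state=seed,
            n_jobs=1,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
            **params,
        )
        m.fit(
            X,
            y,
            eval_set=[(X_val, y_val)],
            callbacks=[lgb.early_stopping(20, verbose=False), lgb.log_evaluation(0)],
        )
        ba = balanced_accuracy(y_val, m.predict(X_val))
        if ba > best[0] + 1e-12:
            best = (ba, dict(params), m)
    ba, params, model = best
    spec = {
        "family": "gradient-boosted-trees",
        "grid": [dict(p) for p in grid],
        "tuned": dict(params, best_iteration=int(model.best_iteration_ or n_estimators)),
        "val_ba": float(ba),
        "seed": seed,
    }
    return spec, model


# --------------------------------------------------------------- evaluation
@dataclass
class ClassificationResult:
    """Fold-wise test metrics for one pipeline on one task."""

    pipeline: str
    task: str
    fold_ba: list[float]
    fold_auc: list[float]
    fold_subject_ba: list[float]
    tuned: list[dict]
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def mean_ba(self) -> float:
        return float(np.mean(self.fold_ba))

    @property
    def sd_ba(self) -> float:
        return float(np.std(self.fold_ba, ddof=1)) if len(self.fold_ba) > 1 else 0.0

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_auc, ddof=1)) if len(self.fold_auc) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "pipeline": self.pipeline,
            "task": self.task,
            "fold_ba": self.fold_ba,
            "fold_auc": self.fold_auc,
            "fold_subject_ba": self.fold_subject_ba,
            "tuned": self.tuned,
            "mean_ba": self.mean_ba,
            "sd_ba": self.sd_ba,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "seed": self.seed,
            "meta": self.meta,
        }


def _leakage_guard(fold: Fold, subject: np.ndarray, fit_mask: np.ndarray) -> None:
    fitted = set(subject[fit_mask])
    banned = fitted & set(fold.test)
    if banned:
        raise RuntimeError(f"leakage: test subject(s) {sorted(banned)} seen during fitting")


def evaluate_pipeline(
    epochs: EpochSet,
    pipeline: str,
    plan: FoldPlan,
    *,
    task: str | None = None,
    bands=None,
    J_candidates=DEFAULT_J_CANDIDATES,
    C_grid=DEFAULT_C_GRID,
    gbm_grid=DEFAULT_GBM_GRID,
    shrinkage: float = 0.05,
    seed: int = 0,
    positive_label: str = "M",
) -> ClassificationResult:
    """Run one pipeline over a fold plan and report fold-wise test metrics.

    ``pipeline`` is ``"supervised"`` (CSP + log-variance + logistic),
    ``"riemann"`` (PCA + tangent space + logistic) or ``"handcrafted"``
    (relative multitaper power + gradient-boosted trees). All feature
    transforms that involve fitting (CSP, PCA, Karcher mean, classifier)
    see training epochs only; J and hyperparameters are tuned on the
    validation subjects by balanced accuracy.
    """
    if pipeline not in PIPELINES:
        raise ValueError(f"pipeline must be one of {PIPELINES}")
    bands = default_bands() if bands is None else bands
    if task is not None:
        epochs = epochs.select_task(task)
    subject = epochs.subject
    y_all = epochs.group

    # fitting-free transforms are computed once
    if pipeline in ("supervised", "riemann"):
        covset = epoch_covariance(apply_filter_bank(epochs, bands), shrinkage=shrinkage)
    else:
        feats_all = relative_power(multitaper_band_power(epochs, bands))

    fold_ba, fold_auc, fold_subj_ba, tuned = [], [], [], []
    for fold in plan.folds:
        m_train = np.isin(subject, fold.train)
        m_val = np.isin(subject, fold.val)
        m_test = np.isin(subject, fold.test)
        _leakage_guard(fold, subject, m_train | m_val)
        y_tr, y_va, y_te = y_all[m_train], y_all[m_val], y_all[m_test]

        if pipeline == "supervised":
            cov_tr, cov_va, cov_te = (covset.select(m) for m in (m_train, m_val, m_test))

            def build(J, cov_tr=cov_tr, cov_va=cov_va, y_tr=y_tr):
                filt = csp_fit(cov_tr, y_tr, J=J, classes=(positive_label,
                               [c for c in np.unique(y_tr) if c != positive_label][0]))
                return filt, csp_log_features(cov_tr, filt), csp_log_features(cov_va, filt)

            cache = {}

            def score(J):
                filt, Xtr, Xva = build(J)
                spec, model = fit_linear(Xtr.values, y_tr, Xva.values, y_va, C_grid)
                cache[J] = (filt, spec, model)
                return spec["val_ba"]

            J, _ = tune_components(score, J_candidates)
            filt, spec, model = cache[J]
            X_te = csp_log_features(cov_te, filt).values
            scores = model.decision_function(X_te)
            if list(model.classes_).index(positive_label) == 0:
                scores = -scores
            y_pred = model.predict(X_te)
            tuned.append({"J": J, **spec["tuned"], "val_ba": spec["val_ba"]})

        elif pipeline == "riemann":
            cov_tr, cov_va, cov_te = (covset.select(m) for m in (m_train, m_val, m_test))
            cache = {}

            def score(J):
                filt = pca_fit(cov_tr, J)
                proj_tr = project_covariances(cov_tr, filt)
                refs = fit_riemann_references(proj_tr)
                Xtr = tangent_features(proj_tr, refs)
                Xva = tangent_features(project_covariances(cov_va, filt), refs)
                spec, model = fit_linear(Xtr.values, y_tr, Xva.values, y_va, C_grid)
                cache[J] = (filt, refs, spec, model)
                return spec["val_ba"]

            J, _ = tune_components(score, J_candidates)
            filt, refs, spec, model = cache[J]
            X_te = tangent_features(project_covariances(cov_te, filt), refs).values
            scores = model.decision_function(X_te)
            if list(model.classes_).index(positive_label) == 0:
                scores = -scores
            y_pred = model.predict(X_te)
            tuned.append({"J": J, **spec["tuned"], "val_ba": spec["val_ba"]})

        else:  # handcrafted
            Xtr, Xva = feats_all.values[m_train], feats_all.values[m_val]
            X_te = feats_all.values[m_test]
            spec, model = fit_gbm(Xtr, y_tr, Xva, y_va, gbm_grid, seed=seed)
            scores = model.predict_proba(X_te)[:, list(model.classes_).index(positive_label)]
            y_pred = model.predict(X_te)
            tuned.append({**spec["tuned"], "val_ba": spec["val_ba"]})

        fold_ba.append(balanced_accuracy(y_te, y_pred))
        fold_auc.append(roc_auc(y_te, scores, positive_label))
        # optional subject-level majority vote over the two test subjects
        subj_votes, subj_truth = [], []
        for s in fold.test:
            m = subject[m_test] == s
            vals, counts = np.unique(np.asarray(y_pred)[m], return_counts=True)
            subj_votes.append(vals[np.argmax(counts)])
            subj_truth.append(y_te[m][0])
        fold_subj_ba.append(float(np.mean(np.array(subj_votes) == np.array(subj_truth))))

    return ClassificationResult(
        pipeline=pipeline,
        task=task or "all",
        fold_ba=fold_ba,
        fold_auc=fold_auc,
        fold_subject_ba=fold_subj_ba,
        tuned=tuned,
        seed=seed,
        meta={"n_folds": len(plan.folds), "J_candidates": list(J_candidates)},
    )


def compare_models(results: list[ClassificationResult]) -> list[dict]:
    """Pairwise two-sided Wilcoxon signed-rank tests on fold-wise BA.

    Results must be paired by fold (same plan). Identical fold scores
    give the degenerate all-zero difference vector, reported with
    statistic 0 and p = 1.
    """
    n = {len(r.fold_ba) for r in results}
    if len(n) != 1:
        raise ValueError("results must have equal fold counts (paired by fold)")
    out = []
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            a = np.asarray(results[i].fold_ba)
            b = np.asarray(results[j].fold_ba)
            d = a - b
            if np.all(d == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = sp_stats.wilcoxon(a, b, alternative="two-sided")
            out.append(
                {
                    "a": results[i].pipeline,
                    "b": results[j].pipeline,
                    "statistic": float(stat),
                    "p": float(p),
                    "mean_diff": float(d.mean()),
                }
            )
    return out
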