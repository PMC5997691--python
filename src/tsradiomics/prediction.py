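"""Cross-validated random-forest prediction of TS status.

The procedure: (1) patients are randomly split into k = 10 equal folds;
(2)-(5) for each fold, variables are selected on the nine training folds by
a two-stage random-forest procedure (importance thresholding against a
pure-noise probe, then nested out-of-bag minimization), a random forest is
fitted on the selected variables and out-of-fold probabilities are emitted;
(7) all out-of-fold probabilities are pooled into a single ROC curve whose
AUC summarizes the model.  Cross-validated AUCs of two models on the same
patients are compared with the DeLong structural-component test.

Everything is driven by one integer seed; per-fold forests are reseeded
from the master seed through a counter, so a CVResult is bit-reproducible
from (X, y, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "FoldAssignment",
    "CVResult",
    "AUCComparison",
    "RFParams",
    "make_folds",
    "rf_variable_select",
    "cv_predict",
    "pooled_roc_auc",
    "delong_test",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index per patient; sizes differ by at most 1."""

    fold: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        sizes = np.bincount(self.fold, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")


@dataclass
class CVResult:
    """Pooled out-of-fold probabilities and the single cross-validated AUC."""

    pooled_probabilities: np.ndarray
    labels: np.ndarray
    selected_variables: list[list[int]]
    auc: float
    folds: FoldAssignment


@dataclass
class AUCComparison:
    """DeLong comparison of two correlated cross-validated AUCs."""

    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    covariance: float
    z: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class RFParams:
    """Forest sizes for selection and final fitting.

    n_probe_forests forests of n_select_trees trees drive the importance
    threshold; nested forests of n_nested_trees trees (with OOB scoring)
    pick the final prefix; the per-fold prediction model uses n_final_trees
    trees with default split parameters.
    """

    n_probe_forests: int = 25
    n_select_trees: int = 25
    n_nested_trees: int = 50
    n_final_trees: int = 500
    max_nested: int = 12  # longest importance-ranked prefix scanned in stage 2


def make_folds(n: int, k: int = 10, seed: int = 0, stratify_by=None) -> FoldAssignment:
    """Seeded shuffle + round-robin assignment into k folds.

    With ``stratify_by`` (a binary label vector), the shuffle and round-robin
    run within each class so class balance is preserved per fold; the
    default is a plain random split.
    """
    if n < k:
        raise ValueError(f"need at least k={k} patients, got {n}")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=np.int64)
    if stratify_by is None:
        perm = rng.permutation(n)
        fold[perm] = np.arange(n) % k
    else:
        labels = np.asarray(stratify_by)
        start = 0
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            perm = rng.permutation(idx)
            fold[perm] = (np.arange(idx.size) + start) % k
            start += idx.size
    return FoldAssignment(fold=fold, k=k, seed=seed)


def _mean_permutation_importance(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator, params: RFParams
) -> tuple[np.ndarray, float]:
    """Stage 1: mean held-out permutation importances plus the probe level.

    Each of the B forests is fitted on a random 2/3 of the training rows with
    one pure-noise probe column (a permuted copy of a rotating real column)
    appended; importances are permutation importances scored on the held-out
    third.  Returns (mean importance per real variable, mean probe
    importance).
    """
    n, p = X.shape
    imp = np.zeros((params.n_probe_forests, p + 1))
    for b in range(params.n_probe_forests):
        probe = rng.permutation(X[:, b % p])
        Xa = np.column_stack([X, probe])
        perm = rng.permutation(n)
        n_fit = max(2, (2 * n) // 3)
        fit_idx, val_idx = perm[:n_fit], perm[n_fit:]
        if np.unique(y[fit_idx]).size < 2 or val_idx.size == 0:
            continue
        forest = RandomForestClassifier(
            n_estimators=params.n_select_trees,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        ).fit(Xa[fit_idx], y[fit_idx])
        Xv, yv = Xa[val_idx], y[val_idx]
        # one batched predict: baseline block + one block per permuted column
        blocks = [Xv]
        for j in range(p + 1):
            Xp = Xv.copy()
            Xp[:, j] = Xp[rng.permutation(Xv.shape[0]), j]
            blocks.append(Xp)
        pred = forest.predict(np.concatenate(blocks)).reshape(p + 2, Xv.shape[0])
        acc = (pred == yv).mean(axis=1)
        imp[b] = acc[0] - acc[1:]
    mean_imp = imp.mean(axis=0)
    return mean_imp[:p], float(mean_imp[p])


def rf_variable_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    seed: int = 0,
    params: RFParams | None = None,
) -> list[int]:
    """Two-stage random-forest variable selection.

    Stage 1 (thresholding): discard variables whose mean permutation
    importance over B forests does not exceed that of an appended pure-noise
    probe.  Stage 2 (interpretation): order survivors by importance, grow
    nested forests over importance-ranked prefixes (up to
    ``params.max_nested``) and keep the smallest prefix whose out-of-bag
    error is within one binomial standard error of the best — the
    parsimonious rule that collapses to one or two variables on pure noise
    while retaining genuinely informative ones.  If everything is discarded
    the single top-importance variable is returned.
    """
    params = params or RFParams()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X_train must be 2D with >= 1 column")
    if np.unique(y).size < 2:
        raise ValueError("y_train must contain both classes")
    if X.shape[1] == 1:
        return [0]
    rng = np.random.default_rng(seed)
    mean_imp, probe_imp = _mean_permutation_importance(X, y, rng, params)

    survivors = np.flatnonzero(mean_imp > probe_imp)
    if survivors.size == 0:
        return [int(np.argmax(mean_imp))]
    order = survivors[np.argsort(-mean_imp[survivors], kind="stable")]

    errs = []
    for m in range(1, min(order.size, params.max_nested) + 1):
        forest = RandomForestClassifier(
            n_estimators=params.n_nested_trees,
            oob_score=True,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        ).fit(X[:, order[:m]], y)
        errs.append(1.0 - forest.oob_score_)
    errs = np.asarray(errs)
    best_err = errs.min()
    # smallest prefix within one binomial SE of the best OOB error
    se = math.sqrt(max(best_err * (1.0 - best_err), 1e-12) / X.shape[0])
    best_m = int(np.flatnonzero(errs <= best_err + se)[0]) + 1
    return [int(v) for v in order[:best_m]]


def cv_predict(
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldAssignment,
    seed: int = 0,
    params: RFParams | None = None,
) -> CVResult:
    """k-fold CV with per-fold variable selection and pooled probabilities.

    Variable selection runs inside each training set (no leakage); the final
    per-fold model is a random forest with ``params.n_final_trees`` trees and
    default split parameters.  Raises if any training set is single-class
    (use stratified folds for small or imbalanced cohorts).
    """
    params = params or RFParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.size or X.shape[0] != folds.fold.size:
        raise ValueError("X, y and folds must be row-aligned")
    pooled = np.full(y.size, np.nan)
    selected: list[list[int]] = []
    ss = np.random.SeedSequence(seed)
    for f in range(folds.k):
        test = folds.fold == f
        train = ~test
        if np.unique(y[train]).size < 2:
            raise ValueError(
                f"training folds for fold {f} contain a single class; "
                "use stratified folds"
            )
        fold_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31))
        sel = rf_variable_select(X[train], y[train], seed=fold_seed, params=params)
        forest = RandomForestClassifier(
            n_estimators=params.n_final_trees,
            random_state=fold_seed,
            n_jobs=1,
        ).fit(X[train][:, sel], y[train])
        pos_col = int(np.flatnonzero(forest.classes_ == 1)[0])
        pooled[test] = forest.predict_proba(X[test][:, sel])[:, pos_col]
        selected.append(sel)
    auc = pooled_roc_auc(pooled, y)
    return CVResult(pooled, np.asarray(y), selected, auc, folds)


def pooled_roc_auc(probabilities, labels) -> float:
    """AUC as the Mann-Whitney statistic of pooled probabilities.

    (#concordant positive-negative pairs + 0.5 * #ties) / (n_pos * n_neg).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pos = p[y == 1]
    neg = p[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("labels must contain both classes")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0)
                 / (pos.size * neg.size))


def _structural_components(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong V10 (per positive) and V01 (per negative) components."""
    pos = p[y == 1]
    neg = p[y == 0]
    # psi(x, y) = 1 if x > y, 0.5 if tie, 0 otherwise
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def delong_test(p_a, p_b, labels) -> AUCComparison:
    """DeLong test for the difference of two correlated AUCs.

    Both probability vectors must score the same patients against the same
    labels.  Variance and covariance come from the empirical covariances of
    the structural components; p is two-sided normal.  A zero-variance
    difference yields p = 1 with a degenerate flag.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    y = np.asarray(labels)
    if not (p_a.shape == p_b.shape == y.shape):
        raise ValueError("p_a, p_b and labels must be aligned")
    v10a, v01a, auc_a = _structural_components(p_a, y)
    v10b, v01b, auc_b = _structural_components(p_b, y)
    m, n = v10a.size, v01a.size
    if m < 2 or n < 2:
        raise ValueError("need >= 2 patients in each class")

    def _cov(u, v):
        return float(np.cov(u, v, ddof=1)[0, 1])

    var_a = _cov(v10a, v10a) / m + _cov(v01a, v01a) / n
    var_b = _cov(v10b, v10b) / m + _cov(v01b, v01b) / n
    cov_ab = _cov(v10a, v10b) / m + _cov(v01a, v01b) / n
    var_diff = var_a + var_b - 2.0 * cov_ab
    if var_diff <= 0:
        return AUCComparison(auc_a, auc_b, var_a, var_b, cov_ab,
                             z=0.0, p_value=1.0, degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return AUCComparison(auc_a, auc_b, var_a, var_b, cov_ab, z=float(z), p_value=float(p))
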