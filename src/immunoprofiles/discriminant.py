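"""Two-class linear discriminant analysis and its cross-validated evaluation.

The classifier is Fisher's LDA with a pooled within-class covariance:
w = S^-1 (mu1 - mu0), decision threshold w'(mu0+mu1)/2 - log(pi1/pi0),
with a small ridge (ridge * trace(S)/p on the diagonal) for numerical
safety when the subset size approaches the sample size.  Evaluation is by
repeated stratified 2-fold cross-validation (the protocol also used as
the genetic-algorithm fitness): per repeat, fit on one fold and predict
the other in both directions, pool the predictions, and average the
accuracy / sensitivity / specificity over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LDAModel", "CVReport", "fit_lda", "predict", "cv_evaluate"]


@dataclass
class LDAModel:
    marker_ids: tuple[str, ...]
    mean0: np.ndarray
    mean1: np.ndarray
    weights: np.ndarray  # w = S^-1 (mu1 - mu0)
    threshold: float  # classify 1 iff w'x > threshold
    log_prior_ratio: float  # log(pi1 / pi0)


@dataclass
class CVReport:
    """Repeated stratified k-fold CV summary (rates pooled within repeat)."""

    accuracy: float
    accuracy_sd: float
    sensitivity: float
    specificity: float
    n_repeats: int
    n_folds: int
    seed: int
    per_repeat_accuracy: np.ndarray = field(repr=False, default=None)


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    priors: str = "empirical",
    ridge: float = 1e-6,
    marker_ids: tuple[str, ...] | None = None,
) -> LDAModel:
    """Fit two-class LDA with pooled within-class covariance and a tiny ridge."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (n, p) with matching labels")
    X0, X1 = X[~y], X[y]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("both classes need >= 2 rows")
    if priors not in ("empirical", "equal"):
        raise ValueError("priors must be 'empirical' or 'equal'")
    p = X.shape[1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    S = ((n0 - 1) * np.cov(X0, rowvar=False, ddof=1).reshape(p, p)
         + (n1 - 1) * np.cov(X1, rowvar=False, ddof=1).reshape(p, p)) / (n0 + n1 - 2)
    S = S + ridge * (np.trace(S) / p) * np.eye(p)
    try:
        L = np.linalg.cholesky(S)
        w = np.linalg.solve(L.T, np.linalg.solve(L, mu1 - mu0))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "pooled covariance singular even after ridge; increase `ridge`"
        ) from err
    if priors == "empirical":
        log_prior_ratio = float(np.log(n1 / n0))
    else:
        log_prior_ratio = 0.0
    threshold = float(w @ (mu0 + mu1) / 2.0 - log_prior_ratio)
    ids = marker_ids if marker_ids is not None else tuple(f"m{j}" for j in range(p))
    return LDAModel(tuple(ids), mu0, mu1, w, threshold, log_prior_ratio)


def predict(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Class labels for X under the fitted rule; boundary ties go to class 0."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.marker_ids):
        raise ValueError(
            f"X has {X.shape[-1] if X.ndim == 2 else '?'} columns, "
            f"model expects {len(model.marker_ids)}"
        )
    return (X @ model.weights) > model.threshold


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random stratified partition into n_folds near-equal folds."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[f].extend(chunk.tolist())
    return [np.asarray(sorted(f)) for f in folds]


def cv_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 30,
    n_folds: int = 2,
    seed: int = 0,
    priors: str = "empirical",
    ridge: float = 1e-6,
) -> CVReport:
    """Repeated stratified n-fold CV of the LDA classifier.

    Accuracy is the pooled correct fraction across the folds of a repeat;
    sensitivity is the correct fraction among class-1 (NCI+) patients and
    specificity among class-0.  Means are taken over repeats.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if min(n0, n1) < 2 * n_folds:
        raise ValueError(
            f"each class needs >= {2 * n_folds} members for stratified "
            f"{n_folds}-fold CV (got {n0} / {n1})"
        )
    rng = np.random.default_rng(seed)
    acc = np.empty(n_repeats)
    sens = np.empty(n_repeats)
    spec = np.empty(n_repeats)
    for r in range(n_repeats):
        folds = _stratified_folds(y, n_folds, rng)
        pred = np.empty_like(y)
        for f, test_idx in enumerate(folds):
            train_idx = np.concatenate([folds[g] for g in range(n_folds) if g != f])
            model = fit_lda(X[train_idx], y[train_idx], priors=priors, ridge=ridge)
            pred[test_idx] = predict(model, X[test_idx])
        correct = pred == y
        acc[r] = correct.mean()
        sens[r] = correct[y].mean()
        spec[r] = correct[~y].mean()
    return CVReport(
        accuracy=float(acc.mean()),
        accuracy_sd=float(acc.std(ddof=1)) if n_repeats > 1 else 0.0,
        sensitivity=float(sens.mean()),
        specificity=float(spec.mean()),
        n_repeats=n_repeats,
        n_folds=n_folds,
        seed=seed,
        per_repeat_accuracy=acc,
    )
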