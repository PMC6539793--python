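"""Two-class linear discriminant analysis with two validation schemes.

The classifier is the classical Fisher discriminant with equal priors: the
weight vector is the pooled within-class covariance inverse applied to the
difference of the class means, and the decision threshold is the midpoint of
the projected class means.  Performance is assessed conservatively in two
complementary ways:

* leave-one-out cross-validation (LOOCV) over the original cohort;
* training on sub-sampled in-silico patterns — balanced synthetic training
  vectors drawn coordinate-wise from each class's empirical per-feature
  value pools, constrained to share fewer than 25% of their coordinate
  values with any original sample — and scoring all original samples as an
  untouched verification set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import FeatureTable

__all__ = [
    "LDAModel",
    "ValidationReport",
    "SubsampleTrainingSet",
    "fit_lda",
    "loocv",
    "generate_training_patterns",
    "subsample_validate",
    "confusion_metrics",
]

RIDGE_CONDITION_LIMIT = 1e10
RIDGE_EPS = 1e-6
DEFAULT_MAX_SHARED = 0.25


@dataclass
class LDAModel:
    """Fisher linear discriminant with equal class priors."""

    weights: np.ndarray
    threshold: float
    mean_case: np.ndarray
    mean_control: np.ndarray
    pooled_cov: np.ndarray
    ridged: bool = False

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights - self.threshold

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Boolean case/control calls (True = case)."""
        return self.decision(X) > 0


@dataclass
class ValidationReport:
    """Confusion counts and Ac/Sp/Sn for one validated model."""

    mode: str  # "LOOCV" or "SUBSAMPLE"
    tp: int
    fp: int
    tn: int
    fn: int
    feature_set: tuple[str, ...] = ()
    accuracy: float = field(init=False)
    specificity: float = field(init=False)
    sensitivity: float = field(init=False)

    def __post_init__(self) -> None:
        self.accuracy, self.specificity, self.sensitivity = confusion_metrics(
            self.tp, self.fp, self.tn, self.fn
        )

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "feature_set": list(self.feature_set),
        }


@dataclass
class SubsampleTrainingSet:
    """Balanced in-silico training vectors with provenance seed."""

    X: np.ndarray  # (2 * n_per_class, d)
    y: np.ndarray  # boolean, True = case
    seed: int | None
    max_shared: float


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """(accuracy, specificity, sensitivity) in percent, rounded to 2 decimals.

    Cases are positives: Ac = (TP+TN)/n, Sp = TN/(TN+FP), Sn = TP/(TP+FN).
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must contribute samples")
    ac = 100.0 * (tp + tn) / (tp + fp + tn + fn)
    sp = 100.0 * tn / (tn + fp)
    sn = 100.0 * tp / (tp + fn)
    return round(ac, 2), round(sp, 2), round(sn, 2)


def fit_lda(X: np.ndarray, y: np.ndarray) -> LDAModel:
    """Fit the Fisher discriminant: w = S_pooled^{-1} (mu_case - mu_control).

    ``y`` is boolean (True = case).  The pooled within-class covariance uses
    the unbiased per-class estimates; if its condition number exceeds 1e10 a
    small ridge (eps * trace/d) is added and flagged on the model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if X.ndim == 1:
        X = X[:, None]
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each class needs at least two samples")
    Xc, Xn = X[y], X[~y]
    mu1, mu0 = Xc.mean(axis=0), Xn.mean(axis=0)
    s1 = np.cov(Xc, rowvar=False, ddof=1)
    s0 = np.cov(Xn, rowvar=False, ddof=1)
    pooled = ((n1 - 1) * np.atleast_2d(s1) + (n0 - 1) * np.atleast_2d(s0)) / (
        n1 + n0 - 2
    )
    ridged = False
    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > RIDGE_CONDITION_LIMIT:
        d = pooled.shape[0]
        pooled = pooled + RIDGE_EPS * (np.trace(pooled) / d) * np.eye(d)
        ridged = True
        if np.linalg.cond(pooled) > 1 / np.finfo(float).eps:
            raise np.linalg.LinAlgError(
                "pooled covariance singular even after ridge regularization"
            )
    w = np.linalg.solve(pooled, mu1 - mu0)
    threshold = float(w @ (mu1 + mu0) / 2.0)
    return LDAModel(w, threshold, mu1, mu0, pooled, ridged)


def _as_matrix(
    table: FeatureTable | pd.DataFrame, feature_set=None, y=None
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    if isinstance(table, FeatureTable):
        df = table.abundances
        y = table.case_mask
    elif isinstance(table, pd.DataFrame):
        if y is None:
            raise TypeError("labels are required when passing a plain DataFrame")
        df = table
        y = np.asarray(y, dtype=bool)
    else:
        raise TypeError("expected a FeatureTable or a DataFrame with labels")
    if feature_set is not None:
        df = df[list(feature_set)]
    return df.to_numpy(dtype=float), y, tuple(df.columns)


def loocv(table, feature_set=None, y=None) -> ValidationReport:
    """Leave-one-out cross-validation of the LDA over the original cohort.

    Each sample in turn is held out, the discriminant is refit on the rest,
    and the held-out prediction is accumulated into the confusion counts.
    """
    X, y, names = _as_matrix(table, feature_set, y)
    n = X.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least four samples")
    tp = fp = tn = fn = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if y[mask].sum() < 2 or (~y[mask]).sum() < 2:
            raise ValueError("a LOOCV fold would leave a class nearly empty")
        model = fit_lda(X[mask], y[mask])
        pred = bool(model.predict(X[i : i + 1])[0])
        if y[i]:
            tp += pred
            fn += not pred
        else:
            fp += pred
            tn += not pred
    return ValidationReport("LOOCV", tp, fp, tn, fn, names)


def generate_training_patterns(
    table: FeatureTable,
    feature_set=None,
    n_per_class: int = 200,
    max_shared: float = DEFAULT_MAX_SHARED,
    seed: int | None = None,
    max_tries: int = 1000,
) -> SubsampleTrainingSet:
    """Balanced in-silico training vectors by per-feature sub-sampling.

    Each synthetic vector draws every coordinate independently from the
    corresponding class's empirical per-feature value pool.  A candidate
    sharing at least ``max_shared`` of its coordinate values (exact matches)
    with any original sample vector is rejected and redrawn, so the training
    set can never memorize an original sample.
    """
    X, y, names = _as_matrix(table, feature_set)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    limit = max_shared * d
    if limit <= 1:
        # every coordinate of a pool-drawn vector exactly matches the sample
        # it came from, so a limit permitting no matches can never be met
        import warnings

        warnings.warn(
            f"shared-value constraint ({max_shared:.0%} of {d} features) "
            "permits no matches and cannot be satisfied by sub-sampling; "
            "constraint disabled",
            stacklevel=2,
        )
        limit = d + 1.0

    out = np.empty((2 * n_per_class, d))
    labels = np.zeros(2 * n_per_class, dtype=bool)
    row = 0
    for is_case in (True, False):
        pool = X[y] if is_case else X[~y]
        if pool.shape[0] == 0:
            raise ValueError("each class needs at least one original sample")
        for _ in range(n_per_class):
            for attempt in range(max_tries):
                idx = rng.integers(0, pool.shape[0], size=d)
                cand = pool[idx, np.arange(d)]
                shared = (X == cand).sum(axis=1)
                if shared.max() < limit:
                    break
            else:
                raise RuntimeError(
                    "could not draw a training vector sharing fewer than "
                    f"{max_shared:.0%} of values with every original sample; "
                    "feature value pools are too degenerate"
                )
            out[row] = cand
            labels[row] = is_case
            row += 1
    return SubsampleTrainingSet(out, labels, seed, max_shared)


def subsample_validate(
    table: FeatureTable,
    feature_set=None,
    n_per_class: int = 200,
    seed: int | None = None,
) -> ValidationReport:
    """Train the LDA on generated patterns; verify on all original samples."""
    X, y, names = _as_matrix(table, feature_set)
    training = generate_training_patterns(
        table, feature_set, n_per_class=n_per_class, seed=seed
    )
    model = fit_lda(training.X, training.y)
    pred = model.predict(X)
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    return ValidationReport("SUBSAMPLE", tp, fp, tn, fn, names)
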