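"""Dimensionality reduction for strongly multicollinear abundance panels.

Glycated-peptide abundances are highly multicollinear (sites on the same
protein rise and fall together), which destabilizes linear discriminant
weights.  Two reductions are provided:

* a randomized variance-inflation-factor (VIF) filter — VIF_i = 1/(1-R_i^2)
  with R_i^2 the coefficient of determination of feature i regressed on the
  rest — that repeatedly grows a random feature subset, pruning the
  worst-VIF feature whenever the subset exceeds the cutoff (conventionally
  5 or 10), and tallies the surviving subsets over many runs;
* PCA on standardized features, retaining the minimal number of leading
  components that explain 95% of the sample variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SubsetTally",
    "PCABasis",
    "vif",
    "randomized_vif_filter",
    "pca_select",
]

_R2_COLLINEAR = 1.0 - 1e-12


def vif(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Variance inflation factor of every feature in a matrix.

    Each feature is regressed (with intercept) on all the others by least
    squares; VIF_i = 1/(1-R_i^2).  Perfectly collinear features get ``inf``.
    """
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("VIF needs a 2-D matrix with at least two features")
    n, d = arr.shape
    if n <= d:
        raise ValueError(f"need more samples ({n}) than features ({d}) for VIF")
    out = np.empty(d)
    ones = np.ones((n, 1))
    for i in range(d):
        yi = arr[:, i]
        others = np.hstack([ones, np.delete(arr, i, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yi, rcond=None)
        resid = yi - others @ coef
        ss_tot = np.sum((yi - yi.mean()) ** 2)
        if ss_tot == 0:
            out[i] = np.inf  # constant feature is degenerate
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[i] = np.inf if r2 >= _R2_COLLINEAR else 1.0 / (1.0 - r2)
    return out


@dataclass
class SubsetTally:
    """Frequency census of feature subsets surviving the randomized filter."""

    counts: dict[tuple[str, ...], int]
    runs: int
    cutoff: float

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.runs:
            raise ValueError("subset counts must sum to the number of runs")

    def most_common(self, k: int = 1) -> list[tuple[tuple[str, ...], int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]

    def above_fraction(self, fraction: float = 0.70) -> list[tuple[str, ...]]:
        """Subsets represented in at least ``fraction`` of all runs."""
        cut = fraction * self.runs
        return [s for s, c in sorted(self.counts.items()) if c >= cut]

    def to_json_dict(self) -> dict:
        return {
            "runs": self.runs,
            "cutoff": self.cutoff,
            "counts": {" ".join(s): c for s, c in self.counts.items()},
        }


def _filter_once(
    arr: np.ndarray, names: list[str], cutoff: float, rng: np.random.Generator
) -> tuple[str, ...]:
    """One randomized grow-and-prune pass over all features."""
    n, d = arr.shape
    order = rng.permutation(d)
    subset: list[int] = list(order[:2])
    for j in order[2:]:
        subset.append(int(j))
        # prune worst-VIF members until the subset is below the cutoff
        while len(subset) >= 2:
            if len(subset) >= n:
                # regressions undetermined at d >= n: the newest feature is
                # perfectly predictable from the rest, so it must go
                subset.pop()
                continue
            v = vif(arr[:, subset])
            worst = int(np.argmax(v))
            if v[worst] <= cutoff:
                break
            subset.pop(worst)
    return tuple(sorted(names[i] for i in subset))


def randomized_vif_filter(
    X: pd.DataFrame,
    cutoff: float = 5.0,
    runs: int = 1000,
    seed: int | None = None,
) -> SubsetTally:
    """Randomized iterative VIF feature filter with subset frequency tally.

    Each run starts from a random pair of features; remaining features are
    added in random order, and whenever the subset's maximum VIF exceeds
    ``cutoff`` the feature with the largest VIF is removed (recomputing VIFs
    after each removal).  Because the surviving subset depends on the test
    order, the procedure is repeated ``runs`` times and the resulting
    subsets are tallied; the most frequently recurring subsets are the
    stable non-collinear feature combinations.
    """
    if cutoff <= 1:
        raise ValueError("VIF cutoff must exceed 1")
    if runs < 1:
        raise ValueError("need at least one run")
    if X.shape[1] < 3:
        raise ValueError("randomized VIF filtering needs at least three features")
    arr = np.asarray(X, dtype=float)
    names = list(X.columns)
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, ...], int] = {}
    for _ in range(runs):
        subset = _filter_once(arr, names, cutoff, rng)
        counts[subset] = counts.get(subset, 0) + 1
    return SubsetTally(counts, runs, cutoff)


@dataclass
class PCABasis:
    """Retained principal-component basis of a standardized feature matrix."""

    loadings: np.ndarray  # (k, d) rows = components
    explained_variance_ratio: np.ndarray  # all d components
    k: int
    feature_names: list[str] = field(default_factory=list)


def pca_select(
    X: pd.DataFrame, var_threshold: float = 0.95
) -> tuple[PCABasis, pd.DataFrame]:
    """PCA of standardized features with a cumulative-variance component cut.

    Features are standardized to zero mean and unit variance (the
    correlation-matrix convention; raw peak areas span orders of magnitude),
    zero-variance features are dropped with a warning, and the minimal
    number of leading components whose cumulative explained variance reaches
    ``var_threshold`` is retained.  Returns the basis and per-sample scores
    of the retained components.
    """
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    keep = X.std(ddof=0) > 0
    if not keep.all():
        dropped = list(X.columns[~keep])
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
        X = X.loc[:, keep]
    Z = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    pca = PCA()
    scores = pca.fit_transform(Z)
    ratios = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(ratios), var_threshold) + 1)
    k = min(k, len(ratios))
    basis = PCABasis(pca.components_[:k], ratios, k, list(X.columns))
    cols = [f"PC{i + 1}" for i in range(k)]
    return basis, pd.DataFrame(scores[:, :k], index=X.index, columns=cols)
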