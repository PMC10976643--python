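"""Downfield/upfield population analysis of a shift distribution.

Selects the n most downfield- and n most upfield-shifted frames of a
P_beta shift series, ranks structural features by L2-regularised logistic
regression on standardized features (importance = |coefficient|, error
bars from bootstrap resampling), and reports pairwise feature
correlations. All stochastic steps are driven by an explicit seed.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "PopulationSplit",
    "ImportanceReport",
    "select_extreme_populations",
    "feature_importance",
    "feature_correlations",
]


@dataclasses.dataclass
class PopulationSplit:
    """Disjoint downfield/upfield frame-index sets of equal size.

    Downfield = larger (more positive) delta. ``tie`` flags an ambiguous
    selection boundary (equal shift values straddling the cut)."""

    downfield: np.ndarray
    upfield: np.ndarray
    n_per_side: int
    tie: bool = False

    def __post_init__(self) -> None:
        if len(self.downfield) != self.n_per_side or \
                len(self.upfield) != self.n_per_side:
            raise ValueError("population sizes must equal n_per_side")
        if set(map(int, self.downfield)) & set(map(int, self.upfield)):
            raise ValueError("downfield and upfield sets must be disjoint")

    def labels(self) -> tuple[np.ndarray, np.ndarray]:
        """(frame_indices, y) with y=1 downfield, y=0 upfield."""
        frames = np.concatenate([self.downfield, self.upfield])
        y = np.concatenate([
            np.ones(self.n_per_side, int), np.zeros(self.n_per_side, int)
        ])
        return frames, y


def select_extreme_populations(
    shifts: Sequence[float],
    n_per_side: int = 150,
    frame_indices: Sequence[int] | None = None,
) -> PopulationSplit:
    """Pick the n most downfield and n most upfield frames of a shift
    series.

    Ties are broken by frame index (earlier frame wins); the downfield set
    is selected first, the upfield set from the remaining frames, so a
    fully degenerate series splits the first 2n frames by index (flagged).
    Invariant to permutation of the input order up to that tie handling.
    """
    v = np.asarray(shifts, float)
    frames = (
        np.arange(len(v)) if frame_indices is None
        else np.asarray(frame_indices, int)
    )
    if len(frames) != len(v):
        raise ValueError("frame_indices length mismatch")
    if len(v) < 2 * n_per_side:
        raise ValueError(
            f"need at least {2 * n_per_side} frames, got {len(v)}"
        )
    order = np.lexsort((frames, -v))  # delta desc, frame asc
    down_pos = order[:n_per_side]
    remaining = order[n_per_side:]
    rem_order = np.lexsort((frames[remaining], v[remaining]))
    up_pos = remaining[rem_order][:n_per_side]

    down_min = v[down_pos].min()
    rest = np.setdiff1d(np.arange(len(v)), down_pos, assume_unique=False)
    tie = bool(np.any(v[rest] >= down_min - 1e-15)) if rest.size else False
    if v[up_pos].max() > down_min + 1e-15:
        raise AssertionError("selection invariant violated")
    return PopulationSplit(
        downfield=frames[down_pos],
        upfield=frames[up_pos],
        n_per_side=n_per_side,
        tie=tie,
    )


@dataclasses.dataclass
class ImportanceReport:
    """Feature importances (|standardized coefficient|) with bootstrap
    error bars, held-out accuracy and the seed that produced them."""

    table: pd.DataFrame  # feature, importance, error
    accuracy: float
    seed: int
    dropped: list[str]
    correlated_pairs: list[tuple[str, str]]

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("importance", ascending=False)

    def top_feature(self) -> str:
        return str(self.ranked().iloc[0]["feature"])


def feature_importance(
    features: pd.DataFrame,
    labels: Sequence[int],
    seed: int = 0,
    C: float = 1.0,
    n_bootstrap: int = 200,
    cv_folds: int = 5,
    correlation_flag: float = 0.95,
) -> ImportanceReport:
    """Logistic-regression feature importance with bootstrap error bars.

    Features are standardized to zero mean/unit variance (zero-variance
    columns are dropped with a warning), an L2-regularised logistic
    regression is fit, and importance is the absolute standardized
    coefficient — invariant to affine rescaling of any input feature.
    Error bars are the standard deviation of the coefficients over
    ``n_bootstrap`` resamples of the rows. Near-duplicate features
    (|Pearson r| >= ``correlation_flag``) are reported, since correlated
    features share importance. Deterministic given ``seed``.
    """
    X = features.copy()
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    variances = X.var(axis=0, ddof=0)
    dropped = [c for c in X.columns if variances[c] == 0.0]
    if dropped:
        warnings.warn(
            f"dropping zero-variance features: {dropped}", UserWarning
        )
        X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise ValueError("no features left after dropping zero variance")

    cols = list(X.columns)
    Xv = X.to_numpy(float)
    rng = np.random.default_rng(seed)

    def fit_coefs(Xa: np.ndarray, ya: np.ndarray) -> np.ndarray:
        scaler = StandardScaler()
        Xs = scaler.fit_transform(Xa)
        clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
        clf.fit(Xs, ya)
        return clf.coef_[0]

    coefs = fit_coefs(Xv, y)

    boot = np.empty((n_bootstrap, len(cols)))
    n = len(y)
    for b in range(n_bootstrap):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        boot[b] = fit_coefs(Xv[idx], y[idx])
    errors = boot.std(axis=0, ddof=1)

    folds = int(min(cv_folds, np.bincount(y).min()))
    if folds < 2:
        raise ValueError("need at least 2 members per class for held-out "
                         "accuracy")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    model = make_pipeline(
        StandardScaler(),
        LogisticRegression(C=C, solver="lbfgs", max_iter=2000),
    )
    accuracy = float(np.mean(cross_val_score(model, Xv, y, cv=cv)))

    corr = np.corrcoef(Xv, rowvar=False)
    pairs = [
        (cols[i], cols[j])
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if abs(corr[i, j]) >= correlation_flag
    ]
    table = pd.DataFrame({
        "feature": cols,
        "importance": np.abs(coefs),
        "error": errors,
    })
    return ImportanceReport(
        table=table, accuracy=accuracy, seed=int(seed), dropped=dropped,
        correlated_pairs=pairs,
    )


def feature_correlations(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the feature columns.

    Symmetric with a unit diagonal; zero-variance features yield NaN
    entries (flagged, not errored)."""
    if len(features) < 2:
        raise ValueError("feature_correlations requires at least 2 rows")
    corr = features.corr(method="pearson")
    degenerate = [c for c in features.columns
                  if features[c].var(ddof=0) == 0.0]
    if degenerate:
        warnings.warn(
            f"zero-variance features have undefined correlations: "
            f"{degenerate}", UserWarning
        )
    return corr
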