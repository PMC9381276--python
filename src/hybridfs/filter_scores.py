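"""Per-feature relevance statistics: chi-squared, F-statistic, mutual information.

Each scorer maps one feature column (already min-max scaled onto [0, 1]) and the
class labels to a single non-negative relevance score.  Larger means more
class-discriminative; 0 means no detectable association.  The three scores per
feature are collected into a feature score table (FST) that the overall ranker
consumes.

Chi-squared is defined over a contingency table between a discretized feature
and the class: X2 = sum_ij (O_ij - E_ij)^2 / E_ij with E_ij the usual
independence expectation (row total x column total / grand total).  Continuous
expression values have no natural levels, so two conventions are offered:

* ``binned-contingency`` (default): equal-width bins on [0, 1] become the table
  rows; empty bins are dropped (they contribute neither observed nor expected
  mass).  This evaluates the statistic literally.
* ``weighted-frequency``: the per-class sums of the scaled values act as
  observed "frequencies" and class proportions give the expected ones — the
  convention used by ML toolkits (e.g. scikit-learn's ``chi2``) for real-valued
  non-negative features.

The F-statistic for two classes is the ratio

    F = [ (mean+ - mean)^2 + (mean- - mean)^2 ] / [ var+ + var- ]

with unbiased within-class variances — note this is *not* the classical one-way
ANOVA ratio of mean squares (no n_k weighting, no degrees-of-freedom scaling);
it agrees with ANOVA only up to monotone rescaling for balanced classes, and
only the induced ranking matters downstream.  For three or more classes the
standard one-way ANOVA F ratio is used.

Mutual information is the discrete plug-in estimate in bits:
I(X;Y) = sum_ij p(i,j) log2 [ p(i,j) / (p(i) p(j)) ], with the feature
discretized into equal-width bins over [0, 1] and 0 log 0 terms dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_preprocess import Dataset

__all__ = [
    "ScoringConfig",
    "FeatureScoreTable",
    "chi_squared_score",
    "f_statistic_score",
    "mutual_information_score",
    "build_fst",
]

CHI2_MODES = ("binned-contingency", "weighted-frequency")


@dataclass(frozen=True)
class ScoringConfig:
    """Knobs of the three filter scorers.

    chi2_mode: contingency construction for continuous features (see module
    docstring).  n_bins: equal-width bins on [0,1] used by the binned chi2 and
    the MI estimator; 10 by default, a common histogram-estimator choice for
    tens-to-hundreds of samples.
    """

    chi2_mode: str = "binned-contingency"
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.chi2_mode not in CHI2_MODES:
            raise ValueError(f"chi2_mode must be one of {CHI2_MODES}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    return labels


def _bin_indices(feature: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin index on [0, 1]; values at 1.0 fall in the last bin."""
    idx = np.floor(np.clip(feature, 0.0, 1.0) * n_bins).astype(int)
    return np.minimum(idx, n_bins - 1)


def _chi2_from_observed(observed: np.ndarray) -> float:
    """Pearson statistic from an observed table; empty rows/columns dropped."""
    observed = np.asarray(observed, dtype=float)
    observed = observed[observed.sum(axis=1) > 0][:, observed.sum(axis=0) > 0]
    if observed.size == 0:
        return 0.0
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / observed.sum()
    return float(((observed - expected) ** 2 / expected).sum())


def chi_squared_score(
    feature: np.ndarray,
    labels: np.ndarray,
    mode: str = "binned-contingency",
    n_bins: int = 10,
) -> float:
    """Chi-squared association between a [0,1]-valued feature and the class."""
    feature = np.asarray(feature, dtype=float)
    labels = _check_labels(labels)
    if mode not in CHI2_MODES:
        raise ValueError(f"unknown chi2 mode {mode!r}")
    _, y = np.unique(labels, return_inverse=True)
    n_classes = y.max() + 1

    if mode == "binned-contingency":
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        rows = _bin_indices(feature, n_bins)
        observed = np.zeros((n_bins, n_classes))
        np.add.at(observed, (rows, y), 1.0)
        return _chi2_from_observed(observed)

    # weighted-frequency: per-class sums of the values as observed mass,
    # expected apportioned by class sample proportions.
    total = feature.sum()
    if total == 0:
        return 0.0
    observed = np.bincount(y, weights=feature, minlength=n_classes)
    proportions = np.bincount(y, minlength=n_classes) / len(y)
    expected = total * proportions
    return float(((observed - expected) ** 2 / expected).sum())


def f_statistic_score(feature: np.ndarray, labels: np.ndarray) -> float:
    """Between-class separation F score; +inf when classes are disjoint points.

    Two classes: unweighted squared mean deviations over summed unbiased class
    variances.  Three or more: one-way ANOVA F.
    """
    feature = np.asarray(feature, dtype=float)
    labels = _check_labels(labels)
    classes, y = np.unique(labels, return_inverse=True)
    groups = [feature[y == k] for k in range(len(classes))]
    for cls, g in zip(classes, groups):
        if len(g) < 2:
            raise ValueError(
                f"class {cls!r} has {len(g)} sample(s); need >= 2 for a variance"
            )

    if len(classes) == 2:
        grand = feature.mean()
        numerator = sum((g.mean() - grand) ** 2 for g in groups)
        denominator = sum(g.var(ddof=1) for g in groups)
    else:
        n = len(feature)
        grand = feature.mean()
        numerator = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / (
            len(classes) - 1
        )
        denominator = sum(((g - g.mean()) ** 2).sum() for g in groups) / (
            n - len(classes)
        )

    if denominator == 0:
        return 0.0 if numerator == 0 else float("inf")
    return float(numerator / denominator)


def mutual_information_score(
    feature: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> float:
    """Histogram mutual information in bits between feature bins and the class."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    feature = np.asarray(feature, dtype=float)
    labels = _check_labels(labels)
    _, y = np.unique(labels, return_inverse=True)
    rows = _bin_indices(feature, n_bins)
    joint = np.zeros((n_bins, y.max() + 1))
    np.add.at(joint, (rows, y), 1.0)
    return mutual_information_from_joint(joint / joint.sum())


def mutual_information_from_joint(joint: np.ndarray) -> float:
    """I(X;Y) in bits from a joint probability table (rows X, columns Y)."""
    joint = np.asarray(joint, dtype=float)
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = joint[mask] / (px @ py)[mask]
    return float((joint[mask] * np.log2(ratio)).sum())


@dataclass
class FeatureScoreTable:
    """Per-feature scores under the three filters, in dataset feature order."""

    feature_names: list[str]
    chi2: np.ndarray
    f_stat: np.ndarray
    mi: np.ndarray

    def __post_init__(self) -> None:
        self.chi2 = np.asarray(self.chi2, dtype=float)
        self.f_stat = np.asarray(self.f_stat, dtype=float)
        self.mi = np.asarray(self.mi, dtype=float)
        m = len(self.feature_names)
        for name, col in [("chi2", self.chi2), ("f_stat", self.f_stat), ("mi", self.mi)]:
            if col.shape != (m,):
                raise ValueError(f"{name} must have one entry per feature")
            if np.any(np.isnan(col)) or np.any(col < 0):
                raise ValueError(f"{name} scores must be >= 0 and not NaN")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "chi2": self.chi2,
                "f_stat": self.f_stat,
                "mi": self.mi,
            }
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "FeatureScoreTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            feature_names=df["feature"].astype(str).tolist(),
            chi2=df["chi2"].to_numpy(),
            f_stat=df["f_stat"].to_numpy(),
            mi=df["mi"].to_numpy(),
        )


def build_fst(data: Dataset, config: ScoringConfig | None = None) -> FeatureScoreTable:
    """Score every feature of a scaled dataset with the three filters."""
    config = config or ScoringConfig()
    chi2 = np.empty(data.n_features)
    f_stat = np.empty(data.n_features)
    mi = np.empty(data.n_features)
    for j in range(data.n_features):
        col = data.values[:, j]
        chi2[j] = chi_squared_score(col, data.labels, config.chi2_mode, config.n_bins)
        f_stat[j] = f_statistic_score(col, data.labels)
        mi[j] = mutual_information_score(col, data.labels, config.n_bins)
    return FeatureScoreTable(
        feature_names=list(data.feature_names), chi2=chi2, f_stat=f_stat, mi=mi
    )
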