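"""Rank fusion with outlier moderation: FST -> RT -> moderated ORT.

The three filter scores of each feature are first converted, per filter, into
integer ranks 1..m (1 = best, ordinal: ties broken by first occurrence so every
feature gets a distinct rank).  A feature that one filter happens to dislike
while the other two rank it highly would be unfairly punished by a plain rank
sum, so each rank triple is *moderated* before summation:

    if max(r1, r2, r3) > 2 * (sum of the other two):
        replace that maximum with exactly 2 * (sum of the other two)

e.g. (8, 2, 1) -> (6, 2, 1).  The replacement value sits exactly at the trigger
threshold, so a single pass is already a fixpoint.  At most one entry of a
triple can trigger (two entries >= 1 can never each exceed twice a sum that
includes the other).  The overall rank OR is the row sum of the moderated
triple; the table sorted ascending by OR (stable, ties keep the original
feature order) is the overall rank table (ORT).  Smaller OR = more important.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .filter_scores import FeatureScoreTable

__all__ = [
    "RankTable",
    "OverallRankTable",
    "ranks_from_scores",
    "moderate_rank_triple",
    "build_rt",
    "build_ort",
]

FILTER_COLUMNS = ("chi2", "f_stat", "mi")


def ranks_from_scores(scores: np.ndarray) -> np.ndarray:
    """Ordinal descending ranks: highest score -> 1, ties by first occurrence.

    The +inf sentinel (perfect class separation under the F score) sorts ahead
    of every finite score.
    """
    scores = np.asarray(scores, dtype=float)
    if np.any(np.isnan(scores)):
        raise ValueError("scores must not contain NaN")
    return rankdata(-scores, method="ordinal").astype(int)


def moderate_rank_triple(triple) -> tuple[tuple[int, int, int], tuple[bool, bool, bool]]:
    """Apply the outlier-moderation rule to one rank triple.

    Returns the (possibly modified) triple and per-entry flags marking the
    moderated entry.  Idempotent; never increases any entry.
    """
    r = [int(v) for v in triple]
    if len(r) != 3 or any(v < 1 for v in r):
        raise ValueError("expected a triple of positive integer ranks")
    flags = [False, False, False]
    i = int(np.argmax(r))
    rest = sum(r) - r[i]
    if r[i] > 2 * rest:
        r[i] = 2 * rest
        flags[i] = True
    return tuple(r), tuple(flags)


@dataclass
class RankTable:
    """Per-filter integer ranks (columns: chi2, f_stat, mi), 1 = best."""

    feature_names: list[str]
    ranks: np.ndarray  # (m, 3) ints

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        m = len(self.feature_names)
        if self.ranks.shape != (m, 3):
            raise ValueError("ranks must be an (m, 3) array aligned with features")
        if np.any(self.ranks < 1):
            raise ValueError("ranks must be positive integers")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ranks, columns=[f"{c}_rank" for c in FILTER_COLUMNS])
        df.insert(0, "feature", self.feature_names)
        return df

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "RankTable":
        df = pd.read_csv(path, sep="\t")
        cols = [f"{c}_rank" for c in FILTER_COLUMNS]
        return cls(
            feature_names=df["feature"].astype(str).tolist(),
            ranks=df[cols].to_numpy(),
        )


@dataclass
class OverallRankTable:
    """Moderated ranks, their row sums (OR), sorted ascending by OR."""

    feature_names: list[str]
    moderated_ranks: np.ndarray  # (m, 3) ints, post-moderation
    or_values: np.ndarray  # (m,) ints, row sums
    moderated_flags: np.ndarray  # (m, 3) bools

    def __post_init__(self) -> None:
        self.moderated_ranks = np.asarray(self.moderated_ranks, dtype=int)
        self.or_values = np.asarray(self.or_values, dtype=int)
        self.moderated_flags = np.asarray(self.moderated_flags, dtype=bool)
        m = len(self.feature_names)
        if self.moderated_ranks.shape != (m, 3):
            raise ValueError("moderated_ranks must be (m, 3)")
        if self.or_values.shape != (m,):
            raise ValueError("or_values must have one entry per feature")
        if not np.array_equal(self.or_values, self.moderated_ranks.sum(axis=1)):
            raise ValueError("or_values must equal row sums of moderated ranks")
        if np.any(np.diff(self.or_values) < 0):
            raise ValueError("rows must be sorted ascending by OR")

    def or_of(self, feature: str) -> int:
        """Overall rank of a named feature."""
        try:
            return int(self.or_values[self.feature_names.index(feature)])
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.moderated_ranks, columns=[f"{c}_rank" for c in FILTER_COLUMNS]
        )
        df.insert(0, "feature", self.feature_names)
        df["or"] = self.or_values
        for i, c in enumerate(FILTER_COLUMNS):
            df[f"{c}_moderated"] = self.moderated_flags[:, i]
        return df

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "OverallRankTable":
        df = pd.read_csv(path, sep="\t")
        rank_cols = [f"{c}_rank" for c in FILTER_COLUMNS]
        flag_cols = [f"{c}_moderated" for c in FILTER_COLUMNS]
        return cls(
            feature_names=df["feature"].astype(str).tolist(),
            moderated_ranks=df[rank_cols].to_numpy(),
            or_values=df["or"].to_numpy(),
            moderated_flags=df[flag_cols].to_numpy(dtype=bool),
        )


def build_rt(fst: FeatureScoreTable) -> RankTable:
    """Convert the score table into per-filter ranks."""
    ranks = np.column_stack(
        [
            ranks_from_scores(fst.chi2),
            ranks_from_scores(fst.f_stat),
            ranks_from_scores(fst.mi),
        ]
    )
    return RankTable(feature_names=list(fst.feature_names), ranks=ranks)


def build_ort(rt: RankTable) -> OverallRankTable:
    """Moderate every rank triple, sum into OR, sort ascending by OR.

    The sort is stable: equal-OR features keep their original order.
    """
    m = len(rt.feature_names)
    moderated = np.empty((m, 3), dtype=int)
    flags = np.empty((m, 3), dtype=bool)
    for i in range(m):
        moderated[i], flags[i] = moderate_rank_triple(rt.ranks[i])
    or_values = moderated.sum(axis=1)
    order = np.argsort(or_values, kind="stable")
    return OverallRankTable(
        feature_names=[rt.feature_names[i] for i in order],
        moderated_ranks=moderated[order],
        or_values=or_values[order],
        moderated_flags=flags[order],
    )
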