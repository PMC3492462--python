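"""Summed mean-normalized expression score of the 8-gene radiation panel.

Each panel gene's linear-scale intensity column is divided by its mean over
all samples (so every normalized column has mean exactly 1), the normalized
values are summed per sample, and sums are expressed relative to the mean
sum of a reference group (sham dose, or healthy donors).  The score is
scale-invariant per gene, so globally normalized microarray intensities
from different platforms are comparable after this step.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .design import PANEL_8
from .stats import safe_ttest

__all__ = [
    "PanelScorer",
    "mean_normalize",
    "sum_score",
    "normalize_to_reference_group",
    "group_summary",
    "separation_check",
]


class PanelScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer computing the summed mean-normalized score.

    Parameters
    ----------
    genes : sequence of str, optional
        Panel genes to score (defaults to the 8-gene radiation panel).
    log2_input : bool
        Set when the matrix stores log2 intensities; columns are
        exponentiated back to the linear scale first.  The choice is
        explicit, never guessed from the data.

    Attributes
    ----------
    gene_means_ : pandas.Series
        Per-gene grand means learned in ``fit`` (the normalizers).
    """

    def __init__(self, genes: Sequence[str] | None = None, log2_input: bool = False):
        self.genes = genes
        self.log2_input = log2_input

    def _prepare(self, X: pd.DataFrame) -> pd.DataFrame:
        genes = list(self.genes) if self.genes is not None else list(PANEL_8)
        missing = [g for g in genes if g not in X.columns]
        if missing:
            raise ValueError(f"matrix lacks panel genes: {missing}")
        sub = X[genes].astype(float)
        if self.log2_input:
            sub = np.power(2.0, sub)
        if not np.isfinite(sub.to_numpy()).all() or (sub.to_numpy() <= 0).any():
            raise ValueError("intensities must be positive and finite")
        return sub

    def fit(self, X: pd.DataFrame, y=None):
        sub = self._prepare(X)
        means = sub.mean(axis=0)
        if (means <= 0).any():
            raise ValueError("non-positive gene mean")
        self.gene_means_ = means
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Mean-normalized matrix (each gene divided by its fitted mean)."""
        return self._prepare(X) / self.gene_means_

    def score_samples(self, X: pd.DataFrame) -> pd.Series:
        """Per-sample raw sum of mean-normalized panel-gene values."""
        return self.transform(X).sum(axis=1).rename("raw_sum")


def mean_normalize(matrix: pd.DataFrame, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Divide each selected gene column (default: all) by its mean over samples."""
    cols = list(genes) if genes is not None else list(matrix.columns)
    return PanelScorer(genes=cols).fit(matrix).transform(matrix)


def sum_score(normalized: pd.DataFrame, genes: Sequence[str] | None = None) -> pd.Series:
    """Per-sample sum over the (already mean-normalized) gene subset."""
    cols = list(genes) if genes is not None else list(normalized.columns)
    return normalized[cols].sum(axis=1).rename("raw_sum")


def normalize_to_reference_group(scores: pd.Series, reference_ids) -> pd.Series:
    """Divide every score by the mean score of the reference samples."""
    ref = scores.loc[list(reference_ids)]
    if len(ref) == 0:
        raise ValueError("reference group is empty")
    return (scores / ref.mean()).rename("relative_score")


def group_summary(
    scores: pd.Series, groups: pd.Series | pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean ± standard error, plus pairwise two-sample t-tests.

    ``groups`` is a per-sample label (Series) or several keys (DataFrame,
    combined into tuples).  Returns ``(summary, pairwise)``; groups with
    fewer than 2 samples are flagged and skipped in the pairwise table.
    """
    if isinstance(groups, pd.DataFrame):
        labels = groups.apply(tuple, axis=1)
    else:
        labels = groups
    df = pd.DataFrame({"score": scores, "group": labels.loc[scores.index]})
    summary = (
        df.groupby("group", sort=False)["score"]
        .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    summary["se"] = summary["sd"] / np.sqrt(summary["n"])
    summary["degenerate"] = summary["n"] < 2

    rows = []
    keys = list(summary["group"])
    by_group = {k: df.loc[df["group"] == k, "score"].to_numpy() for k in keys}
    for i, ga in enumerate(keys):
        for gb in keys[i + 1:]:
            if len(by_group[ga]) < 2 or len(by_group[gb]) < 2:
                continue
            t, p = safe_ttest(by_group[ga], by_group[gb])
            rows.append((ga, gb, t, p))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "t_stat", "p_value"])
    return summary, pairwise


def separation_check(scores_a, scores_b) -> tuple[bool, float]:
    """Whether two score groups' ranges are disjoint, and the gap size.

    The margin is ``max(min_a - max_b, min_b - max_a)``: positive iff one
    group lies entirely above the other, negative by the overlap otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    margin = float(max(a.min() - b.max(), b.min() - a.max()))
    return margin > 0, margin
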