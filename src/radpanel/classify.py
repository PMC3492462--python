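"""Four-class marker screening: Gini ranking, 5NN, and diagnostic metrics.

The screening procedure orders the nine markers (eight transcripts plus the
pCHK2-thr68 protein) by their ability to discriminate pairs of the four
treatment classes, then evaluates a k-nearest-neighbour classifier (k = 5,
odd to prevent vote ties) under repeated stratified 10-fold
cross-validation on nested marker subsets.

Marker ranking uses the Gini impurity ``G = 1 − Σ p_k²`` of a single-split
decision stump: for one continuous marker restricted to a class pair, every
midpoint between consecutive sorted unique values is a candidate threshold
and the marker's score is the minimum size-weighted mean impurity of the
two child nodes.  Markers are then selected across the class-pair list in
rank rounds — the rank-1 marker of each pair in pair order, then rank-2,
and so on — taking each marker at its first appearance.

Diagnostic screening collapses the pooled 4x4 confusion matrix into one
2x2 table per class, yielding sensitivity, specificity, and the positive
and negative predictive values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .design import CLASS_INDEX, CLASS_ORDER, DEFAULT_PAIR_ORDER

__all__ = [
    "ClassifierConfig",
    "GiniScore",
    "MarkerOrder",
    "ScreeningReport",
    "CVResult",
    "gini_node",
    "pairwise_gini",
    "GiniMarkerRanker",
    "order_markers",
    "TieBreakKNN",
    "knn_predict",
    "cross_validate",
    "accuracy_curve",
    "diagnostic_screening",
]


# --------------------------------------------------------------------------
# result / config types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    """Settings of the cross-validated KNN screening stage."""

    k_neighbors: int = 5
    n_folds: int = 10
    n_repeats: int = 10
    stratified: bool = True
    scale: bool = True
    donor_grouped: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors % 2 == 0 or self.k_neighbors < 1:
            raise ValueError("k_neighbors must be odd and positive")
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("need n_folds >= 2 and n_repeats >= 1")


@dataclass(frozen=True)
class GiniScore:
    marker: str
    class_pair: tuple[str, str]
    impurity: float
    split_threshold: float


@dataclass(frozen=True)
class MarkerOrder:
    """A permutation of all markers with first-appearance provenance."""

    order: tuple[str, ...]
    provenance: dict[str, tuple[tuple[str, str], int]]


@dataclass
class CVResult:
    accuracy: float
    per_repeat_accuracy: np.ndarray
    confusion: pd.DataFrame  # true x predicted, pooled over repeats


@dataclass
class ScreeningReport:
    confusion: pd.DataFrame
    metrics: pd.DataFrame  # per class: sensitivity, specificity, ppv, npv
    overall_accuracy: float
    accuracy_curve: pd.DataFrame | None = None
    marker_order: MarkerOrder | None = None


# --------------------------------------------------------------------------
# Gini impurity and marker ordering
# --------------------------------------------------------------------------

def gini_node(class_counts) -> float:
    """Gini impurity ``1 − Σ p_k²`` of a node with the given class counts."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("empty node")
    p = counts / total
    return float(1.0 - np.sum(p ** 2))


def pairwise_gini(values, labels) -> GiniScore:
    """Best single-split (decision-stump) Gini impurity of one marker.

    ``labels`` must contain exactly the two classes of the pair.  Candidate
    thresholds are the midpoints of consecutive sorted unique values; the
    impurity is the minimum size-weighted mean of the child-node Gini
    impurities, with the smallest optimal threshold returned on ties.  A
    marker with a single distinct value scores the unsplit node's Gini.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    classes = pd.unique(y)
    if len(classes) != 2:
        raise ValueError("pairwise_gini needs exactly two classes present")
    pair = tuple(sorted(
        classes, key=lambda c: (CLASS_INDEX.get(c, len(CLASS_ORDER)), str(c))
    ))
    uniq = np.unique(v)
    if len(uniq) == 1:
        counts = [(y == c).sum() for c in classes]
        return GiniScore("", pair, gini_node(counts), float(uniq[0]))
    n = len(v)
    best_g, best_t = np.inf, np.nan
    thresholds = (uniq[:-1] + uniq[1:]) / 2.0
    for t in thresholds:
        left = v <= t
        gl = gini_node([(y[left] == c).sum() for c in classes])
        gr = gini_node([(y[~left] == c).sum() for c in classes])
        g = (left.sum() * gl + (~left).sum() * gr) / n
        if g < best_g - 1e-15:  # strict improvement keeps the smallest tie
            best_g, best_t = g, float(t)
    return GiniScore("", pair, float(best_g), best_t)


class GiniMarkerRanker(BaseEstimator, TransformerMixin):
    """Orders markers by first appearance across pairwise Gini rankings.

    ``fit`` computes, for every class pair in ``pair_order``, the stump
    Gini of every marker; markers are ranked ascending by impurity (ties
    broken by marker name) per pair, then selected rank-round by
    rank-round through the pair list, skipping markers already taken.

    Attributes
    ----------
    order_ : tuple of str
        All markers, best-first.
    provenance_ : dict
        marker -> (class_pair, rank) at which it was first selected.
    scores_ : pandas.DataFrame
        Full marker x pair impurity table.
    """

    def __init__(self, pair_order: tuple[tuple[str, str], ...] = DEFAULT_PAIR_ORDER):
        self.pair_order = pair_order

    def fit(self, X: pd.DataFrame, y):
        y = pd.Series(np.asarray(y), index=X.index)
        markers = list(X.columns)
        impurity = {}
        for pair in self.pair_order:
            mask = y.isin(pair).to_numpy()
            if len(pd.unique(y[mask])) < 2:
                raise ValueError(f"class pair {pair} not both represented")
            for m in markers:
                score = pairwise_gini(X.loc[mask, m].to_numpy(), y[mask].to_numpy())
                impurity[(m, pair)] = score.impurity

        rankings = {
            pair: sorted(markers, key=lambda m: (impurity[(m, pair)], m))
            for pair in self.pair_order
        }
        order: list[str] = []
        provenance: dict[str, tuple[tuple[str, str], int]] = {}
        for rank in range(len(markers)):
            for pair in self.pair_order:
                m = rankings[pair][rank]
                if m not in provenance:
                    provenance[m] = (pair, rank + 1)
                    order.append(m)
            if len(order) == len(markers):
                break
        self.order_ = tuple(order)
        self.provenance_ = provenance
        self.scores_ = pd.DataFrame(
            {str(pair): [impurity[(m, pair)] for m in markers]
             for pair in self.pair_order},
            index=markers,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Reorder marker columns best-first."""
        return X[list(self.order_)]


def order_markers(
    X: pd.DataFrame, y, pair_order=DEFAULT_PAIR_ORDER
) -> MarkerOrder:
    """Functional wrapper over :class:`GiniMarkerRanker`."""
    ranker = GiniMarkerRanker(pair_order=pair_order).fit(X, y)
    return MarkerOrder(order=ranker.order_, provenance=ranker.provenance_)


# --------------------------------------------------------------------------
# KNN with the documented tie-break contract
# --------------------------------------------------------------------------

class TieBreakKNN(BaseEstimator, ClassifierMixin):
    """K-nearest-neighbour vote with fully deterministic tie-breaking.

    Features are z-scored per marker with training statistics (transcript
    relative expressions and protein absorbances live on incommensurate
    scales); distances are Euclidean.  Neighbour candidates are ordered by
    (distance, training index); vote ties between classes are broken by
    the smallest mean distance among each tied class's neighbours, then by
    the canonical class order.
    """

    def __init__(self, k: int = 5, scale: bool = True,
                 class_order: tuple[str, ...] = CLASS_ORDER):
        self.k = k
        self.scale = scale
        self.class_order = class_order

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        if self.k > len(X):
            raise ValueError("k exceeds training-set size")
        self.mean_ = X.mean(axis=0) if self.scale else np.zeros(X.shape[1])
        sd = X.std(axis=0, ddof=0) if self.scale else np.ones(X.shape[1])
        self.sd_ = np.where(sd == 0, 1.0, sd)
        self.X_ = (X - self.mean_) / self.sd_
        self.y_ = y
        seen = list(dict.fromkeys(y))
        ordered = [c for c in self.class_order if c in seen]
        self.classes_ = np.asarray(ordered + [c for c in seen if c not in ordered])
        return self

    def _class_rank(self, label) -> int:
        return int(np.flatnonzero(self.classes_ == label)[0])

    def predict(self, X):
        X = (np.asarray(X, dtype=float) - self.mean_) / self.sd_
        out = []
        for x in X:
            d = np.sqrt(((self.X_ - x) ** 2).sum(axis=1))
            # lexicographic (distance, training index): stable sort on index
            nn = np.lexsort((np.arange(len(d)), d))[: self.k]
            labels = self.y_[nn]
            dists = d[nn]
            counts: dict = {}
            for lab in labels:
                counts[lab] = counts.get(lab, 0) + 1
            top = max(counts.values())
            tied = [c for c, n in counts.items() if n == top]
            if len(tied) > 1:
                mean_d = {c: dists[labels == c].mean() for c in tied}
                best = min(mean_d.values())
                tied = [c for c in tied if mean_d[c] == best]
                tied.sort(key=self._class_rank)
            out.append(tied[0])
        return np.asarray(out)


def knn_predict(train_values, train_labels, test_values, k: int = 5,
                scale: bool = True) -> np.ndarray:
    """Functional wrapper over :class:`TieBreakKNN`."""
    model = TieBreakKNN(k=k, scale=scale).fit(train_values, train_labels)
    return model.predict(test_values)


# --------------------------------------------------------------------------
# cross-validation, accuracy curve, screening
# --------------------------------------------------------------------------

def _fold_iter(X, y, groups, config: ClassifierConfig, repeat_seed: int):
    if config.donor_grouped:
        if groups is None:
            raise ValueError("donor_grouped CV needs group ids")
        cv = GroupKFold(n_splits=config.n_folds)
        return cv.split(X, y, groups)
    if config.stratified:
        cv = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=repeat_seed
        )
        return cv.split(X, y)
    rng = np.random.default_rng(repeat_seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, config.n_folds)
    return (
        (np.setdiff1d(idx, f), f) for f in folds
    )


def cross_validate(
    X: pd.DataFrame,
    y,
    marker_subset=None,
    config: ClassifierConfig = ClassifierConfig(),
    groups=None,
) -> CVResult:
    """Repeated (stratified) k-fold CV of the tie-break KNN.

    Every observation is predicted exactly once per repeat; accuracy is the
    mean over repeats of correct/total, and confusion counts are pooled
    over repeats (total = repeats x observations).
    """
    markers = list(marker_subset) if marker_subset is not None else list(X.columns)
    if not markers:
        raise ValueError("marker subset is empty")
    Xv = X[markers].to_numpy(dtype=float)
    yv = np.asarray(y)
    class_list = [c for c in CLASS_ORDER if c in set(yv)] or sorted(set(yv))
    repeat_seeds = np.random.default_rng(config.seed).integers(
        0, 2 ** 31 - 1, size=config.n_repeats
    )
    conf = pd.DataFrame(0, index=class_list, columns=class_list, dtype=int)
    accs = np.empty(config.n_repeats)
    for r, rs in enumerate(repeat_seeds):
        pred = np.empty(len(yv), dtype=object)
        for train_idx, test_idx in _fold_iter(Xv, yv, groups, config, int(rs)):
            model = TieBreakKNN(k=config.k_neighbors, scale=config.scale)
            model.fit(Xv[train_idx], yv[train_idx])
            pred[test_idx] = model.predict(Xv[test_idx])
        accs[r] = float(np.mean(pred == yv))
        for t, p in zip(yv, pred):
            conf.loc[t, p] += 1
    return CVResult(
        accuracy=float(accs.mean()), per_repeat_accuracy=accs, confusion=conf
    )


def accuracy_curve(
    X: pd.DataFrame,
    y,
    marker_order,
    config: ClassifierConfig = ClassifierConfig(),
    groups=None,
) -> pd.DataFrame:
    """CV accuracy of the nested subsets {m1}, {m1,m2}, ... of the order."""
    order = list(marker_order.order if isinstance(marker_order, MarkerOrder)
                 else marker_order)
    rows = []
    for m in range(1, len(order) + 1):
        res = cross_validate(X, y, order[:m], config, groups)
        rows.append((m, order[m - 1], res.accuracy))
    curve = pd.DataFrame(rows, columns=["n_markers", "added_marker", "accuracy"])
    curve.attrs["best_size"] = int(curve.loc[curve["accuracy"].idxmax(), "n_markers"])
    return curve


def diagnostic_screening(confusion: pd.DataFrame) -> ScreeningReport:
    """Per-class sensitivity, specificity, PV+ and PV− from pooled counts.

    For class c with confusion matrix M (rows true, columns predicted):
    sensitivity = M[c,c]/row_c; specificity = correctly rejected /
    (total − row_c); PV+ = M[c,c]/col_c; PV− = (total − row_c − col_c +
    M[c,c]) / (total − col_c).  Zero rows or columns leave the affected
    metrics NaN with a flag.
    """
    M = confusion.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = M.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    rows = []
    for i, c in enumerate(confusion.index):
        row, col, tp = M[i].sum(), M[:, i].sum(), M[i, i]
        tn = total - row - col + tp
        sens = tp / row if row else np.nan
        spec = tn / (total - row) if total - row else np.nan
        ppv = tp / col if col else np.nan
        npv = tn / (total - col) if total - col else np.nan
        flag = "degenerate" if (row == 0 or col == 0) else ""
        rows.append((c, sens, spec, ppv, npv, flag))
    metrics = pd.DataFrame(
        rows, columns=["class", "sensitivity", "specificity", "ppv", "npv", "flag"]
    ).set_index("class")
    return ScreeningReport(
        confusion=confusion,
        metrics=metrics,
        overall_accuracy=float(np.trace(M) / total),
    )
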