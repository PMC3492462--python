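"""Comparative-Ct (delta-delta-Ct) quantification and panel selection.

Raw qPCR Ct tables are collapsed over technical replicates, normalized to an
endogenous control gene (ΔCt = Ct_target − Ct_reference, relative expression
2^−ΔCt), and fold changes between treatment groups are computed per matched
donor-draw pair as 2^−ΔΔCt.  A reference-gene stability filter excludes
donor-draw pairs whose control-gene Ct differs by 0.3 cycles or more between
the two compared conditions.  Panel selection keeps genes that are both
significantly and substantially modulated, and flags those whose group
relative-expression ranges are disjoint (usable without a pre-exposure
baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stats import safe_ttest

__all__ = [
    "FoldChangeResult",
    "PanelSelection",
    "collapse_replicates",
    "delta_ct",
    "reference_stability_filter",
    "fold_change_ddct",
    "select_panel",
    "relative_expression_wide",
]

_KEY = ["gene", "donor", "draw", "treatment"]


@dataclass
class FoldChangeResult:
    """Fold change of one gene between two treatment groups.

    ``per_pair_folds`` holds 2^−ΔΔCt for each included donor-draw pair;
    ``mean_fold`` is their arithmetic mean (``geometric_fold`` the geometric
    mean).  The t-test compares the relative-expression (2^−ΔCt)
    distributions of the two groups.  ``nonoverlap`` is true iff the two
    groups' relative-expression ranges are disjoint.
    """

    gene: str
    comparison: tuple[str, str]
    per_pair_folds: np.ndarray
    mean_fold: float
    geometric_fold: float
    fold_sd: float
    t_stat: float
    p_value: float
    nonoverlap: bool
    n_pairs: int
    flags: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return "insufficient_pairs" not in self.flags


@dataclass
class PanelSelection:
    """Genes passing significance+magnitude, and the disjoint-range subset."""

    responsive_genes: list[str]
    nonoverlap_genes: list[str]

    def __post_init__(self) -> None:
        extra = set(self.nonoverlap_genes) - set(self.responsive_genes)
        if extra:
            raise ValueError(f"nonoverlap genes not responsive: {sorted(extra)}")


def collapse_replicates(ds: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates on the Ct scale.

    Returns one row per (gene, donor, draw, treatment) with ``ct`` the
    arithmetic mean, plus ``ct_sd`` and ``n_replicates`` for QC.
    """
    required = set(_KEY + ["replicate", "ct"])
    missing = required - set(ds.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if ds["ct"].isna().any() or not np.isfinite(ds["ct"]).all():
        raise ValueError("non-finite Ct values in input")
    out = (
        ds.groupby(_KEY, sort=False)["ct"]
        .agg(ct="mean", ct_sd="std", n_replicates="size")
        .reset_index()
    )
    return out


def delta_ct(
    mean_ct: pd.DataFrame,
    reference_gene: str = "ACTB",
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """ΔCt normalization of every target gene to the reference gene.

    Returns rows (gene, donor, draw, treatment, delta_ct, rel_expr,
    included, reason).  Samples lacking a reference-gene measurement are
    flagged ``included=False`` with reason ``missing_reference`` rather than
    silently dropped.
    """
    ref = mean_ct.loc[mean_ct["gene"] == reference_gene, _KEY[1:] + ["ct"]]
    ref = ref.rename(columns={"ct": "ref_ct"})
    targets = mean_ct[mean_ct["gene"] != reference_gene]
    if genes is not None:
        targets = targets[targets["gene"].isin(genes)]
    merged = targets.merge(ref, on=_KEY[1:], how="left")
    merged["delta_ct"] = merged["ct"] - merged["ref_ct"]
    merged["rel_expr"] = np.power(2.0, -merged["delta_ct"])
    merged["included"] = merged["ref_ct"].notna()
    merged["reason"] = np.where(merged["included"], "", "missing_reference")
    return merged[_KEY + ["delta_ct", "rel_expr", "included", "reason"]]


def reference_stability_filter(
    mean_ct: pd.DataFrame,
    reference_gene: str,
    group_a: str,
    group_b: str,
    threshold: float = 0.3,
) -> pd.DataFrame:
    """Per donor-draw inclusion flags for one pairwise comparison.

    A donor-draw pair is kept iff |Ct_ref(group_a) − Ct_ref(group_b)| is
    strictly below ``threshold`` cycles (0.3 by default; equality excludes).
    """
    ref = mean_ct[mean_ct["gene"] == reference_gene]
    wide = ref.pivot_table(
        index=["donor", "draw"], columns="treatment", values="ct"
    )
    for g in (group_a, group_b):
        if g not in wide.columns:
            raise ValueError(f"no reference measurements for group {g!r}")
    out = wide[[group_a, group_b]].copy()
    out["ref_delta_ct"] = (out[group_a] - out[group_b]).abs()
    out["included"] = out["ref_delta_ct"] < threshold
    return out.reset_index()[["donor", "draw", "ref_delta_ct", "included"]]


def fold_change_ddct(
    rel_table: pd.DataFrame,
    gene: str,
    group_treated: str,
    group_control: str,
    stability: pd.DataFrame | None = None,
    geometric: bool = False,
    equal_var: bool = True,
    min_pairs: int = 2,
) -> FoldChangeResult:
    """ΔΔCt fold change of ``gene`` between two groups.

    Per-pair folds are 2^−(ΔCt_treated − ΔCt_control) matched within each
    donor-draw; ``stability`` (from :func:`reference_stability_filter`)
    restricts the pairs.  The two-sided t-test runs on the two groups'
    relative-expression values.
    """
    sub = rel_table[(rel_table["gene"] == gene) & rel_table["included"]]
    wide_dct = sub.pivot_table(
        index=["donor", "draw"], columns="treatment", values="delta_ct"
    )
    for g in (group_treated, group_control):
        if g not in wide_dct.columns:
            raise ValueError(f"gene {gene!r}: no data for group {g!r}")
    wide_dct = wide_dct[[group_treated, group_control]].dropna()
    if stability is not None:
        keep = stability.loc[stability["included"], ["donor", "draw"]]
        wide_dct = wide_dct.reset_index().merge(
            keep, on=["donor", "draw"]
        ).set_index(["donor", "draw"])

    flags: list[str] = []
    ddct = wide_dct[group_treated] - wide_dct[group_control]
    folds = np.power(2.0, -ddct.to_numpy())
    if len(folds) < min_pairs:
        flags.append("insufficient_pairs")

    rel_t = np.power(2.0, -wide_dct[group_treated].to_numpy())
    rel_c = np.power(2.0, -wide_dct[group_control].to_numpy())
    if len(folds) >= min_pairs:
        t, p = safe_ttest(rel_t, rel_c, equal_var=equal_var)
    else:
        t, p = np.nan, np.nan
    nonoverlap = bool(
        len(rel_t) and len(rel_c)
        and (rel_t.min() > rel_c.max() or rel_c.min() > rel_t.max())
    )
    mean_fold = float(folds.mean()) if len(folds) else np.nan
    geo_fold = float(np.exp(np.mean(np.log(folds)))) if len(folds) else np.nan
    return FoldChangeResult(
        gene=gene,
        comparison=(group_treated, group_control),
        per_pair_folds=folds,
        mean_fold=geo_fold if geometric else mean_fold,
        geometric_fold=geo_fold,
        fold_sd=float(folds.std(ddof=1)) if len(folds) > 1 else np.nan,
        t_stat=t,
        p_value=p,
        nonoverlap=nonoverlap,
        n_pairs=int(len(folds)),
        flags=flags,
    )


def select_panel(
    fold_results: list[FoldChangeResult],
    p_threshold: float = 0.05,
    fold_threshold: float = 2.0,
    fdr: bool = False,
) -> PanelSelection:
    """Keep genes with p < ``p_threshold`` and |fold| beyond ``fold_threshold``.

    A gene is responsive if significant and its mean fold is at least
    ``fold_threshold`` up or down (≤ 1/threshold).  The non-overlap subset
    additionally requires disjoint group ranges.  Raw per-gene p-values are
    thresholded by default; ``fdr=True`` applies Benjamini–Hochberg
    adjustment across the candidate genes first.
    """
    usable = [r for r in fold_results if r.valid and np.isfinite(r.p_value)]
    pvals = np.array([r.p_value for r in usable])
    if fdr and len(pvals):
        pvals = stats.false_discovery_control(pvals)
    responsive, nonoverlap = [], []
    for r, p in zip(usable, pvals):
        magnitude = r.mean_fold >= fold_threshold or r.mean_fold <= 1.0 / fold_threshold
        if p < p_threshold and magnitude:
            responsive.append(r.gene)
            if r.nonoverlap:
                nonoverlap.append(r.gene)
    return PanelSelection(responsive_genes=responsive, nonoverlap_genes=nonoverlap)


def relative_expression_wide(rel_table: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Observations x genes matrix of 2^−ΔCt, indexed by (donor, draw, treatment)."""
    sub = rel_table[rel_table["gene"].isin(genes) & rel_table["included"]]
    wide = sub.pivot_table(
        index=["donor", "draw", "treatment"], columns="gene", values="rel_expr"
    )
    return wide[genes]
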