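"""Differential-enrichment screen over a metabolite abundance matrix.

Per-metabolite one-way fixed-effects ANOVA across sample groups (on
log2-transformed abundances by default — abundances are positive and
right-skewed), Benjamini-Hochberg adjustment across metabolites, Tukey
HSD post hoc pairwise comparisons, reference-group log-fold-change
normalization, and a deterministic hierarchical-clustering row order
for the top-k heatmap export.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "MetaboliteMatrix",
    "anova_per_metabolite",
    "posthoc_pairwise",
    "reference_normalize",
    "top_k_cluster_order",
]


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites abundance matrix with per-sample group labels.

    Invariants: at least two groups with at least two samples each
    (within-group variance is required for ANOVA); strictly positive
    abundances; metabolites containing missing values are dropped with
    a logged count (imputation is out of scope).
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.index)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        counts = self.groups.value_counts()
        if len(counts) < 2:
            raise ValueError("need at least 2 groups")
        small = counts[counts < 2]
        if not small.empty:
            raise ValueError(
                f"groups with < 2 samples (ANOVA needs within-group "
                f"variance): {sorted(small.index)}"
            )
        n_missing = int(self.values.isna().any(axis=0).sum())
        if n_missing:
            logger.warning(
                "dropping %d metabolite(s) with missing values", n_missing)
            self.values = self.values.dropna(axis=1)
        if (self.values.values <= 0).any():
            raise ValueError("abundances must be strictly positive")

    @property
    def group_labels(self) -> list[str]:
        return list(dict.fromkeys(self.groups))

    def group_arrays(self, log_transform: bool = True) -> list[np.ndarray]:
        """Per-group (n_samples_in_group x n_metabolites) value blocks."""
        vals = np.log2(self.values.values) if log_transform else self.values.values
        return [vals[(self.groups == g).values] for g in self.group_labels]


def anova_per_metabolite(matrix: MetaboliteMatrix,
                         log_transform: bool = True,
                         multiple_testing: str = "bh") -> pd.DataFrame:
    """One-way fixed-effects ANOVA per metabolite across groups.

    Returns a DataFrame (metabolite, F, p, padj, degenerate) sorted by
    p.  Metabolites with zero within-group variance everywhere are
    flagged degenerate (p undefined) and excluded from the BH family.
    """
    blocks = matrix.group_arrays(log_transform)
    # within-group sum of squares, vectorized over metabolites
    ssw = sum(((b - b.mean(axis=0)) ** 2).sum(axis=0) for b in blocks)
    degenerate = ssw == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, p = stats.f_oneway(*blocks, axis=0)
    f_stat = np.asarray(f_stat, dtype=float)
    p = np.asarray(p, dtype=float)
    f_stat[degenerate] = np.nan
    p[degenerate] = np.nan
    padj = np.full_like(p, np.nan)
    ok = ~degenerate & np.isfinite(p)
    if multiple_testing == "bh" and ok.any():
        padj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    elif multiple_testing == "none":
        padj[ok] = p[ok]
    if degenerate.any():
        logger.warning(
            "%d metabolite(s) degenerate (zero within-group variance), "
            "excluded from multiple-testing family", int(degenerate.sum()))
    out = pd.DataFrame({
        "metabolite": matrix.values.columns,
        "F": f_stat,
        "p": p,
        "padj": padj,
        "degenerate": degenerate,
    })
    return out.sort_values(["p", "metabolite"], kind="mergesort",
                           na_position="last").reset_index(drop=True)


def posthoc_pairwise(matrix: MetaboliteMatrix, metabolite: str,
                     method: str = "tukey",
                     log_transform: bool = True) -> pd.DataFrame:
    """All pairwise group comparisons for one metabolite.

    Default is Tukey's HSD (studentized-range family-wise adjustment),
    the standard all-pairs companion to one-way ANOVA; "t_bh" switches
    to pairwise Welch t-tests with BH adjustment.
    """
    if metabolite not in matrix.values.columns:
        raise KeyError(f"unknown metabolite {metabolite!r}")
    labels = matrix.group_labels
    if len(labels) < 2:
        raise ValueError("post hoc testing needs at least 2 groups")
    col = matrix.values[metabolite].astype(float)
    vals = np.log2(col) if log_transform else col
    samples = [vals[(matrix.groups == g).values].to_numpy() for g in labels]
    pairs = list(itertools.combinations(range(len(labels)), 2))
    if method == "tukey":
        res = stats.tukey_hsd(*samples)
        padj = [float(res.pvalue[i, j]) for i, j in pairs]
    elif method == "t_bh":
        raw = [stats.ttest_ind(samples[i], samples[j]).pvalue for i, j in pairs]
        padj = multipletests(raw, method="fdr_bh")[1].tolist()
    else:
        raise ValueError(f"unknown post hoc method {method!r}")
    return pd.DataFrame({
        "group1": [labels[i] for i, _ in pairs],
        "group2": [labels[j] for _, j in pairs],
        "p_adj": padj,
    })


def reference_normalize(matrix: MetaboliteMatrix,
                        reference_group: str) -> pd.DataFrame:
    """Log2 fold change of every value relative to the reference group.

    Each value becomes log2(value / geometric mean of the reference
    group for that metabolite); reference-group rows average to zero
    per metabolite by construction.
    """
    if reference_group not in set(matrix.groups):
        raise ValueError(f"reference group {reference_group!r} not present")
    log2 = np.log2(matrix.values)
    ref_mean = log2[(matrix.groups == reference_group).values].mean(axis=0)
    return log2 - ref_mean


def top_k_cluster_order(normalized: pd.DataFrame, anova: pd.DataFrame,
                        k: int) -> list[str]:
    """Leaf order of the top-k smallest-p metabolites after clustering.

    Selects the k smallest ANOVA p-values (ties broken by metabolite
    name), hierarchically clusters the normalized rows (Euclidean
    distance, average linkage) and returns the dendrogram leaf order —
    deterministic for fixed input.
    """
    if k == 0:
        logger.warning("top_k_cluster_order called with k = 0")
        return []
    usable = anova.loc[~anova["degenerate"] & anova["p"].notna()]
    if k > len(usable):
        raise ValueError(
            f"k = {k} exceeds the {len(usable)} non-degenerate metabolites")
    top = (usable.sort_values(["p", "metabolite"], kind="mergesort")
           .head(k)["metabolite"].tolist())
    if k == 1:
        return top
    rows = normalized[top].T.values  # metabolites x samples
    link = hierarchy.linkage(rows, method="average", metric="euclidean")
    order = hierarchy.leaves_list(link)
    return [top[i] for i in order]
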