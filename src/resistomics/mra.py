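"""Master regulator analysis (MRA).

Each transcription factor's regulon (curated target-gene set) is tested
for over-representation among differentially expressed genes, twice:

* a one-sided Fisher's exact test (upper hypergeometric tail at the
  observed regulon/DEG overlap), and
* an empirical permutation null obtained by resampling gene sets of the
  DEG-set size uniformly from the whole assayed genome B times (default
  10,000) and counting how often the resampled overlap reaches the
  observed one.

TFs passing both tests at their alpha (default 0.05 each) are flagged
as key master regulators.  The permutation p uses the add-one estimator
(1 + c) / (B + 1) so finite resampling never reports p = 0.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig

logger = logging.getLogger(__name__)

__all__ = [
    "overlap_counts",
    "fisher_enrichment_p",
    "permutation_null_p",
    "run_mra",
    "venn_partition",
    "deg_set_from_table",
]


def deg_set_from_table(deg_table: pd.DataFrame, padj_cutoff: float,
                       lfc_cutoff: float) -> set[str]:
    """Genes passing padj < padj_cutoff and |log2FC| >= lfc_cutoff."""
    mask = (deg_table["padj"] < padj_cutoff) & (
        deg_table["log2fc"].abs() >= lfc_cutoff
    )
    return set(deg_table.loc[mask, "gene"])


def overlap_counts(targets: Iterable[str], deg_set: set[str],
                   universe: set[str]) -> tuple[int, int, int, int]:
    """2x2 contingency counts partitioning the gene universe.

    Returns (regulon∩DEG, regulon∖DEG, DEG∖regulon, neither); the four
    cells sum to ``len(universe)``.  Regulon targets are intersected
    with the universe first; the DEG set must already lie inside it.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not deg_set <= universe:
        raise ValueError("DEG set must be a subset of the universe")
    t = set(targets) & universe
    a = len(t & deg_set)
    b = len(t) - a
    c = len(deg_set) - a
    d = len(universe) - a - b - c
    return a, b, c, d


def fisher_enrichment_p(counts: tuple[int, int, int, int],
                        alternative: str = "greater") -> float:
    """Exact over-representation p for a 2x2 table.

    With ``alternative="greater"`` this is the upper hypergeometric tail
    P(X >= a) at the observed overlap given the table margins; the
    two-sided variant is available as a configuration switch.
    """
    a, b, c, d = counts
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    if alternative == "greater":
        n_total = a + b + c + d
        k_regulon = a + b
        n_deg = a + c
        return float(stats.hypergeom.sf(a - 1, n_total, k_regulon, n_deg))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(p)


def _membership_draws(n_universe: int, deg_size: int, n_draws: int,
                      rng: np.random.Generator,
                      chunk: int = 256) -> np.ndarray:
    """Boolean (n_draws x n_universe) matrix of uniform DEG-size subsets."""
    member = np.zeros((n_draws, n_universe), dtype=bool)
    rows = np.arange(chunk)
    for start in range(0, n_draws, chunk):
        stop = min(start + chunk, n_draws)
        u = rng.random((stop - start, n_universe))
        idx = np.argpartition(u, deg_size - 1, axis=1)[:, :deg_size]
        member[start:stop][rows[: stop - start, None], idx] = True
    return member


def permutation_null_p(targets: Iterable[str], deg_size: int,
                       universe: Sequence[str], observed_overlap: int,
                       n_permutations: int,
                       rng: np.random.Generator) -> tuple[float, float]:
    """Empirical genome-permutation p for one regulon.

    Draws ``n_permutations`` uniform subsets of size ``deg_size`` from
    the universe (without replacement within each draw), and returns
    ``((1 + #{overlap >= observed}) / (B + 1), mean null overlap)``.
    """
    universe = list(universe)
    n = len(universe)
    if deg_size > n:
        raise ValueError(f"deg_size {deg_size} exceeds universe size {n}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pos = {g: i for i, g in enumerate(universe)}
    t_idx = np.array(sorted(pos[g] for g in set(targets) if g in pos), dtype=int)
    if deg_size == 0:
        overlaps = np.zeros(n_permutations, dtype=int)
    else:
        member = _membership_draws(n, deg_size, n_permutations, rng)
        overlaps = member[:, t_idx].sum(axis=1) if t_idx.size else np.zeros(
            n_permutations, dtype=int)
    c = int((overlaps >= observed_overlap).sum())
    perm_p = (1 + c) / (n_permutations + 1)
    return float(perm_p), float(overlaps.mean())


def run_mra(regulons: Mapping[str, set[str]], deg_table: pd.DataFrame,
            config: AnalysisConfig,
            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Score every regulon against the DEG set; apply dual selection.

    The gene universe is the whole assayed genome, i.e. every gene in
    the DEG table.  One batch of B genome-resampled DEG-size gene sets
    is shared across all TFs, mirroring the resampling scheme (DEG-size
    sets drawn from the whole genome, compared against each TF's
    targets).  Output rows are sorted by Fisher p, then permutation p,
    then TF name; ``selected`` requires both p-values below their alpha.
    Benjamini-Hochberg columns are reported when configured but never
    alter the selection rule.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    universe = list(dict.fromkeys(deg_table["gene"].astype(str)))
    universe_set = set(universe)
    n = len(universe)
    if n == 0:
        raise ValueError("empty gene universe (no genes in DEG table)")
    deg_set = deg_set_from_table(
        deg_table, config.deg_padj_cutoff, config.deg_lfc_cutoff
    ) & universe_set
    deg_size = len(deg_set)
    if deg_size == 0:
        logger.warning("empty DEG set: all Fisher p = 1, nothing selected")

    pos = {g: i for i, g in enumerate(universe)}
    testable: list[tuple[str, np.ndarray]] = []
    for tf, targets in regulons.items():
        idx = np.array(sorted(pos[g] for g in targets if g in pos), dtype=int)
        if idx.size == 0:
            logger.warning("regulon %s has no targets in the universe; skipped", tf)
            continue
        testable.append((tf, idx))
    if not testable:
        raise ValueError("no testable regulon (all empty after universe mapping)")

    B = int(config.permutations)
    if deg_size > 0:
        member = _membership_draws(n, deg_size, B, rng)
    else:
        member = np.zeros((B, n), dtype=bool)
    deg_idx = np.array(sorted(pos[g] for g in deg_set), dtype=int)
    deg_mask = np.zeros(n, dtype=bool)
    deg_mask[deg_idx] = True

    rows = []
    for tf, idx in testable:
        k = idx.size
        a = int(deg_mask[idx].sum())
        counts = (a, k - a, deg_size - a, n - k - deg_size + a)
        fisher_p = fisher_enrichment_p(counts, config.fisher_alternative)
        null_overlaps = member[:, idx].sum(axis=1)
        c = int((null_overlaps >= a).sum())
        perm_p = (1 + c) / (B + 1)
        rows.append({
            "tf": tf,
            "regulon_size": k,
            "deg_size": deg_size,
            "universe_size": n,
            "overlap": a,
            "fisher_p": fisher_p,
            "perm_p": perm_p,
            "perm_mean_overlap": float(null_overlaps.mean()),
            "selected": bool(
                fisher_p < config.alpha_fisher and perm_p < config.alpha_perm
            ),
        })
    result = pd.DataFrame(rows)
    if config.multiple_testing == "bh":
        from statsmodels.stats.multitest import multipletests
        result["fisher_p_bh"] = multipletests(result["fisher_p"], method="fdr_bh")[1]
        result["perm_p_bh"] = multipletests(result["perm_p"], method="fdr_bh")[1]
    result = result.sort_values(
        ["fisher_p", "perm_p", "tf"], kind="mergesort"
    ).reset_index(drop=True)
    return result


def venn_partition(set_a: set[str], set_b: set[str],
                   deg_set: set[str]) -> tuple[int, int, int]:
    """Partition the DEGs hit by two regulons into unique/shared counts.

    Returns (|DEG∩(A∖B)|, |DEG∩A∩B|, |DEG∩(B∖A)|) — the Venn-diagram
    partition of DEG-overlapping targets between two TFs.
    """
    a, b = set(set_a), set(set_b)
    deg = set(deg_set)
    return (
        len(deg & (a - b)),
        len(deg & a & b),
        len(deg & (b - a)),
    )
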