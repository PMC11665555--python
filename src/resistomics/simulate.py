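"""Synthetic multi-omics data with planted, known signal.

Generates all five pipeline inputs — regulons, DEG tables, pathway
graphs, metabolite abundance matrices and survival cohorts — with
signal planted at known locations so every downstream stage can be
tested for recovery without any external download.

The defaults encode the study conditions the pipeline targets: a gene
universe of 5,000 with 50 regulons and a 400-gene DEG set; 3 master
TFs planted at odds ratio 8; a 147-metabolite panel across three
3-sample groups (parental / resistant / resistant-KO) with the second
group shifted by 2 standardized units for perturbed metabolites and
the knockout group restored to baseline; and a 300-subject survival
cohort with hazard ratio 2.35 on the expression effect and 20%
uniform administrative censoring.

All generators are pure functions of their spec: the same spec gives
byte-identical output.  Planted quantities are returned in a sidecar
truth record so tests can assert recovery without re-deriving them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import io
from ._rng import substream
from .jointpath import PathwayGraph
from .metabolites import MetaboliteMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "gen_regulon",
    "gen_deg_table",
    "gen_pathway_graphs",
    "gen_metabolite_table",
    "gen_survival_cohort",
    "gen_bundle",
    "Bundle",
    "write_bundle",
]


@dataclass
class SimulationSpec:
    """Everything the generators need, with study-scale defaults."""

    seed: int = 0
    # transcriptome / regulons
    n_genes: int = 5000
    n_tfs: int = 50
    regulon_size_range: tuple[int, int] = (50, 200)
    planted_tfs: tuple[str, ...] = ("TF01", "TF02", "TF03")
    planted_odds_ratio: float = 8.0
    n_deg: int = 400
    deg_padj_cutoff: float = 0.05
    deg_lfc_cutoff: float = 1.0
    # pathways
    n_pathways: int = 12
    planted_pathway: str = "PW01"
    pathway_gene_range: tuple[int, int] = (12, 30)
    pathway_metabolite_range: tuple[int, int] = (5, 10)
    planted_deg_fraction: float = 0.6
    # metabolomics
    n_metabolites: int = 147
    group_labels: tuple[str, ...] = ("parental", "resistant", "resistant_KO")
    samples_per_group: int = 3
    effect_size: float = 2.0
    n_perturbed_metabolites: int = 10
    # survival
    n_subjects: int = 300
    true_log_hr: float = math.log(2.35)
    censoring_rate: float = 0.2
    hazard_model: str = "continuous"  # "continuous" | "threshold"
    threshold_value: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_deg > self.n_genes:
            raise ValueError("n_deg cannot exceed n_genes")
        lo, hi = self.regulon_size_range
        if not (1 <= lo <= hi):
            raise ValueError("regulon_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError("regulon sizes cannot exceed the gene universe")
        if self.planted_odds_ratio <= 0:
            raise ValueError("planted_odds_ratio must be positive")
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be >= 1")
        if len(self.group_labels) < 2:
            raise ValueError("need at least 2 sample groups")
        if self.samples_per_group < 2:
            raise ValueError(
                "need >= 2 samples per group (ANOVA needs within-group "
                "variance)")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not math.isfinite(self.true_log_hr):
            raise ValueError("true_log_hr must be finite")
        if self.hazard_model not in ("continuous", "threshold"):
            raise ValueError("hazard_model must be 'continuous' or 'threshold'")

    def replace(self, **changes) -> "SimulationSpec":
        return dataclasses.replace(self, **changes)

    # deterministic identifier vocabularies -------------------------------
    def gene_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]

    def tf_names(self) -> list[str]:
        return [f"TF{i:02d}" for i in range(1, self.n_tfs + 1)]

    def metabolite_names(self) -> list[str]:
        return [f"M{i:03d}" for i in range(1, self.n_metabolites + 1)]

    def pathway_names(self) -> list[str]:
        return [f"PW{i:02d}" for i in range(1, self.n_pathways + 1)]


# ---------------------------------------------------------------------------
# Regulons
# ---------------------------------------------------------------------------

def gen_regulon(spec: SimulationSpec) -> dict[str, set[str]]:
    """TF -> target-set mapping: sizes uniform in the configured range."""
    rng = substream(spec.seed, "regulon")
    genes = np.array(spec.gene_names())
    tfs = spec.tf_names()
    missing = set(spec.planted_tfs) - set(tfs)
    if missing:
        raise ValueError(f"planted TFs not in the TF vocabulary: {sorted(missing)}")
    lo, hi = spec.regulon_size_range
    regulons: dict[str, set[str]] = {}
    for tf in tfs:
        size = int(rng.integers(lo, hi + 1))
        regulons[tf] = set(rng.choice(genes, size=size, replace=False))
    return regulons


# ---------------------------------------------------------------------------
# DEG table
# ---------------------------------------------------------------------------

def _weighted_sample_without_replacement(rng: np.random.Generator,
                                         n: int, weights: np.ndarray,
                                         k: int) -> np.ndarray:
    """Efraimidis-Spirakis weighted sampling without replacement.

    Items with weight w are exponentially favoured: key_i = log(u_i)/w_i
    with u ~ U(0,1); the k largest keys are the sample.  At w = 1 for
    every item this is exactly uniform sampling without replacement.
    """
    if k == 0:
        return np.array([], dtype=int)
    u = rng.random(n)
    keys = np.log(u) / weights
    return np.argpartition(keys, -k)[-k:]


def gen_deg_table(spec: SimulationSpec,
                  regulons: dict[str, set[str]]) -> pd.DataFrame:
    """DEG table with planted regulon-target enrichment among the DEGs.

    Exactly ``n_deg`` genes are flagged significant, drawn by weighted
    sampling without replacement with weight = planted_odds_ratio for
    targets of the planted TFs and 1 otherwise.  Significant rows carry
    padj below the cutoff and |log2FC| above it; the rest do not.
    """
    for tf in spec.planted_tfs:
        if tf not in regulons:
            raise ValueError(f"planted TF {tf!r} missing from regulon mapping")
    rng = substream(spec.seed, "deg")
    genes = spec.gene_names()
    n = len(genes)
    planted_targets: set[str] = set()
    for tf in spec.planted_tfs:
        planted_targets |= regulons[tf]
    gpos = {g: i for i, g in enumerate(genes)}
    weights = np.ones(n)
    weights[[gpos[g] for g in planted_targets]] = spec.planted_odds_ratio

    deg_idx = _weighted_sample_without_replacement(rng, n, weights, spec.n_deg)
    sig = np.zeros(n, dtype=bool)
    sig[deg_idx] = True

    log2fc = rng.normal(0.0, 0.3, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    log2fc[sig] = sign[sig] * (spec.deg_lfc_cutoff + rng.exponential(1.0, size=spec.n_deg))
    padj = np.empty(n)
    padj[~sig] = rng.uniform(spec.deg_padj_cutoff, 1.0, size=n - spec.n_deg)
    padj[sig] = spec.deg_padj_cutoff * 10 ** (-rng.uniform(0.5, 4.0, size=spec.n_deg))
    pvalue = padj * rng.uniform(0.1, 1.0, size=n)

    return pd.DataFrame({
        "gene": genes,
        "log2fc": log2fc,
        "pvalue": pvalue,
        "padj": padj,
        "significant": sig,
    })


# ---------------------------------------------------------------------------
# Pathway graphs
# ---------------------------------------------------------------------------

def _random_connected_graph(rng: np.random.Generator,
                            nodes: Sequence[str]) -> list[tuple[str, str]]:
    """Random spanning tree plus extra edges: connected by construction."""
    order = list(rng.permutation(len(nodes)))
    edges = []
    for i in range(1, len(order)):
        j = int(rng.integers(0, i))
        edges.append((nodes[order[i]], nodes[order[j]]))
    n_extra = max(1, len(nodes) // 3)
    for _ in range(n_extra):
        a, b = rng.choice(len(nodes), size=2, replace=False)
        edges.append((nodes[int(a)], nodes[int(b)]))
    return edges


def gen_pathway_graphs(spec: SimulationSpec,
                       deg_genes: set[str] | None = None,
                       ) -> tuple[list[PathwayGraph], dict]:
    """KEGG-style pathway graphs mixing gene and metabolite nodes.

    Every graph is connected.  The planted pathway draws a fraction of
    its gene members from the DEG set (when provided) and its
    metabolite members define the perturbed-metabolite set — so both
    omics layers carry signal for it.  Returns (graphs, truth) where
    truth records the planted pathway and its perturbed metabolites.
    """
    rng = substream(spec.seed, "pathways")
    genes = np.array(spec.gene_names())
    mets = np.array(spec.metabolite_names())
    names = spec.pathway_names()
    if spec.planted_pathway not in names:
        raise ValueError(
            f"planted pathway {spec.planted_pathway!r} not in {names[:3]}...")
    deg_pool = np.array(sorted(deg_genes)) if deg_genes else None

    graphs: list[PathwayGraph] = []
    perturbed: list[str] = []
    for name in names:
        n_g = int(rng.integers(*spec.pathway_gene_range))
        n_m = int(rng.integers(*spec.pathway_metabolite_range))
        if name == spec.planted_pathway and deg_pool is not None:
            n_from_deg = min(int(round(spec.planted_deg_fraction * n_g)),
                             deg_pool.size)
            g_deg = rng.choice(deg_pool, size=n_from_deg, replace=False)
            rest_pool = np.setdiff1d(genes, g_deg, assume_unique=False)
            g_rest = rng.choice(rest_pool, size=n_g - n_from_deg, replace=False)
            g_members = np.concatenate([g_deg, g_rest])
        else:
            g_members = rng.choice(genes, size=n_g, replace=False)
        m_members = rng.choice(mets, size=n_m, replace=False)
        if name == spec.planted_pathway:
            perturbed = sorted(m_members.tolist())
        node_types = {str(g): "gene" for g in g_members}
        node_types.update({str(m): "metabolite" for m in m_members})
        all_nodes = list(node_types)
        edges = _random_connected_graph(rng, all_nodes)
        graphs.append(PathwayGraph.from_parts(name, node_types, edges))
    truth = {
        "planted_pathway": spec.planted_pathway,
        "perturbed_metabolites": perturbed,
    }
    return graphs, truth


# ---------------------------------------------------------------------------
# Metabolite matrix
# ---------------------------------------------------------------------------

def gen_metabolite_table(spec: SimulationSpec,
                         perturbed: set[str] | None = None,
                         ) -> tuple[MetaboliteMatrix, dict]:
    """Log-normal abundance matrix with planted group mean shifts.

    Null metabolites: ln-abundance ~ N(mu_m, 1) with a per-metabolite
    baseline, shared across groups.  Perturbed metabolites: the second
    group's mean is shifted by ``effect_size`` standardized (unit
    log-SD) units; any later group is restored to baseline — emulating
    a resistant-line perturbation that a knockout reverts.  Values are
    strictly positive by construction.
    """
    rng = substream(spec.seed, "metabolites")
    mets = spec.metabolite_names()
    if perturbed is None:
        perturbed = (set(mets[: spec.n_perturbed_metabolites])
                     if spec.effect_size != 0 else set())
    unknown = set(perturbed) - set(mets)
    if unknown:
        raise ValueError(f"perturbed metabolites not on panel: {sorted(unknown)[:5]}")
    groups = [g for g in spec.group_labels for _ in range(spec.samples_per_group)]
    samples = [f"{g}_{r + 1}" for g in spec.group_labels
               for r in range(spec.samples_per_group)]
    n_s, n_m = len(samples), len(mets)
    baseline = rng.normal(2.0, 1.0, size=n_m)
    shift = np.zeros((n_s, n_m))
    pert_idx = [i for i, m in enumerate(mets) if m in perturbed]
    second = spec.group_labels[1]
    row_is_second = np.array([g == second for g in groups])
    shift[np.ix_(row_is_second, pert_idx)] = spec.effect_size
    ln_vals = baseline[None, :] + shift + rng.normal(0.0, 1.0, size=(n_s, n_m))
    values = pd.DataFrame(np.exp(ln_vals), index=samples, columns=mets)
    matrix = MetaboliteMatrix(values, pd.Series(groups, index=samples))
    truth = {"perturbed_metabolites": sorted(perturbed),
             "shifted_group": second,
             "effect_size": spec.effect_size}
    return matrix, truth


# ---------------------------------------------------------------------------
# Survival cohort
# ---------------------------------------------------------------------------

def gen_survival_cohort(spec: SimulationSpec) -> tuple[pd.DataFrame, dict]:
    """Cohort with expression-dependent exponential event times.

    continuous model: log-hazard = true_log_hr * standardized expression.
    threshold model: two constant hazards split at ``threshold_value``.
    Censoring is administrative-uniform on (0, tau) with tau solved
    numerically so the realized censoring fraction approximates
    ``censoring_rate``.
    """
    rng = substream(spec.seed, "survival")
    n = spec.n_subjects
    expr = rng.normal(0.0, 1.0, size=n)
    lam0 = 0.1
    if spec.hazard_model == "continuous":
        lam = lam0 * np.exp(spec.true_log_hr * expr)
    else:
        lam = lam0 * np.exp(spec.true_log_hr * (expr > spec.threshold_value))
    t_event = rng.exponential(1.0 / lam)

    tau = math.inf
    if spec.censoring_rate > 0:
        def censor_gap(log_tau: float) -> float:
            t = math.exp(log_tau)
            return float(np.minimum(t_event, t).mean() / t) - spec.censoring_rate
        # censoring fraction decreases from 1 (tau -> 0) to 0 (tau -> inf)
        lo, hi = -10.0, 10.0
        while censor_gap(hi) > 0:
            hi += 5.0
        tau = math.exp(optimize.brentq(censor_gap, lo, hi))
        c = rng.uniform(0.0, tau, size=n)
        time = np.minimum(t_event, c)
        event = t_event <= c
    else:
        time = t_event
        event = np.ones(n, dtype=bool)

    cohort = pd.DataFrame({
        "subject": [f"S{i:04d}" for i in range(1, n + 1)],
        "time": time,
        "event": event.astype(int),
        "expression": expr,
    })
    truth = {
        "true_log_hr": spec.true_log_hr,
        "true_hr": math.exp(spec.true_log_hr),
        "hazard_model": spec.hazard_model,
        "threshold_value": spec.threshold_value,
        "censoring_tau": tau,
        "realized_censoring": float(1 - event.mean()),
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """One complete synthetic study: all five inputs plus ground truth."""

    regulons: dict[str, set[str]]
    deg_table: pd.DataFrame
    pathways: list[PathwayGraph]
    metabolites: MetaboliteMatrix
    survival: pd.DataFrame
    truth: dict = field(default_factory=dict)


def gen_bundle(spec: SimulationSpec) -> Bundle:
    """Generate a coherent bundle: pathway gene/metabolite signal is
    coupled to the DEG set and the perturbed metabolites."""
    regulons = gen_regulon(spec)
    deg_table = gen_deg_table(spec, regulons)
    deg_genes = set(deg_table.loc[deg_table["significant"], "gene"])
    pathways, pw_truth = gen_pathway_graphs(spec, deg_genes=deg_genes)
    metabolites, met_truth = gen_metabolite_table(
        spec, perturbed=set(pw_truth["perturbed_metabolites"]))
    survival, surv_truth = gen_survival_cohort(spec)
    truth = {
        "planted_tfs": list(spec.planted_tfs),
        "planted_odds_ratio": spec.planted_odds_ratio,
        "n_deg": spec.n_deg,
        **pw_truth,
        **met_truth,
        **surv_truth,
    }
    return Bundle(regulons, deg_table, pathways, metabolites, survival, truth)


def write_bundle(bundle: Bundle, out_dir: str | Path) -> dict[str, str]:
    """Write a bundle to plain-text files; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "regulons": out / "regulons.gmt",
        "deg_table": out / "deg_table.tsv",
        "pathway_membership": out / "pathway_membership.gmt",
        "pathway_edges": out / "pathway_edges.tsv",
        "pathway_node_types": out / "pathway_node_types.tsv",
        "metabolites": out / "metabolites.tsv",
        "survival": out / "survival.tsv",
        "truth": out / "truth.json",
    }
    io.write_gmt(bundle.regulons, paths["regulons"])
    io.write_table(bundle.deg_table, paths["deg_table"])
    io.write_gmt({pw.pathway_id: set(pw.membership) for pw in bundle.pathways},
                 paths["pathway_membership"])
    with open(paths["pathway_edges"], "w") as fh:
        fh.write("pathway\tsource\ttarget\n")
        for pw in bundle.pathways:
            for u, v in sorted(map(tuple, map(sorted, pw.graph.edges))):
                fh.write(f"{pw.pathway_id}\t{u}\t{v}\n")
    with open(paths["pathway_node_types"], "w") as fh:
        fh.write("node\ttype\n")
        seen: set[str] = set()
        for pw in bundle.pathways:
            for node, data in sorted(pw.graph.nodes(data=True)):
                if node not in seen:
                    fh.write(f"{node}\t{data['kind']}\n")
                    seen.add(node)
    io.write_metabolite_table(bundle.metabolites.values,
                              bundle.metabolites.groups, paths["metabolites"])
    io.write_table(bundle.survival, paths["survival"])
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
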