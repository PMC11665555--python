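"""Joint transcriptomics + metabolomics pathway analysis.

Significant genes and metabolites are mapped onto pathway graphs whose
nodes are typed (gene | metabolite).  Each pathway receives:

* per-omics over-representation p-values (one-sided hypergeometric,
  each layer against its own assayed universe),
* a topology impact score: the degree-centrality share of the hit
  nodes, sum(degree over hits) / sum(degree over all nodes), in [0, 1],
* a combined significance treating both omics layers with equal weight
  (Fisher's method, chi-square with 4 df; Stouffer available as a
  non-default switch).

Pathways are ranked by combined p ascending with impact as tie-break.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGraph",
    "map_features",
    "pathway_enrichment_p",
    "pathway_impact",
    "combine_omics_evidence",
    "run_joint_pathway",
    "rank_pathways",
]

_VALID_KINDS = frozenset({"gene", "metabolite"})


@dataclass
class PathwayGraph:
    """A pathway with typed nodes, undirected topology and a membership set."""

    pathway_id: str
    graph: nx.Graph
    membership: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        kinds = {d.get("kind") for _, d in self.graph.nodes(data=True)}
        bad = kinds - _VALID_KINDS
        if bad:
            raise ValueError(
                f"pathway {self.pathway_id}: node kinds must partition into "
                f"gene|metabolite; found {sorted(map(str, bad))}"
            )
        if not self.membership:
            self.membership = frozenset(self.graph.nodes)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def nodes_of_kind(self, kind: str) -> frozenset[str]:
        return frozenset(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == kind
        )

    @property
    def genes(self) -> frozenset[str]:
        return self.nodes_of_kind("gene")

    @property
    def metabolites(self) -> frozenset[str]:
        return self.nodes_of_kind("metabolite")

    @classmethod
    def from_parts(cls, pathway_id: str, node_types: Mapping[str, str],
                   edges: Iterable[tuple[str, str]],
                   membership: Iterable[str] | None = None) -> "PathwayGraph":
        g = nx.Graph()
        for node, kind in node_types.items():
            g.add_node(node, kind=kind)
        for u, v in edges:
            if u not in g or v not in g:
                raise ValueError(
                    f"pathway {pathway_id}: edge ({u}, {v}) references an "
                    "undeclared node"
                )
            g.add_edge(u, v)
        member = frozenset(membership) if membership is not None else frozenset(g.nodes)
        return cls(pathway_id, g, member)


def load_pathways(membership_gmt: str, edges_tsv: str,
                  node_types_tsv: str) -> list[PathwayGraph]:
    """Rebuild pathway graphs from membership GMT + topology TSVs.

    The edge file carries (pathway, source, target) rows; node types
    come from a shared (node, type) table.
    """
    from . import io as _io

    membership = _io.read_gmt(membership_gmt)
    types = _io.read_node_types(node_types_tsv)
    per_pathway_edges: dict[str, list[tuple[str, str]]] = {
        name: [] for name in membership}
    with open(edges_tsv) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise ValueError(
                    f"{edges_tsv}: line {lineno}: expected 3 tab-separated "
                    "fields (pathway, source, target)")
            if lineno == 1 and fields[0].lower() == "pathway":
                continue
            pw, u, v = fields[0], fields[1], fields[2]
            per_pathway_edges.setdefault(pw, []).append((u, v))
    graphs = []
    for name, members in membership.items():
        node_types = {}
        for node in members:
            if node not in types:
                raise ValueError(
                    f"pathway {name}: member {node!r} has no node-type entry")
            node_types[node] = types[node]
        graphs.append(PathwayGraph.from_parts(
            name, node_types, per_pathway_edges.get(name, []), members))
    return graphs


def map_features(sig_genes: set[str], sig_metabolites: set[str],
                 pathways: Sequence[PathwayGraph],
                 ) -> tuple[dict[str, set[str]], set[str]]:
    """Intersect query features with each pathway's node set.

    Returns (per-pathway hit sets, dropped features).  A feature absent
    from every pathway is dropped — the mapping step removes symbols
    with no match rather than guessing.
    """
    if not pathways:
        raise ValueError("pathway list is empty")
    query = set(sig_genes) | set(sig_metabolites)
    if not query:
        logger.warning("empty query: all pathways get zero hits")
    hits: dict[str, set[str]] = {}
    matched: set[str] = set()
    for pw in pathways:
        h = query & pw.nodes
        hits[pw.pathway_id] = h
        matched |= h
    dropped = query - matched
    if dropped:
        logger.info("dropped %d feature(s) with no pathway match", len(dropped))
    return hits, dropped


def pathway_enrichment_p(hits: int, pathway_members: int, query_size: int,
                         universe_size: int) -> float:
    """Upper-tail hypergeometric over-representation p for one layer."""
    if hits < 0 or pathway_members < 0 or query_size < 0 or universe_size < 0:
        raise ValueError("counts must be non-negative")
    if hits > min(pathway_members, query_size):
        raise ValueError(
            f"hits ({hits}) exceed min(pathway members, query size)"
        )
    if universe_size < max(pathway_members, query_size):
        raise ValueError("universe smaller than pathway membership or query")
    return float(stats.hypergeom.sf(hits - 1, universe_size,
                                    pathway_members, query_size))


def pathway_impact(graph: PathwayGraph | nx.Graph, hit_nodes: set[str]) -> float:
    """Degree-centrality share of the hit nodes, in [0, 1].

    impact = sum(degree over hit nodes) / sum(degree over all nodes).
    Raw degree sums are used (ratios are identical under any constant
    normalization); an edgeless graph has impact 0.
    """
    g = graph.graph if isinstance(graph, PathwayGraph) else graph
    unknown = set(hit_nodes) - set(g.nodes)
    if unknown:
        raise ValueError(f"hit nodes not in graph: {sorted(unknown)[:5]}")
    total = sum(d for _, d in g.degree())
    if total == 0:
        return 0.0
    hit = sum(d for n, d in g.degree() if n in hit_nodes)
    return hit / total


def combine_omics_evidence(gene_p: float, metabolite_p: float,
                           method: str = "fisher") -> float:
    """Combine the two omics layers' p-values with equal weight.

    Fisher's method (default): X = -2(ln p1 + ln p2), combined p is the
    upper tail of chi-square with 4 df at X.  Stouffer: equal-weight
    normal-score combination.  Zero inputs are clamped to the smallest
    positive float with a warning (the log diverges at 0).
    """
    ps = []
    for p in (gene_p, metabolite_p):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {p!r}")
        if p == 0.0:
            logger.warning("p = 0 clamped to smallest positive float")
            p = np.nextafter(0.0, 1.0)
        ps.append(p)
    p1, p2 = ps
    if method == "fisher":
        x = -2.0 * (math.log(p1) + math.log(p2))
        combined = float(stats.chi2.sf(x, df=4))
    elif method == "stouffer":
        z = (stats.norm.isf(p1) + stats.norm.isf(p2)) / math.sqrt(2.0)
        combined = float(stats.norm.sf(z))
    else:
        raise ValueError(f"unknown combination method {method!r}")
    # the result contract is (0, 1]: floor survival-function underflow
    return max(combined, float(np.nextafter(0.0, 1.0)))


def run_joint_pathway(sig_genes: set[str], sig_metabolites: set[str],
                      pathways: Sequence[PathwayGraph],
                      gene_universe_size: int, metabolite_universe_size: int,
                      config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Score and rank every pathway on joint gene + metabolite evidence.

    Each omics layer is tested against its own assayed universe (all
    genes in the DEG table; all metabolites on the panel), reflecting
    the distinct measurement platforms.
    """
    config = config or AnalysisConfig()
    hits, dropped = map_features(sig_genes, sig_metabolites, pathways)
    n_mapped = sum(1 for f in (set(sig_genes) | set(sig_metabolites))
                   if f not in dropped)
    gene_query = len({g for g in sig_genes if g not in dropped})
    met_query = len({m for m in sig_metabolites if m not in dropped})

    rows = []
    for pw in pathways:
        h = hits[pw.pathway_id]
        gene_members, met_members = pw.genes, pw.metabolites
        gh = len(h & gene_members)
        mh = len(h & met_members)
        gene_p = pathway_enrichment_p(
            gh, len(gene_members), gene_query, gene_universe_size)
        met_p = pathway_enrichment_p(
            mh, len(met_members), met_query, metabolite_universe_size)
        rows.append({
            "pathway_id": pw.pathway_id,
            "gene_hits": gh,
            "metabolite_hits": mh,
            "gene_p": gene_p,
            "metabolite_p": met_p,
            "combined_p": combine_omics_evidence(
                gene_p, met_p, config.combine_method),
            "impact": pathway_impact(pw, h),
            "n_mapped": n_mapped,
            "n_dropped": len(dropped),
        })
    result = pd.DataFrame(rows)
    if config.multiple_testing == "bh":
        from statsmodels.stats.multitest import multipletests
        result["combined_p_bh"] = multipletests(
            result["combined_p"], method="fdr_bh")[1]
    return rank_pathways(result)


def rank_pathways(results: pd.DataFrame) -> pd.DataFrame:
    """Sort by combined p ascending, impact descending, then pathway id."""
    return results.sort_values(
        ["combined_p", "impact", "pathway_id"],
        ascending=[True, False, True], kind="mergesort",
    ).reset_index(drop=True)
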