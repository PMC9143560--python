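"""Pathway over-representation analysis of score metabolites.

Given the set of metabolites selected into a severity score, a universe
(the harmonized metabolites mappable to pathway ids), and user-supplied
pathway sets (GMT format, optionally with a directed reaction graph per
pathway), computes:

* an upper-tail hypergeometric over-representation p-value per pathway
  (P(X >= k), the observed overlap included);
* Benjamini–Hochberg FDR across pathways;
* a topology-based pathway impact in [0, 1]: the centrality mass
  (betweenness, or out-degree) of the matched metabolites as a fraction
  of the pathway's total centrality.

No pathway database is bundled; pathway content is always user-supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["PathwaySet", "OraResult", "ora_test", "bh_fdr", "pathway_impact",
           "read_pathways", "run_ora"]


@dataclass
class PathwaySet:
    """A named metabolite set, optionally with a directed reaction graph."""

    pathway_id: str
    name: str
    members: frozenset
    graph: nx.DiGraph | None = None

    def __post_init__(self):
        self.members = frozenset(self.members)
        if self.graph is not None:
            extra = set(self.graph.nodes) - self.members
            if extra:
                raise ValueError(
                    f"{self.pathway_id}: graph nodes not in member set: {sorted(extra)[:5]}")


@dataclass
class OraResult:
    pathway_id: str
    name: str
    universe_size: int
    pathway_size: int
    selected_size: int
    overlap: int
    p: float
    fdr: float = np.nan
    impact: float | None = None
    matched: list = field(default_factory=list)


def ora_test(selected, pathway: PathwaySet, universe) -> OraResult:
    """Upper-tail hypergeometric over-representation test.

    N = |universe|, K = |pathway ∩ universe|, n = |selected|,
    k = |selected ∩ pathway|; p = P(X >= k) for X ~ Hypergeom(N, K, n).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected metabolites must be a subset of the universe")
    members = pathway.members & universe
    matched = sorted(selected & members)
    N, K, n, k = len(universe), len(members), len(selected), len(matched)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    return OraResult(pathway_id=pathway.pathway_id, name=pathway.name,
                     universe_size=N, pathway_size=K, selected_size=n,
                     overlap=k, p=min(p, 1.0), matched=matched)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pathway_impact(pathway: PathwaySet, matched, mode="betweenness"):
    """Centrality share of the matched metabolites, in [0, 1].

    ``mode``: "betweenness" (relative betweenness centrality, exact
    shortest-path counting) or "out_degree".  Returns None when the pathway
    has no graph (impact is missing, not zero).  If total pathway centrality
    is zero, impact is 0.
    """
    if pathway.graph is None:
        return None
    G = pathway.graph
    if mode == "betweenness":
        cent = nx.betweenness_centrality(G, normalized=True)
    elif mode == "out_degree":
        cent = dict(G.out_degree())
    else:
        raise ValueError(f"unknown centrality mode {mode!r}")
    total = sum(cent.values())
    if total <= 0:
        return 0.0
    hit = sum(cent.get(m, 0.0) for m in set(matched))
    return float(hit / total)


def read_pathways(gmt_path, edges_dir=None) -> list:
    """Parse a GMT file (name, description, tab-separated member ids).

    Duplicate members within a set are deduplicated with a warning.  If
    ``edges_dir`` is given, a file ``<pathway_id>.edges.tsv`` per pathway
    (tab-separated source/target, one edge per line) supplies the directed
    graph; an edge naming an unknown member is an error.
    """
    from pathlib import Path

    pathways = []
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{gmt_path}: malformed GMT line {lineno} "
                    "(need id, description and at least one member)")
            pid, desc, members = parts[0], parts[1], parts[2:]
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                warnings.warn(f"pathway {pid}: duplicate members deduplicated")
            graph = None
            if edges_dir is not None:
                epath = Path(edges_dir) / f"{pid}.edges.tsv"
                if epath.exists():
                    graph = nx.DiGraph()
                    graph.add_nodes_from(uniq)
                    with open(epath) as efh:
                        for eno, eline in enumerate(efh, start=1):
                            eline = eline.strip()
                            if not eline:
                                continue
                            try:
                                src, dst = eline.split("\t")
                            except ValueError:
                                raise ValueError(
                                    f"{epath}: malformed edge line {eno}")
                            for node in (src, dst):
                                if node not in set(uniq):
                                    raise ValueError(
                                        f"{epath}: line {eno} references "
                                        f"unknown node {node!r}")
                            graph.add_edge(src, dst)
            pathways.append(PathwaySet(pathway_id=pid, name=desc,
                                       members=frozenset(uniq), graph=graph))
    return pathways


def run_ora(selected, pathways, universe, impact_mode="betweenness") -> pd.DataFrame:
    """ORA over all pathways with BH FDR, sorted by FDR then raw p.

    ``selected`` is intersected with the universe first (score features not
    mappable to pathway ids simply drop out).
    """
    selected = set(selected) & set(universe)
    results = [ora_test(selected, pw, universe) for pw in pathways]
    fdrs = bh_fdr([r.p for r in results])
    for r, fdr in zip(results, fdrs):
        r.fdr = float(fdr)
    for r, pw in zip(results, pathways):
        r.impact = pathway_impact(pw, r.matched, mode=impact_mode)
    df = pd.DataFrame([{
        "pathway_id": r.pathway_id, "name": r.name,
        "universe_size": r.universe_size, "pathway_size": r.pathway_size,
        "selected_size": r.selected_size, "overlap": r.overlap,
        "p": r.p, "fdr": r.fdr, "impact": r.impact,
        "matched": ";".join(r.matched),
    } for r in results])
    return df.sort_values(["fdr", "p"], kind="stable").reset_index(drop=True)
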