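"""Correlation-based gene regulatory network construction.

For one cancer type the network is built from the differentially expressed
genes that appear in the interaction database: every unordered gene pair is
scored by the Pearson correlation of log2 expression across samples, edge
p-values are BH-adjusted over the full family of tested pairs, pairs with
adjusted p <= alpha are kept, and the surviving set is refined by
intersection with the interaction database.

Correlation edges carry no direction, but the controllability machinery
downstream operates on directed graphs; by default each kept pair is
expanded into an antiparallel pair of directed edges sharing the same
attributes (``antiparallel_pairs`` convention).  Users with genuinely
directed regulatory input can pass pre-directed edge lists (``as_given``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .io import ExpressionMatrix, GeneSet, InteractionDB

logger = logging.getLogger(__name__)

__all__ = ["GeneNetwork", "pairwise_pcc", "build_network", "read_network", "write_network"]


@dataclass
class GeneNetwork:
    """A directed gene network with per-edge correlation attributes."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    convention: str = "antiparallel_pairs"

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_undirected_edges(self) -> int:
        seen = {frozenset(e) for e in self.graph.edges}
        return len(seen)

    @classmethod
    def from_edges(cls, edges, convention: str = "as_given") -> "GeneNetwork":
        """Build from an iterable of (u, v) or (u, v, attr-dict) tuples."""
        g = nx.DiGraph()
        for edge in edges:
            if len(edge) == 2:
                u, v = edge
                attrs = {}
            else:
                u, v, attrs = edge
            g.add_edge(u, v, **attrs)
            if convention == "antiparallel_pairs":
                g.add_edge(v, u, **attrs)
        return cls(g, convention=convention)


def pairwise_pcc(m: ExpressionMatrix, genes: GeneSet | None = None) -> pd.DataFrame:
    """Pearson correlation and two-sided p for every unordered gene pair.

    p-values use the exact null transform t = r * sqrt((n - 2) / (1 - r^2))
    with n - 2 degrees of freedom.  Genes with zero variance across samples
    have undefined correlations and are excluded with a logged count.
    """
    if m.scale != "log2":
        raise ValueError("pairwise_pcc expects a log2-scale matrix")
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    sub = m if genes is None else m.subset_genes(genes.genes)
    vals = sub.values.to_numpy()
    names = np.array(sub.values.index)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        logger.info("excluding %d zero-variance gene(s) from correlation", int((sd == 0).sum()))
        vals = vals[sd > 0]
        names = names[sd > 0]
    n_genes = len(names)
    if n_genes < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "pcc", "p"])
    n = vals.shape[1]
    r = np.corrcoef(vals)
    r = np.clip(r, -1.0, 1.0)
    iu, ju = np.triu_indices(n_genes, k=1)
    rv = r[iu, ju]
    with np.errstate(divide="ignore"):
        tstat = rv * np.sqrt((n - 2) / np.maximum(1.0 - rv**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.isclose(np.abs(rv), 1.0)] = 0.0
    return pd.DataFrame({"gene_a": names[iu], "gene_b": names[ju], "pcc": rv, "p": p})


def build_network(pcc_table: pd.DataFrame, db: InteractionDB,
                  alpha: float = 0.05) -> GeneNetwork:
    """FDR-filter correlation pairs and refine against the interaction database.

    BH adjustment runs over the full family of tested pairs; pairs with
    adjusted p <= ``alpha`` that are also present in ``db`` become
    antiparallel directed edge pairs.  Nodes are the endpoints of surviving
    edges (isolated candidates are dropped).
    """
    g = nx.DiGraph()
    if len(pcc_table):
        adj = benjamini_hochberg(pcc_table["p"].to_numpy())
        for (_, row), q in zip(pcc_table.iterrows(), adj):
            if q <= alpha and db.has_pair(row["gene_a"], row["gene_b"]):
                attrs = {"pcc": float(row["pcc"]), "adj_p": float(q)}
                g.add_edge(row["gene_a"], row["gene_b"], **attrs)
                g.add_edge(row["gene_b"], row["gene_a"], **attrs)
    if g.number_of_edges() == 0:
        logger.warning("no edges survive the FDR filter and database refinement")
    return GeneNetwork(g, convention="antiparallel_pairs")


def write_network(net: GeneNetwork, path) -> None:
    rows = [
        {"source": u, "target": v,
         "pcc": d.get("pcc", np.nan), "adj_p": d.get("adj_p", np.nan)}
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "pcc", "adj_p"]).to_csv(
        path, sep="\t", index=False)


def read_network(path, convention: str = "as_given") -> GeneNetwork:
    df = pd.read_csv(path, sep="\t")
    edges = [(r["source"], r["target"], {"pcc": r.get("pcc", np.nan),
                                         "adj_p": r.get("adj_p", np.nan)})
             for _, r in df.iterrows()]
    return GeneNetwork.from_edges(edges, convention=convention)
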