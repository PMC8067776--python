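"""Per-group ceRNA network construction and degree/hub/triad analysis.

A ceRNA network is a strictly bipartite graph: lncRNA nodes on one side,
mRNA nodes on the other, with an edge for every retained lncRNA-mRNA
coexpression relationship.  Edges carry the full evidence chain (shared
miRNA count and ids, hypergeometric p, Spearman rho and p).  Biological
ceRNA networks are typically scale-free — most nodes have small degree,
a few hubs have large degree — so the module fits a power law to the
degree histogram by least squares in log-log space and ranks hub nodes
by raw degree.  Each edge unfolds into lncRNA-miRNA-mRNA triads, one per
shared miRNA, the mechanistic sponge relationships.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .expression import CoexpressionResult

logger = logging.getLogger(__name__)

NODE_CLASSES = ("all", "lncRNA", "mRNA")
EXPORT_FORMATS = ("graphml", "sif", "edge_tsv")

_EDGE_ATTRS = ("x", "p_hyper", "rho", "p_corr", "shared_mirnas")


class ClassConflictError(ValueError):
    """A node appears as both lncRNA and mRNA."""


class ConflictingEvidenceError(ValueError):
    """The same edge appears twice with different evidence values."""


class MissingEvidenceError(ValueError):
    """An edge lacks the shared-miRNA evidence needed for triads."""


@dataclass
class CeRNANetwork:
    """A per-group bipartite lncRNA-mRNA graph with edge evidence."""

    group: str
    graph: nx.Graph

    def nodes_of_class(self, node_class: str) -> list[str]:
        if node_class == "all":
            return sorted(self.graph.nodes)
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("cls") == node_class
        )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def check_bipartite(self) -> None:
        """Raise if any edge fails to join a lncRNA to an mRNA."""
        for u, v in self.graph.edges:
            cu = self.graph.nodes[u].get("cls")
            cv = self.graph.nodes[v].get("cls")
            if {cu, cv} != {"lncRNA", "mRNA"}:
                raise ClassConflictError(
                    f"edge ({u}, {v}) joins classes ({cu}, {cv}); "
                    "network must be bipartite lncRNA-mRNA"
                )


@dataclass(frozen=True)
class DegreeFit:
    """Least-squares power-law fit of a degree histogram in log-log space.

    ``exponent`` is the negated slope of log10(count) on log10(degree).
    ``fitted`` is False for degenerate inputs (fewer than 3 nonzero
    bins), in which case no exponent is fabricated.
    """

    exponent: float
    intercept: float
    r_squared: float
    n_bins_used: int
    method: str = "loglog_ls"
    fitted: bool = True


@dataclass(frozen=True)
class Triad:
    """One lncRNA-miRNA-mRNA sponge relationship."""

    lnc_id: str
    mirna_id: str
    mrna_id: str


@dataclass(frozen=True)
class GeneSetOverlap:
    """Node-set comparison of two networks (e.g. disease vs control)."""

    label_a: str
    label_b: str
    shared: tuple[str, ...]
    unique_a: tuple[str, ...]
    unique_b: tuple[str, ...]
    shared_by_class: dict[str, int]
    unique_a_by_class: dict[str, int]
    unique_b_by_class: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "n_shared": len(self.shared),
            "n_unique_a": len(self.unique_a),
            "n_unique_b": len(self.unique_b),
            "shared": list(self.shared),
            "unique_a": list(self.unique_a),
            "unique_b": list(self.unique_b),
            "shared_by_class": self.shared_by_class,
            "unique_a_by_class": self.unique_a_by_class,
            "unique_b_by_class": self.unique_b_by_class,
        }


def _edge_evidence(res: CoexpressionResult) -> dict:
    c = res.candidate
    ev = {
        "rho": float(res.rho),
        "p_corr": float(res.p_value),
        "x": int(c.params.n_shared) if c else 0,
        "p_hyper": float(c.p_value) if c else float("nan"),
        "shared_mirnas": ",".join(sorted(c.shared_ids)) if c else "",
    }
    return ev


def build_network(edges: list[CoexpressionResult], group: str) -> CeRNANetwork:
    """Assemble the bipartite ceRNA network of one group.

    Node classes are inferred from edge roles (lnc_id side = lncRNA).
    A node appearing on both sides raises :class:`ClassConflictError`;
    a duplicate edge with different evidence raises
    :class:`ConflictingEvidenceError`.  Isolated nodes cannot arise: the
    network is edge-defined.
    """
    g = nx.Graph()
    cls: dict[str, str] = {}
    for e in edges:
        if e.group != group:
            raise ValueError(
                f"edge ({e.lnc_id}, {e.mrna_id}) belongs to group {e.group!r}, "
                f"not {group!r}"
            )
        for node, c in ((e.lnc_id, "lncRNA"), (e.mrna_id, "mRNA")):
            if cls.setdefault(node, c) != c:
                raise ClassConflictError(
                    f"node {node!r} appears as both lncRNA and mRNA"
                )
        ev = _edge_evidence(e)
        if g.has_edge(e.lnc_id, e.mrna_id):
            old = {k: g.edges[e.lnc_id, e.mrna_id][k] for k in _EDGE_ATTRS}
            if old != ev:
                raise ConflictingEvidenceError(
                    f"edge ({e.lnc_id}, {e.mrna_id}) duplicated with "
                    "conflicting evidence"
                )
            continue
        g.add_node(e.lnc_id, cls="lncRNA")
        g.add_node(e.mrna_id, cls="mRNA")
        g.add_edge(e.lnc_id, e.mrna_id, **ev)
    net = CeRNANetwork(group=group, graph=g)
    net.check_bipartite()
    logger.info("network %s: %d nodes, %d edges", group, net.n_nodes, net.n_edges)
    return net


def degree_distribution(net: CeRNANetwork, node_class: str = "all") -> pd.DataFrame:
    """Degree histogram: one row per observed degree with its node count."""
    if node_class not in NODE_CLASSES:
        raise ValueError(f"node_class must be one of {NODE_CLASSES}")
    nodes = net.nodes_of_class(node_class)
    degs = pd.Series([net.graph.degree[n] for n in nodes], dtype=int)
    counts = degs.value_counts().sort_index()
    return pd.DataFrame({"degree": counts.index, "node_count": counts.values})


def fit_power_law(dist: pd.DataFrame) -> DegreeFit:
    """Fit count ~ degree^-gamma by least squares on log10-log10 axes.

    Zero-count bins are excluded (log of zero is undefined); fewer than
    3 usable bins yields a flagged no-fit result.
    """
    use = dist[(dist["node_count"] > 0) & (dist["degree"] > 0)]
    if len(use) < 3:
        return DegreeFit(
            exponent=float("nan"), intercept=float("nan"),
            r_squared=float("nan"), n_bins_used=len(use), fitted=False,
        )
    lx = np.log10(use["degree"].to_numpy(dtype=float))
    ly = np.log10(use["node_count"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return DegreeFit(
        exponent=float(-slope), intercept=float(intercept),
        r_squared=r2, n_bins_used=len(use),
    )


def top_hubs(
    net: CeRNANetwork, k: int = 5, node_class: str = "lncRNA"
) -> list[tuple[str, int]]:
    """The k highest-degree nodes of a class; ties broken by node id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    nodes = net.nodes_of_class(node_class)
    ranked = sorted(nodes, key=lambda n: (-net.graph.degree[n], n))
    return [(n, int(net.graph.degree[n])) for n in ranked[:k]]


def compare_gene_sets(net_a: CeRNANetwork, net_b: CeRNANetwork) -> GeneSetOverlap:
    """Shared and group-specific node sets of two networks."""
    a = set(net_a.graph.nodes)
    b = set(net_b.graph.nodes)

    def by_class(net: CeRNANetwork, ids: set[str]) -> dict[str, int]:
        out: dict[str, int] = {}
        for n in ids:
            c = net.graph.nodes[n].get("cls", "unknown")
            out[c] = out.get(c, 0) + 1
        return out

    shared = a & b
    return GeneSetOverlap(
        label_a=net_a.group,
        label_b=net_b.group,
        shared=tuple(sorted(shared)),
        unique_a=tuple(sorted(a - b)),
        unique_b=tuple(sorted(b - a)),
        shared_by_class=by_class(net_a, shared),
        unique_a_by_class=by_class(net_a, a - b),
        unique_b_by_class=by_class(net_b, b - a),
    )


def extract_triads(net: CeRNANetwork) -> list[Triad]:
    """Unfold each edge into its lncRNA-miRNA-mRNA sponge triads.

    One triad per (edge, shared miRNA); the total count equals the sum
    of shared-set sizes over edges.
    """
    triads: list[Triad] = []
    for u, v, data in net.graph.edges(data=True):
        if "shared_mirnas" not in data:
            raise MissingEvidenceError(f"edge ({u}, {v}) lacks shared-miRNA evidence")
        lnc, mrna = (u, v) if net.graph.nodes[u]["cls"] == "lncRNA" else (v, u)
        for mir in data["shared_mirnas"].split(","):
            if mir:
                triads.append(Triad(lnc_id=lnc, mirna_id=mir, mrna_id=mrna))
    triads.sort(key=lambda t: (t.lnc_id, t.mrna_id, t.mirna_id))
    return triads


def export_network(net: CeRNANetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Write a network as GraphML (full attributes), SIF, or edge TSV.

    GraphML carries node ``cls`` and all edge evidence and round-trips
    through :func:`read_network` to an identical network.  SIF lines are
    ``LNC cerna MRNA``.
    """
    path = Path(path)
    if fmt == "graphml":
        g = nx.Graph(group=net.group)
        g.add_nodes_from(sorted(net.graph.nodes(data=True)))
        for u, v in sorted(net.graph.edges, key=lambda e: tuple(sorted(e))):
            g.add_edge(u, v, **net.graph.edges[u, v])
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in _sorted_lnc_mrna_edges(net):
                fh.write(f"{u}\tcerna\t{v}\n")
    elif fmt == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("lnc_id\tmrna_id\tgroup\tx\tp_hyper\trho\tp_corr\tshared_mirnas\n")
            for u, v in _sorted_lnc_mrna_edges(net):
                d = net.graph.edges[u, v]
                fh.write(
                    f"{u}\t{v}\t{net.group}\t{d['x']}\t{d['p_hyper']!r}\t"
                    f"{d['rho']!r}\t{d['p_corr']!r}\t{d['shared_mirnas']}\n"
                )
    else:
        raise ValueError(f"unknown export format {fmt!r}; use one of {EXPORT_FORMATS}")


def _sorted_lnc_mrna_edges(net: CeRNANetwork) -> list[tuple[str, str]]:
    out = []
    for u, v in net.graph.edges:
        if net.graph.nodes[u]["cls"] != "lncRNA":
            u, v = v, u
        out.append((u, v))
    return sorted(out)


def read_network(path: str | Path, fmt: str = "graphml") -> CeRNANetwork:
    """Read a network exported by :func:`export_network` (GraphML only)."""
    if fmt != "graphml":
        raise ValueError("only GraphML re-import is supported")
    g = nx.read_graphml(path)
    group = g.graph.get("group", "")
    clean = nx.Graph()
    for n, d in g.nodes(data=True):
        clean.add_node(n, cls=d.get("cls"))
    for u, v, d in g.edges(data=True):
        clean.add_edge(
            u, v,
            x=int(d["x"]), p_hyper=float(d["p_hyper"]), rho=float(d["rho"]),
            p_corr=float(d["p_corr"]), shared_mirnas=d.get("shared_mirnas", ""),
        )
    net = CeRNANetwork(group=group, graph=clean)
    net.check_bipartite()
    return net


def networks_equal(a: CeRNANetwork, b: CeRNANetwork) -> bool:
    """Structural + evidence equality (group, nodes, classes, edge attrs)."""
    if a.group != b.group:
        return False
    if set(a.graph.nodes) != set(b.graph.nodes):
        return False
    for n in a.graph.nodes:
        if a.graph.nodes[n].get("cls") != b.graph.nodes[n].get("cls"):
            return False
    ea = {frozenset(e) for e in a.graph.edges}
    eb = {frozenset(e) for e in b.graph.edges}
    if ea != eb:
        return False
    for u, v in a.graph.edges:
        da, db = a.graph.edges[u, v], b.graph.edges[u, v]
        for key in _EDGE_ATTRS:
            va, vb = da.get(key), db.get(key)
            if isinstance(va, float) and isinstance(vb, float):
                if not (va == vb or abs(va - vb) < 1e-12):
                    return False
            elif va != vb:
                return False
    return True


def write_degree_table(dist: pd.DataFrame, path: str | Path) -> None:
    dist.to_csv(path, sep="\t", index=False)


def write_hubs(hubs: list[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tdegree\n")
        for n, d in hubs:
            fh.write(f"{n}\t{d}\n")


def write_triads(triads: list[Triad], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("lnc_id\tmirna_id\tmrna_id\n")
        for t in triads:
            fh.write(f"{t.lnc_id}\t{t.mirna_id}\t{t.mrna_id}\n")


def write_overlap(overlap: GeneSetOverlap, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(overlap.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
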