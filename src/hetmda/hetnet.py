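"""Heterogeneous five-type association network.

Loads typed edge lists (one TSV per association class), unifies and
de-duplicates them into a single undirected network over miRNA, lncRNA,
protein, disease and drug nodes, and exposes the binary adjacency matrix
in a deterministic node order.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

NODE_TYPES = ("disease", "drug", "lncRNA", "miRNA", "protein")

#: association class -> (ntype of source column, ntype of target column)
ASSOCIATION_CLASSES: dict[str, tuple[str, str]] = {
    "mirna-lncrna": ("miRNA", "lncRNA"),
    "mirna-protein": ("miRNA", "protein"),
    "mirna-disease": ("miRNA", "disease"),
    "lncrna-disease": ("lncRNA", "disease"),
    "lncrna-protein": ("lncRNA", "protein"),
    "drug-disease": ("drug", "disease"),
    "drug-protein": ("drug", "protein"),
    "protein-protein": ("protein", "protein"),
    "protein-disease": ("protein", "disease"),
}


class HetNetError(Exception):
    """Base class for network construction errors."""


class ConfigurationError(HetNetError):
    """Unknown association class or invalid loader configuration."""


class EdgeListParseError(HetNetError):
    """Malformed row in an edge-list file; message names file and line."""


class IdentifierCollisionError(HetNetError):
    """One identifier implied to have two different node types."""


@dataclass(frozen=True, order=True)
class NodeRef:
    """A typed node reference; ordering is (ntype, id) lexicographic."""

    ntype: str
    id: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be non-empty")
        if self.ntype not in NODE_TYPES:
            raise ValueError(f"unknown node type {self.ntype!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.id, self.ntype)


Edge = tuple[NodeRef, NodeRef, str]  # canonical: endpoints sorted, tagged with class


def _canonical_edge(u: NodeRef, v: NodeRef, assoc_class: str) -> Edge:
    a, b = sorted((u, v))
    return (a, b, assoc_class)


@dataclass
class HeteroNetwork:
    """Typed node set plus undirected, class-tagged edge set.

    Node order is (ntype, id) lexicographic so that derived matrices are
    reproducible across runs.
    """

    nodes: list[NodeRef] = field(default_factory=list)
    edges: set[Edge] = field(default_factory=set)
    index: dict[tuple[str, str], int] = field(default_factory=dict)

    @classmethod
    def from_edges(cls, edges: Iterable[Edge]) -> "HeteroNetwork":
        edge_set = set(edges)
        nodes = sorted({n for a, b, _ in edge_set for n in (a, b)})
        index = {n.key: i for i, n in enumerate(nodes)}
        return cls(nodes=nodes, edges=edge_set, index=index)

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_ids(self, ntype: str) -> list[str]:
        return [n.id for n in self.nodes if n.ntype == ntype]

    def position(self, node_id: str, ntype: str) -> int:
        try:
            return self.index[(node_id, ntype)]
        except KeyError:
            raise KeyError(f"node ({node_id!r}, {ntype!r}) not in network") from None

    def class_counts(self) -> dict[str, int]:
        return dict(Counter(cls for _, _, cls in self.edges))

    def ntype_counts(self) -> dict[str, int]:
        return dict(Counter(n.ntype for n in self.nodes))

    # -- persistence (plain-text archive directory) -------------------------

    def save(self, path: str | Path) -> None:
        """Write the network to a directory of TSV tables plus metadata."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "nodes.tsv", "w") as fh:
            fh.write("id\tntype\n")
            for n in self.nodes:
                fh.write(f"{n.id}\t{n.ntype}\n")
        with open(path / "edges.tsv", "w") as fh:
            fh.write("src_id\tsrc_ntype\tdst_id\tdst_ntype\tclass\n")
            for a, b, cls in sorted(self.edges):
                fh.write(f"{a.id}\t{a.ntype}\t{b.id}\t{b.ntype}\t{cls}\n")
        meta = {"n_nodes": len(self.nodes), "n_edges": len(self.edges),
                "class_counts": self.class_counts(),
                "ntype_counts": self.ntype_counts()}
        (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "HeteroNetwork":
        path = Path(path)
        edges = []
        with open(path / "edges.tsv") as fh:
            next(fh)  # header
            for line in fh:
                sid, st, did, dt, ecls = line.rstrip("\n").split("\t")
                edges.append(_canonical_edge(NodeRef(st, sid), NodeRef(dt, did), ecls))
        return cls.from_edges(edges)


def _parse_edge_file(path: str | Path, header: bool) -> Iterable[tuple[int, str, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected at least 2 tab-separated columns")
            yield lineno, fields[0], fields[1]


def load_edge_lists(
    paths_by_class: Mapping[str, str | Path],
    *,
    header: bool = False,
    case_fold: bool = False,
) -> HeteroNetwork:
    """Load and unify the per-class edge-list TSVs into one network.

    Duplicate rows and reversed orientations collapse to a single undirected
    edge; self-loops are dropped with a warning.  Identifier unification is
    exact string match after whitespace trimming and optional case-folding.

    Parameters
    ----------
    paths_by_class
        Map from association class (see :data:`ASSOCIATION_CLASSES`) to a
        TSV file with columns ``source_id <TAB> target_id`` (extra columns
        ignored).
    header
        Skip the first line of every file.
    case_fold
        Lower-case identifiers before matching.
    """
    unknown = set(paths_by_class) - set(ASSOCIATION_CLASSES)
    if unknown:
        raise ConfigurationError(
            f"unknown association class(es): {sorted(unknown)}; "
            f"expected one of {sorted(ASSOCIATION_CLASSES)}")

    ntype_of: dict[str, str] = {}

    def norm(raw: str, ntype: str, where: str) -> str:
        ident = raw.strip()
        if case_fold:
            ident = ident.lower()
        seen = ntype_of.setdefault(ident, ntype)
        if seen != ntype:
            raise IdentifierCollisionError(
                f"{where}: identifier {ident!r} used as both {seen} and {ntype}")
        return ident

    edges: set[Edge] = set()
    n_self_loops = 0
    for assoc_class in sorted(paths_by_class):
        path = paths_by_class[assoc_class]
        src_t, dst_t = ASSOCIATION_CLASSES[assoc_class]
        for lineno, raw_s, raw_d in _parse_edge_file(path, header):
            where = f"{path}:{lineno}"
            u = NodeRef(src_t, norm(raw_s, src_t, where))
            v = NodeRef(dst_t, norm(raw_d, dst_t, where))
            if u == v:
                n_self_loops += 1
                continue
            edges.add(_canonical_edge(u, v, assoc_class))

    if n_self_loops:
        logger.warning("dropped %d self-loop(s)", n_self_loops)
    net = HeteroNetwork.from_edges(edges)
    logger.info("loaded network: %d nodes %s, %d edges %s", len(net),
                net.ntype_counts(), net.n_edges, net.class_counts())
    return net


def adjacency_matrix(net: HeteroNetwork) -> np.ndarray:
    """Binary symmetric adjacency with zero diagonal over the node order."""
    n = len(net)
    if n == 0:
        raise ValueError("empty network has no adjacency matrix")
    adj = np.zeros((n, n), dtype=float)
    for a, b, _ in net.edges:
        i, j = net.index[a.key], net.index[b.key]
        adj[i, j] = 1.0
        adj[j, i] = 1.0
    return adj
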