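"""Node attribute vectors.

miRNAs are encoded as 3-mer sliding-window frequency vectors over the RNA
alphabet; diseases are encoded as rows of a DAG-based semantic-similarity
matrix built from a parent-child hierarchy with a per-generation
contribution discount.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"


class AttributeComputationError(Exception):
    """Base class for attribute computation errors."""


class SequenceTooShortError(AttributeComputationError):
    pass


class AlphabetError(AttributeComputationError):
    pass


class DAGError(AttributeComputationError):
    """Cycle or structural defect in a disease hierarchy."""


def kmer_words(k: int = 3) -> list[str]:
    """All k-mers over {A,C,G,U} in lexicographic order."""
    return ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=k)]


def kmer_frequency(sequence: str, k: int = 3, *, on_invalid: str = "reject") -> np.ndarray:
    """Sliding-window k-mer frequency vector of an RNA sequence.

    The component for word ``w`` is ``count(w) / (L - k + 1)`` over the
    ``L - k + 1`` windows, so the vector sums to 1.  ``T`` is normalized to
    ``U`` so DNA-alphabet FASTA files work.

    Parameters
    ----------
    on_invalid
        ``"reject"`` raises :class:`AlphabetError` on characters outside
        {A,C,G,U,T}; ``"skip"`` drops them before windowing.
    """
    if on_invalid not in ("reject", "skip"):
        raise ValueError("on_invalid must be 'reject' or 'skip'")
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set(RNA_ALPHABET)
    if bad:
        if on_invalid == "reject":
            raise AlphabetError(f"invalid character(s) {sorted(bad)} in sequence")
        seq = "".join(c for c in seq if c in RNA_ALPHABET)
    n_windows = len(seq) - k + 1
    if n_windows < 1:
        raise SequenceTooShortError(
            f"sequence has {len(seq)} valid bases, need at least {k}")
    word_index = {w: i for i, w in enumerate(kmer_words(k))}
    vec = np.zeros(len(word_index))
    for i in range(n_windows):
        vec[word_index[seq[i:i + k]]] += 1.0
    return vec / n_windows


def load_mirna_sequences(fasta_path: str | Path, *, id_prefix_strip: str = "") -> dict[str, str]:
    """Read miRNA sequences from FASTA, keyed by record id.

    ``id_prefix_strip`` removes a fixed prefix from record ids so they can
    match network node ids.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        ident = rec.id
        if id_prefix_strip and ident.startswith(id_prefix_strip):
            ident = ident[len(id_prefix_strip):]
        seqs[ident] = str(rec.seq)
    return seqs


# ---------------------------------------------------------------------------
# Disease DAG semantic similarity
# ---------------------------------------------------------------------------

@dataclass
class DiseaseDAG:
    """Ancestor closure of one disease in a parent-child hierarchy.

    ``nodes`` is the disease plus every ancestor reachable through parent
    links; ``parents`` maps each node in the closure to its parents inside
    the closure.  The disease is the unique sink.
    """

    disease: str
    nodes: frozenset[str]
    parents: dict[str, frozenset[str]]

    @property
    def children(self) -> dict[str, set[str]]:
        ch: dict[str, set[str]] = {n: set() for n in self.nodes}
        for c, ps in self.parents.items():
            for p in ps:
                ch[p].add(c)
        return ch


def load_hierarchy(path: str | Path) -> dict[str, set[str]]:
    """Read a child<TAB>parent hierarchy table into a parent map."""
    parents: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DAGError(f"{path}:{lineno}: expected child<TAB>parent")
            child, parent = fields[0].strip(), fields[1].strip()
            parents.setdefault(child, set()).add(parent)
    return parents


def dag_for_disease(disease: str, parent_map: Mapping[str, set[str]]) -> DiseaseDAG:
    """Transitive ancestor closure of ``disease`` in the global hierarchy."""
    closure = {disease}
    frontier = [disease]
    while frontier:
        node = frontier.pop()
        for p in parent_map.get(node, ()):  # roots simply have no entry
            if p not in closure:
                closure.add(p)
                frontier.append(p)
    local_parents = {
        n: frozenset(p for p in parent_map.get(n, ()) if p in closure)
        for n in closure
    }
    return DiseaseDAG(disease=disease, nodes=frozenset(closure), parents=local_parents)


def semantic_value(dag: DiseaseDAG, delta: float = 0.5) -> tuple[float, dict[str, float]]:
    """Semantic value of a disease and the per-ancestor contributions.

    The disease itself contributes 1; every other node contributes the
    maximum of ``delta`` times the contribution of any of its children in
    the DAG.  The semantic value is the sum of all contributions.
    """
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must lie in (0, 1)")
    children = dag.children
    contrib: dict[str, float] = {}
    state: dict[str, int] = {}  # 1 = in progress, 2 = done

    def visit(node: str) -> float:
        if state.get(node) == 1:
            raise DAGError(f"cycle detected at {node!r} in DAG of {dag.disease!r}")
        if state.get(node) == 2:
            return contrib[node]
        state[node] = 1
        if node == dag.disease:
            value = 1.0
        else:
            kids = children[node]
            if not kids:
                raise DAGError(
                    f"{node!r} has no path to {dag.disease!r}; not a valid ancestor DAG")
            value = max(delta * visit(c) for c in kids)
        contrib[node] = value
        state[node] = 2
        return value

    for node in dag.nodes:
        visit(node)
    return float(sum(contrib.values())), contrib


def semantic_similarity(dag_i: DiseaseDAG, dag_j: DiseaseDAG, delta: float = 0.5) -> float:
    """Shared-ancestor similarity of two diseases, in [0, 1]."""
    dv_i, c_i = semantic_value(dag_i, delta)
    dv_j, c_j = semantic_value(dag_j, delta)
    shared = dag_i.nodes & dag_j.nodes
    if not shared:
        return 0.0
    return float(sum(c_i[t] + c_j[t] for t in shared) / (dv_i + dv_j))


@dataclass
class SemanticSimilarityMatrix:
    """Pairwise disease similarity; a disease's attribute vector is its row."""

    order: list[str]
    values: np.ndarray
    delta: float
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {d: i for i, d in enumerate(self.order)}

    def row(self, disease: str) -> np.ndarray:
        return self.values[self.index[disease]]


def semantic_similarity_matrix(
    dags: Mapping[str, DiseaseDAG],
    order: Sequence[str],
    delta: float = 0.5,
) -> SemanticSimilarityMatrix:
    """Pairwise semantic-similarity matrix over ``order``.

    Diseases without a DAG are excluded from the matrix with a warning; the
    caller decides between zero-filling and dropping at feature-assembly
    time.
    """
    missing = [d for d in order if d not in dags]
    if missing:
        logger.warning("no DAG for %d disease(s): %s ...", len(missing), missing[:5])
    used = [d for d in order if d in dags]
    contribs: dict[str, tuple[float, dict[str, float]]] = {
        d: semantic_value(dags[d], delta) for d in used
    }
    n = len(used)
    mat = np.eye(n)
    for i in range(n):
        dv_i, c_i = contribs[used[i]]
        for j in range(i + 1, n):
            dv_j, c_j = contribs[used[j]]
            shared = dags[used[i]].nodes & dags[used[j]].nodes
            ss = sum(c_i[t] + c_j[t] for t in shared) / (dv_i + dv_j) if shared else 0.0
            mat[i, j] = mat[j, i] = ss
    return SemanticSimilarityMatrix(order=used, values=mat, delta=delta)
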