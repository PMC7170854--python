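"""Seed-reproducible synthetic studies with planted miRNA-disease signal.

Nodes of all five types are partitioned into latent blocks; every
association class is drawn with a high within-block and low cross-block
edge probability.  True miRNA-disease associations are the within-block
draws; a configured fraction is written out as observed positives and the
rest is held back as recoverable truth.  Sequences carry a block-preferred
trinucleotide bias and disease DAGs share more ancestors within blocks
than across, so attribute features carry independent weak signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .attributes import kmer_words
from .hetnet import ASSOCIATION_CLASSES

TARGET_CLASS = "mirna-disease"


class SyntheticConfigError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    n_mirna: int = 100
    n_disease: int = 80
    n_protein: int = 120
    n_lncrna: int = 50
    n_drug: int = 40
    blocks: int = 5
    p_in: float = 0.25
    p_out: float = 0.01
    observed_fraction: float = 0.7
    seq_len: tuple[int, int] = (18, 30)
    dag_depth: tuple[int, int] = (2, 4)
    kmer_bias_copies: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise SyntheticConfigError(
                f"need 0 <= p_out < p_in <= 1, got p_out={self.p_out}, p_in={self.p_in}")
        for name in ("n_mirna", "n_disease", "n_protein", "n_lncrna", "n_drug", "blocks"):
            if getattr(self, name) < 1:
                raise SyntheticConfigError(f"{name} must be >= 1")
        if not (0.0 < self.observed_fraction <= 1.0):
            raise SyntheticConfigError("observed_fraction must lie in (0, 1]")

    @property
    def counts(self) -> dict[str, int]:
        return {"miRNA": self.n_mirna, "disease": self.n_disease,
                "protein": self.n_protein, "lncRNA": self.n_lncrna,
                "drug": self.n_drug}


@dataclass
class Study:
    """Paths to the generated files plus the generator's ground truth."""

    config: SyntheticConfig
    edge_paths: dict[str, Path]
    fasta_path: Path
    dag_path: Path
    positives_path: Path
    truth_path: Path
    blocks: dict[tuple[str, str], int]
    truth: list[tuple[str, str, bool]] = field(default_factory=list)  # (m, d, observed)

    @property
    def observed_positives(self) -> list[tuple[str, str]]:
        return [(m, d) for m, d, obs in self.truth if obs]

    @property
    def held_out_positives(self) -> list[tuple[str, str]]:
        return [(m, d) for m, d, obs in self.truth if not obs]


_PREFIX = {"miRNA": "mir", "disease": "dis", "protein": "pro",
           "lncRNA": "lnc", "drug": "drg"}


def _node_ids(ntype: str, n: int) -> list[str]:
    return [f"{_PREFIX[ntype]}{i:04d}" for i in range(n)]


def _sample_edges(ids_a: Sequence[str], blk_a: dict[str, int],
                  ids_b: Sequence[str], blk_b: dict[str, int],
                  p_in: float, p_out: float, rng: np.random.Generator,
                  same_type: bool) -> list[tuple[str, str]]:
    edges = []
    for i, a in enumerate(ids_a):
        start = i + 1 if same_type else 0
        for b in ids_b[start:]:
            p = p_in if blk_a[a] == blk_b[b] else p_out
            if rng.random() < p:
                edges.append((a, b))
    return edges


def generate_study(config: SyntheticConfig, out_dir: str | Path) -> Study:
    """Write all pipeline inputs for one synthetic study and return paths.

    Every output stream gets its own child generator spawned from the
    single study seed, so files are byte-identical across runs of the same
    configuration.
    """
    out = Path(out_dir)
    (out / "edges").mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_edges = np.random.default_rng(streams[0])
    rng_assoc = np.random.default_rng(streams[1])
    rng_seq = np.random.default_rng(streams[2])
    rng_dag = np.random.default_rng(streams[3])

    ids = {t: _node_ids(t, n) for t, n in config.counts.items()}
    # round-robin block assignment keeps every type represented in every block
    blocks = {t: {ident: i % config.blocks for i, ident in enumerate(ids[t])}
              for t in ids}
    block_table = {(ident, t): blocks[t][ident] for t in ids for ident in ids[t]}

    # -- background association classes ------------------------------------
    edge_paths: dict[str, Path] = {}
    for assoc_class in sorted(ASSOCIATION_CLASSES):
        if assoc_class == TARGET_CLASS:
            continue
        ta, tb = ASSOCIATION_CLASSES[assoc_class]
        edges = _sample_edges(ids[ta], blocks[ta], ids[tb], blocks[tb],
                              config.p_in, config.p_out, rng_edges, ta == tb)
        path = out / "edges" / f"{assoc_class}.tsv"
        with open(path, "w") as fh:
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")
        edge_paths[assoc_class] = path

    # -- planted miRNA-disease associations --------------------------------
    planted = []
    for m in ids["miRNA"]:
        for d in ids["disease"]:
            if blocks["miRNA"][m] == blocks["disease"][d] and rng_assoc.random() < config.p_in:
                planted.append((m, d))
    n_observed = int(np.floor(config.observed_fraction * len(planted)))
    observed_idx = set(rng_assoc.choice(len(planted), size=n_observed, replace=False).tolist())
    truth = [(m, d, i in observed_idx) for i, (m, d) in enumerate(planted)]

    positives_path = out / "positives.tsv"
    md_path = out / "edges" / f"{TARGET_CLASS}.tsv"
    with open(positives_path, "w") as pf, open(md_path, "w") as ef:
        for m, d, obs in truth:
            if obs:
                pf.write(f"{m}\t{d}\n")
                ef.write(f"{m}\t{d}\n")
    edge_paths[TARGET_CLASS] = md_path

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("mirna\tdisease\tobserved\n")
        for m, d, obs in truth:
            fh.write(f"{m}\t{d}\t{int(obs)}\n")

    # -- miRNA sequences with block-preferred 3-mer bias -------------------
    words = kmer_words(3)
    preferred = {b: words[(b * 7 + 1) % len(words)] for b in range(config.blocks)}
    fasta_path = out / "mirna.fasta"
    lo, hi = config.seq_len
    with open(fasta_path, "w") as fh:
        for m in ids["miRNA"]:
            length = int(rng_seq.integers(lo, hi + 1))
            seq = list("".join(rng_seq.choice(list("ACGU"), size=length)))
            word = preferred[blocks["miRNA"][m]]
            for _ in range(config.kmer_bias_copies):
                pos = int(rng_seq.integers(0, length - 2))
                seq[pos:pos + 3] = word
            fh.write(f">{m}\n{''.join(seq)}\n")

    # -- disease DAGs: per-block ancestor chains under a global root -------
    dag_path = out / "disease_dag.tsv"
    dmin, dmax = config.dag_depth
    rows = []
    for b in range(config.blocks):
        rows.append((f"blk{b}n0", "root"))
        for i in range(1, dmax):
            rows.append((f"blk{b}n{i}", f"blk{b}n{i-1}"))
    for d in ids["disease"]:
        b = blocks["disease"][d]
        level = int(rng_dag.integers(dmin, dmax + 1))  # chain depth above the disease
        anchor = f"blk{b}n{min(level, dmax) - 1}"
        if rng_dag.random() < 0.5:  # private intermediate adds cross-disease noise
            rows.append((f"{d}x", anchor))
            rows.append((d, f"{d}x"))
        else:
            rows.append((d, anchor))
    with open(dag_path, "w") as fh:
        for child, parent in rows:
            fh.write(f"{child}\t{parent}\n")

    meta = {"config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in vars(config).items()},
            "n_planted": len(planted), "n_observed": n_observed}
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    blocks_path = out / "blocks.tsv"
    with open(blocks_path, "w") as fh:
        fh.write("id\tntype\tblock\n")
        for t in sorted(ids):
            for ident in ids[t]:
                fh.write(f"{ident}\t{t}\t{blocks[t][ident]}\n")

    return Study(config=config, edge_paths=edge_paths, fasta_path=fasta_path,
                 dag_path=dag_path, positives_path=positives_path,
                 truth_path=truth_path, blocks=block_table, truth=truth)


def load_truth(path: str | Path) -> list[tuple[str, str, bool]]:
    truth = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            m, d, obs = line.rstrip("\n").split("\t")
            truth.append((m, d, bool(int(obs))))
    return truth


def truth_recovery_report(
    ranked: Sequence[tuple[str, str] | tuple[str, str, float]],
    truth: Sequence[tuple[str, str, bool]],
    ns: Sequence[int] = (10, 25, 50, 100),
) -> dict[int, float]:
    """Precision-at-N of a ranked prediction list against held-out truth.

    ``ranked`` must already exclude the observed positives (they were
    training data); violating that, or disjoint identifier spaces, raises.
    """
    observed = {(m, d) for m, d, obs in truth if obs}
    held_out = {(m, d) for m, d, obs in truth if not obs}
    ranked_pairs = [(t[0], t[1]) for t in ranked]
    truth_mirnas = {m for m, _, _ in truth}
    if truth and ranked_pairs and not ({m for m, _ in ranked_pairs} & truth_mirnas):
        raise AlignmentError("prediction and truth miRNA id spaces are disjoint")
    leaked = observed & set(ranked_pairs)
    if leaked:
        raise ValueError(f"{len(leaked)} observed positive(s) present in predictions")
    report = {}
    for n in ns:
        top = ranked_pairs[:n]
        report[n] = sum(1 for p in top if p in held_out) / n if top else 0.0
    return report
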