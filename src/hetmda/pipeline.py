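"""Stage orchestration and command-line interface.

Stages run in dependency order (simulate -> build-net -> embed ->
featurize -> cv / predict) with a content-hash check that skips stages
whose inputs and parameters are unchanged.  A single YAML config pins
every parameter and seed; CLI flags override config values.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import click
import numpy as np
import yaml

from . import assoc_model, attributes, autoencoder, grarep, hetnet, synthetic

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Feature assembly (glues attributes + autoencoder + embedding)
# ---------------------------------------------------------------------------

def build_feature_table(
    net: hetnet.HeteroNetwork,
    sequences: Mapping[str, str],
    parent_map: Mapping[str, set[str]],
    embedding: grarep.EmbeddingMatrix,
    delta: float = 0.5,
    sae_cfg: Mapping | None = None,
    missing: str = "zero",
) -> assoc_model.FeatureTable:
    """Fused per-node features for every miRNA and disease in the network.

    Raw attributes (64-dim 3-mer frequencies; |diseases|-dim similarity
    rows) are compressed through a per-class stacked autoencoder to a
    uniform dimension.  Nodes lacking a sequence or DAG are zero-filled or
    dropped according to ``missing``.
    """
    if missing not in ("zero", "drop"):
        raise ValueError("missing policy must be 'zero' or 'drop'")
    cfg = dict(sae_cfg or {})
    hidden = tuple(cfg.get("hidden_sizes", (64,)))
    epochs = int(cfg.get("epochs", 100))
    lr = float(cfg.get("lr", 1e-3))
    batch_size = int(cfg.get("batch_size", 32))
    seed = int(cfg.get("seed", 0))
    bypass = bool(cfg.get("bypass", False))

    mirna_ids = net.node_ids("miRNA")
    disease_ids = net.node_ids("disease")

    have_seq = [m for m in mirna_ids if m in sequences]
    n_missing_seq = len(mirna_ids) - len(have_seq)
    if n_missing_seq:
        logger.warning("%d miRNA(s) lack a sequence (%s policy)", n_missing_seq, missing)
    if missing == "drop":
        mirna_ids = have_seq
    kmer_raw = np.zeros((len(mirna_ids), 64))
    for i, m in enumerate(mirna_ids):
        if m in sequences:
            kmer_raw[i] = attributes.kmer_frequency(sequences[m])

    dags = {}
    for d in disease_ids:
        dag = attributes.dag_for_disease(d, parent_map)
        if len(dag.nodes) > 1 or d in parent_map:
            dags[d] = dag
    if missing == "drop":
        disease_ids = [d for d in disease_ids if d in dags]
    sim = attributes.semantic_similarity_matrix(dags, disease_ids, delta)
    dis_raw = np.zeros((len(disease_ids), len(sim.order)))
    for i, d in enumerate(disease_ids):
        if d in sim.index:
            dis_raw[i] = sim.row(d)

    if bypass:
        mirna_attr, dis_attr = kmer_raw, dis_raw
    else:
        m_model = autoencoder.sae_train(kmer_raw, hidden, epochs, lr, seed, batch_size)
        d_model = autoencoder.sae_train(dis_raw, hidden, epochs, lr, seed + 1, batch_size)
        mirna_attr = autoencoder.sae_encode(m_model, kmer_raw)
        dis_attr = autoencoder.sae_encode(d_model, dis_raw)

    mirna_beh = np.stack([embedding.row(net.position(m, "miRNA")) for m in mirna_ids]) \
        if mirna_ids else np.zeros((0, embedding.dim))
    dis_beh = np.stack([embedding.row(net.position(d, "disease")) for d in disease_ids]) \
        if disease_ids else np.zeros((0, embedding.dim))

    return assoc_model.FeatureTable(
        mirna_ids=mirna_ids, disease_ids=disease_ids,
        mirna_attr=mirna_attr, mirna_beh=mirna_beh,
        disease_attr=dis_attr, disease_beh=dis_beh)


# ---------------------------------------------------------------------------
# Archives
# ---------------------------------------------------------------------------

def save_embedding(path: str | Path, net: hetnet.HeteroNetwork,
                   emb: grarep.EmbeddingMatrix) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# K={emb.K} d={emb.d} seed={emb.seed}\n")
        for node, row in zip(net.nodes, emb.W):
            fh.write(f"{node.id}\t{node.ntype}\t"
                     + "\t".join(f"{v:.17g}" for v in row) + "\n")


def load_embedding(path: str | Path) -> tuple[list[tuple[str, str]], grarep.EmbeddingMatrix]:
    keys, rows = [], []
    header = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header = dict(kv.split("=") for kv in line[1:].split())
                continue
            parts = line.rstrip("\n").split("\t")
            keys.append((parts[0], parts[1]))
            rows.append([float(v) for v in parts[2:]])
    emb = grarep.EmbeddingMatrix(W=np.asarray(rows), K=int(header.get("K", 1)),
                                 d=int(header.get("d", len(rows[0]))),
                                 seed=int(header.get("seed", 0)))
    return keys, emb


def load_positives(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            m, d = line.rstrip("\n").split("\t")[:2]
            pairs.append((m, d))
    return pairs


# ---------------------------------------------------------------------------
# Hash-gated stage runner
# ---------------------------------------------------------------------------

def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_fingerprint(inputs: Sequence[Path], params: Mapping) -> str:
    payload = {
        "inputs": {str(p): _hash_file(Path(p)) for p in sorted(map(str, inputs))},
        "params": params,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _stage_up_to_date(meta_path: Path, fingerprint: str, outputs: Sequence[Path]) -> bool:
    if not meta_path.exists():
        return False
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError:
        return False
    if meta.get("fingerprint") != fingerprint:
        return False
    return all(Path(o).exists() and _hash_file(Path(o)) == h
               for o, h in meta.get("outputs", {}).items())


def _record_stage(meta_path: Path, fingerprint: str, outputs: Sequence[Path]) -> None:
    out_files: list[Path] = []
    for o in outputs:
        o = Path(o)
        out_files.extend(sorted(p for p in o.rglob("*") if p.is_file()) if o.is_dir() else [o])
    meta = {"fingerprint": fingerprint,
            "outputs": {str(p): _hash_file(p) for p in out_files}}
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "embed": {"K": 4, "d": 16},
    "attributes": {"delta": 0.5, "missing": "zero"},
    "sae": {"hidden_sizes": [64], "epochs": 100, "lr": 1e-3, "batch_size": 32},
    "cv": {"classifier": "RandomForest", "mode": "both", "k": 5, "threshold": 0.5},
}


def _merged_config(config: Mapping | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, Mapping) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def run_pipeline(config: Mapping, workdir: str | Path) -> dict:
    """Execute all configured stages in order; returns the CV report dict.

    Stages whose inputs (file hashes + parameters) are unchanged since the
    previous run are skipped; corrupting or deleting an output forces that
    stage and everything downstream to re-run.
    """
    cfg = _merged_config(config)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    t_start = time.perf_counter()
    # provenance: the fully merged config (all seeds included) rides along
    (workdir / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))

    # -- simulate ----------------------------------------------------------
    if "simulate" in cfg:
        sim_params = dict(cfg["simulate"])
        sim_params.setdefault("seed", seed)
        data_dir = workdir / "data"
        meta = workdir / "simulate.meta.json"
        fp = _stage_fingerprint([], sim_params)
        if _stage_up_to_date(meta, fp, [data_dir]):
            logger.info("simulate: up to date, skipping")
        else:
            logger.info("simulate: generating study")
            sim_params = {k: tuple(v) if isinstance(v, list) else v
                          for k, v in sim_params.items()}
            synthetic.generate_study(synthetic.SyntheticConfig(**sim_params), data_dir)
            _record_stage(meta, fp, [data_dir])
        edge_lists = {c: str(data_dir / "edges" / f"{c}.tsv")
                      for c in hetnet.ASSOCIATION_CLASSES}
        cfg.setdefault("network", {})["edge_lists"] = edge_lists
        cfg["attributes"].setdefault("fasta", str(data_dir / "mirna.fasta"))
        cfg["attributes"].setdefault("dag", str(data_dir / "disease_dag.tsv"))
        cfg["cv"].setdefault("positives", str(data_dir / "positives.tsv"))

    net_cfg = cfg.get("network", {})
    edge_lists = {c: Path(p) for c, p in net_cfg.get("edge_lists", {}).items()}
    if not edge_lists:
        raise FileNotFoundError("no edge lists configured and no simulate stage")
    for p in edge_lists.values():
        if not p.exists():
            raise FileNotFoundError(f"missing edge list: {p}")

    # -- build-net ---------------------------------------------------------
    net_dir = workdir / "net"
    meta = workdir / "build-net.meta.json"
    net_params = {"header": net_cfg.get("header", False),
                  "case_fold": net_cfg.get("case_fold", False)}
    fp = _stage_fingerprint(list(edge_lists.values()), net_params)
    if _stage_up_to_date(meta, fp, [net_dir]):
        logger.info("build-net: up to date, skipping")
        net = hetnet.HeteroNetwork.load(net_dir)
    else:
        logger.info("build-net: loading %d edge lists", len(edge_lists))
        t0 = time.perf_counter()
        net = hetnet.load_edge_lists(edge_lists, **net_params)
        net.save(net_dir)
        _record_stage(meta, fp, [net_dir])
        logger.info("build-net: %.2fs", time.perf_counter() - t0)

    # -- embed -------------------------------------------------------------
    emb_path = workdir / "embeddings.tsv"
    meta = workdir / "embed.meta.json"
    emb_params = {**cfg["embed"], "seed": seed}
    fp = _stage_fingerprint([net_dir / "edges.tsv"], emb_params)
    if _stage_up_to_date(meta, fp, [emb_path]):
        logger.info("embed: up to date, skipping")
        _, emb = load_embedding(emb_path)
    else:
        logger.info("embed: GraRep K=%s d=%s", cfg["embed"]["K"], cfg["embed"]["d"])
        t0 = time.perf_counter()
        adj = hetnet.adjacency_matrix(net)
        emb = grarep.grarep_embed(adj, K=int(cfg["embed"]["K"]),
                                  d=int(cfg["embed"]["d"]), seed=seed)
        save_embedding(emb_path, net, emb)
        _record_stage(meta, fp, [emb_path])
        logger.info("embed: %.2fs", time.perf_counter() - t0)

    # -- featurize ---------------------------------------------------------
    attr_cfg = cfg["attributes"]
    fasta = Path(attr_cfg["fasta"])
    dag = Path(attr_cfg["dag"])
    for p in (fasta, dag):
        if not p.exists():
            raise FileNotFoundError(f"missing input: {p}")
    feat_dir = workdir / "features"
    meta = workdir / "featurize.meta.json"
    sae_cfg = {**cfg["sae"], "seed": cfg["sae"].get("seed", seed)}
    feat_params = {"delta": attr_cfg["delta"], "missing": attr_cfg["missing"],
                   "sae": sae_cfg}
    fp = _stage_fingerprint([fasta, dag, emb_path, net_dir / "edges.tsv"], feat_params)
    if _stage_up_to_date(meta, fp, [feat_dir]):
        logger.info("featurize: up to date, skipping")
        features = assoc_model.FeatureTable.load(feat_dir)
    else:
        logger.info("featurize: attributes + SAE encoding")
        t0 = time.perf_counter()
        sequences = attributes.load_mirna_sequences(fasta)
        parent_map = attributes.load_hierarchy(dag)
        features = build_feature_table(net, sequences, parent_map, emb,
                                       delta=float(attr_cfg["delta"]),
                                       sae_cfg=sae_cfg,
                                       missing=attr_cfg["missing"])
        features.save(feat_dir)
        _record_stage(meta, fp, [feat_dir])
        logger.info("featurize: %.2fs", time.perf_counter() - t0)

    # -- cv ----------------------------------------------------------------
    cv_cfg = cfg["cv"]
    positives_path = Path(cv_cfg["positives"])
    if not positives_path.exists():
        raise FileNotFoundError(f"missing positives: {positives_path}")
    report_path = workdir / "report.json"
    meta = workdir / "cv.meta.json"
    cv_params = {k: cv_cfg[k] for k in ("classifier", "mode", "k", "threshold")}
    cv_params["seed"] = seed
    fp = _stage_fingerprint([positives_path, *sorted((feat_dir).glob("*.tsv"))], cv_params)
    if _stage_up_to_date(meta, fp, [report_path]):
        logger.info("cv: up to date, skipping")
        return json.loads(report_path.read_text())
    logger.info("cv: %s-fold cross-validation with %s",
                cv_cfg["k"], cv_cfg["classifier"])
    positives = load_positives(positives_path)
    dataset = assoc_model.build_pair_dataset(positives, features,
                                             mode=cv_cfg["mode"], seed=seed)
    report = assoc_model.cross_validate(dataset, classifier=cv_cfg["classifier"],
                                        k=int(cv_cfg["k"]), seed=seed,
                                        threshold=float(cv_cfg["threshold"]))
    report.to_json(report_path)
    report.export_curves(workdir / "curves")
    _record_stage(meta, fp, [report_path])
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t_start)
    return report.to_dict()


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _load_yaml(path: str | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


@click.group()
def main() -> None:
    """Heterogeneous-network miRNA-disease association prediction."""
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--out", "out_dir", required=True, type=click.Path())
def simulate(config_path, seed, out_dir):
    """Generate a synthetic study into OUT."""
    cfg = _load_yaml(config_path).get("simulate", {})
    if seed is not None:
        cfg["seed"] = seed
    cfg = {k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()}
    synthetic.generate_study(synthetic.SyntheticConfig(**cfg), out_dir)
    click.echo(f"study written to {out_dir}")


@main.command("build-net")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
def build_net(config_path, out_dir):
    """Load the configured edge lists and save the unified network."""
    cfg = _load_yaml(config_path)
    net_cfg = cfg.get("network", {})
    net = hetnet.load_edge_lists(net_cfg["edge_lists"],
                                 header=net_cfg.get("header", False),
                                 case_fold=net_cfg.get("case_fold", False))
    net.save(out_dir)
    click.echo(f"network: {len(net)} nodes, {net.n_edges} edges -> {out_dir}")


@main.command()
@click.option("--net", "net_dir", required=True, type=click.Path(exists=True))
@click.option("--K", "K", type=int, default=4, show_default=True)
@click.option("--dim-per-order", "d", type=int, default=16, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def embed(net_dir, K, d, seed, out_path):
    """Compute GraRep behavior embeddings for a saved network."""
    net = hetnet.HeteroNetwork.load(net_dir)
    emb = grarep.grarep_embed(hetnet.adjacency_matrix(net), K=K, d=d, seed=seed)
    save_embedding(out_path, net, emb)
    click.echo(f"embeddings: {emb.W.shape} -> {out_path}")


@main.command()
@click.option("--net", "net_dir", required=True, type=click.Path(exists=True))
@click.option("--fasta", required=True, type=click.Path(exists=True))
@click.option("--dag", required=True, type=click.Path(exists=True))
@click.option("--embeddings", required=True, type=click.Path(exists=True))
@click.option("--delta", type=float, default=0.5, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def featurize(net_dir, fasta, dag, embeddings, delta, seed, out_dir):
    """Compute fused attribute+behavior features for miRNAs and diseases."""
    net = hetnet.HeteroNetwork.load(net_dir)
    _, emb = load_embedding(embeddings)
    features = build_feature_table(net, attributes.load_mirna_sequences(fasta),
                                   attributes.load_hierarchy(dag), emb,
                                   delta=delta, sae_cfg={"seed": seed})
    features.save(out_dir)
    click.echo(f"features -> {out_dir}")


@main.command()
@click.option("--features", "feat_dir", required=True, type=click.Path(exists=True))
@click.option("--positives", required=True, type=click.Path(exists=True))
@click.option("--classifier", default="RandomForest", show_default=True,
              type=click.Choice(assoc_model.CLASSIFIERS))
@click.option("--mode", default="both", show_default=True,
              type=click.Choice(assoc_model.MODES))
@click.option("--k", type=int, default=5, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--report", "report_path", required=True, type=click.Path())
def cv(feat_dir, positives, classifier, mode, k, seed, report_path):
    """Cross-validate the pair classifier and write a JSON report."""
    features = assoc_model.FeatureTable.load(feat_dir)
    dataset = assoc_model.build_pair_dataset(load_positives(positives), features,
                                             mode=mode, seed=seed)
    report = assoc_model.cross_validate(dataset, classifier=classifier, k=k, seed=seed)
    report.to_json(report_path)
    report.export_curves(report_path)
    mean = report.mean
    click.echo("  ".join(f"{m}={mean[m]:.4f}" for m in assoc_model.SCALAR_METRICS))


@main.command()
@click.option("--features", "feat_dir", required=True, type=click.Path(exists=True))
@click.option("--positives", required=True, type=click.Path(exists=True))
@click.option("--disease", required=True)
@click.option("--classifier", default="RandomForest", show_default=True,
              type=click.Choice(assoc_model.CLASSIFIERS))
@click.option("--mode", default="both", show_default=True,
              type=click.Choice(assoc_model.MODES))
@click.option("--top", type=int, default=50, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def predict(feat_dir, positives, disease, classifier, mode, top, seed, out_path):
    """Rank candidate miRNAs for one disease, excluding training pairs."""
    features = assoc_model.FeatureTable.load(feat_dir)
    pos = load_positives(positives)
    dataset = assoc_model.build_pair_dataset(pos, features, mode=mode, seed=seed)
    model = assoc_model.train_classifier(classifier, dataset.X, dataset.y, seed=seed)
    ranked = assoc_model.rank_candidates(disease, model, features, pos,
                                         mode=mode, top=top)
    with open(out_path, "w") as fh:
        fh.write("mirna\tscore\n")
        for m, s in ranked:
            fh.write(f"{m}\t{s:.17g}\n")
    click.echo(f"top {len(ranked)} candidates -> {out_path}")


@main.command("run-all")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--out", "workdir", required=True, type=click.Path())
def run_all(config_path, seed, workdir):
    """Run every configured stage in dependency order."""
    cfg = _load_yaml(config_path)
    if seed is not None:
        cfg["seed"] = seed
    report = run_pipeline(cfg, workdir)
    mean = report["mean"]
    click.echo("  ".join(f"{m}={mean[m]:.4f}" for m in assoc_model.SCALAR_METRICS))


if __name__ == "__main__":
    main()
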