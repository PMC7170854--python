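"""Pair features, negative sampling, cross-validated classification, ranking.

miRNA and disease nodes are represented by the concatenation of their
encoded attribute vector and their network-embedding (behavior) vector;
a labelled pair sample concatenates the two node vectors.  Negatives are
drawn uniformly from unlabelled pairs, matched in count to the positives,
and evaluated under seeded k-fold cross-validation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)
from sklearn.model_selection import KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

MODES = ("attribute", "behavior", "both")
CLASSIFIERS = ("RandomForest", "DecisionTree", "KNN", "NaiveBayes")


class AssocModelError(Exception):
    pass


class InsufficientNegativesError(AssocModelError):
    pass


class DegenerateDataError(AssocModelError):
    pass


# ---------------------------------------------------------------------------
# Node feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Per-node attribute and behavior vectors for miRNAs and diseases.

    Attribute vectors are the autoencoder-compressed node attributes;
    behavior vectors are the embedding rows.  Nodes lacking an attribute
    source are zero-filled (or dropped upstream, per config).
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    mirna_attr: np.ndarray     # (n_mirna, attr_dim)
    mirna_beh: np.ndarray      # (n_mirna, beh_dim)
    disease_attr: np.ndarray   # (n_disease, attr_dim)
    disease_beh: np.ndarray    # (n_disease, beh_dim)
    _m_index: dict[str, int] = field(init=False)
    _d_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self._m_index = {m: i for i, m in enumerate(self.mirna_ids)}
        self._d_index = {d: i for i, d in enumerate(self.disease_ids)}

    def node_vector(self, node_id: str, ntype: str, mode: str = "both") -> np.ndarray:
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        if ntype == "miRNA":
            i = self._m_index[node_id]
            attr, beh = self.mirna_attr[i], self.mirna_beh[i]
        elif ntype == "disease":
            i = self._d_index[node_id]
            attr, beh = self.disease_attr[i], self.disease_beh[i]
        else:
            raise KeyError(f"no features for node type {ntype!r}")
        if mode == "attribute":
            return attr
        if mode == "behavior":
            return beh
        return np.concatenate([attr, beh])

    def pair_vector(self, mirna_id: str, disease_id: str, mode: str = "both") -> np.ndarray:
        return np.concatenate([
            self.node_vector(mirna_id, "miRNA", mode),
            self.node_vector(disease_id, "disease", mode),
        ])

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, ids, arr in (
            ("mirna_attr", self.mirna_ids, self.mirna_attr),
            ("mirna_beh", self.mirna_ids, self.mirna_beh),
            ("disease_attr", self.disease_ids, self.disease_attr),
            ("disease_beh", self.disease_ids, self.disease_beh),
        ):
            with open(path / f"{name}.tsv", "w") as fh:
                for ident, row in zip(ids, arr):
                    fh.write(ident + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
        meta = {"n_mirna": len(self.mirna_ids), "n_disease": len(self.disease_ids),
                "attr_dim": int(self.mirna_attr.shape[1]),
                "beh_dim": int(self.mirna_beh.shape[1])}
        (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)

        def read(name: str) -> tuple[list[str], np.ndarray]:
            ids, rows = [], []
            with open(path / f"{name}.tsv") as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    ids.append(parts[0])
                    rows.append([float(v) for v in parts[1:]])
            return ids, np.asarray(rows)

        m_ids, m_attr = read("mirna_attr")
        _, m_beh = read("mirna_beh")
        d_ids, d_attr = read("disease_attr")
        _, d_beh = read("disease_beh")
        return cls(mirna_ids=m_ids, disease_ids=d_ids, mirna_attr=m_attr,
                   mirna_beh=m_beh, disease_attr=d_attr, disease_beh=d_beh)


# ---------------------------------------------------------------------------
# Pair dataset
# ---------------------------------------------------------------------------

@dataclass
class PairDataset:
    """Labelled (miRNA, disease) samples with feature vectors and folds."""

    pairs: list[tuple[str, str]]
    X: np.ndarray
    y: np.ndarray
    mode: str
    seed: int
    folds: np.ndarray | None = None


def build_pair_dataset(
    positives: Sequence[tuple[str, str]],
    features: FeatureTable,
    mode: str = "both",
    seed: int = 0,
) -> PairDataset:
    """Positives plus an equal number of uniformly sampled negatives.

    The negative universe is every featured miRNA x disease pair that is
    not a positive; sampling is without replacement and reproducible under
    ``seed``.
    """
    pos = sorted(set((m, d) for m, d in positives))
    for m, d in pos:
        if m not in features._m_index or d not in features._d_index:
            raise KeyError(f"positive pair ({m!r}, {d!r}) lacks features")
    pos_set = set(pos)
    universe = [(m, d) for m in features.mirna_ids for d in features.disease_ids
                if (m, d) not in pos_set]
    if len(pos) > len(universe):
        raise InsufficientNegativesError(
            f"{len(pos)} positives but only {len(universe)} candidate negatives")
    rng = np.random.default_rng(seed)
    neg_idx = rng.choice(len(universe), size=len(pos), replace=False)
    negatives = [universe[i] for i in sorted(neg_idx)]
    pairs = pos + negatives
    y = np.array([1] * len(pos) + [0] * len(negatives))
    X = np.stack([features.pair_vector(m, d, mode) for m, d in pairs])
    return PairDataset(pairs=pairs, X=X, y=y, mode=mode, seed=seed)


def kfold_split(dataset: PairDataset, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random partition into k folds of near-equal size (assigned in place)."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(dataset.y) < k:
        raise ValueError("fewer samples than folds")
    folds = np.empty(len(dataset.y), dtype=int)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold_id, (_, test_idx) in enumerate(splitter.split(dataset.X)):
        folds[test_idx] = fold_id
    dataset.folds = folds
    return folds


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def make_classifier(kind: str, hyperparams: Mapping | None = None, seed: int = 0):
    params = dict(hyperparams or {})
    if kind == "RandomForest":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, **params)
    if kind == "DecisionTree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if kind == "KNN":
        params.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**params)
    if kind == "NaiveBayes":
        return GaussianNB(**params)
    raise ValueError(f"unknown classifier kind {kind!r}; expected one of {CLASSIFIERS}")


def train_classifier(kind: str, X: np.ndarray, y: np.ndarray,
                     hyperparams: Mapping | None = None, seed: int = 0):
    """Fit a classifier exposing a positive-class score via predict_proba."""
    if len(y) == 0:
        raise DegenerateDataError("empty training set")
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training set contains a single class")
    model = make_classifier(kind, hyperparams, seed)
    model.fit(X, y)
    return model


def positive_scores(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    pos_col = list(model.classes_).index(1)
    return proba[:, pos_col]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

SCALAR_METRICS = ("Acc", "Prec", "Sen", "Spec", "MCC", "AUC", "AUPR")


def compute_metrics(scores: np.ndarray, y: np.ndarray, threshold: float = 0.5) -> dict:
    """Confusion-matrix metrics at ``threshold`` plus AUC/AUPR over scores.

    Undefined ratios (zero denominators) are reported as NaN with a warning
    rather than silently as 0.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
            return float("nan")
        return num / den

    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out = {
        "Acc": (tp + tn) / len(y),
        "Prec": ratio(tp, tp + fp, "precision"),
        "Sen": ratio(tp, tp + fn, "sensitivity"),
        "Spec": ratio(tn, tn + fp, "specificity"),
        "MCC": ratio(tp * tn - fp * fn, mcc_den, "MCC"),
        "TP": tp, "TN": tn, "FP": fp, "FN": fn,
    }
    if len(np.unique(y)) < 2:
        warnings.warn("AUC/AUPR undefined with a single class; reporting NaN")
        out["AUC"] = out["AUPR"] = float("nan")
        out["roc"] = out["pr"] = None
    else:
        out["AUC"] = float(roc_auc_score(y, scores))
        out["AUPR"] = float(average_precision_score(y, scores))
        fpr, tpr, _ = roc_curve(y, scores)
        prec, rec, _ = precision_recall_curve(y, scores)
        out["roc"] = (fpr, tpr)
        out["pr"] = (prec, rec)
    return out


def evaluate(model, X: np.ndarray, y: np.ndarray, threshold: float = 0.5) -> dict:
    """Score a fitted model on a test set and compute all metrics."""
    return compute_metrics(positive_scores(model, X), y, threshold)


@dataclass
class MetricsReport:
    """Per-fold metrics plus their mean and standard deviation."""

    per_fold: list[dict]
    classifier: str
    mode: str
    seed: int

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(np.mean([f[m] for f in self.per_fold])) for m in SCALAR_METRICS}

    @property
    def std(self) -> dict[str, float]:
        return {m: float(np.std([f[m] for f in self.per_fold])) for m in SCALAR_METRICS}

    def to_dict(self) -> dict:
        folds = [{m: f[m] for m in SCALAR_METRICS} for f in self.per_fold]
        return {"classifier": self.classifier, "mode": self.mode, "seed": self.seed,
                "folds": folds, "mean": self.mean, "std": self.std}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def export_curves(self, prefix: str | Path) -> None:
        """Write per-fold ROC and PR curve points as TSV for plotting."""
        with open(f"{prefix}.roc.tsv", "w") as fh:
            fh.write("fold\tfpr\ttpr\n")
            for i, fold in enumerate(self.per_fold):
                if fold.get("roc") is None:
                    continue
                for fpr, tpr in zip(*fold["roc"]):
                    fh.write(f"{i}\t{fpr:.17g}\t{tpr:.17g}\n")
        with open(f"{prefix}.pr.tsv", "w") as fh:
            fh.write("fold\trecall\tprecision\n")
            for i, fold in enumerate(self.per_fold):
                if fold.get("pr") is None:
                    continue
                prec, rec = fold["pr"]
                for r, p in zip(rec, prec):
                    fh.write(f"{i}\t{r:.17g}\t{p:.17g}\n")


def cross_validate(
    dataset: PairDataset,
    classifier: str = "RandomForest",
    k: int = 5,
    seed: int = 0,
    hyperparams: Mapping | None = None,
    threshold: float = 0.5,
) -> MetricsReport:
    """k-fold cross-validation with per-fold metrics and mean +/- std."""
    folds = dataset.folds if dataset.folds is not None else kfold_split(dataset, k, seed)
    per_fold = []
    for fold_id in range(int(folds.max()) + 1):
        test = folds == fold_id
        model = train_classifier(classifier, dataset.X[~test], dataset.y[~test],
                                 hyperparams, seed)
        per_fold.append(evaluate(model, dataset.X[test], dataset.y[test], threshold))
    return MetricsReport(per_fold=per_fold, classifier=classifier,
                         mode=dataset.mode, seed=seed)


# ---------------------------------------------------------------------------
# Candidate ranking
# ---------------------------------------------------------------------------

def rank_candidates(
    disease_id: str,
    model,
    features: FeatureTable,
    training_positives: Sequence[tuple[str, str]],
    mode: str = "both",
    top: int | None = None,
) -> list[tuple[str, float]]:
    """Score every featured miRNA against ``disease_id``, excluding pairs
    already in the training positives; descending score, ties broken by id."""
    if disease_id not in features._d_index:
        raise KeyError(f"unknown disease id {disease_id!r}")
    known = {m for m, d in training_positives if d == disease_id}
    candidates = [m for m in features.mirna_ids if m not in known]
    if not candidates:
        return []
    X = np.stack([features.pair_vector(m, disease_id, mode) for m in candidates])
    scores = positive_scores(model, X)
    ranked = sorted(zip(candidates, scores), key=lambda t: (-t[1], t[0]))
    return ranked[:top] if top is not None else ranked


def rank_all_pairs(
    model,
    features: FeatureTable,
    training_positives: Sequence[tuple[str, str]],
    mode: str = "both",
) -> list[tuple[str, str, float]]:
    """Global ranking of every unobserved miRNA-disease pair."""
    pos_set = set(training_positives)
    pairs = [(m, d) for m in features.mirna_ids for d in features.disease_ids
             if (m, d) not in pos_set]
    X = np.stack([features.pair_vector(m, d, mode) for m, d in pairs])
    scores = positive_scores(model, X)
    return sorted(((m, d, s) for (m, d), s in zip(pairs, scores)),
                  key=lambda t: (-t[2], t[0], t[1]))
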