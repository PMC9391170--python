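"""Classification metrics, SMOTE rebalancing, cross-validation, and the
end-to-end experiment driver.

The experiment protocol mirrors a typical clinical-tabular study: build
the severity-band graph from the reference ranges, train translational
embeddings and report their link-prediction quality, encode every patient
as a relation matrix, rebalance the (heavily negative-skewed) training
portion with SMOTE, train the attention/CNN classifier, and report
accuracy, recall and F1 with the diseased class as positive — either on a
single stratified 80/20 split or across stratified k folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.metrics.pairwise import nan_euclidean_distances
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from . import embed as _embed
from . import encoder as _encoder
from . import kg as _kg
from . import sac as _sac

__all__ = [
    "MetricReport",
    "ExperimentConfig",
    "metrics",
    "smote",
    "kfold_split",
    "run_experiment",
]


@dataclass
class MetricReport:
    """Binary classification summary; the diseased class (label 1) is the
    positive class for recall and F1."""

    accuracy: float
    recall: float
    f1: float
    confusion: np.ndarray  # rows = true (neg, pos), cols = predicted

    def to_dict(self) -> dict[str, Any]:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
        }


def metrics(y_true, y_pred) -> MetricReport:
    """Accuracy, recall and F1 from binary labels (F1 = 0 when TP = 0)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    n = len(y_true)
    accuracy = (tp + tn) / n
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    confusion = np.array([[tn, fp], [fn, tp]])
    return MetricReport(accuracy=accuracy, recall=recall, f1=f1, confusion=confusion)


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to exact balance.

    Each synthetic row is x + u (x_nn − x) with u ~ uniform(0, 1) and x_nn
    one of x's k nearest minority neighbors (Euclidean; NaN cells are
    ignored in the distance and propagate into synthetic rows, so missing
    stays missing).  Majority rows are returned untouched; already
    balanced input is returned unchanged.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    counts = {c: int((y == c).sum()) for c in np.unique(y)}
    if len(counts) != 2:
        raise ValueError("smote expects exactly two classes")
    minority = min(counts, key=counts.get)
    majority = max(counts, key=lambda c: (counts[c], c != minority))
    n_min, n_maj = counts[minority], counts[majority]
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min < k_neighbors + 1:
        raise ValueError(
            f"minority class has {n_min} rows; needs >= k_neighbors+1 = {k_neighbors + 1}"
        )
    rng = np.random.default_rng(seed)
    Xm = X[y == minority]
    D = nan_euclidean_distances(Xm, Xm)
    np.fill_diagonal(D, np.inf)
    nn_idx = np.argsort(D, axis=1)[:, :k_neighbors]
    n_new = n_maj - n_min
    base = rng.integers(n_min, size=n_new)
    pick = rng.integers(k_neighbors, size=n_new)
    u = rng.random(n_new)
    x0 = Xm[base]
    x1 = Xm[nn_idx[base, pick]]
    synth = x0 + u[:, None] * (x1 - x0)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority)])
    return X_out, y_out


def kfold_split(
    n: int,
    k: int = 5,
    labels: np.ndarray | None = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """k disjoint index folds partitioning range(n); stratified on
    ``labels`` when given.  Deterministic given ``seed``."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    if labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(n), np.asarray(labels))]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n))]


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Everything one end-to-end run needs.

    ``representation`` chooses between the knowledge encoding ("knowledge",
    relation matrices from trained graph embeddings) and the ablation
    ("learned", an entity embedding table trained jointly with the
    classifier).  ``cv_folds=None`` runs a single stratified 80/20 split.
    """

    ranges: list[_kg.ReferenceRange]
    records: list[_encoder.PatientRecord]
    model_kind: str = "transH"
    dim_k: int = 64
    bands: _kg.BandParams = field(default_factory=_kg.BandParams)
    embed_config: _embed.TrainConfig = field(default_factory=_embed.TrainConfig)
    sac_config: _sac.SACConfig | None = None
    representation: str = "knowledge"
    use_smote: bool = True
    resample_test: bool = False
    cv_folds: int | None = None
    test_fraction: float = 0.2
    ranking_side: str = "head"
    seed: int = 0


def _fit_eval_fold(
    cfg: ExperimentConfig,
    catalog: _kg.EntityCatalog,
    params: _embed.TransParams | None,
    order: list[str],
    raw: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    sac_config: _sac.SACConfig,
    fold_seed: int,
) -> dict[str, Any]:
    """Train and evaluate the classifier on one train/test index split.

    SMOTE runs in raw measurement space on the training portion (held-out
    rows too only when ``resample_test``); synthetic rows then pass
    through the ordinary encoder.
    """
    Xtr_raw, ytr = raw[train_idx], y[train_idx]
    Xte_raw, yte = raw[test_idx], y[test_idx]
    if cfg.use_smote and len(np.unique(ytr)) == 2 and (ytr == 1).sum() != (ytr == 0).sum():
        Xtr_raw, ytr = smote(Xtr_raw, ytr, seed=fold_seed)
    if cfg.resample_test and len(np.unique(yte)) == 2 and (yte == 1).sum() != (yte == 0).sum():
        Xte_raw, yte = smote(Xte_raw, yte, seed=fold_seed + 1)

    def to_records(mat: np.ndarray) -> list[_encoder.PatientRecord]:
        return [
            _encoder.PatientRecord(
                values={ind: (None if np.isnan(v) else float(v)) for ind, v in zip(order, row)}
            )
            for row in mat
        ]

    if cfg.representation == "knowledge":
        Xtr = _encoder.encode_dataset(to_records(Xtr_raw), catalog, params, order)
        Xte = _encoder.encode_dataset(to_records(Xte_raw), catalog, params, order)
        n_entities = None
    elif cfg.representation == "learned":
        Xtr = _encoder.matched_entity_ids(to_records(Xtr_raw), catalog, order)
        Xte = _encoder.matched_entity_ids(to_records(Xte_raw), catalog, order)
        n_entities = catalog.n_entities
    else:
        raise ValueError(f"unknown representation {cfg.representation!r}")

    model = _sac.train_classifier(
        Xtr, ytr, sac_config, validation=(Xte, yte), n_entities=n_entities
    )
    pred = model.predict_label(Xte)
    rep = metrics(yte, pred)
    return {
        "n_train": int(len(ytr)),
        "n_test": int(len(yte)),
        "metrics": rep.to_dict(),
        "loss_history": model.history,
        "_model": model,
        "_X_test": Xte,
    }


def run_experiment(cfg: ExperimentConfig) -> dict[str, Any]:
    """Run the full pipeline and return a JSON-serializable report.

    Stages: build graph -> train embeddings -> link-prediction ranking ->
    encode patients -> (SMOTE) -> train classifier -> metrics.  With
    ``cv_folds`` set, the classifier stage runs per stratified fold and
    aggregate metrics are sample-weighted means; otherwise a single
    stratified 80/20 split is used.  Deterministic given ``cfg.seed``.
    """
    catalog, triples = _kg.build_graph(cfg.ranges, cfg.bands)
    order = [r.indicator for r in cfg.ranges]

    params = None
    ranking = None
    if cfg.representation == "knowledge":
        params = _embed.train(
            cfg.model_kind, triples, catalog, cfg.embed_config, dim_k=cfg.dim_k
        )
        ranking = _embed.evaluate_ranking(params, triples, catalog, cfg.ranking_side)

    y = np.array([r.label for r in cfg.records], dtype=int)
    raw = np.array(
        [[np.nan if r.values.get(ind) is None else r.values[ind] for ind in order]
         for r in cfg.records]
    )
    sac_config = cfg.sac_config or _sac.SACConfig(dim_k=cfg.dim_k, seed=cfg.seed)

    folds_out = []
    if cfg.cv_folds:
        folds = kfold_split(len(y), cfg.cv_folds, labels=y, seed=cfg.seed)
        all_idx = np.arange(len(y))
        for i, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            folds_out.append(
                _fit_eval_fold(cfg, catalog, params, order, raw, y,
                               train_idx, test_idx, sac_config, cfg.seed + i)
            )
    else:
        train_idx, test_idx = train_test_split(
            np.arange(len(y)), test_size=cfg.test_fraction, stratify=y,
            random_state=cfg.seed,
        )
        folds_out.append(
            _fit_eval_fold(cfg, catalog, params, order, raw, y,
                           train_idx, test_idx, sac_config, cfg.seed)
        )

    weights = np.array([f["n_test"] for f in folds_out], dtype=float)
    agg = {
        key: float(np.average([f["metrics"][key] for f in folds_out], weights=weights))
        for key in ("accuracy", "recall", "f1")
    }
    report: dict[str, Any] = {
        "config": {
            "model_kind": cfg.model_kind,
            "dim_k": cfg.dim_k,
            "representation": cfg.representation,
            "use_smote": cfg.use_smote,
            "resample_test": cfg.resample_test,
            "cv_folds": cfg.cv_folds,
            "seed": cfg.seed,
            "n_patients": len(cfg.records),
            "indicators": order,
        },
        "graph": {
            "n_entities": catalog.n_entities,
            "n_relations": len(catalog.relation_to_int),
            "n_triples": len(triples),
        },
        "ranking": None if ranking is None else {
            "mean_rank": ranking.mean_rank,
            "hit_at_10": ranking.hit_at_10,
        },
        "folds": [{k: v for k, v in f.items() if not k.startswith("_")} for f in folds_out],
        "aggregate": agg,
    }
    # non-serialized extras for programmatic use
    report["_models"] = [f["_model"] for f in folds_out]
    report["_X_tests"] = [f["_X_test"] for f in folds_out]
    report["_catalog"] = catalog
    report["_params"] = params
    return report
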