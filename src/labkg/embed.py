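"""Translational knowledge-graph embeddings (TransE, TransH, TransR).

All three models represent a relation as a translation in embedding space,
so that for a true fact (h, r, t) the translated head lands near the tail:

    TransE:  l_h + l_r ≈ l_t
    TransH:  proj_w(l_h) + l_r ≈ proj_w(l_t)   (projection onto the
             hyperplane with unit normal w_r)
    TransR:  M_r l_h + l_r ≈ M_r l_t           (relation-specific matrix)

The score of a candidate fact is the L1 or L2 length of the residual;
smaller means more plausible.  Training minimizes a margin-ranking loss
between true triples and uniformly corrupted ones, with Adam, entirely in
NumPy; the constraints (unit hyperplane normals, entity norms <= 1) are
re-imposed after every batch.  Link prediction quality is reported as Mean
Rank and Hit@10 over exhaustive entity corruption.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._optim import Adam as _Adam
from .kg import EntityCatalog, KnowledgeTriple

__all__ = [
    "TransParams",
    "TrainConfig",
    "RankingResult",
    "SamplingError",
    "score",
    "project_hyperplane",
    "negative_sample",
    "train",
    "rank_triple",
    "evaluate_ranking",
    "save_embeddings",
    "load_embeddings",
]

MODEL_KINDS = ("transE", "transH", "transR")
N_RELATIONS = 7


class SamplingError(RuntimeError):
    """Raised when a corrupted triple cannot be drawn."""


@dataclass
class TransParams:
    """Learned parameter tables of one translational model.

    ``entity_vectors`` is |entities| x k, ``relation_vectors`` 7 x k.
    TransH additionally carries unit ``hyperplane_normals`` (7 x k);
    TransR carries ``projection_matrices`` (7 x k x k, source and target
    dimension taken equal).
    """

    model_kind: str
    dim_k: int
    entity_vectors: np.ndarray
    relation_vectors: np.ndarray
    hyperplane_normals: np.ndarray | None = None
    projection_matrices: np.ndarray | None = None
    norm_order: int = 2

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.norm_order not in (1, 2):
            raise ValueError("norm_order must be 1 or 2")
        if self.entity_vectors.shape[1] != self.dim_k:
            raise ValueError("entity table width != dim_k")
        if self.relation_vectors.shape != (N_RELATIONS, self.dim_k):
            raise ValueError("relation table must be 7 x dim_k")
        if self.model_kind == "transH" and (
            self.hyperplane_normals is None
            or self.hyperplane_normals.shape != (N_RELATIONS, self.dim_k)
        ):
            raise ValueError("transH requires 7 x dim_k hyperplane normals")
        if self.model_kind == "transR" and (
            self.projection_matrices is None
            or self.projection_matrices.shape != (N_RELATIONS, self.dim_k, self.dim_k)
        ):
            raise ValueError("transR requires 7 x k x k projection matrices")

    @property
    def n_entities(self) -> int:
        return self.entity_vectors.shape[0]


@dataclass(frozen=True)
class TrainConfig:
    """Margin-ranking training hyperparameters for the embedding stage."""

    margin_gamma: float = 1.0
    epochs: int = 500
    batch_size: int = 128
    learning_rate: float = 1e-3
    negative_ratio: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin_gamma <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("margin, batch size and learning rate must be positive")
        if self.epochs < 0 or self.negative_ratio <= 0:
            raise ValueError("epochs must be >= 0, negative_ratio positive")


@dataclass
class RankingResult:
    """Link-prediction summary: MR = mean of the per-triple ranks,
    Hit@10 = percentage of ranks <= 10."""

    mean_rank: float
    hit_at_10: float
    per_triple_ranks: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def project_hyperplane(e: np.ndarray, w_r: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Project ``e`` onto the hyperplane with unit normal ``w_r``:
    e - (w_r . e) w_r.  The result is orthogonal to ``w_r``."""
    nrm = float(np.linalg.norm(w_r))
    if abs(nrm - 1.0) > tol:
        raise ValueError(f"hyperplane normal must be unit length, got |w|={nrm:.6g}")
    return e - (w_r @ e) * w_r


def _residual(params: TransParams, h_vec: np.ndarray, r: int, t_vec: np.ndarray) -> np.ndarray:
    """Translated-head-minus-tail residual for one (or a batch of) pairs.

    ``h_vec``/``t_vec`` may be (k,) or (B, k); broadcasting is supported so
    one side can be a single vector while the other is a batch.
    """
    lr = params.relation_vectors[r]
    if params.model_kind == "transE":
        return h_vec + lr - t_vec
    if params.model_kind == "transH":
        w = params.hyperplane_normals[r]
        ph = h_vec - np.outer(h_vec @ w, w) if h_vec.ndim == 2 else h_vec - (h_vec @ w) * w
        pt = t_vec - np.outer(t_vec @ w, w) if t_vec.ndim == 2 else t_vec - (t_vec @ w) * w
        return ph + lr - pt
    M = params.projection_matrices[r]
    return h_vec @ M.T + lr - t_vec @ M.T


def _norm(v: np.ndarray, order: int) -> np.ndarray:
    if order == 1:
        return np.abs(v).sum(axis=-1)
    return np.sqrt((v * v).sum(axis=-1))


def score(params: TransParams, h: int, r: int, t: int) -> float:
    """Dissimilarity of the fact (h, r, t): ||proj(l_h) + l_r - proj(l_t)||
    in the configured norm.  Lower is more plausible."""
    n = params.n_entities
    if not (0 <= h < n and 0 <= t < n):
        raise IndexError(f"entity id out of range (n={n})")
    if not (0 <= r < N_RELATIONS):
        raise IndexError("relation id out of range")
    v = _residual(params, params.entity_vectors[h], r, params.entity_vectors[t])
    return float(_norm(v, params.norm_order))


def _scores_all_candidates(
    params: TransParams, triple: KnowledgeTriple, side: str
) -> np.ndarray:
    """Scores of the triple with the given side replaced by every entity."""
    E = params.entity_vectors
    if side == "head":
        v = _residual(params, E, triple.relation, E[triple.tail])
    elif side == "tail":
        v = _residual(params, E[triple.head], triple.relation, E)
    else:
        raise ValueError("side must be 'head' or 'tail'")
    return _norm(v, params.norm_order)


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------

def negative_sample(
    triple: KnowledgeTriple,
    catalog: EntityCatalog,
    rng: np.random.Generator,
) -> KnowledgeTriple:
    """Corrupt one side of a true triple, never its relation.

    With probability 1/2 the head is replaced by a uniformly drawn
    indicator entity, otherwise the tail by a uniformly drawn value
    entity; the result is guaranteed to differ from the input.
    """
    corrupt_head = rng.random() < 0.5
    pool = catalog.indicator_ids() if corrupt_head else catalog.value_ids()
    keep = triple.head if corrupt_head else triple.tail
    candidates = [e for e in pool if e != keep]
    if not candidates:
        kind = "indicator" if corrupt_head else "value"
        raise SamplingError(f"cannot corrupt {kind} side: only one {kind} entity")
    pick = candidates[int(rng.integers(len(candidates)))]
    if corrupt_head:
        return KnowledgeTriple(pick, triple.relation, triple.tail)
    return KnowledgeTriple(triple.head, triple.relation, pick)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _init_params(
    model_kind: str, n_entities: int, dim_k: int, norm_order: int,
    rng: np.random.Generator,
) -> TransParams:
    bound = 6.0 / np.sqrt(dim_k)
    ent = rng.uniform(-bound, bound, size=(n_entities, dim_k))
    ent /= np.maximum(np.linalg.norm(ent, axis=1, keepdims=True), 1.0)
    rel = rng.uniform(-bound, bound, size=(N_RELATIONS, dim_k))
    rel /= np.linalg.norm(rel, axis=1, keepdims=True)
    normals = None
    projections = None
    if model_kind == "transH":
        normals = rng.normal(size=(N_RELATIONS, dim_k))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    if model_kind == "transR":
        projections = np.tile(np.eye(dim_k), (N_RELATIONS, 1, 1))
    return TransParams(
        model_kind=model_kind,
        dim_k=dim_k,
        entity_vectors=ent,
        relation_vectors=rel,
        hyperplane_normals=normals,
        projection_matrices=projections,
        norm_order=norm_order,
    )


def _residual_grad(v: np.ndarray, order: int) -> np.ndarray:
    """d||v||/dv, rows of a batch; safe at v = 0."""
    if order == 1:
        return np.sign(v)
    nrm = np.maximum(np.sqrt((v * v).sum(axis=1, keepdims=True)), 1e-12)
    return v / nrm


def train(
    model_kind: str,
    triples: list[KnowledgeTriple],
    catalog: EntityCatalog,
    config: TrainConfig = TrainConfig(),
    dim_k: int = 256,
    norm_order: int = 2,
) -> TransParams:
    """Fit a translational model by margin-ranking loss.

    Minimizes sum(max(0, score(pos) + gamma - score(neg))) over uniformly
    corrupted negatives with Adam.  After every batch, hyperplane normals
    are renormalized to unit length and entity norms clipped to <= 1.
    Deterministic given ``config.seed``.
    """
    if not triples:
        raise ValueError("cannot train on an empty triple list")
    rng = np.random.default_rng(config.seed)
    params = _init_params(model_kind, catalog.n_entities, dim_k, norm_order, rng)

    tables: dict[str, np.ndarray] = {
        "ent": params.entity_vectors,
        "rel": params.relation_vectors,
    }
    if params.hyperplane_normals is not None:
        tables["w"] = params.hyperplane_normals
    if params.projection_matrices is not None:
        tables["M"] = params.projection_matrices
    opt = _Adam(tables, config.learning_rate)

    heads = np.array([t.head for t in triples])
    rels = np.array([t.relation for t in triples])
    tails = np.array([t.tail for t in triples])
    n = len(triples)
    ind_pool = np.array(catalog.indicator_ids())
    val_pool = np.array(catalog.value_ids())

    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            h, r, t = heads[idx], rels[idx], tails[idx]
            # negative_ratio corrupted copies per positive; vectorized
            # uniform corruption (head from indicators or tail from values,
            # p = 1/2 each, redrawn until it differs from the original)
            h_rep = np.repeat(h, config.negative_ratio)
            r_rep = np.repeat(r, config.negative_ratio)
            t_rep = np.repeat(t, config.negative_ratio)
            nh = h_rep.copy()
            nt = t_rep.copy()
            corrupt_head = rng.random(len(h_rep)) < 0.5
            for mask, pool, orig, dest in (
                (corrupt_head, ind_pool, h_rep, nh),
                (~corrupt_head, val_pool, t_rep, nt),
            ):
                rows = np.where(mask)[0]
                if rows.size and pool.size < 2:
                    kind = "indicator" if pool is ind_pool else "value"
                    raise SamplingError(f"cannot corrupt: only one {kind} entity")
                while rows.size:
                    dest[rows] = pool[rng.integers(pool.size, size=rows.size)]
                    rows = rows[dest[rows] == orig[rows]]
            grads = _batch_grads(params, tables, h_rep, r_rep, t_rep, nh, nt,
                                 config.margin_gamma)
            if grads is not None:
                opt.step(tables, grads)
            # constraint projection after every step
            if "w" in tables:
                tables["w"] /= np.linalg.norm(tables["w"], axis=1, keepdims=True)
            norms = np.linalg.norm(tables["ent"], axis=1, keepdims=True)
            np.divide(tables["ent"], norms, out=tables["ent"], where=norms > 1.0)
    return params


def _batch_grads(
    params: TransParams,
    tables: dict[str, np.ndarray],
    h: np.ndarray, r: np.ndarray, t: np.ndarray,
    nh: np.ndarray, nt: np.ndarray,
    gamma: float,
) -> dict[str, np.ndarray] | None:
    """Gradients of the margin loss summed over a batch; None if inactive."""
    E, R = tables["ent"], tables["rel"]
    vp = _residual_rows(params, E[h], r, E[t])
    vn = _residual_rows(params, E[nh], r, E[nt])
    sp = _norm(vp, params.norm_order)
    sn = _norm(vn, params.norm_order)
    active = (sp + gamma - sn) > 0
    if not active.any():
        return None
    a = np.where(active)[0]
    grads = {k: np.zeros_like(v) for k, v in tables.items()}
    # d loss / d residual for positive (+1) and negative (-1) terms
    gp = _residual_grad(vp[a], params.norm_order)
    gn = -_residual_grad(vn[a], params.norm_order)
    for sign_pair, g in ((("pos"), gp), (("neg"), gn)):
        hh = h[a] if sign_pair == "pos" else nh[a]
        tt = t[a] if sign_pair == "pos" else nt[a]
        rr = r[a]
        _accumulate(params, tables, grads, hh, rr, tt, g)
    return grads


def _residual_rows(params: TransParams, hv: np.ndarray, r: np.ndarray, tv: np.ndarray) -> np.ndarray:
    """Residuals for a batch where the relation varies per row."""
    lr = params.relation_vectors[r]
    if params.model_kind == "transE":
        return hv + lr - tv
    if params.model_kind == "transH":
        w = params.hyperplane_normals[r]
        ph = hv - ((hv * w).sum(axis=1, keepdims=True)) * w
        pt = tv - ((tv * w).sum(axis=1, keepdims=True)) * w
        return ph + lr - pt
    M = params.projection_matrices[r]
    return np.einsum("bij,bj->bi", M, hv) + lr - np.einsum("bij,bj->bi", M, tv)


def _accumulate(
    params: TransParams,
    tables: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    h: np.ndarray, r: np.ndarray, t: np.ndarray,
    g: np.ndarray,
) -> None:
    """Scatter-add d loss/d residual back onto the parameter tables."""
    E = tables["ent"]
    if params.model_kind == "transE":
        np.add.at(grads["ent"], h, g)
        np.add.at(grads["ent"], t, -g)
    elif params.model_kind == "transH":
        w = tables["w"][r]
        g_perp = g - ((g * w).sum(axis=1, keepdims=True)) * w
        np.add.at(grads["ent"], h, g_perp)
        np.add.at(grads["ent"], t, -g_perp)
        u = E[h] - E[t]
        gw = -(((g * w).sum(axis=1, keepdims=True)) * u
               + ((u * w).sum(axis=1, keepdims=True)) * g)
        np.add.at(grads["w"], r, gw)
    else:  # transR
        M = tables["M"][r]
        gM = np.einsum("bji,bj->bi", M, g)  # M^T g
        np.add.at(grads["ent"], h, gM)
        np.add.at(grads["ent"], t, -gM)
        u = E[h] - E[t]
        np.add.at(grads["M"], r, np.einsum("bi,bj->bij", g, u))
    np.add.at(grads["rel"], r, g)


# ---------------------------------------------------------------------------
# Link-prediction evaluation
# ---------------------------------------------------------------------------

def rank_triple(
    params: TransParams,
    triple: KnowledgeTriple,
    catalog: EntityCatalog,
    corruption_side: str = "head",
) -> int:
    """Raw rank of the true triple among all entity corruptions of one side.

    Optimistic ties: rank = 1 + number of candidates scoring strictly
    below the true triple.
    """
    cand = _scores_all_candidates(params, triple, corruption_side)
    # read the true score out of the same batched computation so that
    # candidate-vs-true comparisons are exact, not rounding-dependent
    true_idx = triple.head if corruption_side == "head" else triple.tail
    return int(1 + (cand < cand[true_idx]).sum())


def evaluate_ranking(
    params: TransParams,
    test_triples: list[KnowledgeTriple],
    catalog: EntityCatalog,
    corruption_side: str = "head",
) -> RankingResult:
    """Mean Rank and Hit@10 over exhaustive corruption of one side."""
    if not test_triples:
        raise ValueError("empty test set")
    ranks = [rank_triple(params, t, catalog, corruption_side) for t in test_triples]
    mr = float(np.mean(ranks))
    hit = float(100.0 * np.mean([rk <= 10 for rk in ranks]))
    return RankingResult(mean_rank=mr, hit_at_10=hit, per_triple_ranks=ranks)


# ---------------------------------------------------------------------------
# Serialization (text tables + JSON metadata)
# ---------------------------------------------------------------------------

def save_embeddings(params: TransParams, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    meta = {
        "model_kind": params.model_kind,
        "dim_k": params.dim_k,
        "norm_order": params.norm_order,
        "n_entities": params.n_entities,
    }
    with open(os.path.join(outdir, "meta.json"), "w", encoding="utf-8") as f:
        json.dump(meta, f, indent=1)
    np.savetxt(os.path.join(outdir, "entities.tsv"), params.entity_vectors,
               delimiter="\t", fmt="%.17g")
    np.savetxt(os.path.join(outdir, "relations.tsv"), params.relation_vectors,
               delimiter="\t", fmt="%.17g")
    if params.hyperplane_normals is not None:
        np.savetxt(os.path.join(outdir, "normals.tsv"), params.hyperplane_normals,
                   delimiter="\t", fmt="%.17g")
    if params.projection_matrices is not None:
        flat = params.projection_matrices.reshape(N_RELATIONS, -1)
        np.savetxt(os.path.join(outdir, "projections.tsv"), flat,
                   delimiter="\t", fmt="%.17g")


def load_embeddings(indir: str) -> TransParams:
    with open(os.path.join(indir, "meta.json"), encoding="utf-8") as f:
        meta = json.load(f)
    ent = np.loadtxt(os.path.join(indir, "entities.tsv"), delimiter="\t", ndmin=2)
    rel = np.loadtxt(os.path.join(indir, "relations.tsv"), delimiter="\t", ndmin=2)
    normals = None
    projections = None
    npath = os.path.join(indir, "normals.tsv")
    if os.path.exists(npath):
        normals = np.loadtxt(npath, delimiter="\t", ndmin=2)
    ppath = os.path.join(indir, "projections.tsv")
    if os.path.exists(ppath):
        k = meta["dim_k"]
        projections = np.loadtxt(ppath, delimiter="\t", ndmin=2).reshape(N_RELATIONS, k, k)
    return TransParams(
        model_kind=meta["model_kind"],
        dim_k=meta["dim_k"],
        entity_vectors=ent,
        relation_vectors=rel,
        hyperplane_normals=normals,
        projection_matrices=projections,
        norm_order=meta["norm_order"],
    )
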