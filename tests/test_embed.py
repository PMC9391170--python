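import numpy as np
import pytest

from labkg import (
    KnowledgeTriple,
    TrainConfig,
    TransParams,
    evaluate_ranking,
    negative_sample,
    project_hyperplane,
    rank_triple,
    score,
    train,
)
from labkg.embed import (
    N_RELATIONS,
    SamplingError,
    _init_params,
    load_embeddings,
    save_embeddings,
)


def _random_params(model_kind, n_entities, k, rng, norm_order=2):
    p = _init_params(model_kind, n_entities, k, norm_order, rng)
    if model_kind == "transR":
        # random, not identity, so TransR is genuinely exercised
        p.projection_matrices = rng.normal(size=(N_RELATIONS, k, k)) / np.sqrt(k)
    return p


def brute_force_rank(params, triple, side):
    """Independent oracle: score every corruption with raw NumPy algebra
    (its own projection code), sort ascending, optimistic ties."""
    E, R = params.entity_vectors, params.relation_vectors
    r = triple.relation

    def one_score(h, t):
        lh, lt, lr = E[h], E[t], R[r]
        if params.model_kind == "transH":
            w = params.hyperplane_normals[r]
            lh = lh - np.dot(w, lh) * w
            lt = lt - np.dot(w, lt) * w
        elif params.model_kind == "transR":
            M = params.projection_matrices[r]
            lh, lt = M @ lh, M @ lt
        diff = lh + lr - lt
        return np.abs(diff).sum() if params.norm_order == 1 else np.linalg.norm(diff)

    true = one_score(triple.head, triple.tail)
    cands = []
    for e in range(params.n_entities):
        if side == "head":
            cands.append(one_score(e, triple.tail))
        else:
            cands.append(one_score(triple.head, e))
    return 1 + sum(1 for c in cands if c < true)


class TestScore:
    def test_transE_exact_translation_scores_zero(self, rng):
        p = _random_params("transE", 5, 8, rng)
        p.entity_vectors[1] = p.entity_vectors[0] + p.relation_vectors[2]
        assert score(p, 0, 2, 1) == pytest.approx(0.0, abs=1e-12)

    def test_transH_orthogonal_normal_reduces_to_transE(self, rng):
        k = 6
        pe = _random_params("transE", 4, k, rng)
        ph = _random_params("transH", 4, k, rng)
        ph.entity_vectors = pe.entity_vectors.copy()
        ph.relation_vectors = pe.relation_vectors.copy()
        # normal orthogonal to both entity vectors: use a basis direction
        # unused by h and t
        ph.entity_vectors[:, 0] = 0.0
        pe.entity_vectors[:, 0] = 0.0
        w = np.zeros(k)
        w[0] = 1.0
        ph.hyperplane_normals[3] = w
        assert score(ph, 0, 3, 1) == pytest.approx(score(pe, 0, 3, 1))

    def test_transR_identity_matrix_reduces_to_transE(self, rng):
        k = 8
        pe = _random_params("transE", 5, k, rng)
        pr = _init_params("transR", 5, k, 2, np.random.default_rng(0))
        pr.entity_vectors = pe.entity_vectors.copy()
        pr.relation_vectors = pe.relation_vectors.copy()
        for h, r, t in [(0, 0, 1), (2, 4, 3), (1, 6, 4)]:
            assert score(pr, h, r, t) == pytest.approx(score(pe, h, r, t))

    def test_score_nonnegative(self, rng):
        for kind in ("transE", "transH", "transR"):
            p = _random_params(kind, 6, 5, rng)
            assert score(p, 0, 1, 2) >= 0.0

    def test_transE_translation_invariance(self, rng):
        """Adding the same constant vector to l_h and l_t leaves the
        TransE score unchanged."""
        p = _random_params("transE", 4, 6, rng)
        before = score(p, 0, 1, 2)
        c = rng.normal(size=6)
        p.entity_vectors[0] += c
        p.entity_vectors[2] += c
        assert score(p, 0, 1, 2) == pytest.approx(before)

    def test_bad_ids_rejected(self, rng):
        p = _random_params("transE", 4, 6, rng)
        with pytest.raises(IndexError):
            score(p, 99, 0, 0)
        with pytest.raises(IndexError):
            score(p, 0, 9, 0)


class TestHyperplaneProjection:
    def test_orthogonal_vector_unchanged(self):
        w = np.array([1.0, 0.0, 0.0])
        e = np.array([0.0, 2.0, -1.0])
        assert np.allclose(project_hyperplane(e, w), e)

    def test_normal_itself_projects_to_zero(self):
        w = np.array([0.0, 1.0, 0.0])
        assert np.allclose(project_hyperplane(w.copy(), w), 0.0)

    def test_result_orthogonal_and_idempotent(self, rng):
        for _ in range(20):
            w = rng.normal(size=7)
            w /= np.linalg.norm(w)
            e = rng.normal(size=7)
            p1 = project_hyperplane(e, w)
            assert abs(w @ p1) <= 1e-6
            assert np.allclose(project_hyperplane(p1, w), p1, atol=1e-9)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError):
            project_hyperplane(np.ones(3), np.ones(3))


class TestNegativeSampling:
    def test_differs_in_exactly_one_slot(self, coarse_graph, rng):
        catalog, triples = coarse_graph
        for t in triples[:20]:
            neg = negative_sample(t, catalog, rng)
            changed = (neg.head != t.head) + (neg.tail != t.tail)
            assert changed == 1
            assert neg.relation == t.relation

    def test_head_corruption_fraction_is_half(self, coarse_graph):
        catalog, triples = coarse_graph
        rng = np.random.default_rng(99)
        t = triples[3]
        n = 10_000
        heads = sum(negative_sample(t, catalog, rng).head != t.head for _ in range(n))
        assert abs(heads / n - 0.5) < 0.02

    def test_single_entity_pool_raises(self):
        from labkg import BandParams, ReferenceRange, build_graph

        catalog, triples = build_graph(
            [ReferenceRange("only", 1.0, 2.0, grid_step=0.5)], BandParams()
        )
        rng = np.random.default_rng(0)
        with pytest.raises(SamplingError):
            for _ in range(50):  # head side (single indicator) drawn w.p. 1/2
                negative_sample(triples[0], catalog, rng)


class TestRanking:
    def test_unique_minimum_ranks_first(self, rng):
        p = _random_params("transE", 10, 4, rng)
        p.entity_vectors[2] = p.entity_vectors[5] + p.relation_vectors[1]
        t = KnowledgeTriple(5, 1, 2)
        assert rank_triple(p, t, None, "head") == 1

    def test_all_ties_rank_one(self):
        p = TransParams(
            model_kind="transE",
            dim_k=3,
            entity_vectors=np.zeros((6, 3)),
            relation_vectors=np.zeros((N_RELATIONS, 3)),
        )
        assert rank_triple(p, KnowledgeTriple(0, 0, 1), None, "head") == 1

    @pytest.mark.parametrize("kind", ["transE", "transH", "transR"])
    @pytest.mark.parametrize("norm", [1, 2])
    @pytest.mark.parametrize("side", ["head", "tail"])
    def test_matches_brute_force_oracle(self, kind, norm, side):
        rng = np.random.default_rng(7)
        p = _random_params(kind, 30, 6, rng, norm_order=norm)
        triples = [
            KnowledgeTriple(int(rng.integers(30)), int(rng.integers(7)), int(rng.integers(30)))
            for _ in range(15)
        ]
        for t in triples:
            assert rank_triple(p, t, None, side) == brute_force_rank(p, t, side)
        res = evaluate_ranking(p, triples, None, side)
        oracle_ranks = [brute_force_rank(p, t, side) for t in triples]
        assert res.mean_rank == pytest.approx(np.mean(oracle_ranks))
        assert res.hit_at_10 == pytest.approx(
            100.0 * np.mean([r <= 10 for r in oracle_ranks])
        )
        assert res.per_triple_ranks == oracle_ranks

    def test_single_triple_summary(self, rng):
        p = _random_params("transE", 20, 4, rng)
        p.entity_vectors[1] = p.entity_vectors[0] + p.relation_vectors[0]
        res = evaluate_ranking(p, [KnowledgeTriple(0, 0, 1)], None, "head")
        assert res.mean_rank == 1.0
        assert res.hit_at_10 == 100.0

    def test_rank_eleven_misses_hit10(self):
        # entity 0's corruption list: candidates 1..10 strictly better
        p = TransParams(
            model_kind="transE",
            dim_k=2,
            entity_vectors=np.zeros((12, 2)),
            relation_vectors=np.zeros((N_RELATIONS, 2)),
        )
        for e in range(12):
            p.entity_vectors[e] = [float(e), 0.0]
        p.relation_vectors[0] = [0.5, 0.0]
        # true triple scores 11.5; replacement heads 0..10 all score lower
        t = KnowledgeTriple(11, 0, 0)
        rank = rank_triple(p, t, None, "head")
        res = evaluate_ranking(p, [t], None, "head")
        assert rank == 12
        assert res.hit_at_10 == 0.0

    def test_empty_test_set_rejected(self, rng):
        p = _random_params("transE", 4, 3, rng)
        with pytest.raises(ValueError):
            evaluate_ranking(p, [], None)


class TestTraining:
    def test_zero_epochs_returns_initialization(self, coarse_graph):
        catalog, triples = coarse_graph
        cfg = TrainConfig(epochs=0, seed=5)
        p = train("transH", triples, catalog, cfg, dim_k=8)
        p2 = _init_params("transH", catalog.n_entities, 8, 2, np.random.default_rng(5))
        assert np.array_equal(p.entity_vectors, p2.entity_vectors)
        assert np.array_equal(p.hyperplane_normals, p2.hyperplane_normals)

    def test_determinism_bit_identical(self, coarse_graph):
        catalog, triples = coarse_graph
        cfg = TrainConfig(epochs=5, seed=42)
        a = train("transH", triples, catalog, cfg, dim_k=8)
        b = train("transH", triples, catalog, cfg, dim_k=8)
        assert np.array_equal(a.entity_vectors, b.entity_vectors)
        assert np.array_equal(a.relation_vectors, b.relation_vectors)
        assert np.array_equal(a.hyperplane_normals, b.hyperplane_normals)

    def test_constraints_enforced(self, coarse_graph):
        catalog, triples = coarse_graph
        p = train("transH", triples, catalog, TrainConfig(epochs=3, seed=1), dim_k=8)
        assert np.allclose(np.linalg.norm(p.hyperplane_normals, axis=1), 1.0)
        assert (np.linalg.norm(p.entity_vectors, axis=1) <= 1.0 + 1e-9).all()

    @pytest.mark.parametrize("kind", ["transE", "transH", "transR"])
    def test_separates_positive_from_corrupted(self, coarse_graph, kind):
        catalog, triples = coarse_graph
        gamma = 1.0
        cfg = TrainConfig(margin_gamma=gamma, epochs=200, batch_size=8, seed=3)
        p = train(kind, triples, catalog, cfg, dim_k=16)
        rng = np.random.default_rng(0)
        pos = np.array([score(p, t.head, t.relation, t.tail) for t in triples])
        neg = []
        for t in triples:
            c = negative_sample(t, catalog, rng)
            neg.append(score(p, c.head, c.relation, c.tail))
        assert pos.mean() + gamma / 2 < np.mean(neg)

    def test_empty_triples_rejected(self, coarse_graph):
        catalog, _ = coarse_graph
        with pytest.raises(ValueError):
            train("transE", [], catalog, TrainConfig(epochs=1))


class TestSerialization:
    @pytest.mark.parametrize("kind", ["transE", "transH", "transR"])
    def test_round_trip(self, kind, tmp_path, rng):
        p = _random_params(kind, 9, 5, rng)
        save_embeddings(p, str(tmp_path))
        q = load_embeddings(str(tmp_path))
        assert q.model_kind == p.model_kind
        assert np.array_equal(q.entity_vectors, p.entity_vectors)
        assert np.array_equal(q.relation_vectors, p.relation_vectors)
        if kind == "transH":
            assert np.array_equal(q.hyperplane_normals, p.hyperplane_normals)
        if kind == "transR":
            assert np.array_equal(q.projection_matrices, p.projection_matrices)
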