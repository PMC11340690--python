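import numpy as np
import pytest

from microtopics import (
    DiffResult,
    LdaModel,
    cosine_similarity,
    harmonize_vocabularies,
    match_topics,
    validated_communities,
)
from microtopics.synthetic_data import SyntheticSpec, generate_paired_datasets
from microtopics.lda_vem import VemSettings, fit_lda


def _model(beta, vocab, n_docs=3):
    beta = np.asarray(beta, dtype=float)
    K = beta.shape[0]
    gamma = np.full((n_docs, K), 1.0 / K)
    return LdaModel(
        n_topics=K, beta=beta, gamma=gamma, alpha=np.ones(K), eta=0.1,
        elbo_trace=[-1.0], vocab=list(vocab),
        doc_ids=[f"d{i}" for i in range(n_docs)], seed=0,
    )


class TestHarmonizeVocabularies:
    def test_identical_vocabularies_unchanged(self):
        beta = np.array([[0.6, 0.4], [0.1, 0.9]])
        a, b, union = harmonize_vocabularies(beta, ["x", "y"], beta, ["x", "y"])
        assert union == ["x", "y"]
        np.testing.assert_array_equal(a, beta)
        np.testing.assert_array_equal(b, beta)

    def test_absent_term_zero_filled_not_renormalized(self):
        beta_a = np.array([[0.5, 0.5]])
        beta_b = np.array([[1.0]])
        a, b, union = harmonize_vocabularies(beta_a, ["x", "y"], beta_b, ["x"])
        assert union == ["x", "y"]
        np.testing.assert_array_equal(b, [[1.0, 0.0]])
        np.testing.assert_array_equal(a.sum(axis=1), [1.0])  # mass untouched

    def test_cosine_reduces_to_shared_terms_when_no_outside_mass(self):
        beta_a = np.array([[0.7, 0.3, 0.0]])
        beta_b = np.array([[0.7, 0.3]])
        a, b, _ = harmonize_vocabularies(beta_a, ["x", "y", "z"], beta_b, ["x", "y"])
        assert cosine_similarity(a[0], b[0]) == pytest.approx(1.0)

    def test_disjoint_vocabularies_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            harmonize_vocabularies(np.array([[1.0]]), ["x"], np.array([[1.0]]), ["y"])


class TestCosineSimilarity:
    def test_identical_vectors(self):
        assert cosine_similarity([0.2, 0.8], [0.2, 0.8]) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_closed_form(self):
        assert cosine_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])


class TestMatchTopics:
    def test_self_match_is_diagonal(self):
        beta = np.eye(3) * 0.9 + 0.05
        beta /= beta.sum(axis=1, keepdims=True)
        m = _model(beta, ["x", "y", "z"])
        sim, matches = match_topics(m, m, threshold=0.80)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)
        assert len(matches.pairs) == 3
        assert all(a.split(":")[1] == b.split(":")[1] for a, b, _ in matches.pairs)

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(0)
        a = _model(rng.dirichlet(np.ones(6), 3), [f"t{i}" for i in range(6)])
        b = _model(rng.dirichlet(np.ones(6), 4), [f"t{i}" for i in range(6)])
        sim_ab, _ = match_topics(a, b, threshold=0.5)
        sim_ba, _ = match_topics(b, a, threshold=0.5)
        np.testing.assert_allclose(sim_ab.values, sim_ba.values.T, atol=1e-12)

    def test_threshold_one_generic_fits_empty(self):
        rng = np.random.default_rng(1)
        a = _model(rng.dirichlet(np.ones(8), 3), [f"t{i}" for i in range(8)])
        b = _model(rng.dirichlet(np.ones(8), 3), [f"t{i}" for i in range(8)])
        _, matches = match_topics(a, b, threshold=1.0)
        assert matches.pairs == []

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        beta = rng.dirichlet(np.ones(6), 4)
        vocab = [f"t{i}" for i in range(6)]
        a, b = _model(beta, vocab), _model(rng.dirichlet(np.ones(6), 4), vocab)
        sim, _ = match_topics(a, b, threshold=0.99)
        a_perm = _model(beta[::-1], vocab)
        sim_p, _ = match_topics(a_perm, b, threshold=0.99)
        np.testing.assert_allclose(sim_p.values, sim.values[::-1], atol=1e-14)

    def test_planted_shared_topics_recovered(self):
        spec = SyntheticSpec(D=80, V=80, K=6, depth_mean=8000)
        ds_a, ds_b = generate_paired_datasets(spec, spec, n_shared=2, seed=99)
        ma = fit_lda(ds_a.table, 6, VemSettings(seed=0))
        mb = fit_lda(ds_b.table, 6, VemSettings(seed=1))
        _, matches = match_topics(ma, mb, threshold=0.80)
        assert len(matches.pairs) == 2


def _diff(feature_id, significant, effect=1.0):
    p = 0.01 if significant else 0.5
    return DiffResult(feature_id, effect, 0.1, effect / 0.1, p, p, significant)


class TestValidatedCommunities:
    def _matches(self):
        from microtopics.topic_matching import MatchSet

        pairs = [("A:Topic 1", "B:Topic 1", 0.92), ("A:Topic 2", "B:Topic 1", 0.86),
                 ("A:Topic 3", "B:Topic 2", 0.84)]
        communities = [{"A:Topic 1", "A:Topic 2", "B:Topic 1"},
                       {"A:Topic 3", "B:Topic 2"}]
        return MatchSet(pairs, 0.80, communities)

    def test_both_significant_validates(self):
        diff_a = [_diff("A:Topic 1", True), _diff("A:Topic 2", False),
                  _diff("A:Topic 3", False)]
        diff_b = [_diff("B:Topic 1", True), _diff("B:Topic 2", True)]
        comms = validated_communities(self._matches(), diff_a, diff_b)
        by_member = {min(sorted(c.topics)): c for c in comms}
        assert by_member["A:Topic 1"].validated  # sig A topic paired to sig B
        assert not by_member["A:Topic 3"].validated  # A side not significant

    def test_no_significant_member_excluded(self):
        diff_a = [_diff(f"A:Topic {i}", False) for i in (1, 2, 3)]
        diff_b = [_diff(f"B:Topic {i}", False) for i in (1, 2)]
        comms = validated_communities(self._matches(), diff_a, diff_b,
                                      rule="exploratory-significant")
        assert not any(c.validated for c in comms)

    def test_both_significant_is_subset_of_exploratory(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            diff_a = [_diff(f"A:Topic {i}", bool(rng.integers(2))) for i in (1, 2, 3)]
            diff_b = [_diff(f"B:Topic {i}", bool(rng.integers(2))) for i in (1, 2)]
            strict = validated_communities(self._matches(), diff_a, diff_b,
                                           rule="both-significant")
            loose = validated_communities(self._matches(), diff_a, diff_b,
                                          rule="exploratory-significant")
            for s, l in zip(strict, loose):
                assert (not s.validated) or l.validated

    def test_unknown_topic_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            validated_communities(self._matches(), [_diff("A:Topic 1", True)], [])
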