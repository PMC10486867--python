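import math

import numpy as np
import pytest

from scgem.datamodel import CellLoadings, GemModel, ValidationError, build_tree_spec
from scgem.evalmetrics import (CoherenceConfig, cosine_similarity,
                               export_gene_sets, gem_similarity_matrix,
                               perplexity, pmi, test_log_likelihood,
                               top_genes, topic_coherence)
from tests.conftest import make_counts


def scalar_loop_log_likelihood(counts, theta, beta):
    """Independent oracle: plain double loop over cells and genes."""
    total = 0.0
    for d in range(counts.shape[0]):
        for g in range(counts.shape[1]):
            if counts[d, g] > 0:
                p = sum(theta[d, k] * beta[k, g] for k in range(beta.shape[0]))
                total += counts[d, g] * math.log(p)
    return total


def _toy_model(beta_rows, spec=None):
    beta = np.asarray(beta_rows, dtype=float)
    spec = spec or build_tree_spec([beta.shape[0]])
    genes = [f"G{j}" for j in range(beta.shape[1])]
    return GemModel(tree=spec, beta=beta, gene_names=genes)


def test_log_likelihood_single_cell():
    model = _toy_model([[0.8, 0.2]])
    theta = CellLoadings(tree=model.tree, theta=np.array([[1.0]]),
                         barcodes=["c0"])
    counts = make_counts([[3, 1]])
    expected = 3 * math.log(0.8) + 1 * math.log(0.2)
    assert abs(test_log_likelihood(theta, model, counts) - expected) <= 1e-12


def test_log_likelihood_zero_counts():
    model = _toy_model([[0.8, 0.2]])
    theta = CellLoadings(tree=model.tree, theta=np.array([[1.0]]),
                         barcodes=["c0"])
    assert test_log_likelihood(theta, model, make_counts([[0, 0]])) == 0.0


def test_two_cell_instance_matches_oracle():
    spec = build_tree_spec([2])
    model = GemModel(tree=spec, beta=np.array([[0.8, 0.2], [0.2, 0.8]]),
                     gene_names=["G0", "G1"])
    theta = CellLoadings(tree=spec, theta=np.array([[1.0, 0.0], [0.5, 0.5]]),
                         barcodes=["c0", "c1"])
    counts_arr = np.array([[3, 1], [2, 2]])
    counts = make_counts(counts_arr)
    L = test_log_likelihood(theta, model, counts)
    oracle = scalar_loop_log_likelihood(counts_arr, theta.theta, model.beta)
    assert abs(L - oracle) <= 1e-12
    # perplexity of the same instance: exp(-L / 8 tokens)
    assert abs(perplexity(theta, model, counts) - math.exp(-oracle / 8)) <= 1e-12


def test_uniform_mixture_perplexity_is_vocab_size():
    G = 17
    model = _toy_model([np.full(G, 1.0 / G)])
    rng = np.random.default_rng(0)
    counts = make_counts(rng.integers(0, 4, size=(5, G)))
    theta = CellLoadings(tree=model.tree, theta=np.ones((5, 1)),
                         barcodes=[f"c{i}" for i in range(5)])
    assert abs(perplexity(theta, model, counts) - G) <= 1e-9 * G


def test_perplexity_bounds_and_errors():
    model = _toy_model([[0.5, 0.5]])
    theta = CellLoadings(tree=model.tree, theta=np.ones((1, 1)),
                         barcodes=["c"])
    with pytest.raises(ValidationError):
        perplexity(theta, model, make_counts([[0, 0]]))
    # proper mixture keeps perplexity within [1, G]
    p = perplexity(theta, model, make_counts([[4, 1]]))
    assert 1.0 <= p <= 2.0


@pytest.mark.parametrize("p_joint,p_i,p_j,expected", [
    (0.25, 0.5, 0.5, 0.0),              # independence
    (0.5, 0.5, 0.5, math.log(2)),       # perfect co-occurrence
    (0.1, 0.4, 0.5, math.log(0.5)),
])
def test_pmi_closed_forms(p_joint, p_i, p_j, expected):
    assert abs(pmi(p_joint, p_i, p_j) - expected) <= 1e-12
    assert pmi(p_joint, p_i, p_j) == pmi(p_joint, p_j, p_i)


def test_pmi_errors():
    with pytest.raises(ValidationError):
        pmi(0.1, 0.0, 0.5)


def test_top_genes_ordering_and_ties():
    genes = ["a", "b", "c"]
    assert top_genes(np.array([0.1, 0.7, 0.2]), genes, 2) == ["b", "c"]
    assert top_genes(np.array([0.4, 0.4, 0.2]), genes, 3) == ["a", "b", "c"]
    assert sorted(top_genes(np.array([0.2, 0.5, 0.3]), genes, 3)) == genes
    with pytest.raises(ValidationError):
        top_genes(np.array([0.5, 0.5]), ["a", "b"], 3)


def test_coherence_perfect_cooccurrence():
    # top genes present together in exactly half the cells
    n = 4
    arr = np.zeros((10, n), dtype=int)
    arr[:5] = 1
    counts = make_counts(arr)
    beta_row = np.linspace(0.4, 0.1, n)
    score = topic_coherence(beta_row, counts, CoherenceConfig(top_n=n))
    n_pairs = n * (n - 1) // 2
    assert abs(score - n_pairs * math.log(2)) <= 1e-6


def test_coherence_single_pair():
    arr = np.zeros((10, 2), dtype=int)
    arr[:5] = 1
    score = topic_coherence(np.array([0.6, 0.4]), make_counts(arr),
                            CoherenceConfig(top_n=2))
    assert abs(score - math.log(2)) <= 1e-6


def test_coherence_independent_genes_near_zero():
    rng = np.random.default_rng(0)
    arr = (rng.random((10000, 6)) < 0.4).astype(int)
    score = topic_coherence(np.full(6, 1 / 6), make_counts(arr),
                            CoherenceConfig(top_n=6))
    assert abs(score) < 0.1  # 15 pairs, each ~0 within sampling error


def test_coherence_cell_permutation_invariant():
    rng = np.random.default_rng(1)
    arr = rng.integers(0, 3, size=(50, 8))
    cm = make_counts(arr)
    perm = rng.permutation(50)
    cm_perm = make_counts(arr[perm],
                          barcodes=[f"P{i}" for i in range(50)])
    row = rng.dirichlet(np.ones(8))
    s1 = topic_coherence(row, cm, CoherenceConfig(top_n=5))
    s2 = topic_coherence(row, cm_perm, CoherenceConfig(top_n=5))
    assert abs(s1 - s2) <= 1e-12


def test_cosine_similarity_vectors_and_sets():
    assert cosine_similarity({"a", "b"}, {"a", "b"}) == pytest.approx(1.0)
    assert cosine_similarity({"a"}, {"b"}) == pytest.approx(0.0)
    a = [f"g{i}" for i in range(150)]
    b = a[:75] + [f"h{i}" for i in range(75)]
    assert cosine_similarity(a, b) == pytest.approx(0.5)
    v = np.array([1.0, 2.0])
    assert cosine_similarity(v, 3 * v) == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        cosine_similarity(np.zeros(3), v[:3])


def test_gem_similarity_matrix_modes():
    rng = np.random.default_rng(0)
    spec = build_tree_spec([2, 2])
    beta = rng.dirichlet(np.ones(30), size=spec.n_nodes)
    model = GemModel(tree=spec, beta=beta,
                     gene_names=[f"G{j}" for j in range(30)])
    gem_gem = gem_similarity_matrix(model, None, top_n=10)
    np.testing.assert_allclose(np.diag(gem_gem.to_numpy()), 1.0)
    markers = {"setA": top_genes(beta[0], model.gene_names, 10)}
    df = gem_similarity_matrix(model, markers, top_n=10)
    assert df.loc[spec.node_ids[0], "setA"] == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        gem_similarity_matrix(model, {"empty": []})


def test_export_gmt_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    spec = build_tree_spec([3, 2, 2])
    beta = rng.dirichlet(np.ones(100), size=spec.n_nodes)
    model = GemModel(tree=spec, beta=beta,
                     gene_names=[f"G{j}" for j in range(100)])
    path = export_gene_sets(model, n=50, path=tmp_path / "sets.gmt")
    lines = path.read_text().splitlines()
    assert len(lines) == 21
    for i, line in enumerate(lines):
        parts = line.split("\t")
        assert parts[0] == f"GEM_{spec.node_ids[i]}"
        assert parts[2:] == top_genes(beta[i], model.gene_names, 50)
    single = export_gene_sets(model, n=1, path=tmp_path / "one.gmt")
    for i, line in enumerate(single.read_text().splitlines()):
        assert line.split("\t")[2] == model.gene_names[int(np.argmax(beta[i]))]
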