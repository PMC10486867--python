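"""Held-out perplexity, PMI topic coherence, cosine similarity, gene sets.

Held-out evaluation follows the fold-in protocol: gene distributions
``beta`` learned on training cells are frozen, per-cell loadings
``theta`` are inferred on the test cells, and the predictive likelihood

    L_test = sum_d sum_g C_dg * log sum_k theta_dk * beta_kg

is exponentiated per token into a perplexity (lower is better).  Topic
coherence is the sum of pointwise mutual information over all pairs of
a GEM's top genes, with presence defined as a nonzero UMI count in a
cell (higher usually means more consistent marker genes).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from scgem.datamodel import CellLoadings, CountMatrix, GemModel, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["CoherenceConfig", "test_log_likelihood", "perplexity", "pmi",
           "topic_coherence", "top_genes", "cosine_similarity",
           "gem_similarity_matrix", "export_gene_sets"]


@dataclass(frozen=True)
class CoherenceConfig:
    """Settings for PMI topic coherence.

    Presence of a gene in a cell means UMI count > 0; ``smoothing`` is
    added to the probability estimates so absent pairs stay finite.
    """

    top_n: int = 50
    smoothing: float = 1e-12

    def __post_init__(self) -> None:
        if self.top_n < 2:
            raise ValidationError("top_n must be >= 2")


def _mixture(theta: CellLoadings, model: GemModel) -> np.ndarray:
    return theta.theta @ model.beta


def test_log_likelihood(theta: CellLoadings, model: GemModel,
                        counts: CountMatrix) -> float:
    """Predictive log-likelihood of held-out counts under theta x beta."""
    if counts.n_genes != len(model.gene_names):
        raise ValidationError("counts and model gene dimensions differ")
    if theta.theta.shape[0] != counts.n_cells:
        raise ValidationError("theta and counts cell dimensions differ")
    mix = _mixture(theta, model)
    C = counts.counts.tocsr()
    rows = np.repeat(np.arange(C.shape[0]), np.diff(C.indptr))
    probs = mix[rows, C.indices]
    mask = C.data > 0
    if np.any(probs[mask] <= 0):
        bad = C.indices[mask][probs[mask] <= 0][0]
        raise ValidationError(
            f"gene {model.gene_names[bad]!r} observed with zero mixture "
            "probability")
    return float((C.data[mask] * np.log(probs[mask])).sum())


test_log_likelihood.__test__ = False  # library function, not a pytest case


def perplexity(theta: CellLoadings, model: GemModel,
               counts: CountMatrix) -> float:
    """exp(-L_test / total token count); lower is better, G for uniform."""
    total = counts.counts.sum()
    if total <= 0:
        raise ValidationError("perplexity undefined for zero total counts")
    return float(np.exp(-test_log_likelihood(theta, model, counts) / total))


def pmi(p_joint: float, p_i: float, p_j: float) -> float:
    """Pointwise mutual information log(p_ij / (p_i * p_j)); symmetric."""
    if p_i <= 0 or p_j <= 0:
        raise ValidationError("marginal probabilities must be > 0")
    if p_joint < 0:
        raise ValidationError("joint probability must be >= 0")
    return math.log(p_joint / (p_i * p_j))


def top_genes(beta_row: np.ndarray, gene_names: list[str], n: int) -> list[str]:
    """Top ``n`` genes by descending weight; ties keep input gene order."""
    if not (0 < n <= len(gene_names)):
        raise ValidationError(f"n={n} out of range for {len(gene_names)} genes")
    beta_row = np.asarray(beta_row)
    order = np.argsort(-beta_row, kind="stable")
    return [gene_names[i] for i in order[:n]]


def topic_coherence(beta_row: np.ndarray, reference: CountMatrix,
                    config: CoherenceConfig = CoherenceConfig(),
                    gene_names: list[str] | None = None) -> float:
    """Sum of PMI over all pairs of the GEM's top genes.

    Presence probabilities are cell fractions estimated on the
    reference corpus; top genes missing from the corpus contribute only
    through the smoothing floor (and are logged).  Comparisons across
    GEMs are only meaningful at equal ``top_n`` since the score is the
    raw sum, not the mean, over the C(top_n, 2) pairs.
    """
    if reference.n_cells == 0:
        raise ValidationError("reference corpus is empty")
    if gene_names is None:
        gene_names = reference.gene_names
    tops = top_genes(beta_row, gene_names, config.top_n)
    col_of = {g: j for j, g in enumerate(reference.gene_names)}
    n_cells = reference.n_cells
    presence = {}
    missing = [g for g in tops if g not in col_of]
    if missing:
        logger.warning("%d top genes absent from the reference corpus: %s",
                       len(missing), missing[:5])
    for g in tops:
        if g in col_of:
            col = reference.counts[:, col_of[g]]
            presence[g] = np.zeros(n_cells, dtype=bool)
            presence[g][col.nonzero()[0]] = True
        else:
            presence[g] = np.zeros(n_cells, dtype=bool)
    total = 0.0
    eps = config.smoothing
    for gi, gj in itertools.combinations(tops, 2):
        p_i = max(presence[gi].mean(), eps)
        p_j = max(presence[gj].mean(), eps)
        p_ij = (presence[gi] & presence[gj]).mean() + eps
        total += pmi(p_ij, p_i, p_j)
    return total


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between vectors or gene sets.

    Gene sets (any non-ndarray iterable of strings) are embedded as
    binary indicators over the union vocabulary, so two sets of size n
    sharing m genes score m/n.
    """
    if _is_gene_set(a) or _is_gene_set(b):
        a_set, b_set = set(a), set(b)
        vocab = sorted(a_set | b_set)
        a = np.array([g in a_set for g in vocab], dtype=float)
        b = np.array([g in b_set for g in vocab], dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("cosine similarity undefined for zero vectors")
    return float(a @ b / (na * nb))


def _is_gene_set(x) -> bool:
    if isinstance(x, np.ndarray):
        return False
    try:
        return all(isinstance(el, str) for el in x)
    except TypeError:
        return False


def gem_similarity_matrix(model: GemModel, marker_sets: dict[str, list[str]] | None = None,
                          top_n: int = 150):
    """Cosine similarities between GEM top-gene sets and marker sets.

    With ``marker_sets`` given, returns a (node x set) DataFrame; with
    ``marker_sets=None``, returns the GEM x GEM similarity matrix of
    the models' own top-gene sets (diagonal exactly 1).
    """
    import pandas as pd

    gem_sets = {k: top_genes(model.beta[i], model.gene_names, top_n)
                for i, k in enumerate(model.tree.node_ids)}
    if marker_sets is None:
        ids = list(model.tree.node_ids)
        mat = np.ones((len(ids), len(ids)))
        for i, ki in enumerate(ids):
            for j in range(i + 1, len(ids)):
                mat[i, j] = mat[j, i] = cosine_similarity(
                    gem_sets[ki], gem_sets[ids[j]])
        return pd.DataFrame(mat, index=ids, columns=ids)
    for name, genes in marker_sets.items():
        if not genes:
            raise ValidationError(f"marker set {name!r} is empty")
    mat = np.zeros((len(gem_sets), len(marker_sets)))
    for i, k in enumerate(model.tree.node_ids):
        for j, (name, genes) in enumerate(marker_sets.items()):
            mat[i, j] = cosine_similarity(gem_sets[k], genes)
    return pd.DataFrame(mat, index=list(model.tree.node_ids),
                        columns=list(marker_sets.keys()))


def export_gene_sets(model: GemModel, n: int = 50,
                     path: str | Path = "gem_sets.gmt") -> Path:
    """Write each GEM's top-``n`` weighted genes as a GMT gene-set file.

    One line per node: set name ``GEM_<id>``, a description field, then
    tab-separated gene symbols — directly consumable by enrichment
    tools.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for i, k in enumerate(model.tree.node_ids):
            genes = top_genes(model.beta[i], model.gene_names, n)
            level = model.tree.level_of[k]
            fh.write("\t".join([f"GEM_{k}", f"level={level}"] + genes) + "\n")
    return path
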