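"""Synthetic scRNA-seq corpora with known ground truth.

Two generators:

* :func:`simulate_splatter_like` — unstructured counts with the
  marginal statistics of real UMI data (gamma-distributed gene means,
  log-normal library sizes, Poisson sampling), the splatter recipe
  stripped to its core.
* :func:`simulate_planted_tree` — counts drawn from a known tree of
  gene distributions with nested stick-breaking cell loadings, the
  model's own generative story, used for parameter-recovery tests.

Plus :func:`split_train_test`, the train/test protocol with a fixed
held-out set and nested training sets of increasing size, replicated
with independent seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from scgem.datamodel import CellLoadings, CountMatrix, TreeSpec, ValidationError, ancestors

__all__ = ["SplatterLikeParams", "PlantedTreeParams", "SplitPlan",
           "simulate_splatter_like", "simulate_planted_tree",
           "make_beta_true", "split_train_test"]


@dataclass(frozen=True)
class SplatterLikeParams:
    """Shape and marginal-distribution settings for unstructured counts.

    Defaults give a median library size of about 2000 UMIs and a
    long-tailed gene-mean distribution, typical of 10x data.
    """

    n_cells: int = 1000
    n_genes: int = 2000
    libsize_log_mean: float = 7.6  # exp(7.6) ~ 2000 UMIs
    libsize_log_sd: float = 0.35
    gene_mean_shape: float = 0.6
    gene_mean_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_genes <= 0:
            raise ValidationError("dimensions must be positive")
        if self.libsize_log_sd < 0:
            raise ValidationError("libsize_log_sd must be >= 0")
        if self.gene_mean_shape <= 0 or self.gene_mean_rate <= 0:
            raise ValidationError("gamma parameters must be > 0")


@dataclass(frozen=True)
class PlantedTreeParams:
    """Ground-truth model for planted-tree corpora.

    ``tau_true`` is the stick-breaking concentration for sibling choice
    and within-path weights; ``gamma_true`` the probability of
    descending one more level.  ``beta_true`` defaults to
    :func:`make_beta_true` with ``parent_share``.
    """

    spec: TreeSpec = None
    n_cells: int = 1000
    n_genes: int = 1500
    beta_true: np.ndarray = None
    parent_share: float = 0.3
    tau_true: float = 1.0
    gamma_true: float = 0.75
    libsize_log_mean: float = 7.6
    libsize_log_sd: float = 0.35
    seed: int = 0


@dataclass
class SplitPlan:
    """Held-out test cells plus nested training sets per replicate."""

    test_size: int
    train_sizes: list[int]
    replicates: list[dict] = field(default_factory=list)
    # each replicate: {"test": ndarray, "train": {size: ndarray}}


def simulate_splatter_like(params: SplatterLikeParams) -> CountMatrix:
    """Unstructured UMI counts: gamma gene means x log-normal libraries.

    ``C_dg ~ Poisson(L_d * m_g / sum m)`` with gene means
    ``m_g ~ Gamma(shape, rate)`` and library sizes
    ``L_d ~ LogNormal(log_mean, log_sd)``.  Pure function of the
    parameters and seed.
    """
    rng = np.random.default_rng(params.seed)
    means = rng.gamma(params.gene_mean_shape, 1.0 / params.gene_mean_rate,
                      size=params.n_genes)
    means = np.maximum(means, 1e-12)
    profile = means / means.sum()
    libsizes = rng.lognormal(params.libsize_log_mean, params.libsize_log_sd,
                             size=params.n_cells)
    counts = rng.poisson(np.outer(libsizes, profile))
    return CountMatrix(counts=sp.csr_matrix(counts),
                       gene_names=[f"G{j:05d}" for j in range(params.n_genes)],
                       barcodes=[f"CELL{i:06d}" for i in range(params.n_cells)])


def make_beta_true(spec: TreeSpec, n_genes: int, parent_share: float = 0.3,
                   seed: int = 0) -> np.ndarray:
    """Planted per-node gene distributions with nested supports.

    Every node owns a disjoint block of "specific" genes carrying a
    sparse random profile; a child's distribution is
    ``parent_share * parent + (1 - parent_share) * specific``, so
    top-level nodes are mutually disjoint and child-parent similarity
    grows with ``parent_share``.
    """
    if not (0.0 <= parent_share <= 1.0):
        raise ValidationError("parent_share must lie in [0, 1]")
    K = spec.n_nodes
    block = n_genes // K
    if block < 2:
        raise ValidationError(
            f"{n_genes} genes cannot host {K} nodes (need >= 2 genes each)")
    rng = np.random.default_rng(seed)
    beta = np.zeros((K, n_genes))
    idx = {k: i for i, k in enumerate(spec.node_ids)}
    for i, k in enumerate(spec.node_ids):
        lo, hi = i * block, (i + 1) * block
        specific = np.zeros(n_genes)
        specific[lo:hi] = rng.dirichlet(np.full(block, 0.5))
        if k in spec.parent_of:
            parent_profile = beta[idx[spec.parent_of[k]]]
            beta[i] = parent_share * parent_profile + (1 - parent_share) * specific
        else:
            beta[i] = specific
    return beta


def _stick_choice(rng: np.random.Generator, m: int, tau: float) -> int:
    """Pick one of m siblings by truncated stick-breaking (last absorbs)."""
    remaining = 1.0
    probs = np.zeros(m)
    for i in range(m - 1):
        b = rng.beta(1.0, tau)
        probs[i] = remaining * b
        remaining *= 1.0 - b
    probs[m - 1] = remaining
    return int(rng.choice(m, p=probs))


def simulate_planted_tree(params: PlantedTreeParams
                          ) -> tuple[CountMatrix, CellLoadings, np.ndarray]:
    """Counts drawn from the model's own generative process.

    Per cell: walk the tree top-down — sibling chosen by stick-breaking
    with ``tau_true``, descent continued with probability
    ``gamma_true`` — then spread theta over the visited path by
    stick-breaking and draw ``C_d ~ Poisson(L_d * sum_k theta_k beta_k)``.

    Returns ``(counts, theta_true, beta_true)``.
    """
    spec = params.spec
    if spec is None:
        raise ValidationError("PlantedTreeParams.spec is required")
    rng = np.random.default_rng(params.seed)
    beta = params.beta_true
    if beta is None:
        beta = make_beta_true(spec, params.n_genes, params.parent_share,
                              seed=int(rng.integers(2**31)))
    if beta.shape != (spec.n_nodes, params.n_genes):
        raise ValidationError("beta_true shape does not match spec / n_genes")
    idx = {k: i for i, k in enumerate(spec.node_ids)}
    theta = np.zeros((params.n_cells, spec.n_nodes))
    counts = np.zeros((params.n_cells, params.n_genes), dtype=np.int64)
    libsizes = rng.lognormal(params.libsize_log_mean, params.libsize_log_sd,
                             size=params.n_cells)
    top = spec.nodes_at_level(1)
    for d in range(params.n_cells):
        path = []
        node = top[_stick_choice(rng, len(top), params.tau_true)]
        path.append(node)
        while spec.children_of(node) and rng.random() < params.gamma_true:
            kids = spec.children_of(node)
            node = kids[_stick_choice(rng, len(kids), params.tau_true)]
            path.append(node)
        # theta over the path, root first, by stick-breaking
        remaining = 1.0
        for i, k in enumerate(path):
            if i == len(path) - 1:
                theta[d, idx[k]] = remaining
            else:
                b = rng.beta(1.0, params.tau_true)
                theta[d, idx[k]] = remaining * b
                remaining *= 1.0 - b
        mixture = theta[d] @ beta
        counts[d] = rng.poisson(libsizes[d] * mixture)
    cm = CountMatrix(counts=sp.csr_matrix(counts),
                     gene_names=[f"G{j:05d}" for j in range(params.n_genes)],
                     barcodes=[f"CELL{i:06d}" for i in range(params.n_cells)])
    loadings = CellLoadings(tree=spec, theta=theta, barcodes=cm.barcodes)
    return cm, loadings, beta


def split_train_test(counts: CountMatrix, test_size: int,
                     train_sizes: list[int], replicates: int = 3,
                     seed: int = 0) -> SplitPlan:
    """Held-out test cells plus nested training sets of growing size.

    Per replicate: sample ``test_size`` cells as the fixed test set,
    then draw ``max(train_sizes)`` cells from the remainder; each
    requested training size is a prefix of that draw, so smaller sets
    nest inside larger ones.  Replicates are independent given the
    seed.
    """
    train_sizes = sorted(int(s) for s in train_sizes)
    if test_size + max(train_sizes) > counts.n_cells:
        raise ValidationError(
            f"test {test_size} + max train {max(train_sizes)} exceeds "
            f"{counts.n_cells} cells")
    rng = np.random.default_rng(seed)
    plan = SplitPlan(test_size=test_size, train_sizes=train_sizes)
    for _ in range(replicates):
        order = rng.permutation(counts.n_cells)
        test = np.sort(order[:test_size])
        pool = order[test_size:test_size + max(train_sizes)]
        plan.replicates.append({
            "test": test,
            "train": {s: np.sort(pool[:s]) for s in train_sizes},
        })
    return plan
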