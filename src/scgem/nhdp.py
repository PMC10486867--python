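"""Nested tree-structured topic model: constructions and variational fitting.

The generative story: a global tree of gene distributions (GEMs) is
shared by all cells.  Each cell walks the tree from the top — choosing
among siblings by a stick-breaking draw with cell-level concentration
``tau``, and descending to the chosen node's children with switching
probability ``gamma_switch`` — and spreads its per-cell GEM weights
``theta`` over the visited nodes.  UMI counts are then multinomial draws
from the mixture ``sum_k theta_dk * beta_kg``.

Inference is a finite-truncation variational scheme: the truncation IS
the preset :class:`~scgem.datamodel.TreeSpec`.  Per cell, ``theta`` is
reparametrized exactly by local tree decisions — one stop-vs-descend
probability per internal node and one sibling-choice distribution per
sibling group — a bijection between the ``theta`` simplex and the
product of local simplices.  Stop probabilities carry a
Beta-like prior from ``gamma_switch``; sibling choices carry a
size-biased (stick-breaking-ordered) prior from ``tau``; gene
distributions carry a symmetric Dirichlet ``eta`` prior.  One-batch
training is then exact EM on the resulting penalized objective (so the
per-epoch objective is non-decreasing); mini-batch training replaces
the global update with a stochastic interpolation of the given
learning rate, as in stochastic variational inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from scgem.datamodel import (
    CellLoadings,
    CountMatrix,
    FitTrace,
    GemModel,
    StickWeights,
    TreeSpec,
    ValidationError,
)
from scgem.tree_init import InitResult

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "VariationalState", "stick_breaking_weights",
           "crp_next_probabilities", "fit", "warm_start", "infer_loadings"]


def stick_breaking_weights(breaks) -> StickWeights:
    """Turn successive break fractions into stick weights.

    ``weights[i] = breaks[i] * prod_{j<i}(1 - breaks[j])``; the
    remainder is the unbroken tail of the stick.
    """
    return StickWeights(breaks=np.asarray(breaks, dtype=float))


def crp_next_probabilities(alpha: float, occupancy: dict) -> tuple[float, dict]:
    """Chinese restaurant process predictive probabilities.

    Returns ``(p_new, {atom: p_atom})`` with ``p_new = alpha/(alpha+n)``
    and ``p_atom = n_atom/(alpha+n)`` for occupancy counts ``n_atom``
    summing to ``n``.
    """
    if alpha <= 0:
        raise ValidationError(f"alpha must be > 0, got {alpha}")
    counts = {a: float(c) for a, c in occupancy.items()}
    if any(c < 0 for c in counts.values()):
        raise ValidationError("occupancy counts must be >= 0")
    n = sum(counts.values())
    denom = alpha + n
    return alpha / denom, {a: c / denom for a, c in counts.items()}


@dataclass(frozen=True)
class FitConfig:
    """Training settings.

    ``gamma_switch`` is the depth-switching probability: lower values
    keep more per-cell mass on upper tree levels (a conservative
    search); 0.5 is the "shallow" preset.  ``switch_strength`` is the
    pseudo-token weight of the switching prior at each internal node.
    ``learning_rate`` only applies in mini-batch mode and is constant
    by default (``lr_decay`` enables a Robbins-Monro schedule).
    """

    mode: str = "one-batch"  # "one-batch" | "mini-batch"
    batch_size: int = 512
    learning_rate: float = 0.01
    lr_decay: bool = False
    max_epochs: int = 50
    conv_tol: float = 1e-4
    gamma_switch: float = 0.75
    alpha: float = 1.0
    tau: float = 1.0
    eta: float = 0.01
    switch_strength: float = 10.0
    local_iters: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("one-batch", "mini-batch"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not (0 < self.learning_rate <= 1):
            raise ValidationError("learning_rate must lie in (0, 1]")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if not (0 < self.gamma_switch < 1):
            raise ValidationError("gamma_switch must lie in (0, 1)")


@dataclass
class VariationalState:
    """Cached tree bookkeeping plus per-cell local parameters."""

    tree: TreeSpec
    parent_idx: np.ndarray        # index of parent per node, -1 for top
    internal: np.ndarray          # boolean: node has children
    groups: list[np.ndarray]      # sibling groups as index arrays (id order)
    a_stop: np.ndarray            # switching prior, stop side
    a_go: np.ndarray              # switching prior, descend side
    branch_prior: list[np.ndarray]  # per-group size-biased prior weights
    sigma: np.ndarray = None      # cells x nodes stop probabilities
    psi: np.ndarray = None        # cells x nodes sibling-choice probabilities
    step_count: int = 0


def _build_state(tree: TreeSpec, config: FitConfig) -> VariationalState:
    idx = {k: i for i, k in enumerate(tree.node_ids)}
    K = tree.n_nodes
    parent_idx = np.full(K, -1, dtype=int)
    for child, parent in tree.parent_of.items():
        parent_idx[idx[child]] = idx[parent]
    internal = np.zeros(K, dtype=bool)
    groups = [np.array([idx[k] for k in tree.nodes_at_level(1)])]
    for k in tree.node_ids:
        kids = tree.children_of(k)
        if kids:
            internal[idx[k]] = True
            groups.append(np.array([idx[c] for c in kids]))
    s0, g = config.switch_strength, config.gamma_switch
    a_stop = np.where(internal, s0 * (1.0 - g), 0.0)
    a_go = np.where(internal, s0 * g, 0.0)
    branch_prior = []
    for grp in groups:
        m = len(grp)
        # expected truncated stick-breaking weights, size-biased by id order
        frac = config.tau / (1.0 + config.tau)
        w = (1.0 - frac) * frac ** np.arange(m)
        w[-1] = frac ** (m - 1)
        branch_prior.append(config.tau * w)
    return VariationalState(tree=tree, parent_idx=parent_idx, internal=internal,
                            groups=groups, a_stop=a_stop, a_go=a_go,
                            branch_prior=branch_prior)


def _theta_from_locals(state: VariationalState, sigma: np.ndarray,
                       psi: np.ndarray) -> np.ndarray:
    """Compose theta rows from stop and sibling-choice probabilities."""
    D, K = sigma.shape
    pass_mass = np.zeros((D, K))
    theta = np.zeros((D, K))
    # node ids are level-major, so index order is topological
    for k in range(K):
        p = state.parent_idx[k]
        if p < 0:
            pass_mass[:, k] = psi[:, k]
        else:
            pass_mass[:, k] = pass_mass[:, p] * (1.0 - sigma[:, p]) * psi[:, k]
        stop = sigma[:, k] if state.internal[k] else 1.0
        theta[:, k] = pass_mass[:, k] * stop
    return theta


def _locals_from_counts(state: VariationalState,
                        n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form M-step for the per-cell tree decisions.

    ``n`` holds expected per-node token counts; subtree masses are
    aggregated bottom-up, stop probabilities shrink toward
    ``1 - gamma_switch`` and sibling choices toward the size-biased
    stick prior.
    """
    D, K = n.shape
    m = n.copy()
    for k in range(K - 1, -1, -1):
        p = state.parent_idx[k]
        if p >= 0:
            m[:, p] += m[:, k]
    sigma = np.ones((D, K))
    internal = np.flatnonzero(state.internal)
    sigma[:, internal] = ((n[:, internal] + state.a_stop[internal])
                          / (m[:, internal] + state.a_stop[internal]
                             + state.a_go[internal]))
    psi = np.ones((D, K))
    for grp, prior in zip(state.groups, state.branch_prior):
        num = m[:, grp] + prior
        psi[:, grp] = num / num.sum(axis=1, keepdims=True)
    return sigma, psi


def _expected_node_counts(counts: sp.csr_matrix, theta: np.ndarray,
                          beta: np.ndarray) -> tuple[np.ndarray, sp.csr_matrix]:
    """E-step: expected token counts per (cell, node).

    Returns ``(n, ratio)`` where ``ratio`` is the sparse matrix
    ``C_dg / p_dg`` on the nonzero pattern (``p = theta @ beta``),
    reused for the global sufficient statistics.
    """
    mix = theta @ beta                       # cells x genes, strictly positive
    ratio = counts.copy().astype(float)
    rows = np.repeat(np.arange(ratio.shape[0]), np.diff(ratio.indptr))
    ratio.data = ratio.data / mix[rows, ratio.indices]
    n = np.asarray(ratio @ beta.T) * theta
    return n, ratio


def _prior_terms(state: VariationalState, sigma: np.ndarray, psi: np.ndarray,
                 config: FitConfig) -> float:
    internal = np.flatnonzero(state.internal)
    val = float((state.a_stop[internal] * np.log(sigma[:, internal])
                 + state.a_go[internal] * np.log(1.0 - sigma[:, internal])).sum())
    for grp, prior in zip(state.groups, state.branch_prior):
        val += float((prior * np.log(psi[:, grp])).sum())
    return val


def _objective(counts: sp.csr_matrix, theta: np.ndarray, beta: np.ndarray,
               state: VariationalState, sigma: np.ndarray, psi: np.ndarray,
               config: FitConfig) -> float:
    mix = theta @ beta
    rows = np.repeat(np.arange(counts.shape[0]), np.diff(counts.indptr))
    data_term = float((counts.data * np.log(mix[rows, counts.indices])).sum())
    return (data_term + _prior_terms(state, sigma, psi, config)
            + float(config.eta * np.log(beta).sum()))


def _init_locals(state: VariationalState, n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Prior-mean local parameters (used before any data is seen)."""
    zeros = np.zeros((n_cells, state.tree.n_nodes))
    return _locals_from_counts(state, zeros)


def _local_em(counts: sp.csr_matrix, beta: np.ndarray, state: VariationalState,
              iters: int, sigma=None, psi=None):
    """Per-cell EM sweeps with beta held fixed; returns locals and theta."""
    D = counts.shape[0]
    if sigma is None:
        sigma, psi = _init_locals(state, D)
    theta = _theta_from_locals(state, sigma, psi)
    for _ in range(iters):
        n, _ = _expected_node_counts(counts, theta, beta)
        sigma, psi = _locals_from_counts(state, n)
        theta = _theta_from_locals(state, sigma, psi)
    return sigma, psi, theta


def _align_genes(counts: CountMatrix, model_genes: list[str],
                 beta: np.ndarray, eta: float):
    """Intersect count and model gene sets, renormalizing beta rows."""
    if list(counts.gene_names) == list(model_genes):
        return counts, beta, list(model_genes)
    shared = [g for g in model_genes if g in set(counts.gene_names)]
    if not shared:
        raise ValidationError("count matrix and model share no genes")
    logger.warning("gene sets differ; restricting to %d shared genes",
                   len(shared))
    col_of = {g: j for j, g in enumerate(counts.gene_names)}
    sub_counts = CountMatrix(counts.counts[:, [col_of[g] for g in shared]],
                             shared, counts.barcodes)
    beta_col = {g: j for j, g in enumerate(model_genes)}
    sub_beta = beta[:, [beta_col[g] for g in shared]] + eta
    sub_beta /= sub_beta.sum(axis=1, keepdims=True)
    return sub_counts, sub_beta, shared


def fit(counts: CountMatrix, init: InitResult | GemModel, spec: TreeSpec,
        config: FitConfig = FitConfig()) -> tuple[GemModel, CellLoadings, FitTrace]:
    """Train the nested GEM model.

    ``init`` is either an Algorithm-1 :class:`InitResult` (same gene
    space as ``counts``) or a pretrained :class:`GemModel` (gene sets
    are intersected).  One-batch mode performs full EM updates whose
    penalized objective is non-decreasing; mini-batch mode performs
    stochastic global updates with the configured constant learning
    rate over a seeded shuffle of cells per epoch.

    Returns the fitted model, per-cell loadings on the training cells,
    and the per-epoch trace.
    """
    if counts.n_cells == 0:
        raise ValidationError("empty count matrix")
    if isinstance(init, GemModel):
        if init.tree.branching != spec.branching:
            raise ValidationError(
                f"init tree {init.tree.branching} != spec {spec.branching}")
        counts, beta, genes = _align_genes(counts, init.gene_names,
                                           init.beta, config.eta)
    else:
        if init.tree.branching != spec.branching:
            raise ValidationError(
                f"init tree {init.tree.branching} != spec {spec.branching}")
        if init.init_beta.shape[1] != counts.n_genes:
            raise ValidationError(
                "InitResult gene dimension does not match counts")
        beta = init.init_beta.copy()
        genes = list(counts.gene_names)
    beta = np.maximum(beta, 1e-12)
    beta /= beta.sum(axis=1, keepdims=True)

    state = _build_state(spec, config)
    rng = np.random.default_rng(config.seed)
    D = counts.n_cells
    C = counts.counts.astype(float).tocsr()
    C.eliminate_zeros()
    trace = FitTrace(settings={
        "mode": config.mode, "learning_rate": config.learning_rate,
        "batch_size": config.batch_size, "seed": config.seed,
        "gamma_switch": config.gamma_switch, "tau": config.tau,
        "eta": config.eta, "switch_strength": config.switch_strength,
    })

    sigma, psi = _init_locals(state, D)
    theta = _theta_from_locals(state, sigma, psi)
    prev_obj = None
    for epoch in range(1, config.max_epochs + 1):
        if config.mode == "one-batch":
            # exact EM: E-step with current (theta, beta), joint M-step;
            # the beta statistics must use the E-step theta
            n, ratio = _expected_node_counts(C, theta, beta)
            stats = beta * (theta.T @ ratio)     # expected (node, gene) tokens
            sigma, psi = _locals_from_counts(state, n)
            theta = _theta_from_locals(state, sigma, psi)
            beta = stats + config.eta
            beta /= beta.sum(axis=1, keepdims=True)
        else:
            order = rng.permutation(D)
            for start in range(0, D, config.batch_size):
                batch = order[start:start + config.batch_size]
                Cb = C[batch]
                sb, pb, tb = _local_em(Cb, beta, state, config.local_iters,
                                       sigma[batch], psi[batch])
                sigma[batch], psi[batch] = sb, pb
                _, ratio_b = _expected_node_counts(Cb, tb, beta)
                stats_b = beta * (tb.T @ ratio_b) * (D / len(batch))
                beta_hat = stats_b + config.eta
                beta_hat /= beta_hat.sum(axis=1, keepdims=True)
                state.step_count += 1
                rho = config.learning_rate
                if config.lr_decay:
                    rho = config.learning_rate / np.sqrt(state.step_count)
                beta = (1.0 - rho) * beta + rho * beta_hat
            theta = _theta_from_locals(state, sigma, psi)
        obj = _objective(C, theta, beta, state, sigma, psi, config)
        trace.epoch_likelihoods.append(obj)
        if prev_obj is not None:
            rel = abs(obj - prev_obj) / max(abs(prev_obj), 1e-300)
            if rel < config.conv_tol:
                trace.converged_at = epoch
                break
        prev_obj = obj

    model = GemModel(tree=spec, beta=beta, gene_names=genes,
                     alpha=config.alpha, tau=config.tau, eta=config.eta,
                     gamma_switch=config.gamma_switch,
                     provenance={"mode": config.mode, "seed": config.seed,
                                 "epochs": len(trace.epoch_likelihoods)})
    loadings = CellLoadings(tree=spec, theta=theta, barcodes=counts.barcodes)
    return model, loadings, trace


def warm_start(pretrained: GemModel, target_genes: list[str]) -> GemModel:
    """Transfer a pretrained model onto a new gene vocabulary.

    Shared genes keep their pretrained weight; genes unseen during
    pretraining enter at the ``eta``-smoothed minimum mass.  Rows are
    renormalized and provenance is recorded, so the result can seed
    :func:`fit` directly.
    """
    target_genes = list(target_genes)
    col_of = {g: j for j, g in enumerate(pretrained.gene_names)}
    K = pretrained.tree.n_nodes
    # unseen genes enter at eta mass; shared genes keep their weight
    beta = np.full((K, len(target_genes)), pretrained.eta)
    shared = [g for g in target_genes if g in col_of]
    if shared:
        src = [col_of[g] for g in shared]
        dst = [target_genes.index(g) for g in shared]
        beta[:, dst] = np.maximum(pretrained.beta[:, src], 1e-300)
    beta /= beta.sum(axis=1, keepdims=True)
    prov = dict(pretrained.provenance)
    prov["warm_start"] = {"shared_genes": len(shared),
                          "target_genes": len(target_genes)}
    return replace(pretrained, beta=beta, gene_names=target_genes,
                   provenance=prov)


def infer_loadings(model: GemModel, counts: CountMatrix,
                   config: FitConfig | None = None,
                   max_iters: int = 200, tol: float = 1e-8) -> CellLoadings:
    """Fold-in: infer per-cell theta with the gene distributions frozen.

    Only per-cell local updates run; ``model.beta`` is never modified.
    Cells with no counts on the model's genes get a uniform theta over
    the top-level nodes and are logged.  Deterministic.
    """
    if config is None:
        config = FitConfig(gamma_switch=model.gamma_switch, tau=model.tau,
                           eta=model.eta)
    sub_counts, beta, _ = _align_genes(counts, model.gene_names,
                                       model.beta, model.eta)
    state = _build_state(model.tree, config)
    C = sub_counts.counts.astype(float).tocsr()
    C.eliminate_zeros()
    totals = np.asarray(C.sum(axis=1)).ravel()
    empty = totals == 0
    if empty.any():
        logger.warning("%d cells share no counts with the model genes; "
                       "their theta is uniform over top-level nodes",
                       int(empty.sum()))
    sigma, psi = _init_locals(state, C.shape[0])
    theta = _theta_from_locals(state, sigma, psi)
    for _ in range(max_iters):
        n, _ = _expected_node_counts(C, theta, beta)
        sigma, psi = _locals_from_counts(state, n)
        new_theta = _theta_from_locals(state, sigma, psi)
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if delta < tol:
            break
    if empty.any():
        top = [i for i, k in enumerate(model.tree.node_ids)
               if model.tree.level_of[k] == 1]
        theta[empty] = 0.0
        theta[np.ix_(np.flatnonzero(empty), top)] = 1.0 / len(top)
    return CellLoadings(tree=model.tree, theta=theta,
                        barcodes=sub_counts.barcodes)
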