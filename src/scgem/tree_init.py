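"""Tree initialization: recursive L1 KMeans with information breaking.

The initial gene distribution of every GEM node is found level-by-level.
Top-level centroids come from L1 KMeans (k-medians) on per-cell gene
proportions.  Before clustering a node's cells into its children, each
cell's proportion vector is *residualized* against the node centroid —
"breaking the information" the parent already explains — so the children
pick up what remains.  The L1 norm is used because it is less sensitive
to the extreme sparsity of single-cell data than the squared norm, and
its exact minimizing centroid is the element-wise median.

The break step removes from a cell's proportion vector ``x`` exactly the
mass the renormalized centroid can explain: with overlap coefficient
``c = sum_g min(x_g, centroid_g)``, the residual is
``max(0, x - c * centroid)`` renormalized back onto the simplex.
This is the single most consequential modelling interpretation in the
package; see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from scgem.datamodel import ProportionMatrix, TreeSpec, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["InitResult", "l1_kmeans", "break_information", "initialize_gem_tree"]


@dataclass
class InitResult:
    """Output of the recursive initialization.

    ``centroids[k]`` is the raw per-node centroid, ``init_beta[k]`` the
    smoothed, renormalized gene distribution ready to seed a
    :class:`~scgem.datamodel.GemModel`; ``assignments[l]`` maps each
    sampled cell to its node at 1-based level ``l`` so the per-level
    assignments trace a root-to-leaf path per cell.
    """

    tree: TreeSpec
    centroids: np.ndarray
    assignments: dict[int, np.ndarray]
    init_beta: np.ndarray
    sampled_cells: np.ndarray = field(default=None, repr=False)


def _l1_cost_matrix(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # rows x k pairwise L1 distances; loop over k keeps memory flat
    out = np.empty((X.shape[0], centroids.shape[0]))
    for j in range(centroids.shape[0]):
        out[:, j] = np.abs(X - centroids[j]).sum(axis=1)
    return out


def _kmeanspp_l1(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding with L1 distances."""
    n = X.shape[0]
    first = int(rng.integers(n))
    centers = [X[first]]
    closest = np.abs(X - centers[0]).sum(axis=1)
    for _ in range(1, k):
        total = closest.sum()
        if total <= 0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=closest / total))
        centers.append(X[idx])
        closest = np.minimum(closest, np.abs(X - centers[-1]).sum(axis=1))
    return np.array(centers)


def l1_kmeans(X: np.ndarray, k: int, max_iter: int = 100, tol: float = 1e-6,
              seed: int = 0, n_init: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """k-medians under the L1 norm.

    Each centroid is the element-wise median of its assigned rows (the
    exact L1 minimizer); assignments go to the L1-nearest centroid with
    ties broken toward the lowest centroid index.  Empty clusters are
    re-seeded from the row farthest (L1) from its current centroid.
    ``n_init`` seeded restarts are run and the solution with the lowest
    total L1 cost is kept.

    Returns ``(centroids, assignments)`` with ``centroids`` of shape
    ``(k, n_features)`` and integer ``assignments`` of length ``len(X)``.
    """
    X = np.asarray(X, dtype=float)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > X.shape[0]:
        raise ValidationError(f"k={k} exceeds number of rows {X.shape[0]}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        centroids, assign, cost = _l1_kmeans_once(X, k, max_iter, tol, rng)
        if best is None or cost < best[2]:
            best = (centroids, assign, cost)
        if k == 1:
            break  # restarts cannot change the k=1 solution
    return best[0], best[1]


def _l1_kmeans_once(X: np.ndarray, k: int, max_iter: int, tol: float,
                    rng: np.random.Generator):
    centroids = _kmeanspp_l1(X, k, rng)
    prev_cost = np.inf
    assign = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        dist = _l1_cost_matrix(X, centroids)
        assign = dist.argmin(axis=1)
        # re-seed empty clusters from the globally worst-fit row
        for j in range(k):
            if not np.any(assign == j):
                worst = int(dist[np.arange(len(assign)), assign].argmax())
                centroids[j] = X[worst]
                assign[worst] = j
        cost = float(np.abs(X - centroids[assign]).sum())
        for j in range(k):
            members = X[assign == j]
            if len(members):
                centroids[j] = np.median(members, axis=0)
        if prev_cost - cost < tol:
            break
        prev_cost = cost
    dist = _l1_cost_matrix(X, centroids)
    assign = dist.argmin(axis=1)
    cost = float(dist[np.arange(len(assign)), assign].sum())
    return centroids, assign, cost


def break_information(x: np.ndarray, centroid: np.ndarray) -> tuple[np.ndarray, bool]:
    """Remove from ``x`` the proportion mass its node centroid explains.

    Returns ``(residual, exhausted)`` where ``residual`` is back on the
    simplex (or all-zero) and ``exhausted`` flags a fully explained cell.
    """
    x = np.asarray(x, dtype=float)
    centroid = np.asarray(centroid, dtype=float)
    total = centroid.sum()
    if total <= 0:
        return x.copy(), not np.any(x > 0)
    c_hat = centroid / total
    overlap = np.minimum(x, c_hat).sum()
    residual = np.maximum(0.0, x - overlap * c_hat)
    s = residual.sum()
    if s <= 0:
        return np.zeros_like(x), True
    return residual / s, False


def initialize_gem_tree(props: ProportionMatrix, spec: TreeSpec,
                        train_size: int | None = None, seed: int = 0,
                        smoothing: float = 1e-6, sweeps: int = 1) -> InitResult:
    """Build initial per-node gene distributions by recursive L1 KMeans.

    A seeded subsample of ``train_size`` cells is clustered into the
    top-level nodes; for every deeper level, the cells assigned to a
    parent are residualized against the parent centroid with
    :func:`break_information` and clustered into its children.  Each
    level is processed once in a top-down pass (``sweeps`` re-runs the
    pass on re-broken residuals; the default single pass is the
    recommended reading of the procedure).

    Parents holding fewer cells than their child count have children
    seeded by perturbing the parent centroid with seeded noise.
    """
    rng = np.random.default_rng(seed)
    n_cells = props.props.shape[0]
    if train_size is None:
        train_size = n_cells
    if train_size > n_cells:
        raise ValidationError(f"train_size {train_size} exceeds {n_cells} cells")
    sampled = np.sort(rng.choice(n_cells, size=train_size, replace=False))
    X0 = props.props[sampled]

    n_genes = X0.shape[1]
    centroids = np.zeros((spec.n_nodes, n_genes))
    assignments: dict[int, np.ndarray] = {}
    id_index = {k: i for i, k in enumerate(spec.node_ids)}

    for _sweep in range(max(1, sweeps)):
        residual = X0.copy()
        # level 1: cluster everything into the top-level nodes
        top = spec.nodes_at_level(1)
        cent, assign = l1_kmeans(residual, len(top),
                                 seed=int(rng.integers(2**31)))
        for j, node in enumerate(top):
            centroids[id_index[node]] = cent[j]
        level_assign = np.array([top[a] for a in assign])
        assignments[1] = level_assign

        for level in range(2, spec.n_levels + 1):
            next_assign = np.zeros(train_size, dtype=int)
            new_residual = residual.copy()
            for parent in spec.nodes_at_level(level - 1):
                children = spec.children_of(parent)
                members = np.flatnonzero(assignments[level - 1] == parent)
                parent_centroid = centroids[id_index[parent]]
                if len(members) < len(children):
                    logger.warning(
                        "node %d has %d cells for %d children; seeding "
                        "children from perturbed parent centroid",
                        parent, len(members), len(children))
                    for child in children:
                        noise = rng.gamma(1.0, 1.0, size=n_genes)
                        perturbed = np.maximum(parent_centroid, 0) + 1e-3 * noise
                        centroids[id_index[child]] = perturbed / perturbed.sum()
                    if len(members):
                        next_assign[members] = children[0]
                    continue
                sub = np.empty((len(members), n_genes))
                for i, m in enumerate(members):
                    sub[i], _ = break_information(residual[m], parent_centroid)
                cent, assign = l1_kmeans(sub, len(children),
                                         seed=int(rng.integers(2**31)))
                for j, child in enumerate(children):
                    centroids[id_index[child]] = cent[j]
                next_assign[members] = np.array([children[a] for a in assign])
                new_residual[members] = sub
            assignments[level] = next_assign
            residual = new_residual

    init_beta = centroids + smoothing
    init_beta /= init_beta.sum(axis=1, keepdims=True)
    return InitResult(tree=spec, centroids=centroids, assignments=assignments,
                      init_beta=init_beta, sampled_cells=sampled)
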