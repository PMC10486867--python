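"""Core domain types: the GEM tree, count/proportion matrices, fitted models.

Conventions used throughout the package:

* cells are rows and genes are columns in every matrix;
* tree nodes carry stable integer ids assigned level-major, left-to-right,
  starting at 1, so a 5-4-3 tree numbers its five top-level GEMs 1..5,
  their children 6..25 and the leaves 26..85;
* ``theta`` columns index the *full* tree by node id; nodes outside a
  cell's active subtree carry (near-)zero mass, so flat consumers need
  no tree knowledge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "TreeSpec", "CountMatrix", "ProportionMatrix", "GemModel",
    "CellLoadings", "StickWeights", "FitTrace",
    "build_tree_spec", "total_nodes", "ancestors",
]

_SIMPLEX_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class TreeSpec:
    """A preset finite branching structure for the GEM tree.

    ``branching[l]`` is the number of children each level-``l`` node has
    (1-based levels; ``branching[0]`` is the number of top-level GEMs).
    A "5-4-3" tree therefore has 5 top GEMs, 4 children under each of
    those, and 3 leaves under each second-level GEM: 85 nodes in total.
    """

    branching: tuple[int, ...]
    node_ids: tuple[int, ...] = field(repr=False)
    parent_of: dict[int, int] = field(repr=False)
    level_of: dict[int, int] = field(repr=False)

    @property
    def n_levels(self) -> int:
        return len(self.branching)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def children_of(self, node: int) -> list[int]:
        """Children of ``node`` in id order (empty for leaves)."""
        return self._children.get(node, [])

    def nodes_at_level(self, level: int) -> list[int]:
        """All node ids at a 1-based level, in id order."""
        return [k for k in self.node_ids if self.level_of[k] == level]

    @property
    def _children(self) -> dict[int, list[int]]:
        # built lazily; frozen dataclass so stash on __dict__
        cached = self.__dict__.get("_children_cache")
        if cached is None:
            cached = {}
            for child, parent in self.parent_of.items():
                cached.setdefault(parent, []).append(child)
            for v in cached.values():
                v.sort()
            self.__dict__["_children_cache"] = cached
        return cached

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"branching": list(self.branching), "version": 1}) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TreeSpec":
        payload = json.loads(Path(path).read_text())
        return build_tree_spec(payload["branching"])


def build_tree_spec(branching) -> TreeSpec:
    """Build a :class:`TreeSpec` from a per-level branching list.

    Ids are assigned level-major, left-to-right, starting at 1, which is
    the order every serialized output uses.

    >>> build_tree_spec([5, 4, 3]).n_nodes
    85
    """
    branching = tuple(int(b) for b in branching)
    if len(branching) == 0:
        raise ValidationError("branching must be non-empty")
    if any(b < 1 for b in branching):
        raise ValidationError(f"branching entries must be >= 1, got {branching}")

    node_ids: list[int] = []
    parent_of: dict[int, int] = {}
    level_of: dict[int, int] = {}
    next_id = 1
    prev_level: list[int] = []
    for level, width in enumerate(branching, start=1):
        if level == 1:
            current = list(range(next_id, next_id + width))
            for k in current:
                level_of[k] = 1
            next_id += width
        else:
            current = []
            for parent in prev_level:
                for _ in range(width):
                    parent_of[next_id] = parent
                    level_of[next_id] = level
                    current.append(next_id)
                    next_id += 1
        node_ids.extend(current)
        prev_level = current
    return TreeSpec(branching=branching, node_ids=tuple(node_ids),
                    parent_of=parent_of, level_of=level_of)


def total_nodes(spec: TreeSpec) -> int:
    """Total GEM count of the tree: sum over levels of the level widths."""
    return spec.n_nodes


def ancestors(spec: TreeSpec, node: int) -> list[int]:
    """Root-to-parent path of ``node``; empty for top-level nodes."""
    if node not in spec.level_of:
        raise ValidationError(f"unknown node id {node}")
    path: list[int] = []
    k = node
    while k in spec.parent_of:
        k = spec.parent_of[k]
        path.append(k)
    path.reverse()
    return path


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI counts, cells x genes."""

    counts: sp.csr_matrix
    gene_names: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_names = list(self.gene_names)
        self.barcodes = list(self.barcodes)
        n_cells, n_genes = self.counts.shape
        if n_genes != len(self.gene_names):
            raise ValidationError(
                f"{n_genes} gene columns but {len(self.gene_names)} gene names")
        if n_cells != len(self.barcodes):
            raise ValidationError(
                f"{n_cells} cell rows but {len(self.barcodes)} barcodes")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValidationError("gene names must be unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("barcodes must be unique")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("counts must be integers")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, index) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(self.counts[index],
                           self.gene_names,
                           [self.barcodes[i] for i in index])


@dataclass
class ProportionMatrix:
    """Per-cell relative gene proportions; all-zero cells are flagged."""

    props: np.ndarray
    gene_names: list[str]
    barcodes: list[str]
    zero_cells: np.ndarray = None  # boolean mask of all-zero input rows

    def __post_init__(self) -> None:
        self.props = np.asarray(self.props, dtype=float)
        if self.zero_cells is None:
            self.zero_cells = ~(self.props.sum(axis=1) > 0)
        row_sums = self.props.sum(axis=1)
        live = ~self.zero_cells
        if np.any(self.props < 0):
            raise ValidationError("proportions must be non-negative")
        if live.any() and not np.allclose(row_sums[live], 1.0, atol=_SIMPLEX_TOL):
            raise ValidationError("nonzero proportion rows must sum to 1")


@dataclass
class GemModel:
    """Fitted (or initial) GEM tree model.

    ``beta[k]`` is the gene distribution of node ``node_ids[k]``;
    ``alpha``/``tau`` are the global and cell-level DP concentrations,
    ``eta`` the symmetric Dirichlet weight on gene distributions and
    ``gamma_switch`` the probability of descending a level during the
    per-cell search.
    """

    tree: TreeSpec
    beta: np.ndarray
    gene_names: list[str]
    alpha: float = 1.0
    tau: float = 1.0
    eta: float = 0.01
    gamma_switch: float = 0.75
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.tree.n_nodes, len(self.gene_names)):
            raise ValidationError(
                f"beta shape {self.beta.shape} does not match "
                f"{self.tree.n_nodes} nodes x {len(self.gene_names)} genes")
        if np.any(self.beta < 0):
            raise ValidationError("beta must be non-negative")
        if not np.allclose(self.beta.sum(axis=1), 1.0, atol=_SIMPLEX_TOL):
            raise ValidationError("each beta row must sum to 1")
        for name, val in (("alpha", self.alpha), ("tau", self.tau), ("eta", self.eta)):
            if val <= 0:
                raise ValidationError(f"{name} must be > 0, got {val}")
        if not (0.0 < self.gamma_switch < 1.0):
            raise ValidationError(
                f"gamma_switch must lie in (0, 1), got {self.gamma_switch}")

    def save(self, outdir: str | Path) -> None:
        """Write beta as a dense TSV (rows = node ids) plus a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(self.beta, index=list(self.tree.node_ids),
                          columns=self.gene_names)
        df.index.name = "node_id"
        df.to_csv(outdir / "beta.tsv", sep="\t", float_format="%.17g")
        sidecar = {
            "branching": list(self.tree.branching),
            "alpha": self.alpha, "tau": self.tau, "eta": self.eta,
            "gamma_switch": self.gamma_switch,
            "provenance": self.provenance,
            "version": 1,
        }
        (outdir / "model.json").write_text(json.dumps(sidecar, indent=1) + "\n")

    @classmethod
    def load(cls, outdir: str | Path) -> "GemModel":
        outdir = Path(outdir)
        sidecar = json.loads((outdir / "model.json").read_text())
        df = pd.read_csv(outdir / "beta.tsv", sep="\t", index_col=0)
        tree = build_tree_spec(sidecar["branching"])
        return cls(tree=tree, beta=df.to_numpy(), gene_names=list(df.columns),
                   alpha=sidecar["alpha"], tau=sidecar["tau"],
                   eta=sidecar["eta"], gamma_switch=sidecar["gamma_switch"],
                   provenance=sidecar.get("provenance", {}))


@dataclass
class CellLoadings:
    """Per-cell distribution over tree nodes plus the active subtree.

    ``theta`` columns follow ``tree.node_ids`` order; ``active_subtree``
    is closed under the parent relation (an active node's ancestors are
    active too).
    """

    tree: TreeSpec
    theta: np.ndarray
    barcodes: list[str]
    active_subtree: list[set[int]] = None
    active_threshold: float = 1e-4

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (len(self.barcodes), self.tree.n_nodes):
            raise ValidationError("theta shape does not match barcodes x nodes")
        if np.any(self.theta < 0):
            raise ValidationError("theta must be non-negative")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=_SIMPLEX_TOL):
            raise ValidationError("each theta row must sum to 1")
        if self.active_subtree is None:
            self.active_subtree = [
                self._close_under_parent(row) for row in self.theta]

    def _close_under_parent(self, row: np.ndarray) -> set[int]:
        ids = np.asarray(self.tree.node_ids)
        active = set(ids[row > self.active_threshold].tolist())
        for k in list(active):
            active.update(ancestors(self.tree, k))
        return active

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.theta, index=self.barcodes,
                          columns=list(self.tree.node_ids))
        df.index.name = "barcode"
        df.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class StickWeights:
    """Weights from successive Beta-distributed breaks of a unit stick."""

    breaks: np.ndarray
    weights: np.ndarray = None
    remainder: float = None

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=float)
        if self.breaks.ndim != 1:
            raise ValidationError("breaks must be a vector")
        if np.any(self.breaks <= 0) or np.any(self.breaks > 1):
            raise ValidationError("breaks must lie in (0, 1]")
        if self.weights is None:
            survived = np.concatenate([[1.0], np.cumprod(1.0 - self.breaks)])
            self.weights = self.breaks * survived[:-1]
            self.remainder = float(survived[-1])
        total = self.weights.sum() + self.remainder
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"stick weights + remainder = {total} != 1")


@dataclass
class FitTrace:
    """Per-epoch training objective and convergence metadata."""

    epoch_likelihoods: list[float] = field(default_factory=list)
    converged_at: int | None = None
    settings: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "epoch": np.arange(1, len(self.epoch_likelihoods) + 1),
            "objective": self.epoch_likelihoods,
        })
        df.to_csv(path, sep="\t", index=False)
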