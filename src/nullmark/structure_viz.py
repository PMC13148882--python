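"""Low-dimensional projection and hierarchical clustering of distance matrices.

Two classical, fully deterministic methods:

* **classical (Torgerson) MDS** — double-center the squared distance matrix,
  B = -1/2 * J D^2 J, eigendecompose, and take coordinates as eigenvectors
  scaled by the square roots of the top non-negative eigenvalues.  Negative
  eigenvalues (a non-Euclidean input) are reported as a diagnostic and never
  used; the requested dimension is capped at the number of positive
  eigenvalues.  Axis signs are oriented so the first-listed population has a
  non-negative coordinate on every axis, making plots reproducible.

* **UPGMA** — agglomerative average-linkage clustering.  At each step the pair
  of clusters at minimal distance is merged (ties broken by the
  lexicographically smallest pair of cluster keys, where a cluster's key is
  its smallest member label); the new cluster's distance to any other is the
  size-weighted average, and the merge height is *half* the merged distance so
  that the cophenetic distance between two leaves equals the cluster distance
  at which they were joined.  The result is ultrametric by construction and
  serializes to Newick with branch lengths equal to height differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_distance import DistanceMatrix

__all__ = ["MdsResult", "Dendrogram", "classical_mds", "upgma"]


@dataclass
class MdsResult:
    """Coordinates and spectrum from classical MDS."""

    labels: list[str]
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # all n, descending
    reconstruction_error: float  # Frobenius norm of distance residuals

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    @property
    def negative_inertia(self) -> float:
        """Total magnitude of negative eigenvalues (non-Euclidean diagnostics)."""
        return float(-self.eigenvalues[self.eigenvalues < 0].sum())

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="population")


def classical_mds(matrix: DistanceMatrix, k: int = 2) -> MdsResult:
    """Torgerson's classical scaling of a finite symmetric distance matrix."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if matrix.has_infinite:
        bad = [
            matrix.labels[i]
            for i in range(len(matrix))
            if np.isinf(matrix.values[i]).any()
        ]
        raise ValueError(
            f"matrix contains infinite distances (populations {bad}); "
            "exclude those populations before projecting"
        )
    d = matrix.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(n, 1) * np.abs(eigval).max(initial=0.0) * np.finfo(float).eps
    n_pos = int((eigval > tol).sum())
    k_eff = min(k, n_pos)
    coords = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])

    # Orient each axis so the first-listed population is non-negative; if it
    # sits at zero, fall back to the first population with a nonzero value.
    for axis in range(k_eff):
        col = coords[:, axis]
        nonzero = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nonzero) and col[nonzero[0]] < 0:
            coords[:, axis] = -col

    if k_eff:
        recon = np.sqrt(
            np.maximum(
                ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2), 0.0
            )
        )
    else:
        recon = np.zeros_like(d)
    error = float(np.linalg.norm(d - recon))
    return MdsResult(
        labels=list(matrix.labels),
        coordinates=coords,
        eigenvalues=eigval,
        reconstruction_error=error,
    )


@dataclass
class Dendrogram:
    """Rooted ultrametric tree from UPGMA.

    ``merges`` lists (left_node, right_node, height, size) with leaves
    numbered 0..n-1 in label order and internal nodes n, n+1, ... in merge
    order; ``height`` is the leaf-to-node distance of the new cluster.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        return self.merges[node - self.n_leaves][2]

    def _node_key(self, node: int) -> str:
        """Lexicographically smallest leaf label under a node (child ordering)."""
        if node < self.n_leaves:
            return self.labels[node]
        left, right, _, _ = self.merges[node - self.n_leaves]
        return min(self._node_key(left), self._node_key(right))

    def to_newick(self) -> str:
        """Newick with branch lengths = parent height - child height.

        Children are ordered by their smallest leaf label so serialization is
        deterministic regardless of merge orientation.
        """

        def children(left: int, right: int) -> tuple[int, int]:
            return (left, right) if self._node_key(left) <= self._node_key(right) else (right, left)

        def render(node: int, parent_height: float) -> str:
            length = parent_height - self.node_height(node)
            if node < self.n_leaves:
                label = self.labels[node].replace(" ", "_").replace(",", "").replace("(", "").replace(")", "")
                return f"{label}:{length:.6g}"
            left, right, height, _ = self.merges[node - self.n_leaves]
            a, b = children(left, right)
            return f"({render(a, height)},{render(b, height)}):{length:.6g}"

        left, right, root_height, _ = self.merges[-1]
        a, b = children(left, right)
        return f"({render(a, root_height)},{render(b, root_height)});"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise leaf distances through the tree (2x the merge height)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        coph = np.zeros((n, n))
        for idx, (left, right, height, _) in enumerate(self.merges):
            for a in members[left]:
                for b in members[right]:
                    coph[a, b] = coph[b, a] = 2.0 * height
            members[n + idx] = members.pop(left) + members.pop(right)
        return coph


def upgma(matrix: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a finite distance matrix."""
    if matrix.has_infinite:
        raise ValueError("matrix contains infinite distances; exclude those populations")
    n = len(matrix)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 populations")

    # Active clusters: node id -> (key = smallest member label, size).
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(matrix.values[i, j])
    active: dict[int, tuple[str, int]] = {i: (matrix.labels[i], 1) for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n

    while len(active) > 1:
        # Minimal distance, ties broken on the lexicographically first key pair.
        best: tuple[str, str] | None = None
        best_pair: tuple[int, int] | None = None
        best_d = math.inf
        for (i, j), d in dist.items():
            key = tuple(sorted((active[i][0], active[j][0])))
            if d < best_d or (d == best_d and (best is None or key < best)):
                best_d, best, best_pair = d, key, (i, j)
        assert best_pair is not None
        i, j = best_pair
        size_i, size_j = active[i][1], active[j][1]
        new_size = size_i + size_j
        merges.append((i, j, best_d / 2.0, new_size))

        new_key = min(active[i][0], active[j][0])
        del active[i], active[j]
        new_dist: dict[tuple[int, int], float] = {}
        for (a, b), d in dist.items():
            if i in (a, b) or j in (a, b):
                continue
            new_dist[(a, b)] = d
        for k in active:
            d_ik = dist[(min(i, k), max(i, k))]
            d_jk = dist[(min(j, k), max(j, k))]
            new_dist[(k, next_id)] = (size_i * d_ik + size_j * d_jk) / new_size
        dist = new_dist
        active[next_id] = (new_key, new_size)
        next_id += 1

    return Dendrogram(labels=list(matrix.labels), merges=merges)
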