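"""Neighborhood structures for cluster statistics.

TFCE needs connected components of supra-threshold elements.  Three
kinds of structure cover the pipeline: a 1-D chain (time bins of a
diagonal course), a 2-D grid with 4-connectivity (train-time x test-time
matrices), and an arbitrary symmetric graph (sensor neighborhoods).
Chain and grid use fast array labelling; graphs fall back to sparse
connected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph

_GRID_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class Adjacency:
    """Symmetric, self-loop-free neighborhood structure over n elements."""

    n_elements: int
    kind: str  # "chain" | "grid" | "graph"
    shape: tuple[int, ...] | None = None
    matrix: sparse.csr_matrix | None = None  # graphs only

    # -- constructors -----------------------------------------------------

    @classmethod
    def chain(cls, n: int) -> "Adjacency":
        """Adjacent time bins of a 1-D course."""
        if n < 1:
            raise ValueError("chain needs >= 1 element")
        return cls(n_elements=n, kind="chain", shape=(n,))

    @classmethod
    def grid(cls, shape: tuple[int, int]) -> "Adjacency":
        """4-connectivity over a 2-D grid (no diagonal neighbors)."""
        if len(shape) != 2 or min(shape) < 1:
            raise ValueError("grid needs a 2-D shape")
        return cls(n_elements=int(np.prod(shape)), kind="grid", shape=tuple(shape))

    @classmethod
    def from_neighbors(cls, neighbor_lists: list[list[int]]) -> "Adjacency":
        """Arbitrary graph from per-element neighbor lists (symmetrized,
        self-loops dropped)."""
        n = len(neighbor_lists)
        if n == 0:
            raise ValueError("empty adjacency")
        rows, cols = [], []
        for i, nbrs in enumerate(neighbor_lists):
            for j in nbrs:
                if not 0 <= j < n:
                    raise ValueError(f"neighbor index {j} out of range")
                if j != i:
                    rows.extend([i, j])
                    cols.extend([j, i])
        mat = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        mat.data[:] = 1.0
        return cls(n_elements=n, kind="graph", matrix=mat)

    # -- queries ----------------------------------------------------------

    def neighbors(self, i: int) -> list[int]:
        if self.kind == "chain":
            out = [j for j in (i - 1, i + 1) if 0 <= j < self.n_elements]
            return out
        if self.kind == "grid":
            nr, nc = self.shape
            r, c = divmod(i, nc)
            out = []
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < nr and 0 <= cc < nc:
                    out.append(rr * nc + cc)
            return out
        return list(self.matrix.indices[self.matrix.indptr[i]:self.matrix.indptr[i + 1]])

    def component_labels(self, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Connected components of the active elements.

        Returns ``(labels, sizes)`` where ``labels`` has one entry per
        element (-1 where inactive) and ``sizes[k]`` is the size of
        component k.
        """
        mask = np.asarray(mask, dtype=bool).ravel()
        labels = np.full(self.n_elements, -1, dtype=int)
        if not mask.any():
            return labels, np.zeros(0, dtype=int)
        if self.kind in ("chain", "grid"):
            lab, n_comp = ndimage.label(
                mask.reshape(self.shape),
                structure=_GRID_STRUCTURE if self.kind == "grid" else None,
            )
            lab = lab.ravel()
            labels[mask] = lab[mask] - 1
            sizes = np.bincount(lab[mask] - 1, minlength=n_comp)
            return labels, sizes
        idx = np.flatnonzero(mask)
        sub = self.matrix[idx][:, idx]
        n_comp, comp = csgraph.connected_components(sub, directed=False)
        labels[idx] = comp
        sizes = np.bincount(comp, minlength=n_comp)
        return labels, sizes
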