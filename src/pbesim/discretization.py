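"""Volume grids, aggregation kernels and precomputed aggregation pair sets.

The sectional solvers operate on a truncated one-dimensional volume domain
``(0, v_max]`` split into ``I`` cells.  Each cell ``i`` has a representative
volume ``reps[i]`` strictly inside it; an aggregation event between
representatives ``v_j`` and ``v_k`` deposits its product into the unique cell
whose bounds satisfy ``edges[i] < v_j + v_k <= edges[i+1]``.  The set of all
such (j, k) pairs per destination cell is precomputed once
(:class:`PairIndexSet`) and drives every birth term downstream.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid",
    "KernelFamily",
    "AggregationKernel",
    "PairIndexSet",
    "build_geometric_grid",
    "build_uniform_grid",
    "grid_from_edges",
    "build_pair_index_set",
    "kernel_eval",
]


class InvalidConfigurationError(ValueError):
    """Raised for grid/kernel parameters that violate preconditions."""


@dataclass(frozen=True)
class Grid:
    """Truncated volume grid.

    Attributes
    ----------
    edges : ndarray, shape (I + 1,)
        Cell boundaries.  ``edges[0] == 0`` and ``edges[I] == v_max``.
    reps : ndarray, shape (I,)
        Representative volume of each cell, ``edges[i] < reps[i] <= edges[i+1]``.
    ratio_exponent : int or None
        For geometric grids, the exponent ``p`` in ``reps[i+1] = 2**(1/p) * reps[i]``.
    """

    edges: np.ndarray
    reps: np.ndarray
    ratio_exponent: int | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        reps = np.asarray(self.reps, dtype=float)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "reps", reps)
        if edges.ndim != 1 or reps.ndim != 1 or edges.size != reps.size + 1:
            raise InvalidConfigurationError(
                f"edges must have one more entry than reps; got {edges.size} edges, {reps.size} reps"
            )
        if reps.size < 2:
            raise InvalidConfigurationError("grid needs at least two cells")
        if edges[0] != 0.0:
            raise InvalidConfigurationError("lowest edge must be 0")
        if not np.all(np.diff(edges) > 0):
            raise InvalidConfigurationError("edges must be strictly increasing")
        inside = (edges[:-1] < reps) & (reps <= edges[1:])
        if not np.all(inside):
            bad = np.flatnonzero(~inside)
            raise InvalidConfigurationError(f"representatives outside their cells at indices {bad.tolist()}")

    @property
    def I(self) -> int:  # noqa: E743 - domain convention for the cell count
        return self.reps.size

    @property
    def v_max(self) -> float:
        return float(self.edges[-1])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def locate(self, volume: float) -> int:
        """Index of the cell with ``edges[i] < volume <= edges[i+1]``.

        Raises :class:`InvalidConfigurationError` if ``volume`` is outside the
        domain.
        """
        if not (self.edges[0] < volume <= self.edges[-1]):
            raise InvalidConfigurationError(f"volume {volume} outside domain (0, {self.v_max}]")
        return int(np.searchsorted(self.edges, volume, side="left")) - 1

    def to_dict(self) -> dict:
        return {
            "edges": self.edges.tolist(),
            "reps": self.reps.tolist(),
            "ratio_exponent": self.ratio_exponent,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Grid":
        return cls(
            edges=np.asarray(payload["edges"], dtype=float),
            reps=np.asarray(payload["reps"], dtype=float),
            ratio_exponent=payload.get("ratio_exponent"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "Grid":
        return cls.from_dict(json.loads(text))


class KernelFamily(str, enum.Enum):
    CONSTANT = "constant"
    ADDITIVE = "additive"
    MULTIPLICATIVE = "multiplicative"


@dataclass(frozen=True)
class AggregationKernel:
    """Symmetric nonnegative coalescence rate ``beta(v, eta)``.

    ``constant`` -> beta0; ``additive`` -> beta0*(v + eta);
    ``multiplicative`` -> beta0*v*eta.
    """

    family: KernelFamily
    beta0: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", KernelFamily(self.family))
        if self.beta0 < 0:
            raise InvalidConfigurationError("beta0 must be nonnegative")

    def __call__(self, v, eta):
        v = np.asarray(v, dtype=float)
        eta = np.asarray(eta, dtype=float)
        if np.any(v <= 0) or np.any(eta <= 0):
            raise ValueError("kernel arguments must be positive volumes")
        if self.family is KernelFamily.CONSTANT:
            return np.broadcast_to(np.asarray(self.beta0, dtype=float), np.broadcast_shapes(v.shape, eta.shape)).copy()
        if self.family is KernelFamily.ADDITIVE:
            return self.beta0 * (v + eta)
        return self.beta0 * (v * eta)  # scale the symmetric product: exact symmetry in fp

    def matrix(self, reps: np.ndarray) -> np.ndarray:
        """Dense ``beta(v_i, v_j)`` evaluated on all representative pairs."""
        return self(reps[:, None], reps[None, :])


def kernel_eval(kernel: AggregationKernel, v, eta):
    """Evaluate ``beta(v, eta)``; positive volumes required."""
    return kernel(v, eta)


@dataclass(frozen=True)
class PairIndexSet:
    """Partition of admissible representative pairs over destination cells.

    Pairs are stored unordered (``j <= k``) with multiplicity 2 for ``j < k``
    and 1 for ``j == k``; the symmetric expansion is applied when rates are
    assembled.  Pairs whose volume sum exceeds ``v_max`` are excluded.
    """

    cell: np.ndarray  # destination cell index per stored pair
    j: np.ndarray
    k: np.ndarray
    mult: np.ndarray
    n_cells: int = field(default=0)

    def __len__(self) -> int:
        return self.cell.size

    def ordered_pairs(self, i: int) -> list[tuple[int, int]]:
        """All ordered pairs (j, k) binned into cell ``i``, sorted."""
        sel = self.cell == i
        out: list[tuple[int, int]] = []
        for jj, kk in zip(self.j[sel], self.k[sel]):
            out.append((int(jj), int(kk)))
            if jj != kk:
                out.append((int(kk), int(jj)))
        return sorted(out)

    def to_dict(self) -> dict:
        return {"n_cells": self.n_cells, "cells": [self.ordered_pairs(i) for i in range(self.n_cells)]}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def build_geometric_grid(p: int, I: int, v1: float = 1.0) -> Grid:
    """Geometric grid with representatives ``v1 * 2**((i-1)/p)``.

    Interior edges are arithmetic midpoints of adjacent representatives, the
    lowest edge is pinned to 0 and the top edge extends the last midpoint by
    the grid ratio ``2**(1/p)`` (which defines ``v_max``).
    """
    if not (isinstance(p, (int, np.integer)) and p >= 1):
        raise InvalidConfigurationError(f"ratio exponent p must be a positive integer, got {p!r}")
    if I < 2:
        raise InvalidConfigurationError(f"need at least 2 cells, got {I}")
    if v1 <= 0:
        raise InvalidConfigurationError(f"v1 must be positive, got {v1}")
    ratio = 2.0 ** (1.0 / p)
    reps = v1 * ratio ** np.arange(I)
    edges = np.empty(I + 1)
    edges[0] = 0.0
    edges[1:I] = 0.5 * (reps[:-1] + reps[1:])
    edges[I] = edges[I - 1] * ratio
    return Grid(edges=edges, reps=reps, ratio_exponent=int(p))


def build_uniform_grid(I: int, spacing: float = 1.0) -> Grid:
    """Linear grid with representatives ``spacing * (1..I)`` and half-step edges.

    On this grid the sum of two representatives always coincides with another
    representative, so the sectional schemes reduce to the classic discrete
    coagulation equations (used by the test oracles).
    """
    if I < 2:
        raise InvalidConfigurationError(f"need at least 2 cells, got {I}")
    if spacing <= 0:
        raise InvalidConfigurationError("spacing must be positive")
    reps = spacing * np.arange(1, I + 1, dtype=float)
    edges = np.concatenate(([0.0], reps + 0.5 * spacing))
    return Grid(edges=edges, reps=reps)


def grid_from_edges(edges: np.ndarray, reps: np.ndarray | None = None) -> Grid:
    """Grid from a user-supplied edge array; midpoint representatives by default."""
    edges = np.asarray(edges, dtype=float)
    if reps is None:
        reps = 0.5 * (edges[:-1] + edges[1:])
    return Grid(edges=edges, reps=np.asarray(reps, dtype=float))


def build_pair_index_set(grid: Grid) -> PairIndexSet:
    """Bin every admissible unordered representative pair into its destination cell.

    A pair (j, k) lands in the unique cell with
    ``edges[i] < reps[j] + reps[k] <= edges[i+1]``; sums above ``v_max`` are
    dropped.  Ordering is deterministic: ascending (cell, j, k).
    """
    reps = grid.reps
    I = grid.I
    jj, kk = np.triu_indices(I)
    sums = reps[jj] + reps[kk]
    keep = sums <= grid.v_max
    jj, kk, sums = jj[keep], kk[keep], sums[keep]
    # upper-inclusive binning: a sum exactly on an edge goes to the lower cell
    cell = np.searchsorted(grid.edges, sums, side="left") - 1
    mult = np.where(jj == kk, 1, 2)
    order = np.lexsort((kk, jj, cell))
    return PairIndexSet(
        cell=cell[order].astype(np.intp),
        j=jj[order].astype(np.intp),
        k=kk[order].astype(np.intp),
        mult=mult[order].astype(float),
        n_cells=I,
    )
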