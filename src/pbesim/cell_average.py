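"""Cell-average comparator scheme.

Births landing in a cell are first summarized by their number, volume and
tracer rates; the mean newborn volume then decides how the births are split
between the cell's representative and one adjacent representative so that
newborn number and newborn volume are both preserved.  Tracer births reuse the
number-derived weights.  Death terms are identical to the finite-volume
scheme — the two methods differ only in where births are placed, which is what
lets the comparator go negative on coarse grids with size-dependent kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discretization import AggregationKernel, Grid, PairIndexSet
from .fvs import ParticleState

__all__ = ["BirthSummary", "cat_birth_summary", "cat_redistribute", "cat_rhs"]


@dataclass(frozen=True)
class BirthSummary:
    """Per-cell newborn rates before redistribution."""

    number_rate: np.ndarray
    volume_rate: np.ndarray
    tracer_rate: np.ndarray
    mean_volume: np.ndarray  # nan where no births occur

    @property
    def active(self) -> np.ndarray:
        return self.number_rate > 0


def cat_birth_summary(
    state: ParticleState,
    grid: Grid,
    pairs: PairIndexSet,
    kernel: AggregationKernel,
) -> BirthSummary:
    """Aggregate newborn number/volume/tracer rates and the mean newborn volume."""
    state.check_grid(grid)
    beta = kernel.matrix(grid.reps)
    rates = _summary_arrays(state.N, state.m, grid, pairs, beta)
    return BirthSummary(*rates)


def _summary_arrays(N, m, grid, pairs, beta):
    bjk = pairs.mult * beta[pairs.j, pairs.k]
    nn = 0.5 * bjk * N[pairs.j] * N[pairs.k]
    vsum = grid.reps[pairs.j] + grid.reps[pairs.k]
    number = np.zeros(grid.I)
    volume = np.zeros(grid.I)
    tracer = np.zeros(grid.I)
    np.add.at(number, pairs.cell, nn)
    np.add.at(volume, pairs.cell, nn * vsum)
    np.add.at(tracer, pairs.cell, 0.5 * bjk * (m[pairs.j] * N[pairs.k] + m[pairs.k] * N[pairs.j]))
    with np.errstate(invalid="ignore", divide="ignore"):
        vbar = np.where(number != 0, volume / np.where(number != 0, number, 1.0), np.nan)
    return number, volume, tracer, vbar


def cat_redistribute(summary: BirthSummary, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Split each cell's births between its representative and one neighbour.

    The weight on the home node, lam = (vbar - v_far) / (v_near - v_far),
    preserves both newborn number and newborn volume; the identical weights are
    applied to the tracer birth rate.  An interior mean always lies within the
    neighbour span, so interior weights sit in [0, 1].  At the last cell an
    upward mean has no node above it: the preservation constraints are kept by
    pairing with the node below, which makes the neighbour weight negative —
    this is the scheme's documented boundary pathology and is deliberately not
    clipped.
    """
    I = grid.I
    reps = grid.reps
    eff_number = np.zeros(I)
    eff_tracer = np.zeros(I)
    active = np.flatnonzero((summary.number_rate != 0) | (summary.tracer_rate != 0))
    for i in active:
        vbar = summary.mean_volume[i]
        if summary.number_rate[i] == 0 or vbar == reps[i]:
            lam, neighbour = 1.0, i
        else:
            if vbar > reps[i]:
                neighbour = i + 1 if i + 1 < I else i - 1
            else:
                neighbour = i - 1 if i > 0 else i + 1
            lam = (vbar - reps[neighbour]) / (reps[i] - reps[neighbour])
        eff_number[i] += lam * summary.number_rate[i]
        eff_number[neighbour] += (1.0 - lam) * summary.number_rate[i]
        eff_tracer[i] += lam * summary.tracer_rate[i]
        eff_tracer[neighbour] += (1.0 - lam) * summary.tracer_rate[i]
    return eff_number, eff_tracer


def cat_rhs(
    state: ParticleState,
    grid: Grid,
    pairs: PairIndexSet,
    kernel: AggregationKernel,
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-average rates (number, tracer): redistributed births minus deaths."""
    state.check_grid(grid)
    summary = cat_birth_summary(state, grid, pairs, kernel)
    birth_N, birth_m = cat_redistribute(summary, grid)
    beta = kernel.matrix(grid.reps)
    loss = beta @ state.N
    return birth_N - state.N * loss, birth_m - state.m * loss


def make_cat_agg_rates(grid: Grid, pairs: PairIndexSet, kernel: AggregationKernel):
    """Closure form of :func:`cat_rhs` with kernel precomputation hoisted."""
    beta = kernel.matrix(grid.reps)

    def agg_rates(N: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        number, volume, tracer, vbar = _summary_arrays(N, m, grid, pairs, beta)
        summary = BirthSummary(number, volume, tracer, vbar)
        birth_N, birth_m = cat_redistribute(summary, grid)
        loss = beta @ N
        return birth_N - N * loss, birth_m - m * loss

    return agg_rates
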