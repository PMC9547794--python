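"""Brute-force reference implementations used only by the test suite.

These deliberately share no assembly code with the production schemes: the
pair condition is re-tested inline per (i, j, k) triple, and the linear-grid
reference solves the classic discrete coagulation equations by direct
summation over integer volumes.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .discretization import AggregationKernel, Grid, build_uniform_grid
from .fvs import ParticleState

__all__ = [
    "brute_force_tracer_rhs",
    "brute_force_number_rhs",
    "discrete_smoluchowski_reference",
]


def _in_cell(grid: Grid, i: int, volume_sum: float) -> bool:
    return grid.edges[i] < volume_sum <= grid.edges[i + 1]


def brute_force_tracer_rhs(state: ParticleState, grid: Grid, kernel: AggregationKernel) -> np.ndarray:
    """Triple loop over (i, j, k) with the binning condition re-tested inline."""
    I = grid.I
    reps = grid.reps
    out = np.zeros(I)
    for i in range(I):
        birth = 0.0
        for j in range(I):
            for k in range(I):
                s = reps[j] + reps[k]
                if _in_cell(grid, i, s):
                    birth += 0.5 * float(kernel(reps[j], reps[k])) * (
                        state.m[j] * state.N[k] + state.m[k] * state.N[j]
                    )
        death = 0.0
        for j in range(I):
            death += float(kernel(reps[i], reps[j])) * state.N[j]
        out[i] = birth - death * state.m[i]
    return out


def brute_force_number_rhs(state: ParticleState, grid: Grid, kernel: AggregationKernel) -> np.ndarray:
    """Triple-loop companion for the number field."""
    I = grid.I
    reps = grid.reps
    out = np.zeros(I)
    for i in range(I):
        birth = 0.0
        for j in range(I):
            for k in range(I):
                if _in_cell(grid, i, reps[j] + reps[k]):
                    birth += 0.5 * float(kernel(reps[j], reps[k])) * state.N[j] * state.N[k]
        death = 0.0
        for j in range(I):
            death += float(kernel(reps[i], reps[j])) * state.N[j]
        out[i] = birth - death * state.N[i]
    return out


def discrete_smoluchowski_reference(
    I: int,
    kernel: AggregationKernel,
    N0: np.ndarray,
    m0: np.ndarray,
    t_end: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> ParticleState:
    """Classic discrete coagulation equations on integer volumes 1..I.

    dN_i/dt = 1/2 sum_{j+k=i} beta(j,k) N_j N_k - N_i sum_j beta(i,j) N_j,
    with the tracer analog using the symmetrized m/N product.  Aggregates
    larger than I are truncated exactly as in the sectional schemes.
    """
    sizes = np.arange(1, I + 1, dtype=float)
    beta = kernel(sizes[:, None], sizes[None, :])

    def rhs(t, y):
        N, m = y[:I], y[I:]
        dN = np.zeros(I)
        dm = np.zeros(I)
        for i in range(1, I + 1):
            bN = 0.0
            bm = 0.0
            for j in range(1, i):
                k = i - j
                bN += 0.5 * beta[j - 1, k - 1] * N[j - 1] * N[k - 1]
                bm += 0.5 * beta[j - 1, k - 1] * (m[j - 1] * N[k - 1] + m[k - 1] * N[j - 1])
            loss = float(beta[i - 1] @ N)
            dN[i - 1] = bN - N[i - 1] * loss
            dm[i - 1] = bm - m[i - 1] * loss
        return np.concatenate([dN, dm])

    y0 = np.concatenate([np.asarray(N0, dtype=float), np.asarray(m0, dtype=float)])
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    y = sol.y[:, -1]
    return ParticleState(N=y[:I], m=y[I:], t=t_end)


def matching_uniform_grid(I: int) -> Grid:
    """The sectional grid on which the schemes coincide with the discrete equations."""
    return build_uniform_grid(I)
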