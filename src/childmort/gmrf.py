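"""Gaussian Markov random field building blocks shared by the simulator
and the smoother: proper-CAR spatial precision and AR(1) temporal precision.
"""

from __future__ import annotations

import numpy as np

from .graphs import AdjacencyGraph


def car_precision(graph: AdjacencyGraph, rho_s: float) -> np.ndarray:
    """Proper conditionally-autoregressive precision D - rho_s * W.

    D is the diagonal degree matrix and W the 0/1 adjacency.  For a
    connected graph and rho_s in (0, 1) this is symmetric positive
    definite (the intrinsic CAR rho_s = 1 is excluded so the joint prior
    stays proper).
    """
    rho_s = float(rho_s)
    if not 0.0 <= rho_s < 1.0:
        raise ValueError(f"rho_s must be in [0, 1), got {rho_s}")
    W = graph.adjacency_matrix()
    return np.diag(W.sum(axis=1)) - rho_s * W


def ar1_precision(T: int, phi_t: float) -> np.ndarray:
    """Tridiagonal precision of a stationary AR(1) with unit innovation
    variance: diagonal (1, 1+phi^2, ..., 1+phi^2, 1), off-diagonal -phi."""
    T = int(T)
    if T < 1:
        raise ValueError("need T >= 1")
    phi_t = float(phi_t)
    if not -1.0 < phi_t < 1.0:
        raise ValueError(f"phi_t must be in (-1, 1), got {phi_t}")
    Q = np.zeros((T, T))
    idx = np.arange(T)
    Q[idx, idx] = 1.0 + phi_t ** 2
    Q[0, 0] = Q[-1, -1] = 1.0
    if T > 1:
        Q[idx[:-1], idx[1:]] = -phi_t
        Q[idx[1:], idx[:-1]] = -phi_t
    return Q


def kron_quadform(Qs: np.ndarray, Qt: np.ndarray, X: np.ndarray) -> float:
    """vec(X)^T (Qs kron Qt) vec(X) for X of shape (K, T) flattened in
    C order with cell index k*T + t; avoids forming the Kronecker product."""
    return float(np.sum((Qs @ X) * (X @ Qt)))
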