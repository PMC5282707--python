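"""Gauss-Radau collocation machinery over one finite element on [0, 1].

Within each finite element the state trajectory is a degree-``N_D`` Lagrange
interpolating polynomial on ``N_D + 1`` nodes: the left endpoint 0 (an
interpolation-only point carrying the element's initial condition) plus the
``N_D`` right-endpoint Radau points, which include tau = 1.  Radau points are
the roots of the Jacobi polynomial P^(1,0)_{N_D - 1} mapped to (0, 1),
together with 1; collocating there gives the scheme its stiff decay
(L-stability), which matters because batch dynamics stiffen as glucose runs
out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import roots_jacobi


@dataclass(frozen=True)
class CollocationScheme:
    degree: int                      # N_D
    nodes: np.ndarray                # (N_D+1,) in [0,1], nodes[0]=0, nodes[-1]=1
    diff_matrix: np.ndarray          # D[k, n] = d l_n / d tau at tau_k
    quadrature_weights: np.ndarray   # integrate nodal values over [0,1]


def radau_scheme(degree: int) -> CollocationScheme:
    """Build the degree-``degree`` right-endpoint Radau scheme on [0, 1]."""
    if not 1 <= degree <= 9:
        raise ValueError(f"collocation degree must be in [1, 9], got {degree}")
    if degree == 1:
        interior = np.array([])
    else:
        r, _ = roots_jacobi(degree - 1, 1, 0)
        interior = np.sort((r + 1.0) / 2.0)
    nodes = np.concatenate([[0.0], interior, [1.0]])
    D = _diff_matrix(nodes)
    w = _quadrature_weights(nodes)
    return CollocationScheme(degree=degree, nodes=nodes, diff_matrix=D,
                             quadrature_weights=w)


def _barycentric_weights(nodes: np.ndarray) -> np.ndarray:
    n = len(nodes)
    w = np.ones(n)
    for k in range(n):
        for m in range(n):
            if m != k:
                w[k] /= nodes[k] - nodes[m]
    return w


def _diff_matrix(nodes: np.ndarray) -> np.ndarray:
    """Derivative of each Lagrange basis polynomial at each node."""
    n = len(nodes)
    w = _barycentric_weights(nodes)
    D = np.zeros((n, n))
    for k in range(n):
        for m in range(n):
            if m != k:
                D[k, m] = (w[m] / w[k]) / (nodes[k] - nodes[m])
        D[k, k] = -D[k].sum()
    return D


def _quadrature_weights(nodes: np.ndarray) -> np.ndarray:
    """Weights w_k = integral of l_k over [0,1], from the moment equations."""
    n = len(nodes)
    V = np.vander(nodes, n, increasing=True).T   # V[p, k] = tau_k^p
    moments = 1.0 / np.arange(1, n + 1)
    return np.linalg.solve(V, moments)


def diff_matrix(scheme: CollocationScheme) -> np.ndarray:
    """The (N_D+1)x(N_D+1) differentiation matrix of the scheme."""
    return scheme.diff_matrix


def lagrange_eval(scheme: CollocationScheme, nodal_values: np.ndarray,
                  tau: float | np.ndarray) -> np.ndarray:
    """Evaluate the interpolating polynomial at ``tau``.

    ``nodal_values`` has the node axis first (shape ``(N_D+1,)`` or
    ``(N_D+1, m)``).  Extrapolation outside [0, 1] is permitted.  Uses the
    barycentric form, exact at the nodes.
    """
    nodes = scheme.nodes
    vals = np.asarray(nodal_values, dtype=float)
    if vals.shape[0] != len(nodes):
        raise ValueError(
            f"nodal_values first axis {vals.shape[0]} != {len(nodes)} nodes")
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    w = _barycentric_weights(nodes)
    out = np.empty((len(tau_arr),) + vals.shape[1:])
    for i, t in enumerate(tau_arr):
        diff = t - nodes
        exact = np.flatnonzero(np.abs(diff) < 1e-14)
        if len(exact):
            out[i] = vals[exact[0]]
        else:
            coeff = w / diff
            out[i] = np.tensordot(coeff, vals, axes=(0, 0)) / coeff.sum()
    if np.isscalar(tau) or np.ndim(tau) == 0:
        return out[0]
    return out
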