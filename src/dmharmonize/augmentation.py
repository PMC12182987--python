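"""Augmented connectivity via effective conductance on the connection graph.

Each subject's connectivity matrix is read as a resistor network: an edge
between regions i and j has electrical conductance equal to the direct
connectivity c_ij.  The augmented connectivity between any two regions is the
pairwise effective conductance 1 / R_eff(i, j), which aggregates every path —
direct and multi-synaptic — between them.  R_eff comes from the Moore-Penrose
pseudoinverse of the graph Laplacian:

    R_eff(i, j) = L+_ii + L+_jj - 2 L+_ij

Regions in different connected components have no current path and get
augmented connectivity 0.  By Rayleigh monotonicity, adding or strengthening
any edge never decreases an effective conductance, so augmented values
dominate the direct ones.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import connected_components

from .io import ConnectivityTable, vectorize_matrix

__all__ = ["effective_conductance_matrix", "augment_conductance"]


def effective_conductance_matrix(conductance: np.ndarray) -> np.ndarray:
    """Pairwise effective conductance of one symmetric conductance matrix.

    The diagonal of the result is 0 by convention.  Disconnected pairs are 0.
    """
    c = np.asarray(conductance, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("conductance matrix must be square")
    if (c < 0).any():
        raise ValueError("conductances must be non-negative")
    n = c.shape[0]
    out = np.zeros((n, n))
    n_comp, labels = connected_components(c > 0, directed=False)
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        if idx.size < 2:
            continue
        sub = c[np.ix_(idx, idx)]
        lap = np.diag(sub.sum(axis=1)) - sub
        lplus = np.linalg.pinv(lap, hermitian=True)
        d = np.diag(lplus)
        r_eff = d[:, None] + d[None, :] - 2.0 * lplus
        with np.errstate(divide="ignore"):
            g_eff = 1.0 / r_eff
        np.fill_diagonal(g_eff, 0.0)
        out[np.ix_(idx, idx)] = g_eff
    return out


def augment_conductance(original: ConnectivityTable) -> ConnectivityTable:
    """Augment every subject's matrix with indirect (multi-synaptic) pathways."""
    rows = np.empty_like(original.values)
    for k in range(original.n_subjects):
        rows[k] = vectorize_matrix(
            effective_conductance_matrix(original.matrix(k))
        )
    return original.with_values(rows)
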