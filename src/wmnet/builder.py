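"""Whole-brain → WM sub-network → coarse-region matrix construction.

Three steps, applied in order:

1. volume normalization of whole-brain edge weights (region size drives
   streamline counts, so edges are rescaled by inverse region volume);
2. extraction of the 76-node WM sub-matrix;
3. summation coarse-graining to the 24-region scale.

Coarse within-group mass (the summed edges internal to one coarse region)
is excluded from the coarse graph — nodal metrics are defined on loop-free
graphs — but is returned separately so that total connectivity is
conserved across the two outputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .atlas import NodeHierarchy
from .io import Connectome, ConnectomeError

__all__ = [
    "normalize_by_volume",
    "extract_subnetwork",
    "coarsen",
    "build_multiscale",
]

log = logging.getLogger(__name__)

NORMS = ("sum", "product", "none")


def normalize_by_volume(
    c: Connectome, volumes: pd.DataFrame, method: str = "sum"
) -> Connectome:
    """Rescale edge weights by inverse anatomical region volume.

    The default (``sum``) uses the symmetric rule
    ``w'_ij = w_ij * 2 / (v_i + v_j)``, which reduces to the identity when
    all volumes are 1.  ``product`` divides by ``v_i * v_j``; ``none``
    returns the input unchanged.
    """
    if method not in NORMS:
        raise ConnectomeError(f"unknown normalization {method!r}")
    if method == "none":
        return c
    vol = volumes.set_index("wholebrain_index")["volume"]
    missing = [i for i in range(c.n_nodes) if i not in vol.index]
    if missing:
        raise ConnectomeError(
            f"missing volume for node index(es) {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    v = vol.reindex(range(c.n_nodes)).to_numpy(dtype=float)
    if method == "sum":
        denom = (v[:, None] + v[None, :]) / 2.0
    else:
        denom = v[:, None] * v[None, :]
    w = c.weights / denom
    np.fill_diagonal(w, 0.0)
    return Connectome(w, list(c.labels), c.scale, c.subject_id)


def extract_subnetwork(c: Connectome, hierarchy: NodeHierarchy) -> Connectome:
    """Extract the 76-node WM sub-matrix from a whole-brain connectome.

    Output node order follows the hierarchy's fine order; entry (i, j) is
    the whole-brain entry at the mapped indices.
    """
    if not hierarchy.has_wholebrain_index():
        unmapped = [
            p.label
            for i, p in enumerate(hierarchy.fine_nodes)
            if i not in hierarchy.wholebrain_index
        ]
        raise ConnectomeError(f"unmapped node(s): {unmapped[:5]}")
    idx = np.array(
        [hierarchy.wholebrain_index[i] for i in range(len(hierarchy.fine_nodes))]
    )
    if idx.max() >= c.n_nodes:
        raise ConnectomeError(
            f"whole-brain index {idx.max()} out of range for {c.n_nodes}-node matrix"
        )
    w = c.weights[np.ix_(idx, idx)].copy()
    return Connectome(w, hierarchy.fine_labels, "fine76", c.subject_id)


def coarsen(
    c: Connectome, hierarchy: NodeHierarchy
) -> tuple[Connectome, np.ndarray]:
    """Sum fine edges into the 24-region coarse matrix.

    For coarse regions A ≠ B the coarse edge is the sum of all fine edges
    between constituent nodes of A and B.  Returns ``(coarse, within)``
    where ``within[A]`` is the summed mass of edges internal to region A
    (each unordered pair counted once); the coarse diagonal itself is 0.

    Conservation: fine off-diagonal mass = coarse off-diagonal mass
    + 2 × Σ within.
    """
    n_coarse = len(hierarchy.coarse_groups)
    member = np.zeros((n_coarse, c.n_nodes))
    for i, g in enumerate(hierarchy.fine_to_coarse):
        member[g, i] = 1.0
    w = member @ c.weights @ member.T
    within = np.diagonal(w).copy() / 2.0
    np.fill_diagonal(w, 0.0)
    coarse = Connectome(w, hierarchy.coarse_labels, "coarse24", c.subject_id)
    return coarse, within


def build_multiscale(
    c: Connectome,
    volumes: pd.DataFrame | None,
    hierarchy: NodeHierarchy,
    norm: str = "sum",
) -> tuple[Connectome, Connectome]:
    """Normalize → extract → coarsen; returns (fine76, coarse24).

    Volume normalization is applied at the whole-brain scale before
    extraction so both output scales are consistent by construction.
    """
    if volumes is None:
        norm = "none"
    normed = normalize_by_volume(c, volumes, method=norm) if norm != "none" else c
    fine = extract_subnetwork(normed, hierarchy)
    coarse, within = coarsen(fine, hierarchy)
    log.debug(
        "subject %s: built fine76/coarse24 (within-group mass %.4g)",
        c.subject_id,
        float(within.sum()),
    )
    return fine, coarse
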