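"""Weighted nodal graph metrics: CC, EC, LA, PC.

All four metrics operate on loop-free symmetric nonnegative weight
matrices and are invariant to a positive rescaling of the weights.

* Clustering coefficient (CC) — Onnela geometric-mean form: for node *i*
  with binary degree k_i,
  ``CC_i = 2/(k_i (k_i-1)) * Σ_{j<h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}``
  with ``ŵ = w / max(W)``; CC_i = 0 when k_i < 2.  A segregation measure.
* Eigenvector centrality (EC) — the dominant eigenvector of W, entries
  ≥ 0, L2 norm 1, computed by shifted power iteration.
* Local assortativity (LA) — an edge-decomposition of the global weighted
  strength-assortativity coefficient r: over ordered pairs (i, j) with
  weight w_ij, with stub-weighted mean μ and variance σ² of endpoint
  strengths, ``LA_i = Σ_j w_ij (s_i-μ)(s_j-μ) / (σ² Σ w)``.  By
  construction ``Σ_i LA_i = r``.
* Participation coefficient (PC) — ``PC_i = 1 - Σ_m (s_i(m)/s_i)²`` over
  modules m of a node partition; 0 for isolated nodes.  An integration
  measure, bounded by 1 - 1/M for M modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .atlas import SYSTEMS, NodeHierarchy, coarse_partition
from .io import Connectome

__all__ = [
    "clustering_coefficient",
    "eigenvector_centrality",
    "local_assortativity",
    "participation_coefficient",
    "compute_metric_table",
    "MetricTable",
    "METRICS",
    "DegenerateStrengthsError",
]

log = logging.getLogger(__name__)

METRICS = ("CC", "EC", "LA", "PC")


class MetricError(ValueError):
    pass


class DegenerateStrengthsError(MetricError):
    """All node strengths equal: local assortativity is undefined."""


def _check_matrix(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise MetricError("weight matrix must be square")
    if (w < 0).any():
        raise MetricError("weights must be nonnegative")
    if np.any(np.diagonal(w) != 0):
        raise MetricError("matrix must be loop-free (zero diagonal)")
    if not np.allclose(w, w.T):
        raise MetricError("matrix must be symmetric")
    return w


def clustering_coefficient(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering coefficient per node, in [0, 1]."""
    w = _check_matrix(w)
    wmax = w.max()
    if wmax == 0:
        log.warning("all-zero matrix: clustering coefficient set to 0")
        return np.zeros(w.shape[0])
    a = np.cbrt(w / wmax)
    # diag(A^3)_i = 2 * sum_{j<h} a_ij a_jh a_hi  (zero diagonal kills j==h)
    num = np.einsum("ij,jh,hi->i", a, a, a)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(denom > 0, num / denom, 0.0)
    return cc


def eigenvector_centrality(
    w: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000
) -> np.ndarray:
    """Dominant eigenvector of W (entries ≥ 0, L2 norm 1).

    Uses power iteration on the spectrum-shifted matrix W + max(W)·I so the
    dominant eigenvalue is unique in magnitude on each connected component.
    A disconnected graph is computed on the full matrix with a logged
    warning naming the components.
    """
    w = _check_matrix(w)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        raise MetricError("eigenvector centrality undefined on an all-zero matrix")
    n_comp, labels = connected_components(w > 0, directed=False)
    if n_comp > 1:
        comps = [list(np.flatnonzero(labels == c)) for c in range(n_comp)]
        log.warning(
            "graph has %d connected components %s; centrality computed on the full matrix",
            n_comp,
            comps,
        )
    m = w / wmax + np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = m @ x
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) <= tol * np.linalg.norm(y):
            return y
        x = y
    raise MetricError(f"power iteration did not converge in {max_iter} iterations")


def _stub_moments(w: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    s = w.sum(axis=1)
    w_tot = w.sum()
    mu = float((w @ s).sum() / w_tot)
    sigma2 = float((w * (s[None, :] - mu) ** 2).sum() / w_tot)
    return s, w_tot, mu, sigma2


def local_assortativity(w: np.ndarray) -> np.ndarray:
    """Per-node contribution to the weighted strength assortativity r.

    Raises :class:`DegenerateStrengthsError` when all stub-endpoint
    strengths are equal (σ² = 0), e.g. on a regular equal-weight ring.
    """
    w = _check_matrix(w)
    if w.max() == 0:
        raise MetricError("local assortativity undefined on an all-zero matrix")
    s, w_tot, mu, sigma2 = _stub_moments(w)
    scale = float((w * (s[None, :] ** 2)).sum() / w.sum())
    if sigma2 <= 1e-15 * max(scale, 1.0):
        raise DegenerateStrengthsError(
            "all endpoint strengths equal: assortativity undefined"
        )
    d = s - mu
    return d * (w @ d) / (sigma2 * w_tot)


def participation_coefficient(
    w: np.ndarray, partition: Sequence[int]
) -> np.ndarray:
    """How evenly each node's strength spreads over modules; in [0, 1-1/M]."""
    w = _check_matrix(w)
    n = w.shape[0]
    part = np.asarray(partition)
    if part.shape != (n,):
        raise MetricError(
            f"partition covers {part.shape[0] if part.ndim else 0} nodes, matrix has {n}"
        )
    blocks = np.unique(part)
    onehot = (part[None, :] == blocks[:, None]).astype(float)  # m x n
    sm = w @ onehot.T  # n x m, strength into each module
    s = sm.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = 1.0 - ((sm / s[:, None]) ** 2).sum(axis=1)
    pc[s == 0] = 0.0
    return pc


@dataclass
class MetricTable:
    """Long-format nodal metric values for one scale.

    ``data`` has columns subject_id, node, metric, value.  Subjects whose
    LA is degenerate carry no LA rows (recorded in the log).
    """

    data: pd.DataFrame
    scale: str

    def pivot(self, metric: str) -> pd.DataFrame:
        """Subjects × nodes matrix for one metric (column order preserved)."""
        sub = self.data[self.data["metric"] == metric]
        wide = sub.pivot(index="subject_id", columns="node", values="value")
        order = sub["node"].drop_duplicates().tolist()
        return wide[order]


def _coarse_systems_partition(hierarchy: NodeHierarchy) -> list[int]:
    names = list(SYSTEMS)
    sys_of = {g: names.index(s) for s, gs in SYSTEMS.items() for g in gs}
    return [sys_of[g] for g, _ in hierarchy.coarse_groups]


def _partition_for(
    scale: str, hierarchy: NodeHierarchy, level: str | None, weights: np.ndarray | None
) -> list[int]:
    if level is None:
        level = "groups24" if scale == "fine76" else "systems"
    if level == "louvain":
        return _louvain_partition(weights)
    if scale == "fine76":
        return coarse_partition(hierarchy, level)
    if level == "groups24":
        return list(range(len(hierarchy.coarse_groups)))
    return _coarse_systems_partition(hierarchy)


def _louvain_partition(weights: np.ndarray | None) -> list[int]:
    import networkx as nx

    if weights is None:
        raise MetricError("louvain partition requires a weight matrix")
    g = nx.from_numpy_array(weights)
    comms = nx.community.louvain_communities(g, weight="weight", seed=0)
    part = np.empty(weights.shape[0], dtype=int)
    for b, nodes in enumerate(comms):
        part[list(nodes)] = b
    return part.tolist()


def compute_metric_table(
    connectomes: Sequence[Connectome],
    hierarchy: NodeHierarchy,
    scale: str,
    partition: str | None = None,
) -> MetricTable:
    """All four metrics for every subject at one scale.

    The PC module partition defaults to the 24 anatomical groups at the
    fine scale and the 4 bilateral systems at the coarse scale
    (``partition`` in {"groups24", "systems", "louvain"} overrides).
    Subjects with degenerate strengths have their LA recorded as missing.
    """
    expected_labels = (
        hierarchy.fine_labels if scale == "fine76" else hierarchy.coarse_labels
    )
    rows: list[tuple[str, str, str, float]] = []
    for c in connectomes:
        if c.scale != scale:
            raise MetricError(
                f"subject {c.subject_id}: scale {c.scale} != requested {scale}"
            )
        if list(c.labels) != expected_labels:
            raise MetricError(
                f"subject {c.subject_id}: node labels do not follow the hierarchy order"
            )
        part = _partition_for(scale, hierarchy, partition, c.weights)
        values = {
            "CC": clustering_coefficient(c.weights),
            "EC": eigenvector_centrality(c.weights),
            "PC": participation_coefficient(c.weights, part),
        }
        try:
            values["LA"] = local_assortativity(c.weights)
        except DegenerateStrengthsError:
            log.warning(
                "subject %s: degenerate strengths, LA recorded as missing",
                c.subject_id,
            )
        for metric, vec in values.items():
            rows.extend(
                (c.subject_id, lab, metric, float(v))
                for lab, v in zip(c.labels, vec)
            )
    df = pd.DataFrame(rows, columns=["subject_id", "node", "metric", "value"])
    return MetricTable(df, scale)
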