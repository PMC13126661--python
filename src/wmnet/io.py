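"""Readers and writers for connectivity matrices and tabular inputs.

Connectivity matrices are dense delimited text (comma or whitespace, no
header), the dialect emitted by common tractography connectome commands.
Covariate and region-volume tables are CSV/TSV with named columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "read_connectome",
    "write_connectome",
    "read_covariates",
    "read_volumes",
    "validate_covariates",
    "validate_volumes",
    "ConnectomeError",
]

log = logging.getLogger(__name__)

SCALES = ("wholebrain379", "fine76", "coarse24")
SCALE_DIMS = {"wholebrain379": 379, "fine76": 76, "coarse24": 24}
GROUPS = ("ALL", "HC")
SEXES = ("M", "F")

#: Relative tolerance under which a matrix asymmetry is treated as numeric
#: noise and symmetrized; larger asymmetries indicate a directed matrix.
SYMMETRY_RTOL = 1e-8


class ConnectomeError(ValueError):
    """Raised when a matrix or table violates its contract."""


@dataclass
class Connectome:
    """One subject's symmetric nonnegative weighted connectivity matrix.

    ``weights`` is square with zero diagonal; ``labels`` are the ordered
    node identifiers; ``scale`` is one of ``wholebrain379``, ``fine76``,
    ``coarse24``.
    """

    weights: np.ndarray
    labels: list[str]
    scale: str
    subject_id: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"matrix must be square, got shape {w.shape}")
        if w.shape[0] != len(self.labels):
            raise ConnectomeError(
                f"dimension {w.shape[0]} does not match {len(self.labels)} labels"
            )
        if self.scale not in SCALES:
            raise ConnectomeError(f"unknown scale {self.scale!r}")
        if not np.isfinite(w).all():
            raise ConnectomeError("matrix contains non-finite entries")
        if (w < 0).any():
            raise ConnectomeError("matrix contains negative entries")
        scale_w = max(np.abs(w).max(), 1.0)
        if not np.allclose(w, w.T, rtol=0, atol=SYMMETRY_RTOL * scale_w):
            raise ConnectomeError("matrix asymmetry exceeds tolerance")
        w = (w + w.T) / 2.0
        if np.any(np.diagonal(w) != 0):
            log.warning(
                "subject %s: nonzero diagonal forced to 0", self.subject_id
            )
            np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def read_connectome(
    path: str | Path,
    expected_dim: int,
    subject_id: str,
    scale: str | None = None,
    labels: list[str] | None = None,
) -> Connectome:
    """Read a dense matrix file and validate it as a :class:`Connectome`.

    The delimiter (comma vs. whitespace) is auto-detected.  Small
    asymmetries within tolerance are symmetrized as (W + Wᵀ)/2; a nonzero
    diagonal is zeroed with a logged warning.
    """
    path = Path(path)
    with open(path) as f:
        first = f.readline()
    delimiter = "," if "," in first else None
    try:
        w = np.loadtxt(path, delimiter=delimiter, dtype=float, ndmin=2)
    except ValueError as e:
        raise ConnectomeError(f"{path}: non-numeric cell ({e})") from e
    if w.shape != (expected_dim, expected_dim):
        raise ConnectomeError(
            f"{path}: expected {expected_dim}x{expected_dim}, got {w.shape[0]}x{w.shape[1]}"
        )
    if scale is None:
        by_dim = {v: k for k, v in SCALE_DIMS.items()}
        scale = by_dim.get(expected_dim, "fine76")
    if labels is None:
        labels = [f"n{i}" for i in range(expected_dim)]
    return Connectome(w, list(labels), scale, subject_id)


def write_connectome(c: Connectome, path: str | Path) -> Path:
    """Write the weight matrix as comma-delimited text (full precision)."""
    path = Path(path)
    np.savetxt(path, c.weights, delimiter=",", fmt="%.17g")
    return path


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a covariate table: subject_id, group (ALL/HC), age, sex (M/F)."""
    required = {"subject_id", "group", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ConnectomeError(f"covariates missing columns {sorted(missing)}")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ConnectomeError(f"duplicate subject_id {dup!r}")
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise ConnectomeError(f"invalid group value(s) {sorted(bad_group)}")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise ConnectomeError(f"invalid sex value(s) {sorted(bad_sex)}")
    df["age"] = pd.to_numeric(df["age"], errors="raise").astype(float)
    if (df["age"] <= 0).any():
        raise ConnectomeError("age must be positive")
    return df.reset_index(drop=True)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject covariate table (CSV/TSV with header)."""
    return validate_covariates(_read_table(path))


def validate_volumes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a region-volume table: wholebrain_index, volume (mm^3)."""
    required = {"wholebrain_index", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise ConnectomeError(f"volumes missing columns {sorted(missing)}")
    df = df.copy()
    df["wholebrain_index"] = df["wholebrain_index"].astype(int)
    if df["wholebrain_index"].duplicated().any():
        raise ConnectomeError("duplicate wholebrain_index in volume table")
    df["volume"] = pd.to_numeric(df["volume"], errors="raise").astype(float)
    if (df["volume"] <= 0).any():
        raise ConnectomeError("volumes must be positive")
    return df.reset_index(drop=True)


def read_volumes(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-region anatomical volume table."""
    return validate_volumes(_read_table(path))
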