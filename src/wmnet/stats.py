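"""Nodewise group comparison with robust OLS and BH-FDR; cohort matching.

For every node and metric a linear model ``metric ~ group + age + sex``
is fitted by OLS; the group coefficient (ALL − HC, HC coded 0) is tested
with heteroskedasticity-consistent (HC3 by default) standard errors
against a t reference with n − 4 degrees of freedom.  P-values are
adjusted with the Benjamini–Hochberg step-up procedure within each
(metric, scale) family; significance is FDR-adjusted p < 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .metrics import MetricTable

__all__ = [
    "NodeFit",
    "fit_node_model",
    "bh_fdr",
    "run_group_analysis",
    "frequency_match",
    "StatsError",
]

log = logging.getLogger(__name__)

ROBUST_FLAVORS = ("HC0", "HC1", "HC3")
FAMILIES = ("per-metric-scale", "pooled")


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class NodeFit:
    """Group-effect estimate for one node: beta (ALL − HC), robust SE,
    t statistic and two-sided p-value."""

    beta_group: float
    robust_se: float
    t_stat: float
    p_raw: float
    degenerate: bool = False


def _design(covariates: pd.DataFrame) -> np.ndarray:
    group = (covariates["group"] == "ALL").to_numpy(dtype=float)
    age = covariates["age"].to_numpy(dtype=float)
    sex = (covariates["sex"] == "M").to_numpy(dtype=float)
    return np.column_stack([np.ones_like(age), group, age, sex])


def fit_node_model(
    y: np.ndarray, covariates: pd.DataFrame, robust: str = "HC3"
) -> NodeFit:
    """OLS fit of ``y ~ 1 + group + age + sex`` with sandwich errors.

    Requires at least 10 subjects per group and a full-rank design.  A
    constant response is flagged degenerate with p = 1 by convention.
    """
    if robust not in ROBUST_FLAVORS:
        raise StatsError(f"unknown robust flavor {robust!r}")
    y = np.asarray(y, dtype=float)
    if y.shape[0] != len(covariates):
        raise StatsError("response and covariates disagree in length")
    if not np.isfinite(y).all():
        raise StatsError("response contains non-finite values")
    counts = covariates["group"].value_counts()
    if counts.reindex(["ALL", "HC"]).fillna(0).min() < 10:
        raise StatsError("need at least 10 subjects per group")
    x = _design(covariates)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise StatsError("design matrix is rank deficient")
    if np.ptp(y) == 0:
        return NodeFit(0.0, 0.0, 0.0, 1.0, degenerate=True)
    fit = sm.OLS(y, x).fit(cov_type=robust, use_t=True)
    return NodeFit(
        beta_group=float(fit.params[1]),
        robust_se=float(fit.bse[1]),
        t_stat=float(fit.tvalues[1]),
        p_raw=float(fit.pvalues[1]),
    )


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_group_analysis(
    metrics: MetricTable,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    robust: str = "HC3",
    family: str = "per-metric-scale",
) -> pd.DataFrame:
    """Per node × metric group comparison at one scale.

    Returns a frame with columns scale, node, metric, beta, se, t, p,
    p_fdr, direction, significant.  FDR is applied across nodes within
    each (metric, scale) family (``family="pooled"`` pools all metrics of
    the scale into one family).
    """
    if family not in FAMILIES:
        raise StatsError(f"unknown FDR family {family!r}")
    cov = covariates.set_index("subject_id")
    table_subjects = set(metrics.data["subject_id"].unique())
    if not table_subjects <= set(cov.index):
        missing = sorted(table_subjects - set(cov.index))
        raise StatsError(f"subjects missing from covariates: {missing[:5]}")
    rows = []
    for metric in metrics.data["metric"].unique():
        wide = metrics.pivot(metric)
        cov_m = cov.loc[wide.index].reset_index()
        for node in wide.columns:
            f = fit_node_model(wide[node].to_numpy(), cov_m, robust=robust)
            rows.append(
                {
                    "scale": metrics.scale,
                    "node": node,
                    "metric": metric,
                    "beta": f.beta_group,
                    "se": f.robust_se,
                    "t": f.t_stat,
                    "p": f.p_raw,
                }
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    if family == "pooled":
        out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    else:
        for metric, idx in out.groupby("metric").groups.items():
            out.loc[idx, "p_fdr"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    out["direction"] = np.where(out["beta"] > 0, "ALL>HC", "ALL<HC")
    out["significant"] = out["p_fdr"] < alpha
    return out


def frequency_match(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    age_tol: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Select controls frequency-matched to the cases on age and sex.

    Greedy nearest-age selection without replacement within each sex,
    accepting only controls within ``age_tol`` years of their case (±1-year
    tolerance bins).  The selection is then trimmed (dropping the worst age
    matches) so the male-to-female ratio of the selected controls equals
    the cases' ratio exactly.  Deterministic given ``seed`` (ties in age
    distance are broken by a seeded permutation, then subject_id).
    """
    if pool.empty:
        raise StatsError("control pool is empty")
    rng = np.random.default_rng(seed)
    tie = pd.Series(
        rng.permutation(len(pool)), index=pool["subject_id"].to_numpy()
    )
    picked: dict[str, list[tuple[float, pd.Series]]] = {}
    for sex in ("M", "F"):
        case_ages = sorted(cases.loc[cases["sex"] == sex, "age"])
        candidates = pool[pool["sex"] == sex].copy()
        chosen: list[tuple[float, pd.Series]] = []
        used: set[str] = set()
        for age in case_ages:
            avail = candidates[~candidates["subject_id"].isin(used)]
            if avail.empty:
                continue
            diff = (avail["age"] - age).abs()
            ok = avail[diff <= age_tol]
            if ok.empty:
                continue
            order = ok.assign(
                _d=(ok["age"] - age).abs(),
                _t=tie.loc[ok["subject_id"]].to_numpy(),
            ).sort_values(["_d", "_t", "subject_id"])
            best = order.iloc[0]
            used.add(best["subject_id"])
            chosen.append((float(best["_d"]), best.drop(labels=["_d", "_t"])))
        picked[sex] = chosen
    # trim to the exact case sex ratio
    n_m = int((cases["sex"] == "M").sum())
    n_f = int((cases["sex"] == "F").sum())
    g = math.gcd(n_m, n_f)
    unit = {"M": n_m // g if g else 0, "F": n_f // g if g else 0}
    multiples = [
        len(picked[s]) // unit[s] for s in ("M", "F") if unit[s] > 0
    ]
    t = min(multiples) if multiples else 0
    keep_rows = []
    for s in ("M", "F"):
        target = t * unit[s]
        by_quality = sorted(picked[s], key=lambda q: q[0])[:target]
        keep_rows.extend(r for _, r in by_quality)
    if not keep_rows:
        log.warning("frequency matching found no admissible controls")
        return pool.iloc[0:0].copy()
    out = pd.DataFrame(keep_rows).reset_index(drop=True)
    return out[pool.columns.tolist()]
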