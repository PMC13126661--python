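"""Seeded synthetic cohorts of whole-brain connectomes.

The generator emulates the *structure* of a two-group diffusion-MRI
cohort study — it is a statistical stand-in, not a tractography model.
Each subject receives a symmetric nonnegative zero-diagonal 379-region
matrix with gamma-distributed edge weights (streamline weights are
right-skewed), a planted block structure aligned to the 24-region WM
hierarchy (edges inside one coarse group are boosted), and a Bernoulli
edge-density mask.  Configurable group effects for the patient (ALL)
group raise (a) the weights among the six subcortical WM nodes — an
injected segregation effect — and (b) the cross-module weights of
designated cortical hub parcels — an injected integration effect.

Edge weights use a constant gamma scale parameter, so stronger edge
classes (within-module, homotopic, subcortical-block) are proportionally
more reliable across subjects — mirroring the fact that large white-matter
bundles are reconstructed far more consistently than weak, spurious
streamline connections.  Homotopic (same parcel, opposite hemisphere)
cortical edges are modeled as strong low-variability anchors; they also
stabilize the max-weight normalization used by the Onnela clustering
coefficient.

Random streams are split per subject (keyed by seed, group and subject
index), so changing ``n_per_group`` does not perturb earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .atlas import (
    NodeHierarchy,
    attach_wholebrain_indices,
    build_wm_node_set,
    load_default_lookup,
)
from .builder import build_multiscale
from .classify import classify
from .io import Connectome, validate_covariates, validate_volumes
from .metrics import compute_metric_table
from .stats import run_group_analysis

__all__ = ["SimConfig", "generate_cohort", "recovery_benchmark"]

N_REGIONS = 379


class SimError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator settings.

    Defaults mirror the emulated study design: 70 subjects per group,
    40 male / 30 female each, imaging ages uniform on 6.2–20.3 years.
    ``base_weight_shape``/``base_weight_scale`` parameterize the gamma
    edge-weight distribution (mean 1 by default); ``within_module_boost``
    multiplies edges inside one coarse anatomical group; ``density`` is
    the fraction of nonzero edges.  Group effects are multiplicative and
    act on the patient group only.
    """

    n_per_group: int = 70
    seed: int = 0
    base_weight_shape: float = 4.0
    base_weight_scale: float = 0.25
    within_module_boost: float = 2.0
    subcortical_block_weight: float = 6.0
    homotopic_weight: float = 16.0
    homotopic_shape: float = 1024.0
    density: float = 1.0
    effect_subcortical_seg: float = 1.0
    effect_cortical_int: float = 1.0
    age_range: tuple[float, float] = (6.2, 20.3)
    male_fraction: float = 40 / 70
    hub_groups: tuple[str, ...] = ("DLPC",)
    unit_volumes: bool = False

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise SimError("n_per_group must be at least 2")
        if not 0 < self.density <= 1:
            raise SimError("density must lie in (0, 1]")
        for name in (
            "base_weight_shape",
            "base_weight_scale",
            "within_module_boost",
            "subcortical_block_weight",
            "homotopic_weight",
            "homotopic_shape",
            "effect_subcortical_seg",
            "effect_cortical_int",
        ):
            if getattr(self, name) <= 0:
                raise SimError(f"{name} must be positive")
        if not 0 <= self.male_fraction <= 1:
            raise SimError("male_fraction must lie in [0, 1]")
        if self.age_range[0] <= 0 or self.age_range[1] <= self.age_range[0]:
            raise SimError("age_range must be increasing and positive")


def _mean_structure(
    config: SimConfig, hierarchy: NodeHierarchy
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-group (relative-mean, homotopic-mask) matrices at the whole-brain scale.

    Relative means: background 1, within-coarse-group edges boosted,
    edges among the six subcortical WM nodes at ``subcortical_block_weight``,
    cortical homotopic same-parcel edges at ``homotopic_weight``.  Patient
    (ALL) effects multiply the subcortical block and the hub cross-module
    edges (homotopic edges excluded from the integration effect).
    """
    rel = np.ones((N_REGIONS, N_REGIONS))
    homotopic = np.zeros((N_REGIONS, N_REGIONS), dtype=bool)
    wb = hierarchy.wholebrain_index
    group_of = {wb[i]: hierarchy.fine_to_coarse[i] for i in wb}
    sub_idx = [
        wb[i]
        for i, p in enumerate(hierarchy.fine_nodes)
        if p.kind == "subcortical"
    ]
    hub_idx = [
        wb[i]
        for i, p in enumerate(hierarchy.fine_nodes)
        if p.group_name in config.hub_groups
    ]
    wm_idx = list(group_of)
    # planted community structure: same coarse group -> boosted edge mean
    for a in wm_idx:
        for b in wm_idx:
            if a != b and group_of[a] == group_of[b]:
                rel[a, b] = config.within_module_boost
    # dense low-level interconnection of the subcortical block
    for a in sub_idx:
        for b in sub_idx:
            if a != b:
                rel[a, b] = config.subcortical_block_weight
    # homotopic anchors: same cortical parcel, opposite hemisphere
    by_name: dict[str, list[int]] = {}
    for i, p in enumerate(hierarchy.fine_nodes):
        if p.kind == "cortical":
            by_name.setdefault(p.name, []).append(wb[i])
    for a, b in by_name.values():
        rel[a, b] = rel[b, a] = config.homotopic_weight
        homotopic[a, b] = homotopic[b, a] = True
    rel_all = rel.copy()
    for a in sub_idx:  # injected segregation: subcortical block edges
        for b in sub_idx:
            if a != b:
                rel_all[a, b] *= config.effect_subcortical_seg
    for a in hub_idx:  # injected integration: hub cross-module edges
        for b in wm_idx:
            if b != a and group_of[a] != group_of[b] and not homotopic[a, b]:
                rel_all[a, b] = rel_all[b, a] = (
                    rel[a, b] * config.effect_cortical_int
                )
    np.fill_diagonal(rel, 0.0)
    np.fill_diagonal(rel_all, 0.0)
    return {"HC": (rel, homotopic), "ALL": (rel_all, homotopic)}


def _subject_matrix(
    rng: np.random.Generator,
    rel: np.ndarray,
    homotopic: np.ndarray,
    config: SimConfig,
) -> np.ndarray:
    iu = np.triu_indices(N_REGIONS, k=1)
    mu = rel[iu] * config.base_weight_shape * config.base_weight_scale
    # constant gamma scale: shape grows with the mean, so strong edges are
    # proportionally more reliable; homotopic anchors get a fixed high shape
    shape = mu / config.base_weight_scale
    hom = homotopic[iu]
    shape[hom] = config.homotopic_shape
    w_up = rng.gamma(shape, mu / shape)
    if config.density < 1.0:
        keep = rng.random(w_up.size) < config.density
        w_up = np.where(hom, w_up, w_up * keep)  # anchors always present
    w = np.zeros((N_REGIONS, N_REGIONS))
    w[iu] = w_up
    return w + w.T


def default_hierarchy() -> NodeHierarchy:
    """Packaged WM hierarchy with the default whole-brain lookup attached."""
    return attach_wholebrain_indices(build_wm_node_set(), load_default_lookup())


def generate_cohort(
    config: SimConfig, hierarchy: NodeHierarchy | None = None
) -> tuple[list[Connectome], pd.DataFrame, pd.DataFrame]:
    """Generate (connectomes, covariates, volumes) for one synthetic cohort.

    Fully reproducible from ``config.seed``; the returned matrices pass
    every connectome validation.
    """
    if hierarchy is None:
        hierarchy = default_hierarchy()
    if not hierarchy.has_wholebrain_index():
        raise SimError("hierarchy needs whole-brain indices attached")
    structure = _mean_structure(config, hierarchy)
    connectomes: list[Connectome] = []
    cov_rows = []
    for gi, group in enumerate(("ALL", "HC")):
        rel, homotopic = structure[group]
        n_m = round(config.n_per_group * config.male_fraction)
        for si in range(config.n_per_group):
            rng = np.random.default_rng([config.seed % 2**31, gi, si])
            age = float(rng.uniform(*config.age_range))
            sex = "M" if si < n_m else "F"
            sid = f"{group}{si:03d}"
            w = _subject_matrix(rng, rel, homotopic, config)
            connectomes.append(Connectome(w, [f"r{i}" for i in range(N_REGIONS)],
                                          "wholebrain379", sid))
            cov_rows.append({"subject_id": sid, "group": group, "age": age, "sex": sex})
    covariates = validate_covariates(pd.DataFrame(cov_rows))
    rng_v = np.random.default_rng([config.seed % 2**31, 1_000_003])
    if config.unit_volumes:
        vol = np.ones(N_REGIONS)
    else:
        # log-normal around ~2500 mm^3, the scale of HCP-MMP1 parcels
        vol = np.exp(rng_v.normal(np.log(2500.0), 0.4, size=N_REGIONS))
    volumes = validate_volumes(
        pd.DataFrame({"wholebrain_index": np.arange(N_REGIONS), "volume": vol})
    )
    return connectomes, covariates, volumes


@dataclass
class ReplicateOutcome:
    """Internal: one replicate's analysis products."""

    fine_results: pd.DataFrame
    coarse_results: pd.DataFrame
    report: pd.DataFrame


def run_replicate(
    config: SimConfig, hierarchy: NodeHierarchy | None = None
) -> ReplicateOutcome:
    """Generate one cohort and run build → metrics → stats → classify."""
    if hierarchy is None:
        hierarchy = default_hierarchy()
    connectomes, covariates, volumes = generate_cohort(config, hierarchy)
    fine, coarse = [], []
    for c in connectomes:
        f, co = build_multiscale(c, volumes, hierarchy, norm="sum")
        fine.append(f)
        coarse.append(co)
    mt_fine = compute_metric_table(fine, hierarchy, "fine76")
    mt_coarse = compute_metric_table(coarse, hierarchy, "coarse24")
    res_fine = run_group_analysis(mt_fine, covariates)
    res_coarse = run_group_analysis(mt_coarse, covariates)
    report = classify(res_fine, res_coarse, hierarchy)
    return ReplicateOutcome(res_fine, res_coarse, report)


def _derived_seed(seed: int, r: int) -> int:
    return int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % 2**31)


def recovery_benchmark(
    config: SimConfig,
    n_replicates: int,
    seed: int,
    hierarchy: NodeHierarchy | None = None,
) -> pd.DataFrame:
    """Monte-Carlo detection summary over seeded cohort replicates.

    Runs the full pipeline per replicate and reports, per coarse region ×
    metric: the fraction of replicates with a significant coarse effect
    (split by direction), with any significant fine node, and classified
    ``consistent``.
    """
    if hierarchy is None:
        hierarchy = default_hierarchy()
    tallies: dict[tuple[str, str], dict[str, int]] = {}
    for r in range(n_replicates):
        cfg = replace(config, seed=_derived_seed(seed, r))
        out = run_replicate(cfg, hierarchy)
        for row in out.report.itertuples():
            key = (row.coarse_region, row.metric)
            t = tallies.setdefault(
                key,
                {"coarse_sig": 0, "coarse_up": 0, "coarse_down": 0,
                 "fine_any": 0, "consistent": 0},
            )
            t["coarse_sig"] += int(row.coarse_significant)
            t["coarse_up"] += int(row.coarse_direction == "ALL>HC")
            t["coarse_down"] += int(row.coarse_direction == "ALL<HC")
            t["fine_any"] += int(row.fine_up_count + row.fine_down_count > 0)
            t["consistent"] += int(row.scenario == "consistent")
    rows = [
        {
            "region": region,
            "metric": metric,
            "n_replicates": n_replicates,
            **{f"frac_{k}": v / n_replicates for k, v in t.items()},
        }
        for (region, metric), t in tallies.items()
    ]
    return pd.DataFrame(rows)
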