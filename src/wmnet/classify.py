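"""Cross-scale taxonomy of group effects.

Paired fine-scale (76-node) and coarse-scale (24-node) nodewise results
are summarized per anatomical region × metric and each cell is assigned
one of five scenarios, using FDR-significant calls only:

* ``consistent``  — coarse significant, ≥1 fine node significant in the
  same direction, none in the opposite direction;
* ``fine_only``   — coarse not significant, ≥1 fine node significant, all
  significant fine nodes share one direction;
* ``convergent``  — coarse significant while significant fine nodes exist
  in both directions (or none at all: sub-threshold same-direction shifts
  summing to a coarse effect);
* ``cancelling``  — coarse not significant and significant fine nodes
  exist in both directions;
* ``null``        — no significant call at either scale.

By default the left/right fine nodes of a region are pooled and the two
hemispheric coarse nodes are combined (a region counts as coarse
significant if either hemisphere is, with a direction only when the
significant hemispheres agree); per-hemisphere rows are available with
``pool_hemispheres=False``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import NodeHierarchy

__all__ = ["classify", "scenario_rule", "render_summary", "SCENARIOS"]

SCENARIOS = ("consistent", "fine_only", "convergent", "cancelling", "null")


class ClassifyError(ValueError):
    pass


def scenario_rule(
    coarse_significant: bool,
    coarse_direction: str | None,
    fine_up: int,
    fine_down: int,
) -> str:
    """The pure cross-scale decision rule; returns one scenario label."""
    if coarse_significant:
        same = fine_up if coarse_direction == "ALL>HC" else fine_down
        opposite = fine_down if coarse_direction == "ALL>HC" else fine_up
        if coarse_direction is not None and same >= 1 and opposite == 0:
            return "consistent"
        return "convergent"
    if fine_up >= 1 and fine_down >= 1:
        return "cancelling"
    if fine_up + fine_down >= 1:
        return "fine_only"
    return "null"


def _node_region(label: str, pool: bool) -> str:
    region, hemi = label.rsplit("-", 1)
    return region if pool else f"{region}-{hemi}"


def classify(
    fine_results: pd.DataFrame,
    coarse_results: pd.DataFrame,
    hierarchy: NodeHierarchy,
    pool_hemispheres: bool = True,
) -> pd.DataFrame:
    """Build the cross-scale report from paired nodewise result frames.

    Both inputs are `run_group_analysis` outputs (columns node, metric,
    direction, significant); fine results must cover all 76 fine nodes and
    coarse results all 24 coarse nodes.
    """
    fine_regions = {
        p.label: _node_region(f"{p.group_name}-{p.hemisphere}", pool_hemispheres)
        for p in hierarchy.fine_nodes
    }
    coarse_regions = {
        lab: _node_region(lab, pool_hemispheres) for lab in hierarchy.coarse_labels
    }
    if set(fine_results["node"]) != set(fine_regions):
        raise ClassifyError("fine results do not cover the hierarchy's fine nodes")
    if set(coarse_results["node"]) != set(coarse_regions):
        raise ClassifyError("coarse results do not cover the hierarchy's coarse nodes")
    regions = []
    for lab in hierarchy.coarse_labels:
        r = coarse_regions[lab]
        if r not in regions:
            regions.append(r)
    fine_count = pd.Series(
        [fine_regions[p.label] for p in hierarchy.fine_nodes]
    ).value_counts()

    rows = []
    metrics = fine_results["metric"].unique()
    for metric in metrics:
        f = fine_results[fine_results["metric"] == metric]
        c = coarse_results[coarse_results["metric"] == metric]
        for region in regions:
            f_r = f[f["node"].map(fine_regions) == region]
            c_r = c[c["node"].map(coarse_regions) == region]
            fine_up = int(((f_r["direction"] == "ALL>HC") & f_r["significant"]).sum())
            fine_down = int(((f_r["direction"] == "ALL<HC") & f_r["significant"]).sum())
            fine_null = int(fine_count[region]) - fine_up - fine_down
            c_sig = c_r[c_r["significant"]]
            coarse_sig = len(c_sig) > 0
            dirs = set(c_sig["direction"])
            coarse_dir = dirs.pop() if len(dirs) == 1 else None
            rows.append(
                {
                    "coarse_region": region,
                    "metric": metric,
                    "coarse_direction": coarse_dir if coarse_sig else None,
                    "coarse_significant": coarse_sig,
                    "fine_up_count": fine_up,
                    "fine_down_count": fine_down,
                    "fine_null_count": fine_null,
                    "scenario": scenario_rule(
                        coarse_sig, coarse_dir if coarse_sig else None, fine_up, fine_down
                    ),
                }
            )
    return pd.DataFrame(rows)


def _fine_cell(row: pd.Series) -> str:
    if row["fine_up_count"] > 0 and row["fine_down_count"] == 0:
        return "increase"
    if row["fine_down_count"] > 0 and row["fine_up_count"] == 0:
        return "decrease"
    return "heterogeneous/none"


def _coarse_cell(row: pd.Series) -> str:
    if row["coarse_significant"] and row["coarse_direction"] == "ALL>HC":
        return "increase"
    if row["coarse_significant"] and row["coarse_direction"] == "ALL<HC":
        return "decrease"
    return "heterogeneous/none"


def render_summary(
    report: pd.DataFrame, plot_path: str | Path | None = None
) -> pd.DataFrame:
    """Machine-readable region × metric × scale summary grid.

    Cell values are ``increase`` (ALL > HC), ``decrease`` (ALL < HC) or
    ``heterogeneous/none``.  If ``plot_path`` is given, a red/blue/grey
    heat-grid (decrease/increase/other) is saved alongside.
    """
    grid = report.copy()
    grid["fine"] = grid.apply(_fine_cell, axis=1)
    grid["coarse"] = grid.apply(_coarse_cell, axis=1)
    long = grid.melt(
        id_vars=["coarse_region", "metric"],
        value_vars=["fine", "coarse"],
        var_name="scale",
        value_name="effect",
    )
    out = long.pivot(index="coarse_region", columns=["metric", "scale"], values="effect")
    out = out.loc[report["coarse_region"].unique()]
    if plot_path is not None:
        _plot_grid(out, plot_path)
    return out


def _plot_grid(grid: pd.DataFrame, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    mapping = {"decrease": 0, "increase": 1, "heterogeneous/none": 2}
    data = grid.map(mapping.get).to_numpy(dtype=float)
    cmap = ListedColormap(["#c0392b", "#2e6fb7", "#bdbdbd"])
    fig, ax = plt.subplots(
        figsize=(0.6 * data.shape[1] + 2, 0.4 * data.shape[0] + 2)
    )
    ax.imshow(data, cmap=cmap, vmin=0, vmax=2, aspect="auto")
    ax.set_xticks(np.arange(data.shape[1]))
    ax.set_xticklabels([f"{m}\n{s}" for m, s in grid.columns], fontsize=8)
    ax.set_yticks(np.arange(data.shape[0]))
    ax.set_yticklabels(grid.index, fontsize=8)
    ax.set_title("Group effects (red: ALL<HC, blue: ALL>HC, grey: heterogeneous/none)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
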