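"""Working-memory network atlas: 76 fine parcels, 24 coarse regions.

The working-memory (WM) node set consists of 35 bilateral cortical areas of
the HCP-MMP1 multimodal parcellation plus 3 bilateral subcortical structures
(caudate, putamen, thalamus), 76 nodes in all.  Cortical parcels are grouped
into 9 bilateral anatomical categories; together with the subcortical
structures this yields 24 coarse (group, hemisphere) regions.

The hierarchy ships with the package as a TSV table; node order is
deterministic: coarse-group-major (groups in table row order, left
hemisphere before right), parcels within a group in table row order.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "Parcel",
    "NodeHierarchy",
    "build_wm_node_set",
    "attach_wholebrain_indices",
    "coarse_partition",
    "load_default_lookup",
    "GROUP_ORDER",
    "SYSTEMS",
]

HEMISPHERES = ("left", "right")
KINDS = ("cortical", "subcortical")

#: Region-group labels in canonical (hierarchy table) row order.
GROUP_ORDER = (
    "ACMPC", "DLPC", "IFC", "IPC", "IFOC", "OPFC", "PCC", "PMC", "SPC",
    "caudate", "putamen", "thalamus",
)

#: Default bilateral super-systems used for the coarse-scale participation
#: coefficient partition.
SYSTEMS: Mapping[str, tuple[str, ...]] = {
    "frontal": ("ACMPC", "DLPC", "IFC", "IFOC", "OPFC", "PMC"),
    "parietal": ("IPC", "SPC"),
    "posteromedial": ("PCC",),
    "subcortical": ("caudate", "putamen", "thalamus"),
}


class AtlasError(ValueError):
    """Raised for invalid hierarchy tables or lookup inputs."""


@dataclass(frozen=True)
class Parcel:
    """One fine-scale node of the WM network."""

    name: str
    hemisphere: str
    kind: str
    group_name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise AtlasError("parcel name must be nonempty")
        if self.hemisphere not in HEMISPHERES:
            raise AtlasError(f"invalid hemisphere {self.hemisphere!r}")
        if self.kind not in KINDS:
            raise AtlasError(f"invalid kind {self.kind!r}")
        if self.kind == "subcortical" and self.group_name != self.name:
            raise AtlasError(
                f"subcortical parcel {self.name!r} must be its own group"
            )

    @property
    def label(self) -> str:
        """Unique node label, e.g. ``8C-left``."""
        return f"{self.name}-{self.hemisphere}"


@dataclass(frozen=True)
class NodeHierarchy:
    """The 76-node WM set, its 24-region grouping and whole-brain indices.

    Attributes
    ----------
    fine_nodes:
        Ordered tuple of 76 :class:`Parcel` objects.
    coarse_groups:
        Ordered tuple of 24 ``(group_name, hemisphere)`` pairs.
    fine_to_coarse:
        Total map fine index -> coarse index.
    wholebrain_index:
        Partial map fine index -> index in the 379-region whole-brain
        parcellation; empty until :func:`attach_wholebrain_indices` is used.
    """

    fine_nodes: tuple[Parcel, ...]
    coarse_groups: tuple[tuple[str, str], ...]
    fine_to_coarse: tuple[int, ...]
    wholebrain_index: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.fine_nodes) != 76:
            raise AtlasError(f"expected 76 fine nodes, got {len(self.fine_nodes)}")
        if len(self.coarse_groups) != 24:
            raise AtlasError(f"expected 24 coarse groups, got {len(self.coarse_groups)}")
        if len(self.fine_to_coarse) != len(self.fine_nodes):
            raise AtlasError("fine_to_coarse must cover every fine node")
        if set(self.fine_to_coarse) != set(range(24)):
            raise AtlasError("fine_to_coarse must be surjective onto the 24 groups")
        cort = {p.name for p in self.fine_nodes if p.kind == "cortical"}
        cort_groups = {p.group_name for p in self.fine_nodes if p.kind == "cortical"}
        sub_groups = {p.group_name for p in self.fine_nodes if p.kind == "subcortical"}
        if len(cort) != 35:
            raise AtlasError(f"expected 35 distinct cortical parcels, got {len(cort)}")
        if len(cort_groups) != 9:
            raise AtlasError(f"expected 9 cortical groups, got {len(cort_groups)}")
        if len(sub_groups) != 3:
            raise AtlasError(f"expected 3 subcortical groups, got {len(sub_groups)}")
        # hemispheric symmetry within every group
        by_group: dict[tuple[str, str], set[str]] = {}
        for p in self.fine_nodes:
            by_group.setdefault((p.group_name, p.hemisphere), set()).add(p.name)
        for g in {p.group_name for p in self.fine_nodes}:
            if by_group.get((g, "left")) != by_group.get((g, "right")):
                raise AtlasError(f"group {g!r} is not hemispherically symmetric")
        wb = dict(self.wholebrain_index)
        if len(set(wb.values())) != len(wb):
            raise AtlasError("wholebrain_index must be injective")

    @property
    def fine_labels(self) -> list[str]:
        return [p.label for p in self.fine_nodes]

    @property
    def coarse_labels(self) -> list[str]:
        return [f"{g}-{h}" for g, h in self.coarse_groups]

    @property
    def group_names(self) -> list[str]:
        """The 12 region-group labels in canonical order."""
        seen: list[str] = []
        for g, _ in self.coarse_groups:
            if g not in seen:
                seen.append(g)
        return seen

    def has_wholebrain_index(self) -> bool:
        return len(self.wholebrain_index) == len(self.fine_nodes)

    def to_frame(self) -> pd.DataFrame:
        """Serialize to the on-disk TSV table layout."""
        return pd.DataFrame(
            {
                "parcel": [p.name for p in self.fine_nodes],
                "hemisphere": [p.hemisphere for p in self.fine_nodes],
                "kind": [p.kind for p in self.fine_nodes],
                "group": [p.group_name for p in self.fine_nodes],
            }
        )


def _hierarchy_from_frame(df: pd.DataFrame) -> NodeHierarchy:
    required = {"parcel", "hemisphere", "kind", "group"}
    missing = required - set(df.columns)
    if missing:
        raise AtlasError(f"hierarchy table missing columns {sorted(missing)}")
    parcels = tuple(
        Parcel(str(r.parcel), str(r.hemisphere), str(r.kind), str(r.group))
        for r in df.itertuples()
    )
    coarse: list[tuple[str, str]] = []
    for p in parcels:
        key = (p.group_name, p.hemisphere)
        if key not in coarse:
            coarse.append(key)
    f2c = tuple(coarse.index((p.group_name, p.hemisphere)) for p in parcels)
    return NodeHierarchy(parcels, tuple(coarse), f2c)


def build_wm_node_set(path: str | Path | None = None) -> NodeHierarchy:
    """Load the WM node hierarchy (packaged table by default).

    Returns a validated :class:`NodeHierarchy` with 76 fine nodes and 24
    coarse regions; whole-brain indices are not attached.
    """
    if path is None:
        res = importlib.resources.files("wmnet.data") / "wm_hierarchy.tsv"
        with importlib.resources.as_file(res) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return _hierarchy_from_frame(df)


def read_hierarchy(path: str | Path) -> NodeHierarchy:
    """Read a hierarchy from a TSV with columns parcel/hemisphere/kind/group."""
    return _hierarchy_from_frame(pd.read_csv(path, sep="\t"))


def load_default_lookup() -> dict[tuple[str, str], int]:
    """Packaged (parcel, hemisphere) -> whole-brain index lookup.

    Uses the standard HCP-MMP1 area numbering (left hemisphere occupies
    indices 0-179, right 180-359) followed by a 19-slot subcortical block
    (360-378).
    """
    res = importlib.resources.files("wmnet.data") / "hcpmmp1_lookup.tsv"
    with importlib.resources.as_file(res) as p:
        df = pd.read_csv(p, sep="\t")
    return read_lookup(df)


def read_lookup(source: str | Path | pd.DataFrame) -> dict[tuple[str, str], int]:
    """Read a lookup table with columns parcel/hemisphere/wholebrain_index."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep=None, engine="python")
    required = {"parcel", "hemisphere", "wholebrain_index"}
    missing = required - set(df.columns)
    if missing:
        raise AtlasError(f"lookup table missing columns {sorted(missing)}")
    out: dict[tuple[str, str], int] = {}
    for r in df.itertuples():
        key = (str(r.parcel), str(r.hemisphere))
        if key in out:
            raise AtlasError(f"duplicate lookup entry for {key}")
        out[key] = int(r.wholebrain_index)
    return out


def attach_wholebrain_indices(
    hierarchy: NodeHierarchy, lookup: Mapping[tuple[str, str], int]
) -> NodeHierarchy:
    """Attach whole-brain (379-region) indices to every fine node.

    Parameters
    ----------
    lookup:
        Maps ``(parcel_name, hemisphere)`` to an integer index in [0, 378].

    Raises
    ------
    AtlasError
        If any parcel is unmapped, an index is out of range, or two parcels
        collide on the same index.
    """
    wb: dict[int, int] = {}
    seen: dict[int, str] = {}
    for i, p in enumerate(hierarchy.fine_nodes):
        key = (p.name, p.hemisphere)
        if key not in lookup:
            raise AtlasError(f"unmapped parcel: {p.label}")
        idx = int(lookup[key])
        if not 0 <= idx <= 378:
            raise AtlasError(f"index {idx} for {p.label} outside [0, 378]")
        if idx in seen:
            raise AtlasError(f"collision: index {idx} assigned to both {seen[idx]} and {p.label}")
        seen[idx] = p.label
        wb[i] = idx
    return replace(hierarchy, wholebrain_index=wb)


def coarse_partition(hierarchy: NodeHierarchy, level: str = "groups24") -> list[int]:
    """Partition of fine nodes as a block-index vector.

    ``groups24`` returns the 24-region grouping; ``systems`` returns the
    4-system bilateral super-partition (frontal / parietal / posteromedial /
    subcortical).  Every fine node belongs to exactly one block.
    """
    if level == "groups24":
        return list(hierarchy.fine_to_coarse)
    if level == "systems":
        names = list(SYSTEMS)
        sys_of = {g: names.index(s) for s, gs in SYSTEMS.items() for g in gs}
        try:
            return [sys_of[p.group_name] for p in hierarchy.fine_nodes]
        except KeyError as e:  # pragma: no cover - packaged table covers all
            raise AtlasError(f"group {e} not assigned to a system") from e
    raise AtlasError(f"unknown partition level {level!r}; use 'groups24' or 'systems'")
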