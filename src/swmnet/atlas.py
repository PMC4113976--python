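"""Node space for superficial-white-matter covariance networks.

Each hemisphere carries 39 regions of interest, mainly Brodmann areas (some
merged into composite areas, plus the cuneus), grouped into five lobes:
frontal, parietal, paralimbic, temporal and occipital.  The atlas is a pure
labeled index space — no geometry.  Node ordering puts all left-hemisphere
ROIs first (lobe by lobe), then the right hemisphere in the same area order,
so the homotopic partner of node ``i`` is ``i ± 39`` and hemisphere blocks
are contiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "ROI",
    "ROIAtlas",
    "InvalidEdgeError",
    "AtlasError",
    "default_atlas",
    "classify_edge",
    "EDGE_CLASSES",
]

# Lobe membership of the 39 per-hemisphere areas; composite Brodmann areas
# (1+2+3, 24+33, 29+30) are atomic nodes and are never split.
_LOBE_AREAS: dict[str, tuple[str, ...]] = {
    "frontal": ("4", "6", "8", "9", "10", "13", "44", "45", "46"),
    "parietal": ("1+2+3", "5", "7", "39", "40", "43"),
    "paralimbic": (
        "11", "23", "24+33", "25", "27", "28", "29+30",
        "31", "32", "34", "35", "36", "38", "47",
    ),
    "temporal": ("20", "21", "22", "37", "41", "42"),
    "occipital": ("17", "18", "19", "Cuneus"),
}

LOBES = tuple(_LOBE_AREAS)
EDGE_CLASSES = ("intra-LH", "intra-RH", "interhemispheric")


class AtlasError(ValueError):
    """Atlas construction or validation failure."""


class InvalidEdgeError(ValueError):
    """Self-edge or out-of-range node index."""


@dataclass(frozen=True)
class ROI:
    label: str
    hemisphere: str  # "L" | "R"
    lobe: str

    @property
    def name(self) -> str:
        return f"{self.hemisphere}_{self.label}"


@dataclass(frozen=True)
class ROIAtlas:
    """Registry of nodes with hemisphere, lobe and homotopic pairing."""

    rois: tuple[ROI, ...]
    homotopic_pairs: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        n_left = sum(1 for r in self.rois if r.hemisphere == "L")
        n_right = sum(1 for r in self.rois if r.hemisphere == "R")
        if n_left != n_right:
            raise AtlasError(f"hemisphere imbalance: {n_left} L vs {n_right} R")
        for r in self.rois:
            if r.hemisphere not in ("L", "R"):
                raise AtlasError(f"bad hemisphere {r.hemisphere!r} for {r.label}")
            if r.lobe not in LOBES:
                raise AtlasError(f"bad lobe {r.lobe!r} for {r.label}")
        pairs = self.homotopic_pairs
        if len(pairs) != n_left:
            raise AtlasError("homotopic pairing is not a perfect matching")
        seen_l, seen_r = set(), set()
        for li, ri in pairs:
            if self.rois[li].hemisphere != "L" or self.rois[ri].hemisphere != "R":
                raise AtlasError(f"pair ({li}, {ri}) does not span L→R")
            if self.rois[li].label != self.rois[ri].label:
                raise AtlasError(
                    f"pair ({li}, {ri}) joins different areas "
                    f"{self.rois[li].label!r} / {self.rois[ri].label!r}"
                )
            seen_l.add(li)
            seen_r.add(ri)
        if len(seen_l) != n_left or len(seen_r) != n_right:
            raise AtlasError("homotopic pairing reuses a node")

    @property
    def n_nodes(self) -> int:
        return len(self.rois)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def hemisphere_indices(self, hemisphere: str) -> list[int]:
        return [i for i, r in enumerate(self.rois) if r.hemisphere == hemisphere]

    def lobe_indices(self, lobe: str, hemisphere: str | None = None) -> list[int]:
        return [
            i
            for i, r in enumerate(self.rois)
            if r.lobe == lobe and (hemisphere is None or r.hemisphere == hemisphere)
        ]

    def regions(self) -> dict[str, list[int]]:
        """The 10 lobe-hemisphere clusters used by macro-network mapping."""
        out: dict[str, list[int]] = {}
        for hemi in ("L", "R"):
            for lobe in LOBES:
                out[f"{hemi}_{lobe}"] = self.lobe_indices(lobe, hemi)
        return out

    def homotopic_partner(self, i: int) -> int:
        for li, ri in self.homotopic_pairs:
            if li == i:
                return ri
            if ri == i:
                return li
        raise AtlasError(f"node {i} has no homotopic partner")

    # -- serialization -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "rois": [
                {"label": r.label, "hemisphere": r.hemisphere, "lobe": r.lobe}
                for r in self.rois
            ],
            "homotopic_pairs": [list(p) for p in self.homotopic_pairs],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ROIAtlas":
        doc = json.loads(Path(path).read_text())
        rois = tuple(
            ROI(d["label"], d["hemisphere"], d["lobe"]) for d in doc["rois"]
        )
        pairs = tuple((int(a), int(b)) for a, b in doc["homotopic_pairs"])
        return cls(rois, pairs)  # __post_init__ re-validates invariants


def default_atlas() -> ROIAtlas:
    """The 78-node atlas: 39 areas per hemisphere over five lobes.

    Per hemisphere: 9 frontal, 6 parietal, 14 paralimbic, 6 temporal and
    4 occipital areas.  Left hemisphere occupies indices 0–38, right 39–77,
    with homotopic pairs at offset 39.
    """
    left = tuple(
        ROI(label, "L", lobe) for lobe, labels in _LOBE_AREAS.items() for label in labels
    )
    right = tuple(ROI(r.label, "R", r.lobe) for r in left)
    n = len(left)
    pairs = tuple((i, i + n) for i in range(n))
    return ROIAtlas(left + right, pairs)


def classify_edge(atlas: ROIAtlas, i: int, j: int) -> str:
    """Gross-topology class of the (i, j) edge.

    Returns ``"intra-LH"``, ``"intra-RH"`` or ``"interhemispheric"``.
    """
    n = atlas.n_nodes
    if not (0 <= i < n and 0 <= j < n):
        raise InvalidEdgeError(f"node index out of range: ({i}, {j}) for {n} nodes")
    if i == j:
        raise InvalidEdgeError(f"self-edge ({i}, {i}) has no class")
    hi, hj = atlas.rois[i].hemisphere, atlas.rois[j].hemisphere
    if hi != hj:
        return "interhemispheric"
    return "intra-LH" if hi == "L" else "intra-RH"


def iter_pairs(n: int) -> Iterable[tuple[int, int]]:
    """Unordered node pairs (i < j)."""
    for i in range(n):
        for j in range(i + 1, n):
            yield i, j
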