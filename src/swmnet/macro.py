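"""Lobe-level integration–segregation summaries of a partial-correlation network.

For a node cluster N₁ (a lobe within one hemisphere) the amount of
within-region association is the Gaussian entropy distance from
independence,

    H(N₁) = −½ · ln det(P_{N₁}),

with P_{N₁} the partial-correlation submatrix on N₁ (H = 0 iff the
submatrix is the identity).  Between-region association is the Gaussian
mutual information

    MI(N₁, N₂) = H(N₁) + H(N₂) − H(N₁ ∪ N₂)
               = ½ · ln( det P_{N₁} · det P_{N₂} / det P_{N₁∪N₂} ) ≥ 0.

The 10 region values and 45 pair values per group are ranked weak / medium
/ strong by 1-D k-means (k = 3), fitted on the values of both groups pooled
per quantity, so levels are comparable across groups.  Natural logarithms
throughout (nats).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .atlas import ROIAtlas
from .shrinkage import PartialCorrNetwork

__all__ = [
    "MacroNetwork",
    "gaussian_entropy",
    "mutual_information",
    "rank_levels",
    "build_macro_network",
]

LEVELS = ("weak", "medium", "strong")


class DegenerateClusteringError(ValueError):
    pass


def _submatrix_logdet(pmat: np.ndarray, nodes) -> float:
    sub = pmat[np.ix_(nodes, nodes)]
    sign, logdet = np.linalg.slogdet(sub)
    if sign <= 0:
        raise ValueError("submatrix is not positive definite")
    # slogdet does not verify definiteness, only the determinant sign
    if np.linalg.eigvalsh(sub)[0] <= 0:
        raise ValueError("submatrix is not positive definite")
    return logdet


def gaussian_entropy(pmat: np.ndarray | PartialCorrNetwork, nodes) -> float:
    """H = −½·ln det of the partial-correlation submatrix on ``nodes`` (nats)."""
    if isinstance(pmat, PartialCorrNetwork):
        pmat = pmat.pmat
    nodes = list(nodes)
    if len(nodes) == 0:
        return 0.0
    return -0.5 * _submatrix_logdet(pmat, nodes)


def mutual_information(pmat: np.ndarray | PartialCorrNetwork, n1, n2) -> float:
    """MI(N₁, N₂) = ½·ln( det P_{N₁} · det P_{N₂} / det P_{N₁∪N₂} ), in nats.

    Equivalently H(N₁ ∪ N₂) − H(N₁) − H(N₂) in the −½·ln det convention of
    :func:`gaussian_entropy` (which measures distance from independence, so
    the joint block carries the association); nonnegative for valid blocks.
    """
    if isinstance(pmat, PartialCorrNetwork):
        pmat = pmat.pmat
    n1, n2 = list(n1), list(n2)
    if set(n1) & set(n2):
        raise ValueError("node sets must be disjoint")
    h1 = gaussian_entropy(pmat, n1)
    h2 = gaussian_entropy(pmat, n2)
    h12 = gaussian_entropy(pmat, n1 + n2)
    return max(0.0, h12 - h1 - h2)  # clamp tiny negative round-off


def rank_levels(values: np.ndarray, seed: int = 0) -> list[str]:
    """Three-level (weak/medium/strong) ranking of positive association
    values by 1-D k-means with 50 restarts; labels ordered by centroid."""
    values = np.asarray(values, float)
    if np.unique(values).size < 3:
        raise DegenerateClusteringError("need at least 3 distinct values")
    km = KMeans(n_clusters=3, n_init=50, random_state=seed)
    labels = km.fit_predict(values.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = {cluster: LEVELS[rank] for rank, cluster in enumerate(order)}
    return [relabel[c] for c in labels]


@dataclass
class MacroNetwork:
    """Per-group lobe-level summary: 10 region entropies, 45 pair MIs."""

    group: str
    regions: list[str]
    intra: pd.DataFrame   # region, H, level, significant
    inter: pd.DataFrame   # region_a, region_b, MI, level, significant

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "regions": self.regions,
            "intra": self.intra.to_dict(orient="records"),
            "inter": self.inter.to_dict(orient="records"),
        }


def _region_significance(edge_set, region_nodes: dict[str, list[int]]):
    """Which regions / region pairs contain at least one called edge."""
    intra_sig = {name: False for name in region_nodes}
    inter_sig = {
        frozenset((a, b)): False for a, b in combinations(region_nodes, 2)
    }
    if edge_set is None:
        return intra_sig, inter_sig
    node_region = {}
    for name, nodes in region_nodes.items():
        for i in nodes:
            node_region[i] = name
    for _, row in edge_set.edges.iterrows():
        ra, rb = node_region[row["node_i"]], node_region[row["node_j"]]
        if ra == rb:
            intra_sig[ra] = True
        else:
            inter_sig[frozenset((ra, rb))] = True
    return intra_sig, inter_sig


def build_macro_network(
    networks: dict[str, PartialCorrNetwork],
    atlas: ROIAtlas | None = None,
    edge_sets: dict[str, "object"] | None = None,
    seed: int = 0,
) -> dict[str, MacroNetwork]:
    """Macro-networks for one or more groups on a shared level scale.

    ``networks`` maps group label → partial-correlation network.  The
    k-means level ranking is fitted on the pooled values of all groups
    (separately for H and MI) so ranks are comparable across groups.
    ``edge_sets`` (group → called EdgeSet) drives the significance flags:
    a region (pair) is flagged when it contains ≥ 1 called edge.
    """
    if not networks:
        raise ValueError("no networks given")
    first = next(iter(networks.values()))
    atlas = atlas or first.atlas
    region_nodes = atlas.regions()
    region_names = list(region_nodes)
    pair_list = list(combinations(region_names, 2))

    h_vals: dict[str, np.ndarray] = {}
    mi_vals: dict[str, np.ndarray] = {}
    for g, net in networks.items():
        h_vals[g] = np.array(
            [gaussian_entropy(net.pmat, region_nodes[r]) for r in region_names]
        )
        mi_vals[g] = np.array(
            [
                mutual_information(net.pmat, region_nodes[a], region_nodes[b])
                for a, b in pair_list
            ]
        )

    groups = list(networks)
    pooled_h = np.concatenate([h_vals[g] for g in groups])
    pooled_mi = np.concatenate([mi_vals[g] for g in groups])
    try:
        h_levels = rank_levels(pooled_h, seed=seed)
    except DegenerateClusteringError:
        h_levels = ["weak"] * pooled_h.size
    try:
        mi_levels = rank_levels(pooled_mi, seed=seed)
    except DegenerateClusteringError:
        mi_levels = ["weak"] * pooled_mi.size

    out: dict[str, MacroNetwork] = {}
    nreg, npair = len(region_names), len(pair_list)
    for gi, g in enumerate(groups):
        es = (edge_sets or {}).get(g)
        intra_sig, inter_sig = _region_significance(es, region_nodes)
        intra = pd.DataFrame(
            {
                "region": region_names,
                "H": h_vals[g],
                "level": h_levels[gi * nreg:(gi + 1) * nreg],
                "significant": [intra_sig[r] for r in region_names],
            }
        )
        inter = pd.DataFrame(
            {
                "region_a": [a for a, _ in pair_list],
                "region_b": [b for _, b in pair_list],
                "MI": mi_vals[g],
                "level": mi_levels[gi * npair:(gi + 1) * npair],
                "significant": [inter_sig[frozenset(p)] for p in pair_list],
            }
        )
        out[g] = MacroNetwork(group=g, regions=region_names, intra=intra, inter=inter)
    return out
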