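"""Binary-network topology: degree/hubs, efficiency, modularity, density integration.

Networks are binarized from the partial-correlation matrix either at an
lfdr threshold or to an exact target density (keeping the lowest-lfdr
edges, ties broken by larger |partial correlation|, then node order).
Metrics follow the standard binary undirected conventions:

* degree  k_i = Σ_j a_ij; hubs are nodes whose *density-integrated* degree
  lies at or above the 75th percentile of the integrated-degree distribution;
* efficiency  E(G) = (1/(N(N−1))) Σ_{i≠j} 1/d_ij with 1/d_ij = 0 for
  disconnected pairs (Latora–Marchiori); global efficiency GE = E(G), local
  efficiency LE = mean_i E(G_i) over each node's neighbor-induced subgraph
  (0 for nodes with < 2 neighbors);
* modularity  Q = Σ_c [ L_c/m − (d_c/2m)² ] maximized by a seeded greedy
  agglomerative search.

Because a fixed lfdr cut yields different densities in different groups,
metrics are evaluated on an even grid of densities spanning the
0.2 < lfdr < 0.5 band and averaged (densities treated as equally likely);
group contrasts re-run the whole estimation pipeline under label
permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .lfdr import call_edges, fit_mixture, edge_lfdr
from .shrinkage import PartialCorrNetwork, network_from_data

__all__ = [
    "BinaryNetwork",
    "TopologyReport",
    "binarize",
    "degrees",
    "hubs",
    "global_efficiency",
    "local_efficiency",
    "modularity",
    "best_partition",
    "integrate_over_densities",
    "integrated_degrees",
    "permutation_metric_test",
    "compare_density_matched",
    "topology_report",
]

DEFAULT_LFDR_BAND = (0.2, 0.5)
DEFAULT_N_DENSITIES = 30
METRICS = ("GE", "LE", "Q")


@dataclass(frozen=True)
class BinaryNetwork:
    adjacency: np.ndarray
    density: float
    source: str  # e.g. "lfdr<0.2" or "density=0.05"

    def __post_init__(self) -> None:
        a = self.adjacency
        if not np.array_equal(a, a.T) or np.diag(a).any():
            raise ValueError("adjacency must be symmetric with zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def _ensure_lfdr(network: PartialCorrNetwork) -> None:
    if network.lfdr is None:
        call_edges(network)  # fits the mixture and fills network.lfdr


def _edge_order(network: PartialCorrNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle indices sorted by (lfdr asc, |p| desc, i, j)."""
    k = network.k
    iu = np.triu_indices(k, 1)
    lf = network.lfdr[iu]
    mag = np.abs(network.pmat[iu])
    order = np.lexsort((iu[1], iu[0], -mag, lf))
    return (iu[0][order], iu[1][order])


def binarize(
    network: PartialCorrNetwork,
    lfdr_threshold: float | None = None,
    density: float | None = None,
) -> BinaryNetwork:
    """Binarize at an lfdr threshold or to an exact target density."""
    if (lfdr_threshold is None) == (density is None):
        raise ValueError("give exactly one of lfdr_threshold or density")
    _ensure_lfdr(network)
    k = network.k
    n_pairs = k * (k - 1) // 2
    adj = np.zeros((k, k), dtype=int)
    if lfdr_threshold is not None:
        iu = np.triu_indices(k, 1)
        keep = network.lfdr[iu] < lfdr_threshold
        adj[iu[0][keep], iu[1][keep]] = 1
        source = f"lfdr<{lfdr_threshold:g}"
    else:
        if not 0.0 <= density <= 1.0:
            raise ValueError("density must be in [0, 1]")
        n_keep = int(round(density * n_pairs))
        oi, oj = _edge_order(network)
        adj[oi[:n_keep], oj[:n_keep]] = 1
        source = f"density={density:g}"
    adj = adj + adj.T
    return BinaryNetwork(adjacency=adj, density=adj.sum() / (2 * n_pairs), source=source)


# ---------------------------------------------------------------------------
# metrics


def degrees(a: BinaryNetwork | np.ndarray) -> np.ndarray:
    adj = a.adjacency if isinstance(a, BinaryNetwork) else np.asarray(a)
    return adj.sum(axis=1)


def hubs(integrated_degree: np.ndarray) -> np.ndarray:
    """Node indices whose integrated degree is ≥ the 75th percentile."""
    integrated_degree = np.asarray(integrated_degree, float)
    cut = np.percentile(integrated_degree, 75)
    return np.flatnonzero(integrated_degree >= cut)


def _efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path(adj.astype(float), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(a: BinaryNetwork | np.ndarray) -> float:
    adj = a.adjacency if isinstance(a, BinaryNetwork) else np.asarray(a)
    return _efficiency(adj)


def local_efficiency(a: BinaryNetwork | np.ndarray) -> float:
    adj = a.adjacency if isinstance(a, BinaryNetwork) else np.asarray(a)
    n = adj.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        vals[i] = _efficiency(adj[np.ix_(nbrs, nbrs)])
    return float(vals.mean()) if n else 0.0


def modularity(a: BinaryNetwork | np.ndarray, partition: np.ndarray) -> float:
    """Newman's Q for a given module assignment (one label per node)."""
    adj = a.adjacency if isinstance(a, BinaryNetwork) else np.asarray(a)
    n = adj.shape[0]
    partition = np.asarray(partition)
    if partition.shape != (n,):
        raise ValueError("partition must assign every node to a module")
    m = adj.sum() / 2.0
    if m == 0:
        return 0.0
    q = 0.0
    for c in np.unique(partition):
        nodes = partition == c
        l_c = adj[np.ix_(nodes, nodes)].sum() / 2.0
        d_c = adj[nodes].sum()
        q += l_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def best_partition(
    a: BinaryNetwork | np.ndarray, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Greedy agglomerative Q-maximization (seeded tie-breaking).

    Starts from singleton modules and repeatedly merges the connected
    module pair with the largest positive ΔQ; isolated nodes remain
    singletons.  Returns (module labels, Q).
    """
    adj = a.adjacency if isinstance(a, BinaryNetwork) else np.asarray(a)
    n = adj.shape[0]
    m = adj.sum() / 2.0
    labels = np.arange(n)
    if m == 0:
        return labels, 0.0
    rng = np.random.default_rng(seed)

    # between-module edge counts and module degrees
    between: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                between[(i, j)] = float(adj[i, j])
    deg = {i: float(adj[i].sum()) for i in range(n)}
    alive = set(range(n))

    while True:
        best_dq, candidates = 0.0, []
        for (ca, cb), l_ab in between.items():
            dq = l_ab / m - 2.0 * (deg[ca] / (2 * m)) * (deg[cb] / (2 * m))
            if dq > best_dq + 1e-12:
                best_dq, candidates = dq, [(ca, cb)]
            elif candidates and abs(dq - best_dq) <= 1e-12:
                candidates.append((ca, cb))
        if not candidates:
            break
        ca, cb = candidates[rng.integers(len(candidates))]
        # merge cb into ca
        labels[labels == cb] = ca
        deg[ca] += deg[cb]
        del deg[cb]
        alive.discard(cb)
        new_between: dict[tuple[int, int], float] = {}
        for (x, y), l in between.items():
            x = ca if x == cb else x
            y = ca if y == cb else y
            if x == y:
                continue
            key = (min(x, y), max(x, y))
            new_between[key] = new_between.get(key, 0.0) + l
        between = new_between

    # relabel modules 0..n_modules-1
    _, labels = np.unique(labels, return_inverse=True)
    return labels, modularity(adj, labels)


def _metric(adj: np.ndarray, name: str, seed: int = 0) -> float:
    if name == "GE":
        return global_efficiency(adj)
    if name == "LE":
        return local_efficiency(adj)
    if name == "Q":
        return best_partition(adj, seed=seed)[1]
    raise ValueError(f"unknown metric {name!r}")


# ---------------------------------------------------------------------------
# density integration


def _band_densities(
    network: PartialCorrNetwork, lfdr_band: tuple[float, float], n_points: int
) -> np.ndarray:
    _ensure_lfdr(network)
    iu = np.triu_indices(network.k, 1)
    lf = network.lfdr[iu]
    n_pairs = lf.size
    d_lo = np.mean(lf < lfdr_band[0])
    d_hi = np.mean(lf < lfdr_band[1])
    if d_hi <= d_lo:
        warnings.warn("degenerate lfdr band: endpoints map to one density")
        return np.array([d_lo])
    return np.linspace(d_lo, d_hi, n_points)


def integrate_over_densities(
    network: PartialCorrNetwork,
    metric: str,
    lfdr_band: tuple[float, float] = DEFAULT_LFDR_BAND,
    n_points: int = DEFAULT_N_DENSITIES,
    seed: int = 0,
    densities: np.ndarray | None = None,
) -> float:
    """Average of a metric over the density range spanned by the lfdr band."""
    if densities is None:
        densities = _band_densities(network, lfdr_band, n_points)
    vals = [
        _metric(binarize(network, density=d).adjacency, metric, seed=seed)
        for d in densities
    ]
    return float(np.mean(vals))


def integrated_degrees(
    network: PartialCorrNetwork,
    lfdr_band: tuple[float, float] = DEFAULT_LFDR_BAND,
    n_points: int = DEFAULT_N_DENSITIES,
    densities: np.ndarray | None = None,
) -> np.ndarray:
    """Per-node degree averaged over the density grid of the lfdr band."""
    if densities is None:
        densities = _band_densities(network, lfdr_band, n_points)
    mats = [degrees(binarize(network, density=d)) for d in densities]
    return np.mean(mats, axis=0)


# ---------------------------------------------------------------------------
# group contrasts


def permutation_metric_test(
    data_a,
    data_b,
    metrics: tuple[str, ...] = METRICS,
    n_perm: int = 10_000,
    seed: int = 0,
    lfdr_band: tuple[float, float] = DEFAULT_LFDR_BAND,
    n_points: int = DEFAULT_N_DENSITIES,
    adjust: bool = True,
) -> dict[str, float]:
    """Two-sided label-permutation test of density-integrated metrics.

    Subjects are pooled and group labels reshuffled preserving group
    sizes; at each shuffle the full pipeline — shrinkage, mixture fit,
    density binarization, metric, integration — is re-run for both
    pseudo-groups.  p = (1 + #{|Δ*| ≥ |Δ|}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be ≥ 100")
    n_a, n_b = data_a.n_subjects, data_b.n_subjects
    if min(n_a, n_b) < 3:
        raise ValueError("need at least 3 subjects per group")

    def _integrated(values, age, gender) -> dict[str, float]:
        from .shrinkage import adjust_covariates, partial_correlations, shrink_covariance

        if adjust:
            net = adjust_covariates(values, age, gender)
        else:
            net = partial_correlations(shrink_covariance(values))
        dens = _band_densities(net, lfdr_band, n_points)
        adjs = [binarize(net, density=d).adjacency for d in dens]
        return {
            mname: float(np.mean([_metric(adj, mname, seed=seed) for adj in adjs]))
            for mname in metrics
        }

    obs_a = _integrated(data_a.values, data_a.age, data_a.gender)
    obs_b = _integrated(data_b.values, data_b.age, data_b.gender)
    obs = {mname: obs_a[mname] - obs_b[mname] for mname in metrics}

    pooled = np.vstack([data_a.values, data_b.values])
    age = np.concatenate([data_a.age, data_b.age])
    gender = np.concatenate([data_a.gender, data_b.gender])
    rng = np.random.default_rng(seed)
    exceed = {mname: 0 for mname in metrics}
    for _ in range(n_perm):
        idx = rng.permutation(n_a + n_b)
        ia, ib = idx[:n_a], idx[n_a:]
        pa = _integrated(pooled[ia], age[ia], gender[ia])
        pb = _integrated(pooled[ib], age[ib], gender[ib])
        for mname in metrics:
            if abs(pa[mname] - pb[mname]) >= abs(obs[mname]):
                exceed[mname] += 1
    return {
        mname: (1.0 + exceed[mname]) / (1.0 + n_perm) for mname in metrics
    }


def compare_density_matched(
    net_a: PartialCorrNetwork,
    net_b: PartialCorrNetwork,
    density_grid: np.ndarray,
    metric: str,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate a metric on both networks binarized to the same densities.

    Matching density disentangles topology from edge-count differences;
    per-density comparisons require a multiple-comparison correction,
    which is left to the caller (flag attached as a DataFrame attr).
    """
    rows = []
    for d in np.asarray(density_grid, float):
        va = _metric(binarize(net_a, density=d).adjacency, metric, seed=seed)
        vb = _metric(binarize(net_b, density=d).adjacency, metric, seed=seed)
        rows.append({"density": d, "value_a": va, "value_b": vb})
    out = pd.DataFrame(rows)
    out.attrs["multiple_comparison_note"] = (
        "per-density comparisons are not corrected for multiple comparisons"
    )
    return out


@dataclass
class TopologyReport:
    """Density-integrated topology summary for one or two groups."""

    integrated: dict                      # group → {GE, LE, Q}
    integrated_degree: dict               # group → per-node array
    hub_sets: dict                        # group → sorted node indices
    curves: pd.DataFrame | None = None    # per-density GE/LE/Q per group
    permutation_p: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "integrated": self.integrated,
            "integrated_degree": {
                g: np.asarray(v).tolist() for g, v in self.integrated_degree.items()
            },
            "hubs": {g: list(map(int, v)) for g, v in self.hub_sets.items()},
            "permutation_p": self.permutation_p,
        }


def topology_report(
    networks: dict[str, PartialCorrNetwork],
    lfdr_band: tuple[float, float] = DEFAULT_LFDR_BAND,
    n_points: int = DEFAULT_N_DENSITIES,
    seed: int = 0,
) -> TopologyReport:
    """Integrated GE/LE/Q, integrated degrees and hubs per group."""
    integrated, int_deg, hub_sets = {}, {}, {}
    curve_rows = []
    for g, net in networks.items():
        dens = _band_densities(net, lfdr_band, n_points)
        adjs = [binarize(net, density=d).adjacency for d in dens]
        per_metric = {
            mname: [_metric(adj, mname, seed=seed) for adj in adjs]
            for mname in METRICS
        }
        integrated[g] = {m: float(np.mean(v)) for m, v in per_metric.items()}
        int_deg[g] = np.mean([degrees(adj) for adj in adjs], axis=0)
        hub_sets[g] = hubs(int_deg[g]).tolist()
        for di, d in enumerate(dens):
            curve_rows.append(
                {"group": g, "density": d,
                 **{m: per_metric[m][di] for m in METRICS}}
            )
    return TopologyReport(
        integrated=integrated,
        integrated_degree=int_deg,
        hub_sets=hub_sets,
        curves=pd.DataFrame(curve_rows),
    )
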