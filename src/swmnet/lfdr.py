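"""Local-false-discovery-rate edge inference on partial-correlation networks.

The observed off-diagonal partial correlations are modeled as a two-component
mixture  f(p) = η₀·f₀(p) + (1 − η₀)·f_a(p),  where f₀ is the null density of
an estimated partial correlation — for raw correlations the density
f₀(p; κ) ∝ (1 − p²)^((κ−3)/2) with κ a free degrees-of-freedom parameter
(shrinkage compresses the null spread, so κ is fitted, not fixed at n − 1) —
and f_a is left unspecified.  The per-edge local false discovery rate

    lfdr(p) = η₀ · f₀(p) / f(p),   capped at 1,

is the posterior probability of the edge being null; edges with lfdr < 0.2
are called highly significant.  η₀ and the null scale are estimated from the
central part of the empirical distribution (truncated maximum likelihood up
to the 75th percentile of |p|); the marginal f is a Grenander-type monotone
decreasing density on |p|, and lfdr is made non-increasing in |p|.

Group and hemisphere contrasts Fisher-transform the partial correlations,
form z-scores with the two-sample standard error √(1/(n_a−3) + 1/(n_b−3)),
and run the same machinery with a Gaussian null (normality of the z-scores
is reported via a Jarque–Bera test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .atlas import ROIAtlas, classify_edge
from .shrinkage import PartialCorrNetwork

__all__ = [
    "MixtureFit",
    "EdgeSet",
    "fit_mixture",
    "edge_lfdr",
    "call_edges",
    "compare_groups",
    "compare_hemispheres",
]

DEFAULT_THRESHOLD = 0.2
_CENTRAL_QUANTILE = 0.75  # truncation point for the null fit


class DegenerateDistributionError(ValueError):
    pass


class DensitySupportError(ValueError):
    pass


# ---------------------------------------------------------------------------
# null densities on the absolute statistic


def _hotelling_logpdf_abs(a: np.ndarray, kappa: float) -> np.ndarray:
    # |p| density: 2(1−p²)^((κ−3)/2) / B(1/2, (κ−1)/2) on [0, 1)
    lognorm = np.log(2.0) - special.betaln(0.5, (kappa - 1.0) / 2.0)
    return lognorm + 0.5 * (kappa - 3.0) * np.log1p(-np.minimum(a, 1 - 1e-12) ** 2)


def _hotelling_cdf_abs(a: np.ndarray, kappa: float) -> np.ndarray:
    # under the null p² ~ Beta(1/2, (κ−1)/2)
    return special.betainc(0.5, (kappa - 1.0) / 2.0, np.clip(a, 0, 1) ** 2)


def _gaussian_logpdf_abs(a: np.ndarray, sd: float) -> np.ndarray:
    return np.log(2.0) + stats.norm.logpdf(a, scale=sd)


def _gaussian_cdf_abs(a: np.ndarray, sd: float) -> np.ndarray:
    return special.erf(a / (sd * np.sqrt(2.0)))


# ---------------------------------------------------------------------------
# Grenander decreasing density on |statistic|


class _Grenander:
    """Least-concave-majorant (Grenander) decreasing density on [0, x_max]."""

    def __init__(self, a: np.ndarray, x_end: float | None = None):
        a = np.sort(np.asarray(a, float))
        n = a.size
        if x_end is not None and a[-1] < x_end:
            # pin the support to [0, x_end] (e.g. the p-value unit interval)
            x = np.concatenate([[0.0], a, [x_end]])
            y = np.concatenate([np.arange(n + 1) / n, [1.0]])
        else:
            x = np.concatenate([[0.0], a])
            y = np.arange(n + 1) / n
        # upper concave hull of the ECDF points (slopes non-increasing)
        hull = [0]
        for i in range(1, len(x)):
            while len(hull) >= 2:
                i0, i1 = hull[-2], hull[-1]
                # pop i1 if it lies on/below the chord i0 → i
                if (y[i1] - y[i0]) * (x[i] - x[i0]) <= (y[i] - y[i0]) * (x[i1] - x[i0]):
                    hull.pop()
                else:
                    break
            hull.append(i)
        hx = x[hull]
        hy = y[hull]
        with np.errstate(divide="ignore", invalid="ignore"):
            self.slopes = np.diff(hy) / np.diff(hx)
        self.knots = hx
        self.x_max = hx[-1]

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        if (t < 0).any() or (t > self.x_max + 1e-12).any():
            raise DensitySupportError("value outside the fitted density support")
        # left-derivative convention: a point on a hull knot belongs to the
        # segment ending there (the Grenander value at its own datum)
        seg = np.clip(np.searchsorted(self.knots, t, side="left") - 1, 0,
                      len(self.slopes) - 1)
        return self.slopes[seg]


# ---------------------------------------------------------------------------
# mixture fit


@dataclass
class MixtureFit:
    """Fitted two-component mixture for a set of edge statistics."""

    eta0: float
    null_family: str                      # "hotelling" | "gaussian"
    null_param: float                     # κ or the Gaussian SD
    f0: Callable[[np.ndarray], np.ndarray] = field(repr=False)  # density of |v − loc|
    f: Callable[[np.ndarray], np.ndarray] = field(repr=False)   # marginal density of |v − loc|
    cdf0: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    fp: Callable[[np.ndarray], np.ndarray] = field(repr=False)  # density of null p-values
    loc: float = 0.0  # empirical-null center (gaussian family only)

    @property
    def kappa(self) -> float:
        if self.null_family != "hotelling":
            raise AttributeError("kappa defined only for the hotelling null")
        return self.null_param


def _fit_null_scale(a: np.ndarray, family: str) -> float:
    """Truncated MLE of the null scale from the central |values|."""
    cut = np.quantile(a, _CENTRAL_QUANTILE)
    central = a[a <= cut]
    if cut == 0 or central.size < 10:
        raise DegenerateDistributionError("central window of the distribution is empty")

    if family == "hotelling":
        def nll(u: float) -> float:
            kappa = 3.0 + np.exp(u)
            ll = _hotelling_logpdf_abs(central, kappa).sum()
            ll -= central.size * np.log(_hotelling_cdf_abs(cut, kappa))
            return -ll

        res = optimize.minimize_scalar(nll, bounds=(np.log(0.1), np.log(1e7)),
                                       method="bounded")
        return 3.0 + float(np.exp(res.x))
    if family == "gaussian":
        def nll(u: float) -> float:
            sd = np.exp(u)
            ll = _gaussian_logpdf_abs(central, sd).sum()
            ll -= central.size * np.log(_gaussian_cdf_abs(cut, sd))
            return -ll

        spread = max(np.std(a), 1e-6)
        res = optimize.minimize_scalar(
            nll, bounds=(np.log(spread) - 6, np.log(spread) + 6), method="bounded"
        )
        return float(np.exp(res.x))
    raise ValueError(f"unknown null family {family!r}")


def fit_mixture(values: np.ndarray, null_family: str = "hotelling") -> MixtureFit:
    """Estimate η₀, the null scale and the marginal density from edge statistics.

    ``values`` are the off-diagonal statistics (signed); at least 100 are
    required.  η₀ is the ratio of the observed central mass to the null
    mass below the truncation point, clipped to [0, 1].
    """
    values = np.asarray(values, float).ravel()
    if values.size < 100:
        raise ValueError("need at least 100 values to fit the mixture")
    if np.ptp(values) == 0:
        raise DegenerateDistributionError("all values identical")
    # empirical-null center: z-scores can carry a global shift (e.g. from
    # group-wise shrinkage-intensity differences); most edges are null, so
    # the median locates the null component
    loc = float(np.median(values)) if null_family == "gaussian" else 0.0
    a = np.abs(values - loc)
    if np.ptp(a) == 0:
        raise DegenerateDistributionError("all values identical")

    param = _fit_null_scale(a, null_family)
    if null_family == "hotelling":
        f0 = lambda t: np.exp(_hotelling_logpdf_abs(t, param))
        cdf0 = lambda t: _hotelling_cdf_abs(t, param)
    else:
        f0 = lambda t: np.exp(_gaussian_logpdf_abs(t, param))
        cdf0 = lambda t: _gaussian_cdf_abs(t, param)

    cut = np.quantile(a, _CENTRAL_QUANTILE)
    eta0 = float(np.clip(np.mean(a <= cut) / cdf0(np.array(cut)), 0.0, 1.0))

    # Grenander density on the null p-values 1 − F0(|v|): the null component
    # is then uniform and the lfdr reduces to η₀ / f̂p(pval), which is well
    # behaved in the tail where both f₀ and the marginal vanish.
    pvals = 1.0 - cdf0(a)
    fp = _Grenander(pvals, x_end=1.0)
    # marginal density of |v| by change of variables through the null CDF
    f = lambda t: fp(1.0 - cdf0(np.asarray(t, float))) * f0(t)
    return MixtureFit(eta0=eta0, null_family=null_family, null_param=param,
                      f0=f0, f=f, cdf0=cdf0, fp=fp, loc=loc)


def edge_lfdr(fit: MixtureFit, values: np.ndarray) -> np.ndarray:
    """lfdr = η₀·f₀/f at each value, capped at 1, non-increasing in |value|.

    Accepts a vector or a square matrix; a matrix comes back symmetric with
    unit diagonal masked as lfdr 1 (self-edges are never called).
    """
    values = np.asarray(values, float)
    square = values.ndim == 2
    if square:
        iu = np.triu_indices(values.shape[0], 1)
        vec = values[iu]
    else:
        vec = values.ravel()
    a = np.abs(vec - fit.loc)
    fp_vals = fit.fp(1.0 - fit.cdf0(a))  # = f(a) / f0(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        # fp = 0 only where the marginal mass is exhausted near pval → 1,
        # i.e. at the null-most values: cap there at 1
        raw = np.where(fp_vals > 0, fit.eta0 / fp_vals, np.inf)
    raw = np.minimum(raw, 1.0)
    # enforce monotone non-increasing lfdr in |value| (conservatively:
    # each value is raised to the largest raw lfdr at or above its |value|)
    order = np.argsort(a)
    mono = np.maximum.accumulate(raw[order][::-1])[::-1]
    out = np.empty_like(raw)
    out[order] = mono
    if not square:
        return out
    mat = np.ones_like(values)
    mat[iu] = out
    mat[(iu[1], iu[0])] = out
    return mat


# ---------------------------------------------------------------------------
# edge sets


@dataclass
class EdgeSet:
    """Edges surviving an lfdr threshold, with class and direction labels."""

    edges: pd.DataFrame
    threshold: float
    kind: str                              # single-group | group-difference | hemisphere-difference
    jarque_bera_p: float | None = None
    disconnected: dict | None = None       # hemisphere → count (single-group only)

    def __len__(self) -> int:
        return len(self.edges)

    def counts_by_class(self) -> dict[str, int]:
        out = {"intra-LH": 0, "intra-RH": 0, "interhemispheric": 0}
        for cls, cnt in self.edges["edge_class"].value_counts().items():
            out[cls] = int(cnt)
        return out

    def counts_by_sign(self) -> dict[str, dict[str, int]]:
        out = {}
        for cls in ("intra-LH", "intra-RH", "interhemispheric"):
            sub = self.edges[self.edges["edge_class"] == cls]
            out[cls] = {
                "positive": int((sub["sign"] > 0).sum()),
                "negative": int((sub["sign"] < 0).sum()),
            }
        return out

    def counts_by_direction(self) -> dict[str, dict[str, int]]:
        out = {}
        for direction in sorted(self.edges["direction"].dropna().unique()):
            sub = self.edges[self.edges["direction"] == direction]
            out[direction] = {
                cls: int((sub["edge_class"] == cls).sum())
                for cls in ("intra-LH", "intra-RH", "interhemispheric")
            }
        return out


def _edge_frame(atlas: ROIAtlas | None, rows: list[dict]) -> pd.DataFrame:
    cols = ["node_i", "node_j", "statistic", "lfdr", "sign", "edge_class", "direction"]
    return pd.DataFrame(rows, columns=cols)


def call_edges(
    network: PartialCorrNetwork,
    threshold: float = DEFAULT_THRESHOLD,
    fit: MixtureFit | None = None,
) -> EdgeSet:
    """Call significant edges at the lfdr threshold for one group's network.

    Fits the Hotelling-null mixture to the network's partial correlations
    if ``network.lfdr`` is not already populated, and fills it.
    """
    if network.lfdr is None:
        if fit is None:
            fit = fit_mixture(network.offdiag_values(), null_family="hotelling")
        network.lfdr = edge_lfdr(fit, network.pmat)
        network.provenance.setdefault("eta0", fit.eta0)
        network.provenance.setdefault("null_param", fit.null_param)

    k = network.k
    atlas = network.atlas
    rows = []
    connected = set()
    iu = np.triu_indices(k, 1)
    for i, j in zip(*iu):
        if network.lfdr[i, j] < threshold:
            cls = classify_edge(atlas, int(i), int(j)) if atlas else ""
            rows.append(
                {
                    "node_i": int(i),
                    "node_j": int(j),
                    "statistic": network.pmat[i, j],
                    "lfdr": network.lfdr[i, j],
                    "sign": int(np.sign(network.pmat[i, j])),
                    "edge_class": cls,
                    "direction": None,
                }
            )
            connected |= {int(i), int(j)}
    disconnected = None
    if atlas is not None:
        disconnected = {
            hemi: sum(1 for i in atlas.hemisphere_indices(hemi) if i not in connected)
            for hemi in ("L", "R")
        }
    return EdgeSet(
        edges=_edge_frame(atlas, rows),
        threshold=threshold,
        kind="single-group",
        disconnected=disconnected,
    )


def _fisher_z_edges(
    stat_a: np.ndarray,
    stat_b: np.ndarray,
    se: float,
    atlas: ROIAtlas | None,
    pairs: list[tuple[int, int]],
    threshold: float,
    kind: str,
    directions: tuple[str, str],
) -> EdgeSet:
    # z on the SIGNED partial correlations (their difference is near-normal,
    # which the Jarque–Bera check monitors); direction labels compare the
    # association magnitudes, independent of sign
    z = (np.arctanh(stat_a) - np.arctanh(stat_b)) / se
    jb_p = float(stats.jarque_bera(z).pvalue) if z.size >= 10 else None
    if np.ptp(z) == 0:
        lfdr_vals = np.ones_like(z)  # identical inputs: nothing differs
    else:
        fit = fit_mixture(z, null_family="gaussian")
        lfdr_vals = edge_lfdr(fit, z)
    rows = []
    for (i, j), zz, l, sa, sb in zip(pairs, z, lfdr_vals, stat_a, stat_b):
        if l < threshold:
            cls = classify_edge(atlas, i, j) if atlas else ""
            rows.append(
                {
                    "node_i": i,
                    "node_j": j,
                    "statistic": zz,
                    "lfdr": l,
                    "sign": int(np.sign(zz)),
                    "edge_class": cls,
                    "direction": directions[0] if abs(sa) > abs(sb) else directions[1],
                }
            )
    return EdgeSet(edges=_edge_frame(atlas, rows), threshold=threshold, kind=kind,
                   jarque_bera_p=jb_p)


def compare_groups(
    net_a: PartialCorrNetwork,
    net_b: PartialCorrNetwork,
    n_a: int | None = None,
    n_b: int | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    labels: tuple[str, str] = ("A", "B"),
) -> EdgeSet:
    """Differential edges between two groups via Fisher-z lfdr.

    z = (atanh p_a − atanh p_b)/√(1/(n_a−3) + 1/(n_b−3)) on the signed
    values, Gaussian-null mixture on the z's; direction labels compare
    partial-correlation magnitudes (|p_a| vs |p_b|), independent of sign.
    """
    if net_a.k != net_b.k:
        raise ValueError("networks have different node counts")
    if net_a.atlas is not None and net_b.atlas is not None:
        if net_a.atlas.names != net_b.atlas.names:
            raise ValueError("networks use different atlases")
    n_a = n_a if n_a is not None else net_a.n
    n_b = n_b if n_b is not None else net_b.n
    if n_a is None or n_b is None or min(n_a, n_b) <= 3:
        raise ValueError("need sample sizes > 3 for the Fisher-z SE")
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    iu = np.triu_indices(net_a.k, 1)
    pairs = [(int(i), int(j)) for i, j in zip(*iu)]
    return _fisher_z_edges(
        net_a.pmat[iu], net_b.pmat[iu], se, net_a.atlas, pairs, threshold,
        kind="group-difference",
        directions=(f"{labels[1]}<{labels[0]}", f"{labels[1]}>{labels[0]}"),
    )


def compare_hemispheres(
    net: PartialCorrNetwork,
    atlas: ROIAtlas | None = None,
    n: int | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> EdgeSet:
    """Left-vs-right asymmetric edges of one group's network.

    Every unordered left-hemisphere node pair is matched to its homotopic
    right-hemisphere pair; the two signed partial correlations are compared
    by the Fisher-z construction, with LH>RH / LH<RH labels assigned by
    magnitude (the two sub-networks come from the same subjects, but the
    independent-samples SE is applied).
    """
    atlas = atlas or net.atlas
    if atlas is None or not atlas.homotopic_pairs:
        raise ValueError("atlas with homotopic pairing required")
    n = n if n is not None else net.n
    if n is None or n <= 3:
        raise ValueError("need sample size > 3 for the Fisher-z SE")
    left = atlas.hemisphere_indices("L")
    partner = {li: ri for li, ri in atlas.homotopic_pairs}
    pairs, p_lh, p_rh = [], [], []
    for ai in range(len(left)):
        for bi in range(ai + 1, len(left)):
            i, j = left[ai], left[bi]
            ri, rj = partner[i], partner[j]
            pairs.append((i, j))
            p_lh.append(net.pmat[i, j])
            p_rh.append(net.pmat[ri, rj])
    se = np.sqrt(2.0 / (n - 3))
    return _fisher_z_edges(
        np.array(p_lh), np.array(p_rh), se, atlas, pairs, threshold,
        kind="hemisphere-difference", directions=("LH>RH", "LH<RH"),
    )
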