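"""Shrinkage covariance estimation and partial correlations.

In the n ≪ k regime the sample covariance is singular, so the Gaussian
graphical model is estimated with an analytic shrinkage estimator: sample
correlations are shrunk toward zero (equivalently, the covariance is shrunk
toward its own heteroscedastic diagonal — the graphical model of isolated
nodes) with the minimum-MSE intensity

    λ* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij²   (clipped to [0, 1]),

which leaves a well-conditioned, positive-definite Σ for any λ > 0.  The
partial-correlation matrix follows by inverting Σ and rescaling:
p_ij = −ω_ij / √(ω_ii ω_jj) with Ω = Σ⁻¹, diagonal fixed at 1.  Linear age
and gender effects are removed by estimating the model on the covariate-
augmented matrix (k + 2 variables) and retaining the ROI block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ROIAtlas, classify_edge

__all__ = [
    "ShrunkenCovariance",
    "PartialCorrNetwork",
    "shrink_covariance",
    "partial_correlations",
    "adjust_covariates",
    "network_from_data",
]


class InsufficientSamplesError(ValueError):
    pass


class DegenerateVariableError(ValueError):
    pass


@dataclass(frozen=True)
class ShrunkenCovariance:
    sigma: np.ndarray
    lam: float             # shrinkage intensity λ ∈ [0, 1]
    n: int
    k: int
    lam_var: float = 0.0   # variance-shrinkage intensity (0 unless enabled)


@dataclass
class PartialCorrNetwork:
    """k×k partial-correlation matrix with (optionally) per-edge lfdr."""

    pmat: np.ndarray
    atlas: ROIAtlas | None = None
    lfdr: np.ndarray | None = None
    n: int | None = None                 # sample size behind the estimate
    provenance: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.pmat.shape[0]

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle partial correlations in (i < j) row-major order."""
        iu = np.triu_indices(self.k, 1)
        return self.pmat[iu]

    def write_square_tsv(self, path: str | Path) -> None:
        names = self.atlas.names if self.atlas else [f"v{i}" for i in range(self.k)]
        pd.DataFrame(self.pmat, index=names, columns=names).to_csv(path, sep="\t")

    def write_edge_tsv(self, path: str | Path) -> None:
        names = self.atlas.names if self.atlas else [f"v{i}" for i in range(self.k)]
        rows = []
        iu = np.triu_indices(self.k, 1)
        for i, j in zip(*iu):
            rows.append(
                {
                    "node_i": names[i],
                    "node_j": names[j],
                    "partial_corr": self.pmat[i, j],
                    "lfdr": self.lfdr[i, j] if self.lfdr is not None else np.nan,
                    "edge_class": classify_edge(self.atlas, int(i), int(j))
                    if self.atlas
                    else "",
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DegenerateVariableError(f"zero-variance column(s): {zero.tolist()}")
    return (x - x.mean(axis=0)) / sd, sd


def shrink_covariance(
    x: np.ndarray, shrink_variances: bool = False, lam: float | None = None
) -> ShrunkenCovariance:
    """Analytic-shrinkage covariance with heteroscedastic diagonal target.

    Empirical variances are kept on the diagonal by default; with
    ``shrink_variances`` they are additionally shrunk toward their median
    with a second analytic intensity.  Pass ``lam`` to override the analytic
    intensity with a fixed value (used to put two groups' estimates on a
    common shrinkage scale before comparing them).
    """
    x = np.asarray(x, float)
    n, k = x.shape
    if n < 3:
        raise InsufficientSamplesError(f"need n ≥ 3 samples, got {n}")
    xs, sd = _standardize(x)

    # pairwise products w_kij = z_ki z_kj; r_ij = n/(n-1) * mean_k w_kij
    w_bar = (xs.T @ xs) / n
    r = w_bar * n / (n - 1)
    if lam is None:
        # Var̂(r_ij) = n/(n-1)^3 * Σ_k (w_kij − w̄_ij)²
        w2_sum = (xs**2).T @ (xs**2)  # Σ_k w_kij²
        var_r = n / (n - 1.0) ** 3 * (w2_sum - n * w_bar**2)
        iu = np.triu_indices(k, 1)
        denom = float((r[iu] ** 2).sum())
        lam = 1.0 if denom == 0 else float(np.clip(var_r[iu].sum() / denom, 0.0, 1.0))
    elif not 0.0 <= lam <= 1.0:
        raise ValueError("fixed shrinkage intensity must be in [0, 1]")

    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)

    v = sd**2
    lam_var = 0.0
    if shrink_variances:
        # variance target: the median empirical variance
        xc = x - x.mean(axis=0)
        var_of_v = n / (n - 1.0) ** 3 * ((xc**2 - v * (n - 1) / n) ** 2).sum(axis=0)
        dev = ((v - np.median(v)) ** 2).sum()
        lam_var = 1.0 if dev == 0 else float(np.clip(var_of_v.sum() / dev, 0.0, 1.0))
        v = lam_var * np.median(v) + (1.0 - lam_var) * v
    s_out = np.sqrt(v)
    sigma = r_shrunk * np.outer(s_out, s_out)
    return ShrunkenCovariance(sigma=sigma, lam=lam, n=n, k=k, lam_var=lam_var)


def partial_correlations(
    cov: ShrunkenCovariance, atlas: ROIAtlas | None = None
) -> PartialCorrNetwork:
    """Partial correlations from the inverse shrunken covariance."""
    eigmin = np.linalg.eigvalsh(cov.sigma)[0]
    if eigmin <= 0:
        raise np.linalg.LinAlgError(
            f"covariance not positive definite (min eigenvalue {eigmin:.3g})"
        )
    omega = np.linalg.inv(cov.sigma)
    d = np.sqrt(np.diag(omega))
    pmat = -omega / np.outer(d, d)
    pmat = 0.5 * (pmat + pmat.T)
    np.fill_diagonal(pmat, 1.0)
    return PartialCorrNetwork(
        pmat=pmat, atlas=atlas, n=cov.n, provenance={"lambda": cov.lam}
    )


def adjust_covariates(
    x: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    atlas: ROIAtlas | None = None,
    shrink_variances: bool = False,
    lam: float | None = None,
) -> PartialCorrNetwork:
    """Partial correlations among ROIs with age/gender effects removed.

    The covariates enter the estimation as two extra variables; only the
    ROI × ROI block of the resulting partial-correlation matrix is
    retained (the covariates are then conditioned on by construction).
    """
    x = np.asarray(x, float)
    k = x.shape[1]
    aug = np.column_stack([x, np.asarray(age, float), np.asarray(gender, float)])
    cov = shrink_covariance(aug, shrink_variances=shrink_variances, lam=lam)
    net = partial_correlations(cov)
    block = net.pmat[:k, :k].copy()
    np.fill_diagonal(block, 1.0)
    return PartialCorrNetwork(
        pmat=block, atlas=atlas, n=cov.n, provenance={"lambda": cov.lam, "adjusted": True}
    )


def network_from_data(
    dataset, adjust: bool = True, shrink_variances: bool = False,
    lam: float | None = None,
) -> PartialCorrNetwork:
    """Convenience: MTRDataset → covariate-adjusted partial-correlation network."""
    if adjust:
        net = adjust_covariates(
            dataset.values, dataset.age, dataset.gender,
            atlas=dataset.atlas, shrink_variances=shrink_variances, lam=lam,
        )
    else:
        cov = shrink_covariance(
            dataset.values, shrink_variances=shrink_variances, lam=lam
        )
        net = partial_correlations(cov, atlas=dataset.atlas)
    groups = np.unique(dataset.group)
    net.provenance["group"] = groups[0] if len(groups) == 1 else "mixed"
    return net
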