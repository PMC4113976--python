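"""MTR computation, ROI averaging, laterality scores and permutation GLM.

The magnetization transfer ratio of a voxel is the percentage signal loss
attributable to the MT effect, ``MTR = 100·(M0 − MS)/M0``; voxels with
MTR ≤ 10% are treated as noise and excluded from ROI means.  Hemispheric
asymmetry of a homotopic ROI pair is summarized by the laterality score
``(L − R)/(L + R)`` (positive = leftward) and tested with a general linear
model with age and gender as nuisance covariates, permutation-based
p-values and Benjamini–Hochberg step-up FDR across the 39 pairs.

The voxel-level operations exist for completeness and toy arrays; the
pipeline's native entry point is the ROI-level matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NOISE_MASK_THRESHOLD",
    "LateralityResult",
    "compute_mtr",
    "roi_mean",
    "laterality_score",
    "laterality_scores",
    "laterality_glm",
]

NOISE_MASK_THRESHOLD = 10.0  # percent; voxels at or below are excluded


class InvalidIntensityError(ValueError):
    pass


class MissingRegionError(ValueError):
    pass


def compute_mtr(m0: np.ndarray, ms: np.ndarray) -> np.ma.MaskedArray:
    """Percent MTR per voxel with the >10% noise mask applied.

    Returns a masked array: masked entries are noise voxels excluded from
    any downstream averaging.
    """
    m0 = np.asarray(m0, float)
    ms = np.asarray(ms, float)
    if m0.shape != ms.shape:
        raise ValueError("m0 and ms must have the same shape")
    if (m0 <= 0).any():
        raise InvalidIntensityError("non-positive unsaturated intensity")
    mtr = 100.0 * (m0 - ms) / m0
    return np.ma.masked_array(mtr, mask=mtr <= NOISE_MASK_THRESHOLD)


def roi_mean(mtr: np.ma.MaskedArray, labels: np.ndarray) -> dict:
    """Mean MTR over mask-passing voxels for every ROI label."""
    labels = np.asarray(labels)
    out = {}
    for lab in np.unique(labels):
        sel = mtr[labels == lab]
        if np.ma.count(sel) == 0:
            raise MissingRegionError(f"ROI {lab!r} has no voxels above the noise mask")
        out[lab] = float(sel.mean())
    return out


def laterality_score(left, right):
    """(L − R)/(L + R); positive = leftward asymmetry."""
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    total = left + right
    if (total <= 0).any():
        raise ValueError("laterality undefined for L + R ≤ 0")
    return (left - right) / total


def laterality_scores(values: np.ndarray, atlas) -> np.ndarray:
    """Subject × pair matrix of laterality scores for all homotopic pairs."""
    cols = []
    for li, ri in atlas.homotopic_pairs:
        cols.append(laterality_score(values[:, li], values[:, ri]))
    return np.column_stack(cols)


@dataclass
class LateralityResult:
    """Per-homotopic-pair laterality inference table."""

    pair_labels: list[str]
    score: np.ndarray        # mean score (within) or group difference (between)
    t: np.ndarray
    p: np.ndarray            # permutation two-sided p
    q: np.ndarray            # BH step-up across pairs
    contrast: str            # "within" | "between"
    degenerate: np.ndarray   # pairs where t was undefined
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return (self.q < self.alpha) & ~self.degenerate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": self.pair_labels,
                "score": self.score,
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "significant": self.significant,
            }
        )


def _residualize(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residuals of each column of y on the nuisance design z (with intercept)."""
    beta, *_ = np.linalg.lstsq(z, y, rcond=None)
    return y - z @ beta


def _t_two_sample(y: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column; 0 where variance vanishes."""
    a, b = y[g == 1], y[g == 0]
    na, nb = len(a), len(b)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    return t


def _t_one_sample(y: np.ndarray) -> np.ndarray:
    n = y.shape[0]
    se = y.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, y.mean(axis=0) / se, 0.0)
    return t


def laterality_glm(
    scores: np.ndarray,
    group: np.ndarray | None,
    age: np.ndarray,
    gender: np.ndarray,
    contrast: str = "between",
    n_perm: int = 10_000,
    seed: int = 0,
    pair_labels: list[str] | None = None,
    adjust_within: bool = True,
) -> LateralityResult:
    """Permutation GLM on laterality scores with age/gender as nuisance.

    between
        Two-sample contrast of the two groups.  Scores are residualized on
        the nuisance covariates and group labels permuted (Freedman–Lane
        style exchangeability).
    within
        One-sample test that mean laterality differs from zero, via random
        sign-flips of the (by default covariate-adjusted) scores; the
        nuisance covariates are centered so adjustment leaves the mean
        untouched.

    Two-sided p = (1 + #{|t*| ≥ |t|}) / (1 + n_perm); q by BH step-up.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be ≥ 100")
    scores = np.asarray(scores, float)
    n, n_pairs = scores.shape
    rng = np.random.default_rng(seed)
    z = np.column_stack(
        [np.ones(n), np.asarray(age, float) - np.mean(age),
         np.asarray(gender, float) - np.mean(gender)]
    )

    if contrast == "between":
        if group is None:
            raise ValueError("between-group contrast needs group labels")
        group = np.asarray(group)
        levels = np.unique(group)
        if len(levels) != 2:
            raise ValueError("between-group contrast needs exactly two groups")
        g = (group == levels[1]).astype(int)
        resid = _residualize(scores, z)
        t_obs = _t_two_sample(resid, g)
        score_summary = scores[g == 1].mean(axis=0) - scores[g == 0].mean(axis=0)
        exceed = np.zeros(n_pairs)
        for _ in range(n_perm):
            gp = rng.permutation(g)
            exceed += np.abs(_t_two_sample(resid, gp)) >= np.abs(t_obs)
    elif contrast == "within":
        y = _residualize(scores, z[:, 1:]) if adjust_within else scores
        # centered covariates: residualization preserves the column means
        t_obs = _t_one_sample(y)
        score_summary = scores.mean(axis=0)
        yc = y - y.mean(axis=0)  # sign-flip the null-centered part
        exceed = np.zeros(n_pairs)
        for _ in range(n_perm):
            flips = rng.choice([-1.0, 1.0], size=n)
            exceed += np.abs(_t_one_sample(yc * flips[:, None])) >= np.abs(t_obs)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    degenerate = np.ptp(scores, axis=0) == 0
    p = (1.0 + exceed) / (1.0 + n_perm)
    p[degenerate] = 1.0
    _, q, _, _ = multipletests(p, method="fdr_bh")
    if pair_labels is None:
        pair_labels = [f"pair{i}" for i in range(n_pairs)]
    return LateralityResult(
        pair_labels=list(pair_labels),
        score=score_summary,
        t=t_obs,
        p=p,
        q=q,
        contrast=contrast,
        degenerate=degenerate,
    )
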