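"""Synthetic cohorts from sparse Gaussian graphical models.

Emulates the statistical structure the network analysis assumes: subject ×
ROI mean-MTR matrices drawn from a multivariate normal whose precision
matrix carries a configurable set of planted edges, with optional group
differences (lost/gained edges), hemispheric mean asymmetries and age /
gender covariate effects.  Synthesis starts at the ROI-mean level — no
voxel images, scanner noise or segmentation are simulated.

The default scenario mirrors the regime the shrinkage estimator exists
for: two groups of 15 subjects, 78 ROIs, ~100 true edges, i.e. n ≪ k.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ROIAtlas, default_atlas

__all__ = [
    "PrecisionModel",
    "MTRDataset",
    "ModelConstructionError",
    "build_precision",
    "simulate_cohort",
    "two_group_scenario",
]

Edge = tuple[int, int]

# Construction / simulation defaults; MTR is in percent units throughout.
MIN_EIGENVALUE = 0.1          # SPD margin enforced on every precision matrix
MEAN_MTR_RANGE = (30.0, 60.0)  # physiological regional mean MTR (%)
DEFAULT_NOISE_SD = 1.5         # between-subject SD of a regional mean (%)
AGE_RANGE = (55.0, 80.0)       # elderly cohort; uniform draw
POSITIVE_EDGE_PROB = 0.9       # ~90% of edges are positive associations


class ModelConstructionError(ValueError):
    """Requested planted-edge structure is incompatible with positive definiteness."""


@dataclass(frozen=True)
class PrecisionModel:
    """A sparse-precision population model for k ROI variables.

    ``omega`` is the precision (inverse covariance) on the *standardized*
    scale; marginal location and scale are carried separately by
    ``regional_means`` (percent MTR) and ``noise_sd``.
    """

    omega: np.ndarray
    true_edges: frozenset[Edge]
    regional_means: np.ndarray
    noise_sd: np.ndarray
    atlas: ROIAtlas = field(default_factory=default_atlas, compare=False)

    def __post_init__(self) -> None:
        k = self.omega.shape[0]
        if self.omega.shape != (k, k) or not np.allclose(self.omega, self.omega.T):
            raise ModelConstructionError("omega must be square symmetric")
        if np.linalg.eigvalsh(self.omega)[0] <= 0:
            raise ModelConstructionError("omega is not positive definite")
        support = {
            (i, j)
            for i in range(k)
            for j in range(i + 1, k)
            if self.omega[i, j] != 0.0
        }
        if support != set(self.true_edges):
            raise ModelConstructionError("true_edges does not match omega support")

    @property
    def k(self) -> int:
        return self.omega.shape[0]

    def implied_partial_correlations(self) -> np.ndarray:
        """Population partial-correlation matrix, directly from the precision."""
        d = np.sqrt(np.diag(self.omega))
        p = -self.omega / np.outer(d, d)
        np.fill_diagonal(p, 1.0)
        return p

    def covariance(self) -> np.ndarray:
        """Population covariance on the MTR scale (means excluded)."""
        corr = np.linalg.inv(self.omega)
        s = np.sqrt(np.diag(corr))
        corr = corr / np.outer(s, s)
        return corr * np.outer(self.noise_sd, self.noise_sd)


@dataclass
class MTRDataset:
    """Subject × ROI matrix of mean MTR values with covariates."""

    values: np.ndarray        # (n_subjects, k), percent MTR
    group: np.ndarray         # per-subject label, e.g. "control" / "AD"
    age: np.ndarray           # years
    gender: np.ndarray        # 0/1 coding
    atlas: ROIAtlas = field(default_factory=default_atlas)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if k != self.atlas.n_nodes:
            raise ValueError(f"{k} columns but atlas has {self.atlas.n_nodes} nodes")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not allowed")
        for name in ("group", "age", "gender"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per subject")
            setattr(self, name, arr)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.atlas.names)

    def write_tsv(self, values_path: str | Path, covariates_path: str | Path) -> None:
        self.to_frame().to_csv(values_path, sep="\t", index=False)
        cov = pd.DataFrame(
            {
                "subject": [f"s{i:03d}" for i in range(self.n_subjects)],
                "group": self.group,
                "age": self.age,
                "gender": self.gender,
            }
        )
        cov.to_csv(covariates_path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls,
        values_path: str | Path,
        covariates_path: str | Path,
        atlas: ROIAtlas | None = None,
    ) -> "MTRDataset":
        atlas = atlas or default_atlas()
        vals = pd.read_csv(values_path, sep="\t")
        if list(vals.columns) != atlas.names:
            raise ValueError("ROI columns do not match the atlas node order")
        cov = pd.read_csv(covariates_path, sep="\t")
        return cls(
            vals.to_numpy(float),
            cov["group"].to_numpy(),
            cov["age"].to_numpy(float),
            cov["gender"].to_numpy(int),
            atlas,
        )


# ---------------------------------------------------------------------------
# model construction


def _solve_diagonal_shift(
    targets: np.ndarray, edges: list[Edge], k: int, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray] | None:
    """Find omega with unit-ish diagonal whose implied partial correlations
    hit ``targets`` on ``edges``, keeping min-eigenvalue ≥ MIN_EIGENVALUE.

    Off-diagonal entries are set to −rho·d with diagonal d = 1 + c; the
    smallest diagonal shift c restoring the eigenvalue margin scales the
    implied correlations down by 1/(1+c), so the off-diagonals are
    re-inflated and the shift re-solved until the pair is self-consistent.
    Returns (omega, implied values on edges) or None if the fixed point
    escapes (targets too strong for the requested support).
    """
    work = targets.copy()
    for _ in range(max_iter):
        omega = np.eye(k)
        for (i, j), w in zip(edges, work):
            omega[i, j] = omega[j, i] = -w
        lam = np.linalg.eigvalsh(omega)[0]
        c = max(0.0, MIN_EIGENVALUE - lam)
        if c == 0.0:
            return omega, work
        implied = work / (1.0 + c)
        if np.allclose(implied, targets, atol=1e-9):
            omega[np.diag_indices(k)] += c
            return omega, implied
        new_work = targets * (1.0 + c)
        if np.abs(new_work).max() > 0.95:  # diverging: infeasible targets
            return None
        work = new_work
    return None


def _grow_feasible_support(
    k: int,
    n_edges: int,
    lo: float,
    hi: float,
    positive_fraction: float,
    rng: np.random.Generator,
    margin: float = MIN_EIGENVALUE,
    max_proposals_per_edge: int = 3000,
) -> dict[Edge, float]:
    """Random edge placement conditioned on positive definiteness.

    Edges are proposed uniformly at random with signed strengths drawn from
    [lo, hi] and accepted only if the connected component they join keeps
    ``min-eigenvalue(I − R) ≥ margin``; the resulting I − R is then
    block-diagonal over components, so the accepted strengths ARE the
    implied partial correlations, exactly.  (A dense random support at
    these strengths is spectrally infeasible — conditioning placement on
    feasibility is what makes strong planted edges realizable at all.)
    """
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    big_r = np.zeros((k, k))
    edges: dict[Edge, float] = {}
    budget = max_proposals_per_edge * max(n_edges, 1)
    while len(edges) < n_edges and budget > 0:
        budget -= 1
        i, j = rng.choice(k, 2, replace=False)
        i, j = (int(min(i, j)), int(max(i, j)))
        if (i, j) in edges:
            continue
        w = rng.uniform(lo, hi)
        if rng.random() >= positive_fraction:
            w = -w
        ra, rb = find(i), find(j)
        comp = [x for x in range(k) if find(x) in (ra, rb)]
        sub = big_r[np.ix_(comp, comp)].copy()
        ci, cj = comp.index(i), comp.index(j)
        sub[ci, cj] = sub[cj, ci] = w
        if np.linalg.eigvalsh(np.eye(len(comp)) - sub)[0] >= margin:
            big_r[i, j] = big_r[j, i] = w
            edges[(i, j)] = w
            parent[rb] = ra
    if len(edges) < n_edges:
        raise ModelConstructionError(
            f"placed only {len(edges)} of {n_edges} edges with strengths in "
            f"[{lo}, {hi}] before exhausting proposals"
        )
    return edges


def build_precision(
    atlas: ROIAtlas | None = None,
    n_edges: int = 100,
    partial_corr_range: tuple[float, float] = (0.3, 0.5),
    seed: int = 0,
    positive_fraction: float = POSITIVE_EDGE_PROB,
    mean_mtr_range: tuple[float, float] = MEAN_MTR_RANGE,
    noise_sd: float | np.ndarray = DEFAULT_NOISE_SD,
    edges: list[Edge] | None = None,
) -> PrecisionModel:
    """Build a sparse SPD precision with planted partial correlations.

    The implied partial-correlation magnitudes on the planted edges land
    inside ``partial_corr_range``; all other off-diagonal partial
    correlations are exactly zero.  Edge placement and signed strengths are
    drawn from ``seed``; pass ``edges`` to fix the support explicitly (the
    strengths are then realized via the diagonal-shift solver and must be
    jointly feasible).
    """
    atlas = atlas or default_atlas()
    k = atlas.n_nodes
    lo, hi = partial_corr_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("partial_corr_range must lie inside (0, 1)")
    n_pairs = k * (k - 1) // 2
    if n_edges > n_pairs:
        raise ValueError(f"n_edges={n_edges} exceeds {n_pairs} pairs")

    rng = np.random.default_rng(seed)

    if edges is not None:
        chosen = [(min(i, j), max(i, j)) for i, j in edges]
        signs = np.where(rng.random(len(chosen)) < positive_fraction, 1.0, -1.0)
        mags = rng.uniform(lo, hi, size=len(chosen))
        solved = _solve_diagonal_shift(signs * mags, chosen, k)
        if solved is None:
            raise ModelConstructionError(
                "requested support cannot realize strengths in "
                f"[{lo}, {hi}] as a positive-definite precision"
            )
        omega, implied = solved
        if len(chosen) and np.abs(implied).min() < lo - 1e-9:
            raise ModelConstructionError(
                "diagonal shift pushed implied partial correlations below range"
            )
        edge_map = dict(zip(chosen, implied))
    else:
        edge_map = _grow_feasible_support(
            k, n_edges, lo, hi, positive_fraction, rng
        )
        omega = np.eye(k)
        for (i, j), w in edge_map.items():
            omega[i, j] = omega[j, i] = -w

    means = rng.uniform(*mean_mtr_range, size=k)
    sd = np.broadcast_to(np.asarray(noise_sd, float), (k,)).copy()
    return PrecisionModel(
        omega=omega,
        true_edges=frozenset(edge_map),
        regional_means=means,
        noise_sd=sd,
        atlas=atlas,
    )


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(
    model: PrecisionModel,
    n_subjects: int = 15,
    group_label: str = "control",
    covariate_effect: tuple[np.ndarray | float, np.ndarray | float] | None = None,
    asymmetry: dict[int, float] | None = None,
    seed: int = 0,
) -> MTRDataset:
    """Draw an independent cohort from the population model.

    covariate_effect
        Optional ``(age_slope, gender_slope)`` — per-ROI (or scalar) linear
        effects added as ``slope_age · (age − mean_age) + slope_gender ·
        gender``; age is centered so regional means stay at their nominal
        values.
    asymmetry
        Mapping from homotopic-pair index to a mean offset δ (MTR %) added
        to the *left* member, giving a population laterality score of
        δ/(2μ+δ) at equal baseline means μ.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be ≥ 2")
    rng = np.random.default_rng(seed)
    atlas = model.atlas
    k = model.k

    means = model.regional_means.copy()
    if asymmetry:
        for pair_idx, delta in asymmetry.items():
            li, _ = atlas.homotopic_pairs[pair_idx]
            means[li] += delta

    age = rng.uniform(*AGE_RANGE, size=n_subjects)
    gender = (rng.random(n_subjects) < 0.5).astype(int)

    cov = model.covariance()
    chol = np.linalg.cholesky(cov)  # raises LinAlgError if model not SPD
    noise = rng.standard_normal((n_subjects, k)) @ chol.T
    values = means[None, :] + noise
    if covariate_effect is not None:
        age_slope, gender_slope = covariate_effect
        age_slope = np.broadcast_to(np.asarray(age_slope, float), (k,))
        gender_slope = np.broadcast_to(np.asarray(gender_slope, float), (k,))
        mid_age = 0.5 * (AGE_RANGE[0] + AGE_RANGE[1])
        values = values + np.outer(age - mid_age, age_slope)
        values = values + np.outer(gender, gender_slope)

    return MTRDataset(
        values=values,
        group=np.array([group_label] * n_subjects),
        age=age,
        gender=gender,
        atlas=atlas,
    )


def modify_precision(
    base: PrecisionModel,
    lost_edges: set[Edge] = frozenset(),
    gained_edges: dict[Edge, float] | None = None,
) -> PrecisionModel:
    """Zero out ``lost_edges`` and plant ``gained_edges`` (edge → implied
    partial correlation), re-solving the diagonal so the surviving planted
    values keep their magnitudes and the matrix stays positive definite."""
    gained_edges = gained_edges or {}
    lost = {(min(i, j), max(i, j)) for i, j in lost_edges}
    if not lost <= set(base.true_edges):
        raise ModelConstructionError("lost_edges must be a subset of true_edges")
    gained = {(min(i, j), max(i, j)): w for (i, j), w in gained_edges.items()}
    if set(gained) & set(base.true_edges):
        raise ModelConstructionError("gained_edges must be disjoint from true_edges")
    if any(w == 0.0 for w in gained.values()):
        raise ModelConstructionError("gained edges must have nonzero strength")

    p_true = base.implied_partial_correlations()
    kept = [e for e in sorted(base.true_edges) if e not in lost]
    edges = kept + sorted(gained)
    # direct construction keeps the surviving implied values bit-exact
    omega = np.eye(base.k)
    for i, j in kept:
        omega[i, j] = omega[j, i] = -p_true[i, j]
    for (i, j), w in gained.items():
        omega[i, j] = omega[j, i] = -w
    if np.linalg.eigvalsh(omega)[0] <= 1e-6:
        raise ModelConstructionError("edge modification breaks positive definiteness")
    return replace(base, omega=omega, true_edges=frozenset(edges))


def two_group_scenario(
    base: PrecisionModel,
    lost_edges: set[Edge] = frozenset(),
    gained_edges: dict[Edge, float] | None = None,
    n_per_group: int = 15,
    seed: int = 0,
    labels: tuple[str, str] = ("control", "AD"),
    covariate_effect=None,
    asymmetry: dict[int, float] | None = None,
) -> tuple[MTRDataset, MTRDataset]:
    """Simulate a two-group contrast: the second group comes from ``base``
    with ``lost_edges`` removed and ``gained_edges`` planted; both groups
    share the atlas, means and covariate distributions."""
    altered = modify_precision(base, lost_edges, gained_edges)
    ds_a = simulate_cohort(
        base, n_per_group, labels[0], covariate_effect, asymmetry, seed=seed
    )
    ds_b = simulate_cohort(
        altered, n_per_group, labels[1], covariate_effect, asymmetry, seed=seed + 1
    )
    return ds_a, ds_b
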