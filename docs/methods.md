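# Methods

`swmnet` implements a structural-covariance network analysis for superficial
white matter (SWM): regional magnetization-transfer-ratio (MTR) values from
two cohorts are turned into Gaussian-graphical-model estimates, edges are
called by local false discovery rate, and the resulting networks are
summarized at the lobe level (integration–segregation) and with
density-integrated binary graph metrics. A synthetic-cohort generator stands
in for the MRI data so that every stage is testable.

## Node space

Each hemisphere carries 39 regions — Brodmann-style areas with three
composites (1+2+3, 24+33, 29+30) and the cuneus — grouped into frontal (9),
parietal (6), paralimbic (14), temporal (6) and occipital (4) lobes.
Left-hemisphere nodes occupy indices 0–38 (lobe by lobe), right-hemisphere
nodes 39–77 in the same order, so homotopic partners differ by 39. The
within-lobe ordering is a free choice (all statistics are order-invariant);
the order of the lobe tables is used.

## MTR and laterality

Voxel MTR is `100·(M0 − MS)/M0` (percent signal loss under magnetization
transfer); voxels with MTR ≤ 10% are treated as noise and excluded from ROI
means. Hemispheric asymmetry of a homotopic pair is the laterality score
`(L − R)/(L + R)` (positive = leftward). Scores are tested with a
permutation GLM: age and gender are nuisance covariates, the between-group
contrast residualizes scores on the covariates and permutes group labels
(Freedman–Lane), the within-group contrast sign-flips the null-centered
covariate-adjusted scores (adjustment is the default; raw scores are an
option). Two-sided p = (1 + #{|t*| ≥ |t|})/(1 + n_perm), so p is never zero;
Benjamini–Hochberg step-up across the 39 pairs gives q. With the default
n_perm = 10 000 the smallest attainable q is 39/10 001 ≈ 0.004; substantially
smaller n_perm makes q < 0.05 unreachable after correction (the floor is
39·(1 + 0)/(1 + n_perm)).

## Network estimation

With n subjects and k = 78 regions (n ≪ k) the sample covariance is
singular, so the covariance is estimated by analytic shrinkage toward its
own diagonal (the graphical model of isolated nodes): sample correlations
are scaled by (1 − λ) with

    λ* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij²,  clipped to [0, 1],

empirical variances are kept on the diagonal (optionally shrunk toward
their median behind a flag), and the result is positive definite for any
λ > 0. Partial correlations follow from Ω = Σ⁻¹ as
p_ij = −ω_ij/√(ω_ii·ω_jj), diagonal 1. Age and gender are removed by
augmenting the data matrix with the two covariates (k = 80), estimating the
model, and keeping the 78×78 region block.

Two properties of λ* worth knowing: on *null* data λ* → 1 at any sample
size (numerator and denominator are both ≈ m/n), which is the correct
minimum-mean-squared-error behavior, and at n = 15 with weak-to-moderate
planted structure λ* lands around 0.8–1.0, leaving estimated partial
correlations of magnitude ~0.02–0.1 regardless of the population values.
λ → 0 only when genuine correlation dominates sampling noise.

## Edge inference

Off-diagonal partial correlations are modeled as a two-component mixture
f = η₀·f₀ + (1 − η₀)·f_a. The null f₀ for partial correlations is
(1 − p²)^((κ−3)/2) (normalized), with the degrees-of-freedom parameter κ
*fitted* rather than fixed at n − 1, because shrinkage compresses the null
spread by orders of magnitude. κ is estimated by truncated maximum
likelihood on the central |p| values (up to their 75th percentile — the
window is a design choice; the central region is where nulls dominate), and
η₀ is the ratio of the observed central mass to the fitted null mass there,
clipped to [0, 1].

The local false discovery rate is computed in null-p-value space: with
u = 1 − F₀(|p|), the marginal density of u is estimated by a Grenander
(least-concave-majorant) decreasing density, and lfdr(p) = η₀ / f̂(u),
capped at 1. This is algebraically the same as η₀·f₀/f but numerically
stable in the tail, where f₀ and f both vanish; it also makes lfdr
monotone non-increasing in |p| up to hull granularity (a conservative
reverse-cummax pass enforces exact monotonicity). The Grenander density is
evaluated with the left-derivative convention — a datum sitting exactly on
a hull knot takes the slope of the segment ending there — which matters
precisely for the most extreme statistics, whose density would otherwise
be taken from the flatter right-adjacent segment. Edges with lfdr < 0.2
are called significant; 0.2 < lfdr < 0.5 is treated as the uncertain band.

Group and hemisphere contrasts Fisher-transform the *signed* partial
correlations and form z = (atanh p_a − atanh p_b)/SE with SE = √(1/(n_a−3)
+ 1/(n_b−3)); the same mixture machinery with a Gaussian null (location
fitted as the median, scale by truncated MLE) gives per-edge lfdr on z.
Signed differences matter: differences of folded magnitudes are
leptokurtic and fail the normality assumption, producing spurious calls.
A Jarque–Bera p-value on the z distribution is reported alongside as the
normality check. Direction labels ("AD < Controls", "LH > RH") compare
association *magnitudes*, independent of sign, so a weakened negative
association counts as a loss. Because the analytic shrinkage intensity
differs between groups — which rescales every estimate and masquerades as
a systematic difference — the pipeline estimates both comparison networks
at a common intensity, the larger of the two per-group λ*. The hemisphere
contrast matches each left-hemisphere node pair to its homotopic
right-hemisphere pair; both estimates come from the same subjects, but the
independent-samples SE is applied — the dependence is acknowledged, not
modeled. The contrast is run per group.

## Macro-network summaries

For a node cluster N (a lobe within one hemisphere), within-region
association is H(N) = −½·ln det P_N on the partial-correlation submatrix
(0 iff the block is the identity; computed on partial correlations, with a
correlation-matrix mode behind a flag). Between-region association is the
Gaussian mutual information MI = ½·ln(det P_N1 · det P_N2 / det P_N1∪N2)
≥ 0. Note that in the −½·ln det convention MI equals H(N1∪N2) − H(N1) −
H(N2), i.e. the joint block carries the association. The 10 region values
and 45 pair values are ranked weak/medium/strong by 1-D k-means (k = 3,
50 restarts, labels ordered by centroid), fitted on the *pooled* values of
both groups separately per quantity, so levels are comparable across
groups. A region (pair) is flagged significant when it contains at least
one called edge at lfdr < 0.2 — a documented proxy, configurable by
passing different edge sets.

## Graph topology

Binary networks come from the partial-correlation matrix either at an lfdr
threshold or at an exact target density (the ⌊d·3003⌉ lowest-lfdr edges;
ties broken by larger |p|, then node order). Degree is the row sum; hubs
are nodes whose *density-integrated* degree is at or above the 75th
percentile (linear-interpolation percentile) of the pooled two-hemisphere
distribution — about 20 of 78 nodes when degrees are distinct, all nodes in
the degenerate all-equal case. Efficiency is the inverse-harmonic-mean
shortest-path measure with 1/d = 0 for disconnected pairs
(Latora–Marchiori); local efficiency averages the neighborhood-subgraph
efficiency, zero for nodes with fewer than two neighbors. Modularity Q
sums L_c/m − (d_c/2m)² over modules; `best_partition` maximizes Q by
seeded greedy agglomeration from singletons, merging the connected module
pair with the largest positive ΔQ (ties broken reproducibly by the seed).

Because a fixed lfdr cut yields different densities in different groups,
metrics are evaluated on an even grid of densities spanning the band
between the densities at lfdr = 0.2 and lfdr = 0.5 and averaged with equal
weights (n_points = 30 by default; a grid fine enough that the average is
stable, exposed in config). If both endpoints map to one density a warning
is issued and the single-density value returned. Group contrasts re-run
the entire pipeline (shrinkage → mixture fit → binarization → metric →
integration) under group-label permutation, with
p = (1 + #{|Δ*| ≥ |Δ|})/(1 + n_perm). The density-matched comparison
instead binarizes both networks to a common density grid and compares
metrics density-wise (a multiple-comparison note is attached; no
correction is applied).

## Synthetic cohorts

The generator draws subject × ROI matrices from multivariate normals whose
precision matrix Ω carries a configurable planted edge set: off-diagonal
entries are −ρ with unit diagonal, so the planted ρ are *exactly* the
population partial correlations. A dense random support at magnitudes
0.3–0.5 on 78 nodes is spectrally infeasible (λ_max of the off-diagonal
matrix exceeds 1 essentially always), so edges are placed by random
sequential proposals accepted only when the affected connected component
keeps min-eigenvalue(I − R) ≥ 0.1 — random placement conditioned on
positive definiteness. Group scenarios zero "lost" edges and plant
"gained" ones, keeping surviving values bit-exact; modifications that
break positive definiteness raise an error.

Defaults (units): regional mean MTR uniform in 30–60%, between-subject SD
1.5%, age uniform 55–80 years, gender 0/1 balanced, ~90% of planted edges
positive (matching the preponderance of positive associations in real
structural covariance), two groups of 15 subjects, 100 true edges.
Hemispheric asymmetry is planted as a mean offset δ on the left member of
a homotopic pair, giving a population laterality score δ/(2μ + δ).
Covariate effects add per-ROI linear terms in centered age and gender.

What the generator does *not* emulate: voxel-level noise, segmentation and
partial-volume effects, and — importantly — the strong global covariance of
real structural data (real inter-regional MTR correlations are large
because overall myelination varies between people, which drives shrinkage
intensities far below 1 and makes many edges detectable even at n = 15).
Consequently, at the default study scale (n = 15/group) the generator's
cohorts are in a regime where the honest estimator calls few or no edges:
λ* ≈ 0.8–1, all lfdr ≈ 1, called-edge sets are empty, the 0.2 < lfdr < 0.5
band collapses to density ≈ 0 and integrated metrics are 0. The pipeline
runs end-to-end and its null calibration holds, but passing tests at that
scale demonstrate contracts and calibration, not detection power. The
machinery's detection behavior is validated at n = 60–500, where ~100
edges are called with positive predictive value 0.8–1.0, differential
edges are recovered in ≥90% of replicates, and planted hemispheric
asymmetries are flagged.

## Numerical choices and degenerate inputs

SPD margin 0.1 on every constructed precision; covariance inversion guarded
by an eigenvalue check (unreachable for λ > 0). Mixture fitting requires
≥100 values and errors on constant input; identical networks short-circuit
the contrast with no differential edges. Constant laterality scores are
flagged degenerate and reported non-significant (p = 1). K-means ranking
requires three distinct values; callers may fall back to uniform labels
(the pipeline labels everything "weak" in that case). Binarization
tie-breaks are deterministic, and all stochastic stages take explicit
seeds, so identical configuration reproduces byte-identical reports.

## Known limitations

The hemisphere contrast ignores the dependence between hemispheres'
estimates (documented above). η₀ estimation is biased toward 1 when
alternatives are undetectable and slightly below the nominal null
proportion when estimation leakage makes indirect within-component pairs
non-null in the estimates. The greedy Q-maximizer is a local optimizer;
it reaches the known optimum on small benchmarks but carries no global
guarantee. The laterality permutation test needs n_perm ≈ 10 000 for
BH-corrected decisions at 39 pairs; with heavy multiplicity and n =
15/group, even the exact t-test tops out near 70% power for a
1.5-pooled-SD shift, so corrected detection of single-pair effects at
that scale is intrinsically unreliable.
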