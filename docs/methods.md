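# Methods

This note records the models, conventions and numerical choices behind
`modediff`, the way we would want them written down before trusting any
number the package prints.

## Data model and units

An ensemble is a `frames × atoms × 3` array of coordinates in Ångström
over a fixed topology; times are in nanoseconds. Internal atom indexing
is 0-based; user-facing residue numbers are the 1-based PDB numbers, so
selections can be written the way the structural literature cites them
(`resid 771-777`, `name CA and not resid 1-7,231-240`). File I/O goes
through MDAnalysis (PDB, multi-model PDB, DCD, XTC; XTC's nm are
converted to Å on read). Alternate locations keep the highest-occupancy
copy; insertion codes are rejected with an explicit error rather than
silently renumbered. Selections are resolved by the MDAnalysis selection
grammar after a light rewrite of comma-separated hyphen ranges; an empty
selection is a warning, not an error, because "nothing matched" is a
legitimate analysis outcome the caller must see.

## Superposition, RMSD, RMSF

Superposition is least-squares rigid-body fitting (Kabsch via SVD) with
the proper-rotation determinant correction, so mirror images are never
produced. Fitting to the mean uses two fit–recompute-mean passes (fit to
the raw coordinate mean, then to the mean of the fitted frames), the
standard essential-dynamics convention. Fewer than 3 fit atoms, or
collinear fit atoms, are a geometry error: the rotation would be
underdetermined. No mass weighting is applied anywhere — all shipped
analyses are Cα-based, where uniform masses make it a no-op.

RMSF is computed per replica about that replica's own mean structure
after mean-fitting (a deliberate choice where conventions differ; a
global-mean reference would mix inter-replica drift into the
fluctuations), and residue profiles pool a residue's atoms as the root
mean square fluctuation. Cross-replica dispersion is the sample SD.

## Gromos clustering

The Daura neighbor-counting algorithm on the matrix of *pairwise-fitted*
RMSDs (each pair superposed independently, not against a shared
reference): repeatedly declare the frame with the most neighbors within
the cutoff a cluster centroid, assign and remove its neighborhood,
repeat. Ties break to the lowest frame index; final cluster ids are
renumbered by population (cluster 1 largest) with the greedy extraction
order retained on the result. More than 10⁴ frames are refused without
an explicit override because the matrix is O(n²).

## PCA, projections, RMSIP

PCA is the eigendecomposition of the covariance of the selected atoms'
coordinates (n−1 normalization), computed by economy SVD; the number of
modes is min(3N, frames−1). Eigenvector signs are fixed so each column's
largest-magnitude component is positive — linear-algebra backends are
free to flip signs, outputs should not be. An input whose rigid-body
drift would still absorb >10% of the apparent fluctuation triggers a
warning (never an error; synthetic ensembles are generated directly in a
superposed frame).

The 2D projection overlap of two trajectories on a shared leading-mode
pair is the histogram intersection Σ min(pᵢ, qᵢ) on a common grid
(default 25×25); it is 1 for identical samples and approaches 1 from
below for finite samples of the same distribution, so "same phase space"
reads as values near the self-overlap, not exactly 1.

RMSIP over the leading d modes (default d = 10) is reported raw, and —
because published "normalized" overlaps rarely state their normalization
— optionally divided by an explicit, tagged baseline: the mean
split-half self-consistency RMSIP of the first trajectory. Both numbers
appear in the output with the scheme recorded.

## Functional mode analysis

The functional quantities shipped are a hinge Cα–Cα distance between two
residues flanking a catalytic cleft (defaults 781/922, the convention
for class-I PI3K kinase domains) and the active-site Cα RMSD *without
refitting on the site* — the global alignment is retained deliberately,
which is what makes the quantity three-dimensional and nonlinear.

Linear FMA maximizes Pearson R between ⟨δx, α⟩ and f over
α ∈ span(v₁…vₖ); this is exactly OLS of f on the first k mode
projections, so the fit is closed-form and the brute-force sphere search
in the tests is an independent check, not a tautology. Cross-validation
is a *contiguous* time split (model prefix, held-out suffix; default
fractions 0.7 for the hinge analysis and 0.8 for the twist analysis,
mirroring 35/50 and 40/10 ns conventions) — a random split would leak
autocorrelated frames across segments and flatter R_c.

Mutual information uses the Kraskov–Stögbauer–Grassberger kNN estimator
(algorithm 1, k = 3, Chebyshev joint metric, marginal counts by sorted
search; deterministic tiny jitter only if exact ties occur), which is
invariant under monotone maps and near-unbiased for continuous data; a
histogram plug-in estimator is available for quick looks. Estimates can
be slightly negative on independent data (noise floor ~0.02 nats); they
are not clipped.

MI-FMA maximizes the estimated MI of the projection with f over unit
vectors in the k-mode span with Powell's derivative-free method,
warm-started from the linear solution plus 8 seed-controlled random
restarts (the objective is non-convex and the kNN estimate has no
gradients). For affordability the optimizer evaluates MI on at most
1500 evenly strided model-segment frames; reported MI uses the full
segment. Because MI fixes no readout scale, Pearson R_m/R_c for MI
models are computed through a monotone readout: isotonic regression of f
on the projection over the model segment, orientation chosen by the rank
correlation. The basis-size cap (default 20) and the selection rule —
minimize |R_m − R_c| over the scan subject to R_c ≥ 0.5, ties to the
smallest k — guard against over-fitting; the floor exists because a
vanishing gap between two useless correlations should never win.

## Contact statistics

Hydrogen bond: donor–acceptor heavy distance ≤ 3.5 Å **and** donor–H–
acceptor angle ≥ 150°, the common defaults of MD analysis toolchains
(published tables rarely state their criteria; these are configurable).
Donors are N/O with a covalently attached hydrogen (≤ 1.25 Å in frame
0); intra-residue pairs are excluded. With hydrogen-free topologies the
detector refuses and points at the distance-only `heavy_only` mode,
which flags its output. Histidine imidazole nitrogens are mapped
π(δ) → ND1, τ(ε) → NE2 and annotated in the output. Salt bridge: minimum
side-chain N–O distance ≤ 4.0 Å between Arg/Lys/His and Asp/Glu groups.
Stacking is tracked as mass-weighted COM distances with a 5.5 Å
threshold. A 5% frequency floor bounds table sizes (configurable to 0).

Occupancy errors: the presence series is autocorrelated, so the SE uses
n_eff = n/(1+2τ) with τ the integrated autocorrelation time from the
FFT ACF summed under a Sokal adaptive window (c = 6); a series is
"converged" when its ACF decays below 1/e within the first half of the
trajectory. Across replicas the dispersion is reported as the SD of the
per-replica frequencies (SE also emitted). Condition comparison flags a
contact `lost`/`gained` when one condition's mean crosses 40% and the
other falls below 10%, `shifted` when |Δmean| > 25 points, else
`unchanged`; all three thresholds are configuration.

## SASA

Shrake–Rupley with Bondi van der Waals radii, probe 1.4 Å, 960
quasi-uniform sphere points from a Fibonacci spiral (for which an
isolated atom is exact by construction and the acceptance check measures
the discretization of *occluded* geometry). Occlusion always uses every
atom; a residue selection only restricts what is reported. Unknown
elements raise an error naming the atom rather than guessing a radius.

## Synthetic ground truth

The generator emulates the statistical skeleton of a two-condition ×
five-replica comparative MD study:

* **Gaussian ensembles**: frames = mean + Σᵢ √λᵢ zᵢ vᵢ, zᵢ ~ N(0,1),
  with a prescribed descending spectrum (Å²) and an orthonormal mode
  matrix (given, or drawn from the spec seed). The default mean
  structure is a helical Cα curve with exactly 3.8 Å consecutive
  spacing — a straight chain would be collinear and rigid-body
  superposition about its axis underdetermined, which the package's own
  geometry guard correctly rejects.
* **Planted functional quantities**: f(t) = link(⟨δx(t), w⟩) + ε,
  ε ~ N(0, σ²), with link ∈ {identity, cubic}; the cubic default is the
  monotone nonlinearity that linear FMA under-fits but MI-FMA should
  resolve. The attenuation identity R = 1/√(1+σ²/Var(signal)) converts a
  target correlation into a noise level.
* **Planted contacts**: a donor–H–acceptor fragment whose bonded state
  follows a two-state Markov chain with switch probabilities q·p and
  q·(1−p), giving stationary occupancy exactly p and ACF (1−q)^lag
  (hence τ = (1−q)/q); bonded geometry satisfies the default detector,
  broken geometry violates the distance criterion by ≥ 1 Å.
* **Condition sets**: replicas share a condition's modes and differ only
  by the frame seed, derived as seed + condition_index·replicas +
  replica_index (the per-condition offset keeps the two conditions'
  replica streams disjoint).

What the generator does *not* emulate — anharmonicity, slow
conformational exchange between basins, solvent coupling, correlated
contact networks — bounds what green tests mean: they certify the
estimators and algorithms against known truth, not the physics of any
real protein.

## Problem sizes and determinism

All generators and fits are pure functions of (spec, seed). The shipped
fixture is 2 conditions × 5 replicas × 240 frames of a 40-residue chain
plus 600-frame contact trajectories, chosen so the full pipeline
(including the O(n²) clustering and per-frame SASA) completes in well
under a minute per stage on a single core; the acceptance script uses
n = 5000 frames for linear-FMA and MI closed-form checks, n = 2000 for
MI-FMA recovery, 45 frames for clustering-oracle equality and 100
planted chains of 4000 frames for coverage. The fixture's planted
contact occupancies (92→5, 5→92, 85→50, 60→60 %) sit several replicate
SDs away from every flag threshold so the expected flags are
statistically unambiguous at these sizes.

## Known limitations

* The MI optimizer is local-search with restarts; for k close to the cap
  and weak signals it can return a secondary optimum (the error path
  carries the best-so-far model).
* RMSIP normalization is a convention, not an estimate; compare only
  like-tagged values.
* Contact detection is geometric only — no energetic scoring, no
  water-mediated bridges.
* The pairwise-RMSD clustering is quadratic in frames by design; stride
  the trajectory rather than forcing the override for long runs.
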