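# modediff

Comparative analysis of protein conformational ensembles — the toolchain a
structural-bioinformatics group needs when asking *"how does a point
mutation change the dynamics of a protein?"* from sets of independent
simulation replicas: rigid-body superposition, RMSD/RMSF, Gromos
conformational clustering, Cα-covariance PCA (essential dynamics) with
convergence diagnostics, RMSIP eigenspace overlap, **functional mode
analysis** (linear and mutual-information variants) with contiguous
cross-validation, hydrogen-bond/salt-bridge/stacking statistics with
autocorrelation-aware error bars, and per-residue solvent accessible
surface areas.

Because real comparative MD datasets (hundreds of nanoseconds per replica)
are rarely shareable, the package ships a first-class synthetic-ensemble
generator whose outputs have *known ground truth* — planted covariance
spectra, planted collective modes behind a functional quantity, and
planted two-state contact dynamics — so every analysis stage can be
validated end to end without running a single force-field step.

## The core method

Given frames **x**(t) ∈ ℝ³ᴺ of superposed Cα coordinates, PCA
diagonalizes the positional covariance **C** = ⟨δ**x** δ**x**ᵀ⟩ into
eigenvectors **v**ᵢ (modes) and eigenvalues λᵢ (Å²). Two ensembles are
compared through the root mean square inner product of their leading-*d*
eigenspaces,

    RMSIP(A, B; d) = sqrt( (1/d) Σᵢ₌₁..d Σⱼ₌₁..d ⟨aᵢ, bⱼ⟩² ) ∈ [0, 1],

reported both raw and normalized by a split-half self-consistency
baseline.

Functional mode analysis (FMA) asks which *single* collective unit vector
**α** ∈ span(**v**₁…**v**ₖ) best explains a scalar functional quantity
f(t) — here a hinge-opening Cα distance or an active-site Cα RMSD:

* **linear FMA** maximizes the Pearson correlation R between the
  projection pₜ = ⟨δ**x**(t), **α**⟩ and f(t) (equivalent to least
  squares on the first k mode projections);
* **MI-FMA** maximizes a Kraskov k-nearest-neighbor estimate of the
  mutual information I(p; f), capturing monotone nonlinear couplings,
  with Pearson correlations reported through an isotonic readout.

Over-fitting is controlled by a contiguous time split into a
model-building segment (correlation R_m) and a held-out segment (R_c),
and the basis size k is chosen by minimizing |R_m − R_c| subject to a
floor on R_c.

Contact occupancies (% of frames a geometric hydrogen-bond or
salt-bridge criterion holds) carry standard errors deflated by the
integrated autocorrelation time τ (effective sample size n/(1+2τ)), and
two conditions are compared per contact as gained / lost / shifted /
unchanged with replicate SDs.

## Worked example

```python
import numpy as np
import modediff as md

# a 50-residue Gaussian ensemble with 5 planted modes, and a functional
# quantity driven by a hidden collective vector w through a cubic link
spec = md.EnsembleSpec(50, [10, 6, 4, 2, 1], seed=3)
ens, truth = md.generate_gaussian_ensemble(spec, 2000, seed=0)
w = np.random.default_rng(200).standard_normal(5); w /= np.linalg.norm(w)
f, w_cart = md.plant_functional_quantity(
    ens, truth, md.PlantSpec(w, link="cubic", sigma=0.5), seed=0)

dec  = md.pca(ens)
proj = md.project(ens, dec, 5)
lin  = md.fit_linear_fma(proj, f, split=0.8, k=5)
mi   = md.fit_mi_fma(proj, f, split=0.8, k=5, seed=0)
print(f"linear: R_c = {lin.r_c:.3f},  |cos(alpha, w)| = {abs(lin.alpha @ w_cart):.4f}")
print(f"MI-FMA: R_c = {mi.r_c:.3f},  |cos(alpha, w)| = {abs(mi.alpha @ w_cart):.4f}")
```

prints

```
linear: R_c = 0.786,  |cos(alpha, w)| = 1.0000
MI-FMA: R_c = 0.999,  |cos(alpha, w)| = 0.9999
```

— both objectives point at the planted vector (the cubic link preserves
the direction), but only the MI model's monotone readout explains the
held-out data (R_c ≈ 1 versus ≈ 0.79 for the straight-line readout),
which is exactly the situation MI-FMA exists for.

The same machinery runs from the shell on a complete synthetic
two-condition × five-replica study written through the public PDB/DCD
file interface:

```bash
modediff fixture -o demo --seed 0     # writes data + config.yaml + ground truth
modediff run -c demo/config.yaml      # full pipeline -> demo/results/
modediff report demo/results/report.json
```

The report lists per-stage outputs (RMSD/RMSF/SASA profiles, cluster
populations, projection overlaps, raw and normalized RMSIP, FMA scans and
models, hydrogen-bond tables and the condition-difference table) with
checksums, timings and warnings.

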