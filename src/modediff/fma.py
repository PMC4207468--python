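"""Functional Mode Analysis: the collective motion behind a scalar observable.

Given a PCA basis of an ensemble and a per-frame functional quantity f(t)
(e.g. a hinge-opening Cα distance, or the active-site Cα RMSD), FMA fits a
single unit collective vector α in the span of the leading k eigenvectors
whose per-frame projection best explains f:

* linear FMA maximizes the Pearson correlation R between the projection
  and f — equivalent to least-squares regression of f on the first k mode
  projections over the model-building segment;
* MI-FMA maximizes a k-nearest-neighbor (Kraskov) estimate of the mutual
  information between the projection and f, capturing monotone nonlinear
  relationships a linear model under-fits. Pearson correlations for MI
  models are reported through a monotone (isotonic) readout fitted on the
  model segment.

Cross-validation uses a contiguous time split (model-building prefix,
held-out suffix), mirroring the field's convention of building on an early
trajectory window and validating on the remainder. Basis size is chosen by
minimizing |R_m - R_c| over a scan in k, subject to a floor on R_c, to
avoid over-fitting as the basis grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.special import digamma
from scipy.stats import pearsonr, spearmanr

from .core import Ensemble, FunctionalSeries, InputError, ModeDiffError, SelectionMask
from .modes import ModeDecomposition, ProjectionSeries
from .synthetic import ca_chain_topology

__all__ = ["FMAModel", "BasisScan", "OptimizationError",
           "hinge_distance", "active_site_rmsd",
           "fit_linear_fma", "mutual_information", "fit_mi_fma",
           "scan_basis_sizes", "select_basis_size", "render_mode"]


class OptimizationError(ModeDiffError):
    """MI optimizer failed to converge; carries the best model found so far."""

    def __init__(self, message: str, model: "FMAModel | None" = None):
        super().__init__(message)
        self.model = model


# ------------------------------------------------------- functional quantities

def hinge_distance(ensemble: Ensemble, residue_a: int = 781,
                   residue_b: int = 922) -> FunctionalSeries:
    """Per-frame Cα–Cα distance (Å) between two residues.

    The defaults are the hinge residues flanking a kinase catalytic cleft,
    whose separation tracks active-site opening/closing.
    """
    try:
        ia = ensemble.topology.atom_index(residue_a, "CA")
        ib = ensemble.topology.atom_index(residue_b, "CA")
    except InputError as exc:
        raise InputError(f"hinge distance needs Cα atoms: {exc}") from exc
    d = np.linalg.norm(ensemble.coordinates[:, ia] - ensemble.coordinates[:, ib], axis=1)
    return FunctionalSeries(d, units="Å", name=f"d_CA({residue_a},{residue_b})",
                            frame_times=ensemble.frame_times)


def active_site_rmsd(ensemble: Ensemble, site: SelectionMask,
                     reference: int | str = "mean") -> FunctionalSeries:
    """Per-frame RMSD (Å) of site atoms to a reference, WITHOUT refitting.

    The ensemble must already be globally superposed; the global alignment
    is retained so the measure mixes internal deformation with site
    re-orientation relative to the rest of the structure (deliberately —
    that is what makes it a nonlinear, 3D functional quantity).
    """
    site.validate(ensemble.topology)
    if len(site) == 0:
        raise InputError("active-site selection is empty")
    X = ensemble.coordinates[:, site.indices]
    if isinstance(reference, str):
        if reference != "mean":
            raise InputError(f"unknown reference {reference!r}")
        ref = X.mean(axis=0)
    else:
        ref = X[int(reference)]
    vals = np.sqrt(np.mean(np.sum((X - ref) ** 2, axis=2), axis=1))
    return FunctionalSeries(vals, units="Å", name="rmsd_site",
                            frame_times=ensemble.frame_times)


# ------------------------------------------------------------------ the model

@dataclass
class FMAModel:
    """A fitted functional mode.

    ``alpha`` is the unit collective vector in Cartesian (3N) space;
    ``coefficients`` are its coordinates over the first k basis
    eigenvectors. The linear readout is f ≈ intercept + scale * s with
    s the projection onto alpha; MI models instead carry a monotone
    (isotonic) readout as breakpoint arrays.
    """

    alpha: np.ndarray
    coefficients: np.ndarray
    k: int
    objective: str                  # "pearson" | "mutual_information"
    r_m: float
    r_c: float
    intercept: float = 0.0
    scale: float = 1.0
    mi_nats: float | None = None
    split: float = 0.7
    n_model: int = 0
    readout_x: np.ndarray | None = None   # isotonic breakpoints (MI models)
    readout_y: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64).ravel()
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64).ravel()
        nrm = np.linalg.norm(self.alpha)
        if abs(nrm - 1.0) > 1e-8:
            raise InputError("alpha must have unit norm")

    def predict(self, proj_values: np.ndarray) -> np.ndarray:
        """Model readout from projection values (frames x >=k)."""
        s = np.atleast_2d(proj_values)[:, : self.k] @ self.coefficients
        if self.readout_x is not None:
            return np.interp(s, self.readout_x, self.readout_y)
        return self.intercept + self.scale * s


@dataclass
class BasisScan:
    """R_m/R_c as a function of basis size k, plus the chosen k and rule."""

    records: list[dict]
    chosen_k: int | None = None
    rule: str = ""

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.records)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) < 1e-14 or np.std(b) < 1e-14:
        return 0.0
    return float(pearsonr(a, b)[0])


def _split_segments(n: int, split: float, k: int) -> int:
    if not 0.0 < split < 1.0:
        raise InputError(f"split fraction must be in (0, 1), got {split}")
    n_model = int(round(split * n))
    if n_model <= k + 1:
        raise InputError(f"model segment ({n_model} frames) too short for k={k}")
    if n_model >= n:
        raise InputError("cross-validation segment is empty; lower the split")
    return n_model


def fit_linear_fma(proj: ProjectionSeries, f: FunctionalSeries,
                   split: float = 0.7, k: int | None = None) -> FMAModel:
    """Maximize Pearson R between a collective projection and f.

    Equivalent to ordinary least squares of f on the first k mode
    projections over the contiguous model segment; R_m is evaluated there
    and R_c on the held-out remainder.
    """
    if len(f) != proj.n_frames:
        raise InputError(f"series length {len(f)} != projection frames {proj.n_frames}")
    k = proj.k if k is None else int(k)
    if k < 1 or k > proj.k:
        raise InputError(f"k={k} outside [1, {proj.k}]")
    y = f.values
    if np.std(y) < 1e-14:
        raise InputError("functional quantity is constant; correlation undefined")
    n_model = _split_segments(len(y), split, k)
    X = proj.values[:, :k]
    Xm, ym = X[:n_model], y[:n_model]
    A = np.column_stack([np.ones(n_model), Xm])
    sol, *_ = np.linalg.lstsq(A, ym, rcond=None)
    intercept, beta = float(sol[0]), sol[1:]
    bnorm = np.linalg.norm(beta)
    if bnorm < 1e-14:
        raise InputError("degenerate fit: zero collective vector")
    coeffs = beta / bnorm
    alpha = proj.source.eigenvectors[:, :k] @ coeffs
    alpha /= np.linalg.norm(alpha)
    pred = intercept + X @ beta
    r_m = _pearson(pred[:n_model], ym)
    r_c = _pearson(pred[n_model:], y[n_model:])
    return FMAModel(alpha=alpha, coefficients=coeffs, k=k, objective="pearson",
                    r_m=r_m, r_c=r_c, intercept=intercept, scale=bnorm,
                    split=split, n_model=n_model,
                    metadata={"basis": "pca", "cv": "contiguous"})


# --------------------------------------------------------- mutual information

def _ksg_mi(x: np.ndarray, y: np.ndarray, k_nn: int) -> float:
    """Kraskov–Stögbauer–Grassberger estimator (algorithm 1), in nats."""
    n = x.size
    xs = (x - x.mean()) / (x.std() + 1e-300)
    ys = (y - y.mean()) / (y.std() + 1e-300)
    pts = np.column_stack([xs, ys])
    tree = cKDTree(pts)
    eps = tree.query(pts, k=k_nn + 1, p=np.inf)[0][:, -1]
    if np.any(eps <= 0):
        # duplicate points break the strict-inequality counts; deterministic jitter
        rng = np.random.default_rng(1234)
        xs = xs + rng.normal(0, 1e-10, n)
        ys = ys + rng.normal(0, 1e-10, n)
        pts = np.column_stack([xs, ys])
        tree = cKDTree(pts)
        eps = tree.query(pts, k=k_nn + 1, p=np.inf)[0][:, -1]
    xo = np.sort(xs)
    yo = np.sort(ys)
    nx = (np.searchsorted(xo, xs + eps, side="left")
          - np.searchsorted(xo, xs - eps, side="right"))
    ny = (np.searchsorted(yo, ys + eps, side="left")
          - np.searchsorted(yo, ys - eps, side="right"))
    # counts include the point itself; strict neighbors = count - 1, psi wants +1
    return float(digamma(k_nn) + digamma(n)
                 - np.mean(digamma(nx) + digamma(ny)))


def _histogram_mi(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    h, _, _ = np.histogram2d(x, y, bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))


def mutual_information(x, y, estimator: str = "knn", k_nn: int = 3,
                       bins: int = 32) -> float:
    """Mutual information between two scalar series, in nats.

    The default is the Kraskov k-nearest-neighbor estimator (k_nn=3),
    which is asymptotically unbiased for continuous data and invariant
    under monotone reparametrization; a histogram plug-in estimator is
    available for quick looks. Constant inputs give 0 with a warning.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise InputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 50:
        raise InputError("mutual information needs at least 50 samples")
    if np.std(x) < 1e-14 or np.std(y) < 1e-14:
        warnings.warn("constant input to mutual_information; returning 0", stacklevel=2)
        return 0.0
    if estimator == "knn":
        return _ksg_mi(x, y, k_nn)
    if estimator == "histogram":
        return _histogram_mi(x, y, bins)
    raise InputError(f"unknown estimator {estimator!r} (knn or histogram)")


# ----------------------------------------------------------------- MI-FMA fit

def _isotonic_readout(s: np.ndarray, y: np.ndarray):
    """Monotone readout s -> y via isotonic regression; direction from the
    sign of the rank correlation. Returns (x_grid, y_grid, sign)."""
    from sklearn.isotonic import IsotonicRegression
    rho = spearmanr(s, y)[0]
    increasing = bool(rho >= 0) if np.isfinite(rho) else True
    iso = IsotonicRegression(increasing=increasing, out_of_bounds="clip")
    iso.fit(s, y)
    order = np.argsort(s)
    xg = s[order]
    yg = iso.predict(xg)
    return xg, yg, (1.0 if increasing else -1.0)


def fit_mi_fma(proj: ProjectionSeries, f: FunctionalSeries, split: float = 0.8,
               k: int | None = None, seed: int = 0, k_cap: int = 20,
               n_restarts: int = 8, k_nn: int = 3,
               max_eval_points: int = 1500, maxiter: int = 200) -> FMAModel:
    """Maximize estimated MI(projection onto α, f) over the k-mode span.

    The optimizer is derivative-free (Powell) on the unit sphere,
    warm-started from the linear solution plus seed-controlled random
    restarts. To keep the objective affordable the MI is evaluated on at
    most ``max_eval_points`` evenly strided model-segment frames; the
    reported MI uses the full model segment. R_m/R_c are Pearson
    correlations of the isotonic monotone readout on each segment.
    """
    if len(f) != proj.n_frames:
        raise InputError(f"series length {len(f)} != projection frames {proj.n_frames}")
    k = min(proj.k, k_cap - 1) if k is None else int(k)
    if k >= k_cap:
        raise InputError(f"k={k} reaches the over-fitting cap ({k_cap})")
    if k < 1 or k > proj.k:
        raise InputError(f"k={k} outside [1, {proj.k}]")
    y = f.values
    if np.std(y) < 1e-14:
        raise InputError("functional quantity is constant")
    n_model = _split_segments(len(y), split, k)
    X = proj.values[:, :k]
    Xm, ym = X[:n_model], y[:n_model]
    # column scales for a well-conditioned search space
    col_scale = Xm.std(axis=0)
    col_scale[col_scale < 1e-12] = 1.0

    stride = max(1, int(np.ceil(n_model / max_eval_points)))
    Xe, ye = Xm[::stride], ym[::stride]

    def objective(theta: np.ndarray) -> float:
        beta = theta * col_scale
        nrm = np.linalg.norm(beta)
        if nrm < 1e-12:
            return 0.0
        s = Xe @ (beta / nrm)
        return -_ksg_mi(s, ye, k_nn)

    linear = fit_linear_fma(proj, f, split=split, k=k)
    starts = [linear.coefficients / col_scale]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        v = rng.standard_normal(k)
        starts.append(v / np.linalg.norm(v))

    best_theta, best_val, any_success = None, np.inf, False
    for theta0 in starts:
        res = minimize(objective, theta0, method="Powell",
                       options={"maxiter": maxiter, "xtol": 1e-4, "ftol": 1e-4})
        any_success = any_success or bool(res.success)
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x

    beta = best_theta * col_scale
    coeffs = beta / np.linalg.norm(beta)
    s_all = X @ coeffs
    # orient so the monotone readout is increasing
    if spearmanr(s_all[:n_model], ym)[0] < 0:
        coeffs = -coeffs
        s_all = -s_all
    alpha = proj.source.eigenvectors[:, :k] @ coeffs
    alpha /= np.linalg.norm(alpha)
    xg, yg, _ = _isotonic_readout(s_all[:n_model], ym)
    pred = np.interp(s_all, xg, yg)
    r_m = _pearson(pred[:n_model], ym)
    r_c = _pearson(pred[n_model:], y[n_model:])
    mi_full = _ksg_mi(s_all[:n_model], ym, k_nn)
    model = FMAModel(alpha=alpha, coefficients=coeffs, k=k,
                     objective="mutual_information", r_m=r_m, r_c=r_c,
                     mi_nats=max(mi_full, 0.0), split=split, n_model=n_model,
                     readout_x=xg, readout_y=yg,
                     metadata={"estimator": "ksg", "k_nn": k_nn,
                               "n_restarts": n_restarts, "seed": seed,
                               "readout": "isotonic", "cv": "contiguous"})
    if not any_success and best_val >= 0.0:
        raise OptimizationError(
            "MI optimization did not converge in any restart", model=model)
    return model


# ------------------------------------------------------------ basis selection

def scan_basis_sizes(proj: ProjectionSeries, f: FunctionalSeries, ks,
                     objective: str = "pearson", split: float | None = None,
                     **fit_kwargs) -> BasisScan:
    """Fit models over a strictly increasing list of basis sizes k."""
    ks = [int(k) for k in ks]
    if any(b <= a for a, b in zip(ks, ks[1:])):
        raise InputError("basis sizes must be strictly increasing")
    records = []
    for k in ks:
        if objective == "pearson":
            m = fit_linear_fma(proj, f, split=0.7 if split is None else split, k=k)
        elif objective == "mutual_information":
            m = fit_mi_fma(proj, f, split=0.8 if split is None else split,
                           k=k, **fit_kwargs)
        else:
            raise InputError(f"unknown objective {objective!r}")
        records.append({"k": k, "r_m": m.r_m, "r_c": m.r_c,
                        "gap": abs(m.r_m - m.r_c)})
    return BasisScan(records=records)


def select_basis_size(scan, r_c_threshold: float = 0.5) -> int:
    """Choose k minimizing |R_m - R_c| among sizes with R_c >= threshold.

    Ties break to the smallest k. Records the rule on the scan when one
    is passed; raises when no basis size clears the floor.
    """
    records = scan.records if isinstance(scan, BasisScan) else list(scan)
    if len(records) < 2:
        raise InputError("basis-size selection needs at least 2 scan points")
    eligible = [r for r in records if r["r_c"] >= r_c_threshold]
    if not eligible:
        raise InputError(
            f"no basis size reaches R_c >= {r_c_threshold}; inspect the scan "
            "before trusting any model")
    best = min(eligible, key=lambda r: (abs(r["r_m"] - r["r_c"]), r["k"]))
    chosen = int(best["k"])
    if isinstance(scan, BasisScan):
        scan.chosen_k = chosen
        scan.rule = f"min|R_m-R_c| s.t. R_c>={r_c_threshold}; tie->smallest k"
    return chosen


# ---------------------------------------------------------------- visualization

def render_mode(model: FMAModel, dec: ModeDecomposition, amplitudes,
                topology=None) -> Ensemble:
    """Frames interpolated along the functional mode: mean + a * alpha.

    For visualization of the collective motion; projecting the rendered
    frames back onto alpha recovers the amplitudes exactly.
    """
    amplitudes = np.asarray(amplitudes, dtype=np.float64).ravel()
    if not np.all(np.isfinite(amplitudes)):
        raise InputError("amplitudes must be finite")
    frames = dec.mean[None, :] + amplitudes[:, None] * model.alpha[None, :]
    n_atoms = dec.n_atoms
    topo = topology if topology is not None else ca_chain_topology(n_atoms)
    return Ensemble(topo, frames.reshape(len(amplitudes), n_atoms, 3),
                    label="functional-mode")
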