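"""Essential dynamics: covariance eigendecomposition of Cα coordinates,
mode projections, 2D projection overlap, and RMSIP subspace comparison.

A :class:`ModeDecomposition` holds the mean structure and the orthonormal
eigenvectors/eigenvalues of the positional covariance matrix of a set of
selected atoms after rigid-body superposition. The root mean square inner
product (RMSIP) between two decompositions A, B over the leading *d* modes,

    RMSIP = sqrt( (1/d) * sum_{i<=d} sum_{j<=d} <a_i, b_j>^2 ),

is 1 for identical subspaces and 0 for orthogonal ones, and is invariant
to any rotation of the eigenvectors within each subspace.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Ensemble, InputError, SelectionMask

__all__ = ["ModeDecomposition", "ProjectionSeries", "SubspaceOverlap",
           "pca", "project", "projection_overlap", "rmsip", "split_half_rmsip"]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector orientation: largest-|component| positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


@dataclass
class ModeDecomposition:
    """Mean structure plus eigenvectors/eigenvalues of a Cα covariance matrix."""

    mean: np.ndarray          # (3N,) Å
    eigenvectors: np.ndarray  # (3N, m), orthonormal columns, descending eigenvalue
    eigenvalues: np.ndarray   # (m,) Å^2
    atom_indices: np.ndarray | None = None  # indices into the source topology
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64).ravel()
        if self.mean.size % 3 != 0:
            raise InputError("mean structure length must be a multiple of 3")
        if self.eigenvectors.shape != (self.mean.size, self.eigenvalues.size):
            raise InputError(
                f"eigenvector matrix {self.eigenvectors.shape} inconsistent with "
                f"mean ({self.mean.size}) and eigenvalues ({self.eigenvalues.size})")
        if np.any(self.eigenvalues < -1e-10):
            raise InputError("negative eigenvalues")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise InputError("eigenvalues must be in descending order")
        m = self.n_modes
        if m:
            gram = self.eigenvectors.T @ self.eigenvectors
            if not np.allclose(gram, np.eye(m), atol=1e-8):
                raise InputError("eigenvectors are not orthonormal (|V'V - I| > 1e-8)")
        if self.atom_indices is not None:
            self.atom_indices = np.asarray(self.atom_indices, dtype=np.int64)

    @property
    def n_modes(self) -> int:
        return int(self.eigenvalues.size)

    @property
    def n_atoms(self) -> int:
        return self.mean.size // 3

    def save(self, prefix) -> None:
        """Persist as <prefix>.json (metadata) + <prefix>.npz (matrices)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        meta = {"n_atoms": self.n_atoms, "n_modes": self.n_modes,
                "provenance": self.provenance,
                "eigenvalues_A2": self.eigenvalues.tolist()}
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        np.savez(prefix.with_suffix(".npz"), mean=self.mean,
                 eigenvectors=self.eigenvectors, eigenvalues=self.eigenvalues,
                 atom_indices=(self.atom_indices if self.atom_indices is not None
                               else np.array([], dtype=np.int64)))

    @classmethod
    def load(cls, prefix) -> "ModeDecomposition":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        arrs = np.load(prefix.with_suffix(".npz"))
        idx = arrs["atom_indices"]
        return cls(arrs["mean"], arrs["eigenvectors"], arrs["eigenvalues"],
                   atom_indices=idx if idx.size else None,
                   provenance=meta.get("provenance", ""))


@dataclass
class ProjectionSeries:
    """frames x k projections (Å) of an ensemble onto leading eigenvectors."""

    values: np.ndarray
    source: ModeDecomposition
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class SubspaceOverlap:
    """RMSIP between two eigenvector subspaces of size d."""

    d: int
    value: float
    normalized: float | None = None
    scheme: str | None = None


def _selected_flat(ensemble: Ensemble, mask: SelectionMask | None) -> np.ndarray:
    if mask is None:
        X = ensemble.coordinates
    else:
        mask.validate(ensemble.topology)
        X = ensemble.coordinates[:, mask.indices, :]
    return X.reshape(ensemble.n_frames, -1)


def _drift_warning(X: np.ndarray) -> None:
    """Warn when rigid-body fitting would still remove a sizeable variance share."""
    from .analysis import _kabsch_rmsd  # local import to avoid a cycle
    n = X.shape[0]
    if n < 4:
        return
    coords = X.reshape(n, -1, 3)
    mean = coords.mean(axis=0)
    sample = np.linspace(0, n - 1, min(20, n)).astype(int)
    no_fit = np.sqrt(np.mean((coords[sample] - mean) ** 2, axis=(1, 2)))
    fit = np.array([_kabsch_rmsd(mean, coords[i]) for i in sample])
    denom = float(np.mean(no_fit))
    if denom > 1e-12 and (denom - float(np.mean(fit))) / denom > 0.10:
        warnings.warn("ensemble appears unsuperposed: rigid-body fitting would "
                      "remove >10% of the apparent fluctuation", stacklevel=3)


def pca(ensemble: Ensemble, mask: SelectionMask | None = None,
        check_superposition: bool = True) -> ModeDecomposition:
    """Eigendecomposition of the positional covariance of the selected atoms.

    The ensemble is expected to be superposed already; residual rigid-body
    drift triggers a warning (never an error). The number of modes returned
    is min(3N, frames - 1); the covariance uses the n-1 normalization.
    """
    if ensemble.n_frames < 2:
        raise InputError("PCA needs at least two frames")
    X = _selected_flat(ensemble, mask)
    if check_superposition:
        _drift_warning(X)
    mean = X.mean(axis=0)
    Xc = X - mean
    n = X.shape[0]
    # economy SVD: eigenvalues = s^2/(n-1), eigenvectors = right singular vectors
    _, s, Vt = np.linalg.svd(Xc / np.sqrt(n - 1), full_matrices=False)
    m = min(X.shape[1], n - 1)
    eigenvalues = (s ** 2)[:m]
    eigenvectors = _fix_signs(Vt.T[:, :m])
    return ModeDecomposition(
        mean, eigenvectors, eigenvalues,
        atom_indices=None if mask is None else mask.indices.copy(),
        provenance=(mask.provenance if mask is not None else "all") + f"|{ensemble.label}")


def project(ensemble: Ensemble, dec: ModeDecomposition, k: int) -> ProjectionSeries:
    """Project centered coordinates onto the first k eigenvectors."""
    if k < 0 or k > dec.n_modes:
        raise InputError(f"k={k} outside [0, {dec.n_modes}]")
    if dec.atom_indices is not None and ensemble.n_atoms > dec.n_atoms:
        if dec.atom_indices.max() >= ensemble.n_atoms:
            raise InputError("decomposition atom indices out of bounds for ensemble")
        X = ensemble.coordinates[:, dec.atom_indices, :].reshape(ensemble.n_frames, -1)
    elif ensemble.n_atoms == dec.n_atoms:
        X = ensemble.coordinates.reshape(ensemble.n_frames, -1)
    else:
        raise InputError(
            f"ensemble has {ensemble.n_atoms} atoms but decomposition covers "
            f"{dec.n_atoms}; masks do not match")
    values = (X - dec.mean) @ dec.eigenvectors[:, :k]
    return ProjectionSeries(values.reshape(ensemble.n_frames, k), dec,
                            frame_times=ensemble.frame_times)


def projection_overlap(a: ProjectionSeries, b: ProjectionSeries, bins: int = 25) -> float:
    """Histogram-intersection overlap of two 2D projections on a shared grid.

    Both series must be projections onto the *same* decomposition; the
    overlap is sum(min(p_i, q_i)) over shared bins, in [0, 1].
    """
    if a.source is not b.source and not (
            a.source.eigenvectors.shape == b.source.eigenvectors.shape
            and np.array_equal(a.source.eigenvectors, b.source.eigenvectors)):
        raise InputError("projections come from different decompositions")
    if a.k < 2 or b.k < 2:
        raise InputError("projection overlap needs k >= 2 columns")
    pa, pb = a.values[:, :2], b.values[:, :2]
    lo = np.minimum(pa.min(axis=0), pb.min(axis=0))
    hi = np.maximum(pa.max(axis=0), pb.max(axis=0))
    span = np.where(hi - lo < 1e-12, 1e-12, hi - lo)
    edges = [np.linspace(lo[i] - 1e-9 * span[i], hi[i] + 1e-9 * span[i], bins + 1)
             for i in (0, 1)]
    ha, _, _ = np.histogram2d(pa[:, 0], pa[:, 1], bins=edges)
    hb, _, _ = np.histogram2d(pb[:, 0], pb[:, 1], bins=edges)
    ha /= ha.sum()
    hb /= hb.sum()
    return float(np.minimum(ha, hb).sum())


def rmsip(a: ModeDecomposition, b: ModeDecomposition, d: int = 10,
          baseline: float | None = None) -> SubspaceOverlap:
    """Root mean square inner product of the leading-d eigenspaces.

    ``baseline`` (e.g. a split-half self-consistency RMSIP of trajectory a)
    yields a tagged normalized value alongside the raw one.
    """
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise InputError(
            f"decompositions have different dimensions: "
            f"{a.eigenvectors.shape[0]} vs {b.eigenvectors.shape[0]}")
    if d < 1 or d > min(a.n_modes, b.n_modes):
        raise InputError(f"d={d} exceeds available modes "
                         f"({a.n_modes}, {b.n_modes})")
    inner = a.eigenvectors[:, :d].T @ b.eigenvectors[:, :d]
    value = float(np.sqrt(np.sum(inner ** 2) / d))
    value = min(value, 1.0)
    if baseline is not None and baseline > 0:
        return SubspaceOverlap(d, value, normalized=value / baseline,
                               scheme="split-half-baseline")
    return SubspaceOverlap(d, value)


def split_half_rmsip(ensemble: Ensemble, mask: SelectionMask | None = None,
                     d: int = 10) -> float:
    """Self-consistency RMSIP: PCA of the two trajectory halves, then RMSIP."""
    n = ensemble.n_frames
    if n < 4:
        raise InputError("split-half RMSIP needs at least 4 frames")
    half = n // 2
    da = pca(ensemble.slice_frames(0, half), mask, check_superposition=False)
    db = pca(ensemble.slice_frames(half, n), mask, check_superposition=False)
    return rmsip(da, db, min(d, da.n_modes, db.n_modes)).value
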