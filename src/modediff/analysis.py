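"""Superposition, RMSD/RMSF, Gromos conformational clustering, and SASA.

The flexibility layer: every downstream analysis (PCA, FMA) assumes frames
have been rigid-body superposed on a fit selection first. Superposition is
least-squares (Kabsch) with a proper rotation enforced; clustering is the
Daura/Gromos greedy neighbor-counting algorithm on a pairwise-fitted RMSD
matrix; solvent accessible surface areas use the Shrake–Rupley rolling-probe
construction with Bondi van der Waals radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (BONDI_RADII, Ensemble, FunctionalSeries, GeometryError,
                   InputError, RadiusError, SelectionMask)

__all__ = ["ProfileResult", "ClusterResult", "superpose", "rmsd_series",
           "rmsf_profile", "cluster_gromos", "sasa_profile", "shrake_rupley"]


# ---------------------------------------------------------------- superposition

def _kabsch_rotation(ref_c: np.ndarray, mob_c: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing |ref - mob @ R.T| for centered coordinates."""
    H = mob_c.T @ ref_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _kabsch_rmsd(ref: np.ndarray, mob: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets under rigid superposition."""
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    ga = float(np.sum(ref_c ** 2) + np.sum(mob_c ** 2))
    s = np.linalg.svd(mob_c.T @ ref_c, compute_uv=False)
    H = mob_c.T @ ref_c
    d = np.sign(np.linalg.det(H)) if abs(np.linalg.det(H)) > 1e-300 else 1.0
    traced = s[0] + s[1] + d * s[2]
    msd = max(ga - 2.0 * traced, 0.0) / ref.shape[0]
    return float(np.sqrt(msd))


def _check_fit_atoms(ref_sel: np.ndarray) -> None:
    if ref_sel.shape[0] < 3:
        raise GeometryError("superposition needs at least 3 fit atoms")
    c = ref_sel - ref_sel.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] < 1e-8:
        raise GeometryError("fit atoms are collinear; rotation is underdetermined")


def _fit_frames_to(coords: np.ndarray, sel: np.ndarray, ref_sel: np.ndarray) -> np.ndarray:
    """Rigid-fit every frame so its sel atoms match ref_sel in the LS sense."""
    out = np.empty_like(coords)
    ref_centroid = ref_sel.mean(axis=0)
    ref_c = ref_sel - ref_centroid
    for f in range(coords.shape[0]):
        mob_sel = coords[f, sel]
        mob_centroid = mob_sel.mean(axis=0)
        R = _kabsch_rotation(ref_c, mob_sel - mob_centroid)
        out[f] = (coords[f] - mob_centroid) @ R.T + ref_centroid
    return out


def superpose(ensemble: Ensemble, mask: SelectionMask | None = None,
              reference: int | str = "mean") -> Ensemble:
    """Rigid-body superpose every frame onto a reference.

    ``reference`` is a frame index or ``"mean"``; the mean reference uses
    two fit–recompute-mean passes (fit to the raw coordinate mean, then to
    the mean of the fitted frames). Rotations are proper (det = +1), so
    chirality is preserved.
    """
    if mask is not None:
        mask.validate(ensemble.topology)
        sel = mask.indices
    else:
        sel = np.arange(ensemble.n_atoms)
    coords = ensemble.coordinates
    if isinstance(reference, str):
        if reference != "mean":
            raise InputError(f"reference must be a frame index or 'mean', got {reference!r}")
        ref_sel = coords[:, sel].mean(axis=0)
        _check_fit_atoms(ref_sel)
        fitted = _fit_frames_to(coords, sel, ref_sel)
        ref_sel = fitted[:, sel].mean(axis=0)
        fitted = _fit_frames_to(fitted, sel, ref_sel)
    else:
        ref_sel = coords[int(reference), sel]
        _check_fit_atoms(ref_sel)
        fitted = _fit_frames_to(coords, sel, ref_sel)
    return Ensemble(ensemble.topology, fitted, ensemble.frame_times, ensemble.label)


def _reference_coords(ensemble: Ensemble, sel: np.ndarray,
                      reference: int | str | np.ndarray) -> np.ndarray:
    if isinstance(reference, np.ndarray):
        if reference.shape != (sel.size, 3):
            raise InputError(f"reference coordinates must be ({sel.size}, 3)")
        return reference
    if isinstance(reference, str):
        if reference != "mean":
            raise InputError(f"unknown reference {reference!r}")
        return ensemble.coordinates[:, sel].mean(axis=0)
    return ensemble.coordinates[int(reference), sel]


def rmsd_series(ensemble: Ensemble, reference: int | str | np.ndarray = 0,
                mask: SelectionMask | None = None, fit: bool = True) -> FunctionalSeries:
    """Per-frame RMSD of the mask atoms to a reference, after superposition.

    With ``fit=False`` frames are compared in place (no refitting) — used
    e.g. for an active-site RMSD under a retained global alignment.
    """
    if mask is not None:
        mask.validate(ensemble.topology)
        sel = mask.indices
        if sel.size == 0:
            raise InputError("empty mask for RMSD")
    else:
        sel = np.arange(ensemble.n_atoms)
    work = ensemble
    if fit:
        work = superpose(ensemble, mask, reference if not isinstance(reference, np.ndarray)
                         else "mean")
    ref = _reference_coords(work, sel, reference)
    diffs = work.coordinates[:, sel] - ref
    vals = np.sqrt(np.mean(np.sum(diffs ** 2, axis=2), axis=1))
    return FunctionalSeries(vals, units="Å", name="rmsd",
                            frame_times=ensemble.frame_times)


# ---------------------------------------------------------------------- RMSF

@dataclass
class ProfileResult:
    """Per-residue profile (RMSF in Å, SASA in Å^2) per replica, with
    cross-replica mean and standard deviation."""

    residue_numbers: np.ndarray
    per_replica: np.ndarray     # (n_replicas, n_residues)
    mean: np.ndarray
    sd: np.ndarray
    units: str = ""
    kind: str = ""
    replica_labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = {"resid": self.residue_numbers}
        for i, row in enumerate(self.per_replica):
            label = self.replica_labels[i] if i < len(self.replica_labels) else f"rep{i+1}"
            cols[label] = row
        cols["mean"] = self.mean
        cols["sd"] = self.sd
        return pd.DataFrame(cols)


def _make_profile(residues: np.ndarray, rows: list[np.ndarray], units: str,
                  kind: str, labels: list[str]) -> ProfileResult:
    per = np.vstack(rows)
    mean = per.mean(axis=0)
    sd = per.std(axis=0, ddof=1) if per.shape[0] > 1 else np.zeros(per.shape[1])
    return ProfileResult(residues, per, mean, sd, units, kind, labels)


def rmsf_profile(ensembles, mask: SelectionMask | None = None) -> ProfileResult:
    """Per-residue RMSF per replica about that replica's mean structure.

    Each replica is mean-fitted on the mask before the fluctuations are
    computed; the per-residue value pools the residue's mask atoms as the
    root of their mean square fluctuation.
    """
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    if not ensembles:
        raise InputError("need at least one replica")
    topo0 = ensembles[0].topology
    for e in ensembles[1:]:
        if e.topology != topo0:
            raise InputError("replica topologies differ")
    sel = mask.indices if mask is not None else np.arange(topo0.n_atoms)
    key = [(str(topo0.chainids[i]), int(topo0.resids[i])) for i in sel]
    unique_res = sorted(set(key), key=lambda t: key.index(t))
    res_index = {r: i for i, r in enumerate(unique_res)}
    groups = [[] for _ in unique_res]
    for pos, r in enumerate(key):
        groups[res_index[r]].append(pos)

    rows = []
    for e in ensembles:
        fitted = superpose(e, mask, "mean")
        X = fitted.coordinates[:, sel]
        msf = np.mean(np.sum((X - X.mean(axis=0)) ** 2, axis=2), axis=0)  # per atom
        rows.append(np.array([np.sqrt(np.mean(msf[g])) for g in groups]))
    residues = np.array([r for _, r in unique_res])
    labels = [e.label or f"rep{i+1}" for i, e in enumerate(ensembles)]
    return _make_profile(residues, rows, "Å", "rmsf", labels)


# ----------------------------------------------------------- Gromos clustering

@dataclass
class ClusterResult:
    """Daura/Gromos clustering outcome; cluster ids are 1-based, 1 = largest."""

    cutoff: float
    labels: np.ndarray        # per-frame cluster id
    populations: list[int]    # frames per cluster, descending
    centroids: list[int]      # representative (centroid) frame per cluster
    extraction_order: list[int] = field(default_factory=list)  # 1-based ids, greedy order

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def pairwise_rmsd_matrix(ensemble: Ensemble, mask: SelectionMask | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise minimum (superposed) RMSDs over mask atoms."""
    sel = mask.indices if mask is not None else np.arange(ensemble.n_atoms)
    X = ensemble.coordinates[:, sel]
    n = X.shape[0]
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.sum(centered ** 2, axis=(1, 2))
    D = np.zeros((n, n))
    m = X.shape[1]
    for i in range(n):
        a = centered[i]
        for j in range(i + 1, n):
            H = centered[j].T @ a
            s = np.linalg.svd(H, compute_uv=False)
            det = np.linalg.det(H)
            traced = s[0] + s[1] + (s[2] if det >= 0 else -s[2])
            msd = max(norms[i] + norms[j] - 2.0 * traced, 0.0) / m
            D[i, j] = D[j, i] = np.sqrt(msd)
    return D


def cluster_gromos(ensemble: Ensemble, mask: SelectionMask | None = None,
                   cutoff: float = 1.0, force: bool = False) -> ClusterResult:
    """Gromos (Daura) clustering on the pairwise-superposed RMSD matrix.

    Repeatedly takes the unassigned frame with the most neighbors within
    ``cutoff`` as a cluster centroid and removes its neighborhood. Clusters
    are renumbered by population (1 = largest). Refuses more than 10^4
    frames (O(n^2) matrix) unless ``force`` is set.
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    n = ensemble.n_frames
    if n > 10_000 and not force:
        raise InputError(f"{n} frames would need an O(n^2) RMSD matrix; "
                         "pass force=True to override")
    D = pairwise_rmsd_matrix(ensemble, mask)
    within = D <= cutoff
    remaining = np.ones(n, dtype=bool)
    raw_labels = np.full(n, -1, dtype=int)
    raw_centroids: list[int] = []
    cluster = 0
    while remaining.any():
        counts = (within & remaining).sum(axis=1)
        counts[~remaining] = -1
        centroid = int(np.argmax(counts))   # tie -> lowest frame index
        members = within[centroid] & remaining
        raw_labels[members] = cluster
        raw_centroids.append(centroid)
        remaining &= ~members
        cluster += 1
    pops = np.bincount(raw_labels, minlength=cluster)
    order = np.argsort(-pops, kind="stable")
    rank = np.empty(cluster, dtype=int)
    rank[order] = np.arange(cluster)
    labels = rank[raw_labels] + 1
    populations = [int(pops[c]) for c in order]
    centroids = [raw_centroids[c] for c in order]
    extraction = [int(rank[c]) + 1 for c in range(cluster)]
    return ClusterResult(cutoff, labels, populations, centroids, extraction)


# ------------------------------------------------------------------------ SASA

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (Fibonacci spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(i * phi), r * np.sin(i * phi), z])


def _radii_for(topology, radii: dict | None) -> np.ndarray:
    table = dict(BONDI_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    out = np.empty(topology.n_atoms)
    for i, el in enumerate(topology.elements):
        key = str(el).upper()
        if key not in table:
            raise RadiusError(
                f"no van der Waals radius for element {el!r} "
                f"(atom {topology.names[i]} in residue {int(topology.resids[i])})")
        out[i] = table[key]
    return out


def shrake_rupley(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
                  n_points: int = 960) -> np.ndarray:
    """Per-atom solvent accessible surface area (Å^2) for one frame.

    Each atom's extended sphere (r + probe) is sampled at ``n_points``
    quasi-uniform points; a point is accessible when it lies outside every
    other atom's extended sphere.
    """
    pts = _sphere_points(n_points)
    n = coords.shape[0]
    ext = radii + probe
    tree = cKDTree(coords)
    areas = np.empty(n)
    max_ext = ext.max()
    for i in range(n):
        cand = tree.query_ball_point(coords[i], ext[i] + max_ext)
        cand = [j for j in cand if j != i]
        surface = coords[i] + ext[i] * pts
        if cand:
            others = coords[cand]
            reach = ext[np.asarray(cand)]
            d2 = np.sum((surface[:, None, :] - others[None, :, :]) ** 2, axis=2)
            accessible = np.all(d2 >= (reach ** 2)[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return areas


def sasa_profile(ensembles, residues: SelectionMask | None = None,
                 probe: float = 1.4, n_points: int = 960,
                 radii: dict | None = None) -> ProfileResult:
    """Time-averaged per-residue SASA per replica, with cross-replica stats.

    Occlusion always uses every atom of the ensemble; ``residues`` only
    restricts which residues are reported.
    """
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    if not ensembles:
        raise InputError("need at least one replica")
    topo = ensembles[0].topology
    r = _radii_for(topo, radii)
    if residues is not None:
        residues.validate(topo)
        wanted = {(str(topo.chainids[i]), int(topo.resids[i])) for i in residues.indices}
    else:
        wanted = None
    keys = [(str(c), int(ri)) for c, ri in zip(topo.chainids, topo.resids)]
    unique_res = []
    for kk in keys:
        if kk not in unique_res and (wanted is None or kk in wanted):
            unique_res.append(kk)
    groups = {kk: np.array([i for i, k2 in enumerate(keys) if k2 == kk])
              for kk in unique_res}

    rows = []
    for e in ensembles:
        if e.topology != topo:
            raise InputError("replica topologies differ")
        per_frame = np.zeros((e.n_frames, len(unique_res)))
        for f in range(e.n_frames):
            atom_areas = shrake_rupley(e.coordinates[f], r, probe, n_points)
            for gi, kk in enumerate(unique_res):
                per_frame[f, gi] = atom_areas[groups[kk]].sum()
        rows.append(per_frame.mean(axis=0))
    residues_arr = np.array([ri for _, ri in unique_res])
    labels = [e.label or f"rep{i+1}" for i, e in enumerate(ensembles)]
    return _make_profile(residues_arr, rows, "Å²", "sasa", labels)
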