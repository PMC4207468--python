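"""Superposition, RMSD/RMSF, Gromos clustering and SASA against oracles."""

import numpy as np
import pytest

import modediff as md
from modediff.analysis import (_kabsch_rmsd, cluster_gromos, pairwise_rmsd_matrix,
                               shrake_rupley)
from modediff.core import GeometryError, InputError, RadiusError
from conftest import apply_rigid, random_rigid_transform


def kearsley_rmsd(ref: np.ndarray, mob: np.ndarray) -> float:
    """Independent quaternion (Kearsley) minimum-RMSD oracle."""
    x = ref - ref.mean(axis=0)
    y = mob - mob.mean(axis=0)
    sm = x + y
    dm = x - y
    K = np.zeros((4, 4))
    K[0, 0] = np.sum(dm ** 2)
    K[1, 1] = np.sum(dm[:, 0] ** 2 + sm[:, 1] ** 2 + sm[:, 2] ** 2)
    K[2, 2] = np.sum(sm[:, 0] ** 2 + dm[:, 1] ** 2 + sm[:, 2] ** 2)
    K[3, 3] = np.sum(sm[:, 0] ** 2 + sm[:, 1] ** 2 + dm[:, 2] ** 2)
    K[0, 1] = K[1, 0] = np.sum(sm[:, 1] * dm[:, 2] - dm[:, 1] * sm[:, 2])
    K[0, 2] = K[2, 0] = np.sum(dm[:, 0] * sm[:, 2] - sm[:, 0] * dm[:, 2])
    K[0, 3] = K[3, 0] = np.sum(sm[:, 0] * dm[:, 1] - dm[:, 0] * sm[:, 1])
    K[1, 2] = K[2, 1] = np.sum(dm[:, 0] * dm[:, 1] - sm[:, 0] * sm[:, 1])
    K[1, 3] = K[3, 1] = np.sum(dm[:, 0] * dm[:, 2] - sm[:, 0] * sm[:, 2])
    K[2, 3] = K[3, 2] = np.sum(dm[:, 1] * dm[:, 2] - sm[:, 1] * sm[:, 2])
    lam = np.linalg.eigvalsh(K)[0]
    return float(np.sqrt(max(lam, 0.0) / ref.shape[0]))


class TestSuperposition:
    def test_rigid_transforms_recovered_exactly(self, toy_ensemble):
        rng = np.random.default_rng(0)
        base = toy_ensemble.coordinates[0]
        frames = [base]
        for _ in range(5):
            R, t = random_rigid_transform(rng)
            frames.append(apply_rigid(base, R, t))
        ens = md.Ensemble(toy_ensemble.topology, np.stack(frames))
        fitted = md.superpose(ens, reference=0)
        assert np.abs(fitted.coordinates - base).max() < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_minimized_rmsd_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        assert abs(_kabsch_rmsd(a, b) - kearsley_rmsd(a, b)) < 1e-10

    def test_reflection_pair_keeps_chirality(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 3))
        b = a.copy()
        b[:, 0] = -b[:, 0]  # improper transform of a
        # a proper rotation cannot map a mirror image back: RMSD stays > 0
        assert _kabsch_rmsd(a, b) > 0.1

    def test_too_few_or_collinear_atoms_raise(self, toy_ensemble):
        two = md.SelectionMask(np.array([0, 1]))
        with pytest.raises(GeometryError):
            md.superpose(toy_ensemble, two)
        line = np.tile(np.arange(5)[:, None] * [1.0, 0.0, 0.0], (3, 1, 1))
        ens = md.Ensemble(md.ca_chain_topology(5), line)
        with pytest.raises(GeometryError):
            md.superpose(ens)


class TestRmsdSeries:
    def test_identical_frames_zero(self, toy_ensemble):
        coords = np.repeat(toy_ensemble.coordinates[:1], 5, axis=0)
        ens = md.Ensemble(toy_ensemble.topology, coords)
        series = md.rmsd_series(ens, reference=0)
        assert np.abs(series.values).max() < 1e-10

    def test_single_displaced_atom_hand_formula(self):
        """One atom shifted by d among N atoms -> RMSD d/sqrt(N), fitting off."""
        base = np.random.default_rng(2).normal(size=(8, 3))
        moved = base.copy()
        moved[3] += [0.0, 0.0, 1.2]
        ens = md.Ensemble(md.ca_chain_topology(8), np.stack([base, moved]))
        series = md.rmsd_series(ens, reference=0, fit=False)
        assert series.values[1] == pytest.approx(1.2 / np.sqrt(8), abs=1e-12)

    def test_mean_square_matches_spectrum(self):
        """E[RMSD^2 to the mean] = sum(lambda)/N for a planted ensemble."""
        spec = md.EnsembleSpec(50, [10.0, 6.0, 3.0], seed=1)
        ens, truth = md.generate_gaussian_ensemble(spec, 8000, seed=4)
        ref = truth.mean.reshape(-1, 3)
        series = md.rmsd_series(ens, reference=ref, mask=None, fit=False)
        expected = truth.eigenvalues.sum() / 50
        assert np.mean(series.values ** 2) == pytest.approx(expected, rel=0.05)

    def test_rigid_transform_invariance(self, toy_ensemble):
        rng = np.random.default_rng(3)
        R, t = random_rigid_transform(rng)
        moved = md.Ensemble(toy_ensemble.topology,
                            apply_rigid(toy_ensemble.coordinates, R, t))
        s0 = md.rmsd_series(toy_ensemble, reference=0)
        s1 = md.rmsd_series(moved, reference=0)
        assert np.abs(s0.values - s1.values).max() < 1e-8


class TestRmsf:
    def test_zero_variance_gives_zero(self, toy_ensemble):
        coords = np.repeat(toy_ensemble.coordinates[:1], 6, axis=0)
        ens = md.Ensemble(toy_ensemble.topology, coords)
        prof = md.rmsf_profile([ens])
        assert np.abs(prof.mean).max() < 1e-12

    def test_localized_mode_localizes_rmsf(self):
        """A planted mode on one residue puts ~sqrt(lambda) there, ~0 elsewhere.

        The planted vector is first projected out of the rigid-body subspace
        (translations + linearized rotations about the mean), since the
        mean-fit superposition legitimately absorbs any rigid component.
        """
        n = 20
        spec0 = md.EnsembleSpec(n, [1.0], seed=0)
        mean = spec0.resolved_mean().reshape(n, 3)
        centered = mean - mean.mean(axis=0)
        rigid = []
        for ax in range(3):  # translations
            t = np.zeros((n, 3))
            t[:, ax] = 1.0
            rigid.append(t.ravel())
        for ax in range(3):  # linearized rotations about the centroid
            e = np.zeros(3)
            e[ax] = 1.0
            rigid.append(np.cross(e, centered).ravel())
        Q, _ = np.linalg.qr(np.column_stack(rigid))
        v = np.zeros(3 * n)
        v[3 * 7] = 1.0  # x of residue 8
        v -= Q @ (Q.T @ v)
        v /= np.linalg.norm(v)
        spec = md.EnsembleSpec(n, [4.0], modes=v[:, None], seed=0)
        ens, _ = md.generate_gaussian_ensemble(spec, 6000, seed=1)
        prof = md.rmsf_profile([ens])
        expected = 2.0 * abs(v[3 * 7])  # sqrt(lambda) times the local weight
        assert prof.per_replica[0, 7] == pytest.approx(expected, rel=0.05)
        assert prof.per_replica[0, 7] > 3 * np.delete(prof.per_replica[0], 7).max()

    def test_identical_replicas_zero_sd(self, gaussian_ensemble):
        ens, _ = gaussian_ensemble
        small = ens.slice_frames(0, 50)
        prof = md.rmsf_profile([small, small.copy(), small.copy()])
        assert np.abs(prof.sd).max() < 1e-12

    def test_rigid_transform_invariance(self, gaussian_ensemble):
        ens, _ = gaussian_ensemble
        small = ens.slice_frames(0, 100)
        rng = np.random.default_rng(5)
        R, t = random_rigid_transform(rng)
        moved = md.Ensemble(small.topology, apply_rigid(small.coordinates, R, t))
        a = md.rmsf_profile([small])
        b = md.rmsf_profile([moved])
        assert np.abs(a.per_replica - b.per_replica).max() < 1e-8


def brute_force_gromos(D: np.ndarray, cutoff: float):
    """Independent re-implementation: greedy neighbor counting on a distance matrix."""
    n = D.shape[0]
    remaining = set(range(n))
    labels = {}
    cluster = 0
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if D[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = [j for j in sorted(remaining) if D[best, j] <= cutoff]
        for j in members:
            labels[j] = cluster
        remaining -= set(members)
        cluster += 1
    return np.array([labels[i] for i in range(n)])


class TestGromosClustering:
    def test_all_identical_one_cluster(self, toy_ensemble):
        coords = np.repeat(toy_ensemble.coordinates[:1], 7, axis=0)
        ens = md.Ensemble(toy_ensemble.topology, coords)
        res = md.cluster_gromos(ens, cutoff=0.5)
        assert res.populations == [7]
        assert np.all(res.labels == 1)

    def test_two_separated_conformations(self):
        """Two tight conformational families ~10x the cutoff apart in shape."""
        rng = np.random.default_rng(8)
        base = rng.normal(scale=3.0, size=(6, 3))
        other = rng.normal(scale=3.0, size=(6, 3))  # genuinely different shape
        tight_a = base[None] + rng.normal(scale=0.01, size=(4, 6, 3))
        tight_b = other[None] + rng.normal(scale=0.01, size=(3, 6, 3))
        ens = md.Ensemble(md.ca_chain_topology(6),
                          np.concatenate([tight_a, tight_b]))
        assert _kabsch_rmsd(base, other) > 1.0  # shape difference survives fitting
        res = md.cluster_gromos(ens, cutoff=0.1)
        assert res.populations == [4, 3]

    @pytest.mark.parametrize("cutoff", [0.3, 0.8, 2.0])
    def test_partition_matches_brute_force(self, cutoff):
        spec = md.EnsembleSpec(10, [4.0, 2.0, 1.0], seed=6)
        ens, _ = md.generate_gaussian_ensemble(spec, 30, seed=7)
        D = pairwise_rmsd_matrix(ens)
        oracle = brute_force_gromos(D, cutoff)
        res = md.cluster_gromos(ens, cutoff=cutoff)
        # same partition: every oracle cluster maps 1:1 onto a result cluster
        for c in np.unique(oracle):
            ours = res.labels[oracle == c]
            assert len(set(ours)) == 1
        assert len(np.unique(oracle)) == res.n_clusters

    def test_centroid_has_max_neighbors_at_selection(self):
        """Replaying the greedy order, each centroid dominates the remaining pool."""
        spec = md.EnsembleSpec(8, [3.0, 1.0], seed=2)
        ens, _ = md.generate_gaussian_ensemble(spec, 40, seed=3)
        cutoff = 0.8
        D = pairwise_rmsd_matrix(ens)
        res = md.cluster_gromos(ens, cutoff=cutoff)
        remaining = np.ones(40, dtype=bool)
        for cid in res.extraction_order:
            centroid = res.centroids[cid - 1]
            c_count = ((D[centroid] <= cutoff) & remaining).sum()
            counts = [((D[i] <= cutoff) & remaining).sum()
                      for i in np.flatnonzero(remaining)]
            assert c_count >= max(counts)
            remaining &= ~(res.labels == cid)

    def test_refuses_huge_frame_count(self):
        coords = np.zeros((10_001, 3, 3))
        coords[:, 1, 0] = 3.8
        coords[:, 2, 1] = 3.8
        ens = md.Ensemble(md.ca_chain_topology(3), coords)
        with pytest.raises(InputError):
            md.cluster_gromos(ens, cutoff=1.0)


class TestSasa:
    def test_isolated_sphere_analytic(self):
        r = 1.7
        area = shrake_rupley(np.zeros((1, 3)), np.array([r]), probe=1.4, n_points=960)
        assert area[0] == pytest.approx(4 * np.pi * (r + 1.4) ** 2, rel=0.02)

    def test_far_apart_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.7, 1.52])
        areas = shrake_rupley(coords, radii)
        expected = 4 * np.pi * (radii + 1.4) ** 2
        assert np.allclose(areas, expected, rtol=0.02)

    def test_buried_atom_zero(self):
        """A small atom inside a tight shell of occluders has ~no surface."""
        from modediff.analysis import _sphere_points
        shell = 3.0 * _sphere_points(200)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.concatenate([[1.0], np.full(200, 1.6)])
        areas = shrake_rupley(coords, radii)
        assert areas[0] < 1e-6

    def test_monotone_under_occlusion(self):
        rng = np.random.default_rng(9)
        center = np.zeros((1, 3))
        occluders = rng.normal(scale=3.0, size=(12, 3))
        radii0 = np.array([1.7])
        prev = shrake_rupley(center, radii0)[0]
        for k in range(1, 13):
            coords = np.vstack([center, occluders[:k]])
            radii = np.concatenate([radii0, np.full(k, 1.7)])
            cur = shrake_rupley(coords, radii)[0]
            assert cur <= prev + 1e-9
            prev = cur

    def test_cross_check_against_mdtraj(self):
        """Independent Shrake-Rupley implementation agrees on a carbon cluster.

        mdtraj's radius table uses the same Bondi carbon radius (1.7 Å), so
        the only difference is the sphere-point construction.
        """
        import mdtraj
        rng = np.random.default_rng(12)
        coords = rng.normal(scale=2.5, size=(8, 3))
        ours = shrake_rupley(coords, np.full(8, 1.7), probe=1.4, n_points=960)
        top = mdtraj.Topology()
        chain = top.add_chain()
        res = top.add_residue("LIG", chain)
        for i in range(8):
            top.add_atom(f"C{i}", mdtraj.element.carbon, res)
        traj = mdtraj.Trajectory(coords[None] / 10.0, top)  # nm
        theirs = mdtraj.shrake_rupley(traj, probe_radius=0.14,
                                      n_sphere_points=960)[0] * 100.0  # nm^2 -> Å^2
        assert np.abs(ours - theirs).max() < 0.02 * (4 * np.pi * 3.1 ** 2)

    def test_unknown_element_names_atom(self, toy_ensemble):
        bad = toy_ensemble.topology
        bad.elements[0] = "XX"
        with pytest.raises(RadiusError, match="XX"):
            md.sasa_profile(toy_ensemble)

    def test_profile_shape_and_units(self, toy_ensemble):
        prof = md.sasa_profile(toy_ensemble.slice_frames(0, 3), n_points=120)
        assert prof.units == "Å²"
        assert prof.residue_numbers.tolist() == [1, 2, 3]
        assert np.all(prof.mean >= 0)
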