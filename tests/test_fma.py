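"""Functional mode analysis: functional quantities, linear and MI fits,
estimator sanity, and the basis-size selection rule."""

import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

import modediff as md
from modediff.core import InputError
from modediff.fma import BasisScan, fit_linear_fma, fit_mi_fma, select_basis_size
from conftest import apply_rigid, random_rigid_transform


@pytest.fixture(scope="module")
def planted():
    spec = md.EnsembleSpec(30, [10.0, 6.0, 4.0, 2.0, 1.0], seed=3)
    ens, truth = md.generate_gaussian_ensemble(spec, 5000, seed=4)
    dec = md.pca(ens, check_superposition=False)
    proj = md.project(ens, dec, 5)
    return ens, truth, dec, proj


class TestFunctionalQuantities:
    def test_hinge_distance_3_4_5(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1] = [3.0, 4.0, 0.0]
        topo = md.Topology(names=np.array(["CA", "CA"]), elements=np.array(["C", "C"]),
                           resnames=np.array(["LEU", "MET"]),
                           resids=np.array([781, 922]), chainids=np.array(["A", "A"]))
        ens = md.Ensemble(topo, coords)
        series = md.hinge_distance(ens)  # defaults are 781 and 922
        assert series.values[0] == pytest.approx(5.0)

    def test_hinge_distance_rigid_invariance(self, planted):
        ens = planted[0].slice_frames(0, 20)
        rng = np.random.default_rng(0)
        R, t = random_rigid_transform(rng)
        moved = md.Ensemble(ens.topology, apply_rigid(ens.coordinates, R, t))
        a = md.hinge_distance(ens, 5, 25)
        b = md.hinge_distance(moved, 5, 25)
        assert np.abs(a.values - b.values).max() < 1e-8

    def test_hinge_missing_ca_raises(self, toy_ensemble):
        with pytest.raises(InputError):
            md.hinge_distance(toy_ensemble, 1, 99)

    def test_site_rmsd_reference_frame_zero(self, planted):
        ens = planted[0].slice_frames(0, 10)
        site = md.select_atoms(ens.topology, "resid 3-8")
        series = md.active_site_rmsd(ens, site, reference=0)
        assert series.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_site_rmsd_hand_formula(self):
        base = np.random.default_rng(1).normal(size=(6, 3))
        moved = base.copy()
        moved[2] += [1.0, 0.0, 0.0]
        ens = md.Ensemble(md.ca_chain_topology(6), np.stack([base, moved]))
        site = md.SelectionMask(np.array([1, 2, 3, 4]))
        series = md.active_site_rmsd(ens, site, reference=0)
        assert series.values[1] == pytest.approx(1.0 / np.sqrt(4), abs=1e-12)

    def test_site_rmsd_not_refit(self):
        """A rigid transform after global alignment changes the value: the
        global frame is deliberately retained (no refit on the site)."""
        base = np.random.default_rng(2).normal(size=(6, 3))
        rng = np.random.default_rng(3)
        R, t = random_rigid_transform(rng)
        ens = md.Ensemble(md.ca_chain_topology(6),
                          np.stack([base, apply_rigid(base, R, t)]))
        site = md.SelectionMask(np.array([0, 1, 2]))
        series = md.active_site_rmsd(ens, site, reference=0)
        assert series.values[1] > 0.1


class TestLinearFma:
    def test_perfect_linear_target(self, planted):
        ens, truth, dec, proj = planted
        f = md.FunctionalSeries(proj.values[:, 1].copy(), name="pc2")
        model = fit_linear_fma(proj, f, split=0.7, k=3)
        assert model.r_m == pytest.approx(1.0, abs=1e-8)
        assert model.r_c == pytest.approx(1.0, abs=1e-8)
        assert abs(model.alpha @ dec.eigenvectors[:, 1]) == pytest.approx(1.0, abs=1e-8)

    def test_planted_vector_recovery_noiseless(self, planted):
        ens, truth, dec, proj = planted
        w = np.array([0.5, -0.5, 0.5, 0.3, np.sqrt(1 - 0.84)])
        w /= np.linalg.norm(w)
        f, w_cart = md.plant_functional_quantity(ens, truth, md.PlantSpec(w), seed=0)
        model = fit_linear_fma(proj, f, split=0.7, k=5)
        assert abs(model.alpha @ w_cart) > 0.99

    def test_noise_attenuates_r_c_per_closed_form(self, planted):
        ens, truth, dec, proj = planted
        w = np.zeros(5)
        w[0] = 0.6
        w[2] = 0.8
        var_signal = float(w @ (truth.eigenvalues * w))
        sigma = np.sqrt(var_signal)  # true R = 1/sqrt(2)
        f, _ = md.plant_functional_quantity(ens, truth,
                                            md.PlantSpec(w, sigma=sigma), seed=5)
        model = fit_linear_fma(proj, f, split=0.7, k=5)
        assert abs(model.r_c - 1.0 / np.sqrt(2.0)) < 0.02

    def test_constant_target_rejected(self, planted):
        proj = planted[3]
        f = md.FunctionalSeries(np.ones(proj.n_frames))
        with pytest.raises(InputError):
            fit_linear_fma(proj, f, split=0.7, k=2)

    def test_alpha_in_basis_span(self, planted):
        ens, truth, dec, proj = planted
        f = md.FunctionalSeries(proj.values[:, 0] + 0.5 * proj.values[:, 2])
        model = fit_linear_fma(proj, f, split=0.7, k=3)
        V = dec.eigenvectors[:, :3]
        residual = model.alpha - V @ (V.T @ model.alpha)
        assert np.linalg.norm(residual) < 1e-8

    def test_matches_brute_force_sphere_maximization(self, planted):
        """Grid+refine maximization of Pearson R over the k=2 sphere."""
        ens, truth, dec, proj = planted
        rng = np.random.default_rng(6)
        f = md.FunctionalSeries(
            0.8 * proj.values[:, 0] - 0.6 * proj.values[:, 1]
            + rng.normal(scale=1.0, size=proj.n_frames))
        model = fit_linear_fma(proj, f, split=0.7, k=2)
        n_model = model.n_model
        X, y = proj.values[:n_model, :2], f.values[:n_model]
        thetas = np.linspace(0, np.pi, 20001)  # R(+-v) is identical: half circle
        dirs = np.column_stack([np.cos(thetas), np.sin(thetas)])
        rs = np.array([abs(pearsonr(X @ v, y)[0]) for v in dirs])
        best = dirs[np.argmax(rs)]
        assert abs(best @ model.coefficients) > 0.999

    def test_no_anti_overfitting_paradox(self, planted):
        """R_c does not systematically exceed R_m on planted data (20 seeds)."""
        ens, truth, dec, proj = planted
        w = np.array([0.6, 0.0, 0.8, 0.0, 0.0])
        gaps = []
        for seed in range(20):
            f, _ = md.plant_functional_quantity(
                ens, truth, md.PlantSpec(w, sigma=2.0), seed=seed)
            m = fit_linear_fma(proj, f, split=0.7, k=5)
            gaps.append(m.r_c - m.r_m)
        assert np.mean(gaps) <= 0.05


class TestMutualInformation:
    def test_independent_gaussians_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 5000))
        assert abs(md.mutual_information(x, y)) < 0.02

    def test_bivariate_gaussian_closed_form(self):
        rho = 0.9
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 5000)
        mi = md.mutual_information(z[:, 0], z[:, 1])
        assert abs(mi - (-0.5 * np.log(1 - rho ** 2))) < 0.05

    def test_invariance_under_monotone_map(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(3000)
        noise = rng.normal(scale=0.3, size=3000)
        mi_linear = md.mutual_information(x, x + noise)
        mi_cubic = md.mutual_information(x, (x + noise) ** 3)
        assert abs(mi_linear - mi_cubic) < 0.1

    def test_nonnegative_within_noise_floor(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            x, y = np.random.default_rng(seed).standard_normal((2, 2000))
            assert md.mutual_information(x, y) > -0.02

    def test_constant_input_warns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            mi = md.mutual_information(np.ones(100), np.arange(100.0))
        assert mi == 0.0

    def test_matches_sklearn_ksg_family(self):
        """Independent cross-check against scikit-learn's kNN MI estimator."""
        from sklearn.feature_selection import mutual_info_regression
        rng = np.random.default_rng(4)
        x = rng.standard_normal(3000)
        y = 0.8 * x + rng.normal(scale=0.6, size=3000)
        ours = md.mutual_information(x, y, k_nn=3)
        theirs = mutual_info_regression(x[:, None], y, n_neighbors=3,
                                        random_state=0)[0]
        assert abs(ours - theirs) < 0.1

    def test_histogram_estimator_agrees_roughly(self):
        rho = 0.8
        rng = np.random.default_rng(5)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 8000)
        hist = md.mutual_information(z[:, 0], z[:, 1], estimator="histogram", bins=24)
        exact = -0.5 * np.log(1 - rho ** 2)
        assert abs(hist - exact) < 0.15


class TestMiFma:
    def test_identity_link_matches_linear_solution(self, planted):
        ens, truth, dec, proj = planted
        w = np.array([0.6, 0.8, 0.0, 0.0, 0.0])
        f, w_cart = md.plant_functional_quantity(
            ens, truth, md.PlantSpec(w, sigma=0.5), seed=7)
        linear = fit_linear_fma(proj, f, split=0.8, k=3)
        mi = fit_mi_fma(proj, f, split=0.8, k=3, seed=0, n_restarts=2)
        assert abs(mi.alpha @ linear.alpha) > 0.98

    def test_cubic_link_recovery_beats_linear(self, planted):
        ens, truth, dec, proj = planted
        w = np.array([0.5, 0.5, -0.5, 0.5, 0.0])
        f, w_cart = md.plant_functional_quantity(
            ens, truth, md.PlantSpec(w, link="cubic", sigma=0.5), seed=8)
        linear = fit_linear_fma(proj, f, split=0.8, k=5)
        mi = fit_mi_fma(proj, f, split=0.8, k=5, seed=1, n_restarts=2)
        assert abs(mi.alpha @ w_cart) >= 0.95
        assert mi.r_c > linear.r_c

    def test_independent_target_gives_null_r_c(self, planted):
        ens, truth, dec, proj = planted
        f = md.FunctionalSeries(np.random.default_rng(9).standard_normal(proj.n_frames))
        model = fit_mi_fma(proj, f, split=0.8, k=3, seed=2, n_restarts=1)
        assert abs(model.r_c) < 0.1

    def test_k_cap_enforced(self, planted):
        proj = planted[3]
        f = md.FunctionalSeries(proj.values[:, 0].copy())
        with pytest.raises(InputError, match="cap"):
            fit_mi_fma(proj, f, k=5, k_cap=5)


class TestBasisSelection:
    def test_rule_prefers_small_gap(self):
        scan = BasisScan(records=[{"k": 3, "r_m": 0.9, "r_c": 0.89},
                                  {"k": 8, "r_m": 0.99, "r_c": 0.7}])
        assert select_basis_size(scan) == 3
        assert "min|R_m-R_c|" in scan.rule

    def test_tie_breaks_to_smallest_k(self):
        # exactly representable gaps so the ties are exact
        scan = [{"k": 2, "r_m": 0.75, "r_c": 0.625},
                {"k": 4, "r_m": 0.875, "r_c": 0.75},
                {"k": 6, "r_m": 1.0, "r_c": 0.875}]
        assert select_basis_size(scan) == 2

    def test_threshold_excludes_weak_models(self):
        scan = [{"k": 2, "r_m": 0.4, "r_c": 0.39},   # tiny gap but useless R_c
                {"k": 5, "r_m": 0.9, "r_c": 0.8}]
        assert select_basis_size(scan, r_c_threshold=0.5) == 5

    def test_no_eligible_k_raises(self):
        scan = [{"k": 2, "r_m": 0.4, "r_c": 0.2}, {"k": 4, "r_m": 0.5, "r_c": 0.3}]
        with pytest.raises(InputError):
            select_basis_size(scan)

    def test_exhaustive_rule_equivalence(self):
        """The selection matches a literal re-statement of the rule on random scans."""
        rng = np.random.default_rng(10)
        for _ in range(200):
            ks = np.sort(rng.choice(np.arange(2, 20), size=5, replace=False))
            records = [{"k": int(k), "r_m": float(rng.uniform(0, 1)),
                        "r_c": float(rng.uniform(0, 1))} for k in ks]
            eligible = [r for r in records if r["r_c"] >= 0.5]
            if not eligible:
                with pytest.raises(InputError):
                    select_basis_size(records)
                continue
            gaps = [(abs(r["r_m"] - r["r_c"]), r["k"]) for r in eligible]
            expected = min(gaps)[1]
            assert select_basis_size(records) == expected


class TestRenderMode:
    def test_zero_amplitude_is_mean(self, planted):
        ens, truth, dec, proj = planted
        f = md.FunctionalSeries(proj.values[:, 0].copy())
        model = fit_linear_fma(proj, f, split=0.7, k=2)
        rendered = md.render_mode(model, dec, [0.0])
        assert np.allclose(rendered.coordinates[0].ravel(), dec.mean)

    def test_symmetric_amplitudes(self, planted):
        ens, truth, dec, proj = planted
        f = md.FunctionalSeries(proj.values[:, 0].copy())
        model = fit_linear_fma(proj, f, split=0.7, k=2)
        rendered = md.render_mode(model, dec, [-2.0, 2.0])
        mid = (rendered.coordinates[0] + rendered.coordinates[1]) / 2
        assert np.allclose(mid.ravel(), dec.mean)

    def test_projection_recovers_amplitudes(self, planted):
        ens, truth, dec, proj = planted
        f = md.FunctionalSeries(proj.values[:, 0] - proj.values[:, 1])
        model = fit_linear_fma(proj, f, split=0.7, k=3)
        amps = np.array([-3.0, -1.0, 0.0, 2.0, 5.0])
        rendered = md.render_mode(model, dec, amps)
        flat = rendered.coordinates.reshape(len(amps), -1)
        back = (flat - dec.mean) @ model.alpha
        assert np.abs(back - amps).max() < 1e-8
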