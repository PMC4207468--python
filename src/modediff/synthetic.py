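"""Synthetic conformational ensembles with known ground truth.

Real comparative MD studies of this kind rest on trajectories that are
too expensive to regenerate, so every analysis stage here is exercised
on surrogates whose answers are known by construction:

* multivariate-Gaussian Cα fluctuations with a prescribed eigenvalue
  spectrum and orthonormal mode matrix (the ground truth for PCA, RMSF,
  RMSIP);
* a scalar functional quantity planted as a (linear or monotone
  nonlinear) function of the projection onto a known collective vector,
  plus Gaussian noise (the ground truth for functional mode analysis);
* donor–hydrogen–acceptor fragments whose bonded state follows a
  two-state Markov chain with prescribed stationary occupancy and
  switching rate (the ground truth for contact frequency/ACF statistics);
* a two-condition × n-replica design mirroring a wild-type/mutant study
  with five independent simulations per condition.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Ensemble, FunctionalSeries, SpecError, Topology
from .modes import ModeDecomposition, _fix_signs

__all__ = ["EnsembleSpec", "PlantSpec", "ContactPlantSpec",
           "generate_gaussian_ensemble", "plant_functional_quantity",
           "plant_contact_dynamics", "combine_contact_fragments",
           "generate_condition_set", "ca_chain_topology"]

CA_SPACING = 3.8  # Å, consecutive Cα distance in an extended chain


def ca_chain_topology(n_residues: int) -> Topology:
    """A Cα-only chain topology (one CA atom per residue, chain A)."""
    n = int(n_residues)
    return Topology(names=np.array(["CA"] * n), elements=np.array(["C"] * n),
                    resnames=np.array(["ALA"] * n),
                    resids=np.arange(1, n + 1), chainids=np.array(["A"] * n))


@dataclass
class EnsembleSpec:
    """Recipe for a Gaussian Cα ensemble with a planted mode spectrum.

    ``eigenvalues`` (Å^2, descending, >= 0) set the variance along each
    planted mode. ``modes`` may give an explicit orthonormal 3N x m matrix;
    otherwise a random orthonormal basis is drawn from ``seed``. The mean
    structure defaults to an extended chain with 3.8 Å Cα spacing.
    """

    n_residues: int
    eigenvalues: np.ndarray
    modes: np.ndarray | None = None
    mean: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64).ravel()
        if self.n_residues < 1:
            raise SpecError("need at least one residue")
        if np.any(self.eigenvalues < 0):
            raise SpecError("eigenvalues must be non-negative")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise SpecError("eigenvalues must be in descending order")
        dim = 3 * self.n_residues
        if self.eigenvalues.size > dim:
            raise SpecError(
                f"{self.eigenvalues.size} eigenvalues exceed the 3N = {dim} "
                "degrees of freedom")
        if self.modes is not None:
            self.modes = np.asarray(self.modes, dtype=np.float64)
            if self.modes.shape != (dim, self.eigenvalues.size):
                raise SpecError(f"mode matrix must be ({dim}, {self.eigenvalues.size})")
            gram = self.modes.T @ self.modes
            if not np.allclose(gram, np.eye(self.eigenvalues.size), atol=1e-8):
                raise SpecError("mode matrix is not orthonormal within 1e-8")
        if self.mean is not None:
            self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
            if self.mean.size != dim:
                raise SpecError(f"mean structure must have length {dim}")

    @property
    def dim(self) -> int:
        return 3 * self.n_residues

    def resolved_mean(self) -> np.ndarray:
        # Default mean: a helical Cα curve with exactly 3.8 Å between
        # consecutive residues. A straight chain would be collinear and make
        # rigid-body superposition underdetermined about the chain axis.
        if self.mean is not None:
            return self.mean
        theta = np.radians(100.0) * np.arange(self.n_residues)
        rise = 1.5
        radius = np.sqrt(CA_SPACING ** 2 - rise ** 2) / (2 * np.sin(np.radians(50.0)))
        coords = np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                                  rise * np.arange(self.n_residues)])
        return coords.ravel()

    def resolved_modes(self) -> np.ndarray:
        if self.modes is not None:
            return self.modes
        rng = np.random.default_rng(self.seed)
        raw = rng.standard_normal((self.dim, self.eigenvalues.size))
        q, _ = np.linalg.qr(raw)
        return _fix_signs(q[:, : self.eigenvalues.size])


def generate_gaussian_ensemble(spec: EnsembleSpec, n_frames: int, seed: int,
                               dt_ns: float = 0.1) -> tuple[Ensemble, ModeDecomposition]:
    """Draw frames = mean + sum_i sqrt(lambda_i) z_i v_i with z ~ N(0, 1).

    Returns the ensemble and the ground-truth decomposition holding the
    planted modes and eigenvalues. Reproducible given (spec, seed).
    """
    if n_frames < 2:
        raise SpecError("need at least 2 frames")
    modes = spec.resolved_modes()
    mean = spec.resolved_mean()
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, spec.eigenvalues.size))
    flat = mean + (z * np.sqrt(spec.eigenvalues)) @ modes.T
    coords = flat.reshape(n_frames, spec.n_residues, 3)
    times = dt_ns * np.arange(n_frames)
    ensemble = Ensemble(ca_chain_topology(spec.n_residues), coords, times)
    truth = ModeDecomposition(mean, modes, spec.eigenvalues,
                              atom_indices=None, provenance="planted")
    return ensemble, truth


_LINKS = {
    "identity": lambda s: s,
    "cubic": lambda s: s ** 3,
}


@dataclass
class PlantSpec:
    """Ground truth for a planted functional quantity.

    ``w`` is the unit collective vector, given either as coefficients over
    the ground-truth modes (length m) or in Cartesian space (length 3N,
    must lie in the mode span). The link is the identity or a monotone
    nonlinearity; ``sigma`` is the SD of additive Gaussian noise.
    """

    w: np.ndarray
    link: str = "identity"
    sigma: float = 0.0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64).ravel()
        if abs(np.linalg.norm(self.w) - 1.0) > 1e-6:
            raise SpecError("collective vector w must have unit norm")
        if self.link not in _LINKS:
            raise SpecError(f"unknown link {self.link!r}; choose from {sorted(_LINKS)}")
        if self.sigma < 0:
            raise SpecError("noise SD must be >= 0")


def plant_functional_quantity(ensemble: Ensemble, truth: ModeDecomposition,
                              plant: PlantSpec, seed: int
                              ) -> tuple[FunctionalSeries, np.ndarray]:
    """f(t) = link(<frame_t - mean, w>) + N(0, sigma^2) noise.

    Returns the series and the Cartesian ground-truth vector w (unit norm)
    for recovery scoring.
    """
    dim = truth.mean.size
    if plant.w.size == truth.n_modes:
        w_cart = truth.eigenvectors @ plant.w
    elif plant.w.size == dim:
        w_cart = plant.w
        coeffs = truth.eigenvectors.T @ w_cart
        residual = w_cart - truth.eigenvectors @ coeffs
        if np.linalg.norm(residual) > 1e-8:
            raise SpecError("w is not expressible in the ground-truth mode space")
    else:
        raise SpecError(
            f"w has length {plant.w.size}; expected {truth.n_modes} (mode space) "
            f"or {dim} (Cartesian)")
    w_cart = w_cart / np.linalg.norm(w_cart)
    flat = ensemble.coordinates.reshape(ensemble.n_frames, -1)
    s = (flat - truth.mean) @ w_cart
    signal = _LINKS[plant.link](s)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, plant.sigma, size=signal.size) if plant.sigma > 0 else 0.0
    series = FunctionalSeries(signal + noise, units="Å",
                              name=f"planted-{plant.link}",
                              frame_times=ensemble.frame_times)
    return series, w_cart


@dataclass
class ContactPlantSpec:
    """Two-state Markov hydrogen-bond dynamics with known occupancy.

    The per-frame bonded state switches with probabilities q*(1-p)
    (bonded -> broken) and q*p (broken -> bonded), giving stationary
    occupancy exactly ``p`` and autocorrelation (1-q)^lag. Bonded frames
    satisfy the default geometric detector (donor–acceptor distance
    ``bonded_distance``, angle 180°); broken frames place the acceptor at
    ``unbonded_distance``, at least 1 Å beyond the distance criterion.
    """

    p: float
    q: float
    bonded_distance: float = 2.9
    unbonded_distance: float = 4.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise SpecError("occupancy p must lie in [0, 1]")
        if not 0.0 < self.q <= 1.0:
            raise SpecError("switching probability q must lie in (0, 1]")


def _contact_topology(donor_resid: int = 1) -> Topology:
    return Topology(names=np.array(["N", "H", "O"]),
                    elements=np.array(["N", "H", "O"]),
                    resnames=np.array(["DNR", "DNR", "ACP"]),
                    resids=np.array([donor_resid, donor_resid, donor_resid + 1]),
                    chainids=np.array(["A", "A", "A"]))


def markov_states(p: float, q: float, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary two-state chain: P(0->1) = q*p, P(1->0) = q*(1-p)."""
    states = np.empty(n_frames, dtype=bool)
    states[0] = rng.random() < p
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        if states[t - 1]:
            states[t] = u[t - 1] >= q * (1.0 - p)
        else:
            states[t] = u[t - 1] < q * p
    return states


def plant_contact_dynamics(plant: ContactPlantSpec, n_frames: int,
                           dt_ns: float = 0.1) -> Ensemble:
    """Three-atom donor/hydrogen/acceptor fragment with Markov bond dynamics.

    Degenerate occupancies p in {0, 1} yield constant chains; otherwise
    the chain is drawn from its stationary distribution.
    """
    rng = np.random.default_rng(plant.seed)
    if plant.p in (0.0, 1.0):
        states = np.full(n_frames, bool(plant.p))
    else:
        states = markov_states(plant.p, plant.q, n_frames, rng)
    coords = np.zeros((n_frames, 3, 3))
    coords[:, 1, 0] = 1.0  # H on the donor–acceptor axis: D–H–A angle 180°
    coords[:, 2, 0] = np.where(states, plant.bonded_distance, plant.unbonded_distance)
    times = dt_ns * np.arange(n_frames)
    ens = Ensemble(_contact_topology(), coords, times, label="planted-contact")
    ens.planted_states = states  # ground truth, carried for scoring
    return ens


def combine_contact_fragments(fragments: list[Ensemble], spacing: float = 25.0) -> Ensemble:
    """Stack independent contact fragments into one ensemble, offset along y
    so fragments cannot cross-detect. Residues are renumbered sequentially."""
    if not fragments:
        raise SpecError("no fragments to combine")
    n_frames = fragments[0].n_frames
    names, elements, resnames, resids, chains, blocks, states = [], [], [], [], [], [], []
    next_resid = 1
    for fi, frag in enumerate(fragments):
        if frag.n_frames != n_frames:
            raise SpecError("fragments must have equal frame counts")
        t = frag.topology
        offset = {int(r): next_resid + i for i, r in enumerate(dict.fromkeys(t.resids))}
        next_resid += len(offset)
        names.extend(t.names); elements.extend(t.elements); resnames.extend(t.resnames)
        resids.extend(offset[int(r)] for r in t.resids)
        chains.extend(t.chainids)
        shifted = frag.coordinates.copy()
        shifted[:, :, 1] += spacing * fi
        blocks.append(shifted)
        states.append(getattr(frag, "planted_states", None))
    topo = Topology(np.array(names), np.array(elements), np.array(resnames),
                    np.array(resids), np.array(chains))
    ens = Ensemble(topo, np.concatenate(blocks, axis=1), fragments[0].frame_times,
                   label="planted-contacts")
    ens.planted_states = states
    return ens


def generate_condition_set(spec_a: EnsembleSpec, spec_b: EnsembleSpec,
                           replicas: int, n_frames: int, seed: int,
                           labels: tuple[str, str] = ("A", "B"),
                           dt_ns: float = 0.1) -> list[Ensemble]:
    """Two conditions x ``replicas`` independent ensembles.

    Replicas within a condition share the condition's planted modes and
    differ only by the frame-noise seed, derived deterministically as
    seed + condition_index*replicas + replica_index.
    """
    if replicas < 2:
        raise SpecError("need at least 2 replicas per condition")
    out: list[Ensemble] = []
    for ci, (spec, label) in enumerate(zip((spec_a, spec_b), labels)):
        for ri in range(replicas):
            ens, truth = generate_gaussian_ensemble(
                spec, n_frames, seed + ci * replicas + ri, dt_ns=dt_ns)
            ens.label = f"{label}-r{ri + 1}"
            ens.ground_truth = truth
            out.append(ens)
    return out
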