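"""Core data model shared by every analysis stage.

A conformational ensemble is represented as a plain-array container:
a :class:`Topology` (atom metadata), a ``frames x atoms x 3`` coordinate
array in Ångström, and an optional per-frame time axis in nanoseconds.
All internal atom indexing is 0-based; residue numbers exposed to users
are the 1-based PDB numbers.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Topology",
    "Ensemble",
    "SelectionMask",
    "FunctionalSeries",
    "ModeDiffError",
    "FormatError",
    "SelectionParseError",
    "GeometryError",
    "SpecError",
    "InputError",
    "RadiusError",
    "ATOMIC_MASSES",
    "BONDI_RADII",
    "element_from_name",
]


class ModeDiffError(Exception):
    """Base class for all package errors."""


class FormatError(ModeDiffError):
    """A file could not be interpreted (bad format, atom-count mismatch...)."""


class SelectionParseError(ModeDiffError):
    """An atom-selection expression could not be parsed."""


class GeometryError(ModeDiffError):
    """Degenerate geometry (too few / collinear fit atoms, ...)."""


class SpecError(ModeDiffError):
    """An inconsistent specification of a synthetic ensemble or plant."""


class InputError(ModeDiffError):
    """Inconsistent inputs to an analysis operation."""


class RadiusError(ModeDiffError):
    """No van der Waals radius known for an element."""


# Standard atomic masses (u) and Bondi van der Waals radii (Å) for the
# elements that occur in protein structures.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078,
}

BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "ZN": 1.39, "MG": 1.73, "NA": 2.27, "K": 2.75,
}


def element_from_name(name: str) -> str:
    """Guess an element symbol from a PDB atom name.

    Strips digits/primes and, for standard protein atom names, takes the
    first letter (``CA`` is a carbon, not calcium, in a protein context).
    """
    core = "".join(c for c in name.strip() if c.isalpha())
    if not core:
        return "X"
    two = core[:2].upper()
    # Two-letter elements seen in structures, excluding protein-name clashes
    if two in {"FE", "ZN", "MG", "NA", "CL", "BR", "SE"} and len(name.strip()) <= 2:
        return two
    return core[0].upper()


@dataclass
class Topology:
    """Ordered atom metadata: names, elements, residue assignment, chains.

    Residue numbers are 1-based PDB numbers and must be non-decreasing
    within each chain.
    """

    names: np.ndarray          # atom names, dtype str
    elements: np.ndarray       # element symbols
    resnames: np.ndarray       # residue names
    resids: np.ndarray         # 1-based residue numbers, int
    chainids: np.ndarray       # chain identifiers

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.resnames = np.asarray(self.resnames, dtype="U6")
        self.resids = np.asarray(self.resids, dtype=np.int64)
        self.chainids = np.asarray(self.chainids, dtype="U4")
        n = len(self.names)
        if n == 0:
            raise FormatError("topology must contain at least one atom")
        for arr, what in ((self.elements, "elements"), (self.resnames, "resnames"),
                          (self.resids, "resids"), (self.chainids, "chainids")):
            if len(arr) != n:
                raise FormatError(f"topology field {what} has length {len(arr)} != {n} atoms")
        for chain in np.unique(self.chainids):
            r = self.resids[self.chainids == chain]
            if np.any(np.diff(r) < 0):
                raise FormatError(f"residue numbers decrease within chain {chain!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique residues in order of first appearance, as (chain, resid, resname)."""
        seen: dict[tuple[str, int], str] = {}
        for c, r, rn in zip(self.chainids, self.resids, self.resnames):
            seen.setdefault((str(c), int(r)), str(rn))
        return [(c, r, rn) for (c, r), rn in seen.items()]

    def atom_index(self, resid: int, name: str) -> int:
        """Index of the atom ``name`` in residue ``resid`` (first chain match)."""
        hits = np.flatnonzero((self.resids == resid) & (self.names == name))
        if hits.size == 0:
            raise InputError(f"no atom {name!r} in residue {resid}")
        return int(hits[0])

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e.upper(), 12.011) for e in self.elements])

    def subset(self, indices: np.ndarray) -> "Topology":
        idx = np.asarray(indices, dtype=np.int64)
        return Topology(self.names[idx], self.elements[idx], self.resnames[idx],
                        self.resids[idx], self.chainids[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return all(np.array_equal(getattr(self, f.name), getattr(other, f.name))
                   for f in dataclasses.fields(self))


@dataclass
class SelectionMask:
    """Sorted unique 0-based atom indices plus the expression that produced them."""

    indices: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        if idx.size and idx[0] < 0:
            raise InputError("selection indices must be non-negative")
        self.indices = idx

    def __len__(self) -> int:
        return int(self.indices.size)

    def validate(self, topology: Topology) -> None:
        if self.indices.size and self.indices[-1] >= topology.n_atoms:
            raise InputError(
                f"selection index {int(self.indices[-1])} out of bounds "
                f"for topology with {topology.n_atoms} atoms")


@dataclass
class Ensemble:
    """frames x atoms x 3 coordinates (Å) over a fixed topology."""

    topology: Topology
    coordinates: np.ndarray
    frame_times: np.ndarray | None = None   # ns
    label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise FormatError(f"coordinates must be (frames, atoms, 3), got {self.coordinates.shape}")
        if self.coordinates.shape[0] < 1:
            raise FormatError("ensemble needs at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"coordinate array has {self.coordinates.shape[1]} atoms but "
                f"topology has {self.topology.n_atoms}")
        if not np.all(np.isfinite(self.coordinates)):
            raise FormatError("coordinates contain non-finite values")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
            if self.frame_times.shape != (self.n_frames,):
                raise FormatError("frame_times length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def copy(self) -> "Ensemble":
        return Ensemble(self.topology, self.coordinates.copy(),
                        None if self.frame_times is None else self.frame_times.copy(),
                        self.label)

    def subset(self, mask: SelectionMask) -> "Ensemble":
        """Restrict to the atoms in ``mask`` (topology and coordinates)."""
        mask.validate(self.topology)
        return Ensemble(self.topology.subset(mask.indices),
                        self.coordinates[:, mask.indices, :].copy(),
                        self.frame_times, self.label)

    def slice_frames(self, start: int, stop: int) -> "Ensemble":
        return Ensemble(self.topology, self.coordinates[start:stop].copy(),
                        None if self.frame_times is None else self.frame_times[start:stop].copy(),
                        self.label)

    def window_ns(self, t0: float, t1: float) -> "Ensemble":
        """Frames with time in [t0, t1] ns; requires a time axis."""
        if self.frame_times is None:
            raise InputError("ensemble has no frame times; cannot slice by ns window")
        keep = (self.frame_times >= t0) & (self.frame_times <= t1)
        if not keep.any():
            raise InputError(f"window [{t0}, {t1}] ns selects no frames")
        return Ensemble(self.topology, self.coordinates[keep].copy(),
                        self.frame_times[keep].copy(), self.label)


@dataclass
class FunctionalSeries:
    """Per-frame scalar functional quantity (e.g. a hinge distance in Å)."""

    values: np.ndarray
    units: str = ""
    name: str = ""
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InputError(f"functional series {self.name!r} contains non-finite values")

    def __len__(self) -> int:
        return self.values.size
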