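"""Reading and writing structures, trajectories and result tables.

File handling is delegated to MDAnalysis: PDB (single- and multi-model)
topologies, DCD and XTC trajectories. Coordinates are normalized to
Ångström on read (MDAnalysis converts XTC's nm natively) and times to
nanoseconds. Atom selections use the MDAnalysis selection language with
a small preprocessing step so residue ranges may be written either as
``resid 1:7`` or in the PDB-citation style ``resid 1-7,231-240``.
"""

from __future__ import annotations

import math
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (Ensemble, FormatError, InputError, SelectionMask,
                   SelectionParseError, Topology, element_from_name)

__all__ = ["read_ensemble", "write_ensemble", "select_atoms", "write_table", "read_table"]


def _import_mda():
    import MDAnalysis as mda
    return mda


def _topology_from_atomgroup(ag) -> Topology:
    n = len(ag)
    names = ag.names if hasattr(ag, "names") else np.array(["X"] * n)
    try:
        elements = np.asarray(ag.elements)
        if np.all(elements == ""):
            raise AttributeError
    except Exception:
        elements = np.array([element_from_name(nm) for nm in names])
    resnames = ag.resnames if hasattr(ag, "resnames") else np.array(["UNK"] * n)
    resids = ag.resids if hasattr(ag, "resids") else np.ones(n, dtype=int)
    try:
        chainids = np.asarray(ag.chainIDs)
    except Exception:
        try:
            chainids = np.asarray(ag.segids)
        except Exception:
            chainids = np.array(["A"] * n)
    chainids = np.where(chainids == "", "A", chainids)
    return Topology(np.asarray(names), elements, np.asarray(resnames),
                    np.asarray(resids), chainids)


def _dedupe_altlocs(universe):
    """AtomGroup keeping one altloc per (resid, name): the highest-occupancy one."""
    ag = universe.atoms
    try:
        altlocs = ag.altLocs
    except Exception:
        return ag
    if np.all((altlocs == "") | (altlocs == " ")):
        return ag
    try:
        occ = ag.occupancies
    except Exception:
        occ = np.ones(len(ag))
    best: dict[tuple, int] = {}
    for i in range(len(ag)):
        key = (str(ag.segids[i]) if hasattr(ag, "segids") else "", int(ag.resids[i]),
               str(ag.names[i]))
        if key not in best or occ[i] > occ[best[key]]:
            best[key] = i
    keep = np.sort(np.fromiter(best.values(), dtype=np.int64))
    return ag[keep]


def _check_icodes(universe) -> None:
    try:
        icodes = universe.atoms.icodes
    except Exception:
        return
    bad = set(str(c) for c in icodes) - {"", " "}
    if bad:
        raise FormatError(
            f"insertion codes {sorted(bad)} are not supported; renumber the structure")


def read_ensemble(topology_path, trajectory_path=None, selection: str | None = None) -> Ensemble:
    """Read a PDB topology (plus optional DCD/XTC/multi-model-PDB trajectory).

    Returns an :class:`Ensemble` with frames in file order and coordinates
    in Å. ``selection`` (MDAnalysis-style expression) restricts the atoms.
    """
    mda = _import_mda()
    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FormatError(f"topology file not found: {topology_path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory_path is None:
                u = mda.Universe(str(topology_path))
            else:
                trajectory_path = Path(trajectory_path)
                if not trajectory_path.exists():
                    raise FormatError(f"trajectory file not found: {trajectory_path}")
                u = mda.Universe(str(topology_path), str(trajectory_path))
    except FormatError:
        raise
    except Exception as exc:  # MDAnalysis raises assorted errors for bad files
        msg = str(exc)
        if "atoms" in msg.lower() and ("match" in msg.lower() or "number" in msg.lower()):
            raise FormatError(f"topology/trajectory atom-count mismatch: {msg}") from exc
        raise FormatError(f"could not read {topology_path}"
                          + (f" + {trajectory_path}" if trajectory_path else "")
                          + f": {msg}") from exc

    _check_icodes(u)
    ag = _dedupe_altlocs(u)
    if selection is not None:
        mask = select_atoms(_topology_from_atomgroup(ag), selection)
        ag = ag[mask.indices]
    if len(ag) == 0:
        raise InputError(f"selection {selection!r} matches no atoms in {topology_path}")

    topology = _topology_from_atomgroup(ag)
    coords = []
    times = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            coords.append(ag.positions.astype(np.float64).copy())
            times.append(ts.time)  # MDAnalysis time unit: ps
    coords = np.stack(coords, axis=0)
    times = np.asarray(times, dtype=np.float64) / 1000.0  # ps -> ns
    frame_times = times if (len(times) > 1 and np.any(np.diff(times) > 0)) else None
    return Ensemble(topology, coords, frame_times, label=topology_path.stem)


def write_ensemble(ensemble: Ensemble, topology_path, trajectory_path=None) -> None:
    """Write a PDB topology and optionally a DCD trajectory.

    Without ``trajectory_path`` a multi-model PDB holding every frame is
    written; with it, the PDB holds frame 0 and the DCD all frames.
    """
    mda = _import_mda()
    topo = ensemble.topology
    n = topo.n_atoms
    resk = topo.residue_keys()
    res_lookup = {(c, r): i for i, (c, r, _) in enumerate(resk)}
    atom_resindex = np.array([res_lookup[(str(c), int(r))]
                              for c, r in zip(topo.chainids, topo.resids)])
    chains_per_res = [c for c, _, _ in resk]
    seg_names = sorted(set(chains_per_res))
    seg_lookup = {s: i for i, s in enumerate(seg_names)}
    u = mda.Universe.empty(n, n_residues=len(resk), n_segments=len(seg_names),
                           atom_resindex=atom_resindex,
                           residue_segindex=np.array([seg_lookup[c] for c in chains_per_res]),
                           trajectory=True)
    u.add_TopologyAttr("names", topo.names)
    u.add_TopologyAttr("elements", topo.elements)
    u.add_TopologyAttr("resnames", [rn for _, _, rn in resk])
    u.add_TopologyAttr("resids", [r for _, r, _ in resk])
    u.add_TopologyAttr("segids", seg_names)
    u.add_TopologyAttr("chainIDs", [str(c)[:1] or "A" for c in topo.chainids])
    u.add_TopologyAttr("occupancies", np.ones(n))
    u.add_TopologyAttr("tempfactors", np.zeros(n))

    topology_path = Path(topology_path)
    topology_path.parent.mkdir(parents=True, exist_ok=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is None:
            with mda.Writer(str(topology_path), multiframe=ensemble.n_frames > 1, n_atoms=n) as w:
                for f in range(ensemble.n_frames):
                    u.atoms.positions = ensemble.coordinates[f]
                    w.write(u.atoms)
        else:
            u.atoms.positions = ensemble.coordinates[0]
            with mda.Writer(str(topology_path), n_atoms=n) as w:
                w.write(u.atoms)
            trajectory_path = Path(trajectory_path)
            with mda.Writer(str(trajectory_path), n_atoms=n) as w:
                for f in range(ensemble.n_frames):
                    u.atoms.positions = ensemble.coordinates[f]
                    w.write(u.atoms)


_RANGE_RE = re.compile(r"(?<=[\s,])(\d+)-(\d+)(?=[\s,)]|$)")


def _normalize_expression(expression: str) -> str:
    """Map literature-style residue lists (``resid 1-7,231-240``) onto MDAnalysis syntax."""
    expr = expression.replace(",", " ")
    return _RANGE_RE.sub(r"\1:\2", " " + expr)[1:]


def select_atoms(topology: Topology, expression: str) -> SelectionMask:
    """Resolve a selection expression against a topology.

    The grammar is MDAnalysis's (``name CA``, ``resid 771:777``, ``and``,
    ``or``, ``not``, parentheses), extended to accept comma-separated
    hyphen ranges as the structural-biology literature writes them.
    An empty result is a warning, not an error.
    """
    mda = _import_mda()
    from MDAnalysis.exceptions import SelectionError

    n = topology.n_atoms
    resk = topology.residue_keys()
    res_lookup = {(c, r): i for i, (c, r, _) in enumerate(resk)}
    atom_resindex = np.array([res_lookup[(str(c), int(r))]
                              for c, r in zip(topology.chainids, topology.resids)])
    u = mda.Universe.empty(n, n_residues=len(resk), atom_resindex=atom_resindex,
                           trajectory=False)
    u.add_TopologyAttr("names", topology.names)
    u.add_TopologyAttr("elements", topology.elements)
    u.add_TopologyAttr("resnames", [rn for _, _, rn in resk])
    u.add_TopologyAttr("resids", [r for _, r, _ in resk])
    u.add_TopologyAttr("chainIDs", [str(c)[:1] or "A" for c in topology.chainids])

    normalized = _normalize_expression(expression)
    try:
        ag = u.select_atoms(normalized)
    except SelectionError as exc:
        raise SelectionParseError(
            f"cannot parse selection {expression!r} (as {normalized!r}): {exc}") from exc
    if len(ag) == 0:
        warnings.warn(f"selection {expression!r} matches no atoms", stacklevel=2)
    return SelectionMask(ag.indices, provenance=expression)


def write_table(records, path, format: str = "csv") -> None:
    """Write a list of dict records (or a DataFrame) as CSV or JSON.

    Floats are kept to full round-trip precision; NaN serializes as an
    empty CSV field / JSON null.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if format == "csv":
        df.to_csv(path, index=False, na_rep="", float_format=lambda x: f"{x:.10g}")
    elif format == "json":
        df.to_json(path, orient="records", double_precision=10, indent=1)
    else:
        raise InputError(f"unknown table format {format!r} (csv or json)")


def read_table(path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "json":
        return pd.read_json(path, orient="records")
    raise InputError(f"unknown table format {fmt!r}")
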