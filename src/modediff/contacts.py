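"""Hydrogen-bond, salt-bridge and stacking analyses with honest error bars.

A contact's occupancy ("frequency") is the percentage of frames in which a
geometric criterion holds. Because contact time series are autocorrelated,
the standard error uses an effective sample size n_eff = n / (1 + 2*tau),
with tau the integrated autocorrelation time estimated by FFT with a Sokal
adaptive window. Replicate dispersion across independent simulations is
reported as the standard deviation over replicas.

Default geometric criteria (all configurable): hydrogen bond when the
donor–acceptor heavy-atom distance is <= 3.5 Å and the donor–H–acceptor
angle is >= 150°; salt bridge when the minimum side-chain N–O distance
between a basic and an acidic group is <= 4.0 Å; ring/side-chain stacking
tracked as mass-weighted center-of-mass distances with a 5.5 Å threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Ensemble, FunctionalSeries, InputError, ModeDiffError, SelectionMask

__all__ = ["ContactSeries", "ACFResult", "ConditionDiffTable", "StackingResult",
           "detect_hbonds", "autocorrelation", "detect_salt_bridges",
           "stacking_distances", "compare_conditions"]

# His imidazole nitrogens: pi (delta) = ND1, tau (epsilon) = NE2 in PDB naming
HIS_NITROGEN_NOTES = {"ND1": "pi(delta)", "NE2": "tau(epsilon)"}


@dataclass
class ACFResult:
    """Normalized autocorrelation function with integrated time and a
    convergence flag (ACF decays below 1/e within the first half)."""

    acf: np.ndarray
    tau: float          # integrated autocorrelation time, frames
    converged: bool
    window: int = 0


def autocorrelation(presence) -> ACFResult:
    """FFT autocorrelation of a (boolean or scalar) series.

    tau = sum of the ACF over an adaptive Sokal window (the summation stops
    at the first lag W with W >= 6 * tau(W)); a constant series has tau = 0
    and is trivially converged.
    """
    x = np.asarray(presence, dtype=np.float64).ravel()
    n = x.size
    if n < 20:
        raise InputError("autocorrelation needs at least 20 frames")
    var = x.var()
    if var < 1e-14:
        warnings.warn("constant series: autocorrelation undefined, tau = 0",
                      stacklevel=2)
        return ACFResult(np.zeros(n), 0.0, True, 0)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    acf = acov / acov[0]
    tau = 0.0
    window = 0
    c = 6.0
    for lag in range(1, n // 2):
        tau += acf[lag]
        window = lag
        if lag >= c * (0.5 + tau):
            break
    tau = max(tau, 0.0)
    half = acf[: max(n // 2, 2)]
    converged = bool(np.any(half < 1.0 / np.e))
    return ACFResult(acf, float(tau), converged, window)


@dataclass
class ContactSeries:
    """Per-frame presence of one donor–acceptor contact, with statistics."""

    donor: tuple          # (resid, resname, atom name)
    acceptor: tuple
    presence: np.ndarray
    kind: str = "hbond"
    note: str = ""

    frequency: float = field(init=False)   # %
    se: float = field(init=False)          # %, autocorrelation-corrected
    tau: float = field(init=False)         # frames
    converged: bool = field(init=False)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool).ravel()
        n = self.presence.size
        p = float(self.presence.mean())
        self.frequency = 100.0 * p
        if 0.0 < p < 1.0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = autocorrelation(self.presence)
            self.tau, self.converged = res.tau, res.converged
        else:
            self.tau, self.converged = 0.0, True
        n_eff = max(n / (1.0 + 2.0 * self.tau), 1.0)
        self.se = 100.0 * float(np.sqrt(p * (1.0 - p) / n_eff))

    @property
    def key(self) -> tuple:
        return (self.kind, int(self.donor[0]), str(self.donor[2]),
                int(self.acceptor[0]), str(self.acceptor[2]))

    def label(self) -> str:
        return (f"{self.donor[1]}{self.donor[0]}:{self.donor[2]}"
                f"->{self.acceptor[1]}{self.acceptor[0]}:{self.acceptor[2]}")


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle at b (degrees) for frames x 3 arrays."""
    v1 = a - b
    v2 = c - b
    cosang = np.sum(v1 * v2, axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1) + 1e-300)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _atom_tuple(topo, i: int) -> tuple:
    return (int(topo.resids[i]), str(topo.resnames[i]), str(topo.names[i]))


def detect_hbonds(ensemble: Ensemble, d_max: float = 3.5, angle_min: float = 150.0,
                  pairs=None, min_frequency: float = 5.0,
                  heavy_only: bool = False) -> list[ContactSeries]:
    """Geometric hydrogen-bond detection over all frames.

    Donors are N/O heavy atoms with a covalently attached hydrogen
    (H within 1.25 Å in frame 0); acceptors are N/O atoms of a different
    residue. A bond is present in a frame when the donor–acceptor distance
    is <= d_max and the donor–H–acceptor angle is >= angle_min. ``pairs``
    optionally restricts to (donor_resid, acceptor_resid) tuples; contacts
    below ``min_frequency`` % are dropped.

    With no hydrogens in the topology an error suggests ``heavy_only``
    mode, which applies the distance criterion alone (flagged in the note).
    """
    topo = ensemble.topology
    elements = np.char.upper(topo.elements.astype(str))
    is_h = elements == "H"
    is_no = (elements == "N") | (elements == "O")
    coords = ensemble.coordinates

    if not heavy_only and not is_h.any():
        raise ModeDiffError(
            "topology contains no hydrogens; re-run with heavy_only=True for a "
            "distance-only criterion")

    donors: list[tuple[int, int]] = []   # (heavy, hydrogen)
    if heavy_only:
        donors = [(i, -1) for i in np.flatnonzero(is_no)]
    else:
        h_idx = np.flatnonzero(is_h)
        heavy_idx = np.flatnonzero(is_no)
        if h_idx.size and heavy_idx.size:
            d0 = np.linalg.norm(coords[0, h_idx][:, None, :]
                                - coords[0, heavy_idx][None, :, :], axis=2)
            for hi, row in zip(h_idx, d0):
                j = int(np.argmin(row))
                if row[j] <= 1.25:
                    donors.append((int(heavy_idx[j]), int(hi)))
    acceptors = np.flatnonzero(is_no)

    restrict = None if pairs is None else {(int(a), int(b)) for a, b in pairs}
    out: list[ContactSeries] = []
    seen: set[tuple[int, int]] = set()
    for d_heavy, d_h in donors:
        for a in acceptors:
            if a == d_heavy or (d_heavy, a) in seen:
                continue
            if topo.resids[a] == topo.resids[d_heavy] and \
               topo.chainids[a] == topo.chainids[d_heavy]:
                continue
            if restrict is not None and \
               (int(topo.resids[d_heavy]), int(topo.resids[a])) not in restrict:
                continue
            dist = np.linalg.norm(coords[:, d_heavy] - coords[:, a], axis=1)
            present = dist <= d_max
            if not heavy_only and present.any():
                ang = _angle_deg(coords[:, d_heavy], coords[:, d_h], coords[:, a])
                present = present & (ang >= angle_min)
            if 100.0 * present.mean() < min_frequency:
                continue
            seen.add((d_heavy, a))
            note = "distance-only" if heavy_only else ""
            dn, an = str(topo.names[d_heavy]), str(topo.names[a])
            if str(topo.resnames[d_heavy]).upper() == "HIS" and dn in HIS_NITROGEN_NOTES:
                note = (note + " " if note else "") + f"donor {HIS_NITROGEN_NOTES[dn]}"
            if str(topo.resnames[a]).upper() == "HIS" and an in HIS_NITROGEN_NOTES:
                note = (note + " " if note else "") + f"acceptor {HIS_NITROGEN_NOTES[an]}"
            out.append(ContactSeries(_atom_tuple(topo, d_heavy), _atom_tuple(topo, a),
                                     present, kind="hbond", note=note))
    out.sort(key=lambda c: -c.frequency)
    return out


_BASIC = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
_ACIDIC = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def detect_salt_bridges(ensemble: Ensemble, d_max: float = 4.0,
                        min_frequency: float = 5.0) -> list[ContactSeries]:
    """Salt bridge present when the minimum basic-N to acidic-O side-chain
    distance is <= d_max (default 4.0 Å)."""
    topo = ensemble.topology
    coords = ensemble.coordinates

    def _group_atoms(table):
        groups: dict[tuple, list[int]] = {}
        for i in range(topo.n_atoms):
            rn = str(topo.resnames[i]).upper()
            if rn in table and str(topo.names[i]) in table[rn]:
                groups.setdefault((str(topo.chainids[i]), int(topo.resids[i]), rn),
                                  []).append(i)
        return groups

    basics = _group_atoms(_BASIC)
    acidics = _group_atoms(_ACIDIC)
    out: list[ContactSeries] = []
    for (bc, br, brn), bidx in basics.items():
        for (ac, ar, arn), aidx in acidics.items():
            d = np.linalg.norm(coords[:, bidx][:, :, None, :]
                               - coords[:, aidx][:, None, :, :], axis=3)
            dmin = d.min(axis=(1, 2))
            present = dmin <= d_max
            if 100.0 * present.mean() < min_frequency:
                continue
            out.append(ContactSeries((br, brn, "sidechain-N"), (ar, arn, "sidechain-O"),
                                     present, kind="saltbridge"))
    out.sort(key=lambda c: -c.frequency)
    return out


@dataclass
class StackingResult:
    """Center-of-mass distance between two atom groups across frames."""

    pair: tuple[str, str]
    series: FunctionalSeries
    fraction_within: float
    threshold: float


def stacking_distances(ensemble: Ensemble, groups, threshold: float = 5.5,
                       labels=None) -> list[StackingResult]:
    """Mass-weighted COM–COM distances for every pair of atom groups, plus
    the fraction of frames within the stacking threshold."""
    masses = ensemble.topology.masses()
    resolved = []
    for g in groups:
        idx = g.indices if isinstance(g, SelectionMask) else np.asarray(g, dtype=np.int64)
        if idx.size == 0:
            raise InputError("empty atom group in stacking analysis")
        resolved.append(idx)
    labels = labels or [f"group{i+1}" for i in range(len(resolved))]
    out: list[StackingResult] = []
    for i in range(len(resolved)):
        for j in range(i + 1, len(resolved)):
            coms = []
            for idx in (resolved[i], resolved[j]):
                w = masses[idx]
                coms.append(np.einsum("fad,a->fd", ensemble.coordinates[:, idx], w)
                            / w.sum())
            d = np.linalg.norm(coms[0] - coms[1], axis=1)
            series = FunctionalSeries(d, units="Å",
                                      name=f"com({labels[i]},{labels[j]})",
                                      frame_times=ensemble.frame_times)
            out.append(StackingResult((labels[i], labels[j]), series,
                                      float((d <= threshold).mean()), threshold))
    return out


@dataclass
class ConditionDiffTable:
    """Per-contact condition comparison with gained/lost/shifted flags."""

    table: pd.DataFrame
    labels: tuple[str, str]
    thresholds: dict


def _condition_stats(replicas: list[list[ContactSeries]]):
    """{contact key: (mean %, sd %, label)} over replicas; absent = 0%."""
    keys: dict[tuple, str] = {}
    for rep in replicas:
        for c in rep:
            keys.setdefault(c.key, c.label())
    stats = {}
    for key, label in keys.items():
        freqs = []
        for rep in replicas:
            hit = next((c for c in rep if c.key == key), None)
            freqs.append(hit.frequency if hit is not None else 0.0)
        freqs = np.asarray(freqs)
        sd = float(freqs.std(ddof=1)) if freqs.size > 1 else np.nan
        stats[key] = (float(freqs.mean()), sd, label, freqs)
    return stats


def compare_conditions(cond_a: list[list[ContactSeries]],
                       cond_b: list[list[ContactSeries]],
                       labels: tuple[str, str] = ("A", "B"),
                       gain_loss_low: float = 10.0, gain_loss_high: float = 40.0,
                       shift_threshold: float = 25.0) -> ConditionDiffTable:
    """Compare contact frequencies between two conditions.

    Each condition is a list of replicas, each replica a list of
    ContactSeries; contacts are matched by (kind, donor, acceptor) with
    absent contacts counted at 0%. A contact is ``lost`` when the first
    condition's mean is above ``gain_loss_high`` and the second's below
    ``gain_loss_low`` (``gained`` for the reverse), ``shifted`` when the
    mean difference exceeds ``shift_threshold``, else ``unchanged``.
    A single replica per condition is allowed but leaves the SD undefined.
    """
    if not cond_a or not cond_b:
        raise InputError("both conditions need at least one replica")
    if len(cond_a) < 2 or len(cond_b) < 2:
        warnings.warn("fewer than 2 replicas in a condition: SD undefined",
                      stacklevel=2)
    sa = _condition_stats(cond_a)
    sb = _condition_stats(cond_b)
    rows = []
    for key in sorted(set(sa) | set(sb)):
        ma, sda, label, fa = sa.get(key, (0.0, np.nan, None, np.zeros(len(cond_a))))
        mb, sdb, label_b, fb = sb.get(key, (0.0, np.nan, None, np.zeros(len(cond_b))))
        label = label or label_b
        diff = mb - ma
        if ma > gain_loss_high and mb < gain_loss_low:
            flag = "lost"
        elif mb > gain_loss_high and ma < gain_loss_low:
            flag = "gained"
        elif abs(diff) > shift_threshold:
            flag = "shifted"
        else:
            flag = "unchanged"
        rows.append({"contact": label, "kind": key[0],
                     "donor_resid": key[1], "donor_atom": key[2],
                     "acceptor_resid": key[3], "acceptor_atom": key[4],
                     f"mean_{labels[0]}": ma, f"sd_{labels[0]}": sda,
                     f"mean_{labels[1]}": mb, f"sd_{labels[1]}": sdb,
                     "difference": diff, "flag": flag})
    table = pd.DataFrame(rows)
    return ConditionDiffTable(table, labels,
                              {"gain_loss_low": gain_loss_low,
                               "gain_loss_high": gain_loss_high,
                               "shift_threshold": shift_threshold})
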