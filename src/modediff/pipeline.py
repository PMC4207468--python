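"""Configuration-driven orchestration of the full two-condition workflow.

``run_pipeline`` executes read -> window-slice -> superpose -> {rmsd, rmsf,
cluster, pca + projection overlap, rmsip, fma (linear + MI), contacts,
sasa} -> condition comparison, writing CSV/JSON tables plus a manifest
report with parameter echo, per-stage timings, warnings and a sha256
checksum for every output file. ``make_fixture`` writes a complete small
synthetic two-condition x five-replica dataset (PDB + DCD through the
public file interface) together with a matching config and the planted
ground truth, so the whole pipeline is testable end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import analysis, contacts, fma, io, modes, synthetic
from .core import Ensemble, InputError, ModeDiffError

__all__ = ["AnalysisConfig", "Report", "StageError", "run_pipeline", "make_fixture"]

log = logging.getLogger("modediff")

ALL_STAGES = ("rmsd", "rmsf", "cluster", "pca", "rmsip", "fma", "contacts",
              "sasa", "compare")


class StageError(ModeDiffError):
    """A pipeline stage failed; carries the stage name and partial report."""

    def __init__(self, stage: str, cause: Exception, report: "Report"):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.report = report


@dataclass
class ReplicaSpec:
    topology: str
    trajectory: str | None = None
    window_ns: tuple[float, float] | None = None
    contacts_topology: str | None = None
    contacts_trajectory: str | None = None


@dataclass
class ConditionSpec:
    name: str
    replicas: list[ReplicaSpec] = field(default_factory=list)


@dataclass
class AnalysisConfig:
    """Everything one run needs: inputs, selections, and stage parameters."""

    conditions: list[ConditionSpec] = field(default_factory=list)
    fit_selection: str = "name CA"
    exclude_selection: str | None = None     # flexible loops left out of RMSD
    active_site_selection: str | None = None
    hinge_residues: tuple[int, int] = (781, 922)
    cluster_cutoff: float = 1.0
    overlap_bins: int = 25
    rmsip_d: int = 10
    fma_split_linear: float = 0.7
    fma_split_mi: float = 0.8
    fma_k_scan: list[int] = field(default_factory=lambda: [2, 3, 5, 8])
    fma_k_cap: int = 20
    fma_restarts: int = 8
    fma_max_eval_points: int = 1500
    hbond_d_max: float = 3.5
    hbond_angle_min: float = 150.0
    contact_min_frequency: float = 5.0
    diff_gain_loss_low: float = 10.0
    diff_gain_loss_high: float = 40.0
    diff_shift_threshold: float = 25.0
    sasa_probe: float = 1.4
    sasa_points: int = 960
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    output_dir: str = "modediff-out"

    def validate(self) -> None:
        if not self.conditions:
            raise InputError("config lists no conditions")
        for cond in self.conditions:
            if not cond.replicas:
                raise InputError(f"condition {cond.name!r} has no replicas")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise InputError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")
        if max(self.fma_k_scan, default=0) >= self.fma_k_cap:
            raise InputError("fma_k_scan exceeds the over-fitting cap fma_k_cap")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        conds = []
        for c in d.pop("conditions", []):
            reps = [ReplicaSpec(**{**r, "window_ns": tuple(r["window_ns"])
                                   if r.get("window_ns") else None})
                    for r in c.get("replicas", [])]
            conds.append(ConditionSpec(name=c["name"], replicas=reps))
        if "hinge_residues" in d:
            d["hinge_residues"] = tuple(d["hinge_residues"])
        cfg = cls(conditions=conds, **d)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class Report:
    """Versioned manifest of a pipeline run."""

    config: dict
    seed: int
    stages_run: list[str] = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # path -> sha256
    warnings: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def register(self, path) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        self.outputs[str(p)] = digest

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ----------------------------------------------------------------- pipeline

def _load_condition(cond: ConditionSpec, cfg: AnalysisConfig):
    main, contact_ens = [], []
    for rep in cond.replicas:
        ens = io.read_ensemble(rep.topology, rep.trajectory)
        if rep.window_ns is not None and ens.frame_times is not None:
            ens = ens.window_ns(*rep.window_ns)
        ens.label = f"{cond.name}:{Path(rep.topology).stem}"
        main.append(ens)
        if rep.contacts_topology:
            ce = io.read_ensemble(rep.contacts_topology, rep.contacts_trajectory)
            contact_ens.append(ce)
        else:
            contact_ens.append(None)
    return main, contact_ens


def run_pipeline(config: AnalysisConfig) -> Report:
    """Execute the configured stages; returns (and writes) the report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = Report(config=config.to_dict(), seed=config.seed)
    caught: list[warnings.WarningMessage] = []

    def _stage(name: str):
        return name in config.stages

    def _run(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            with warnings.catch_warnings(record=True) as w:
                warnings.simplefilter("always")
                fn()
            caught.extend(w)
        except Exception as exc:
            report.warnings.extend(str(x.message) for x in caught)
            report.save(out / "report.json")
            raise StageError(name, exc, report) from exc
        report.stages_run.append(name)
        report.timings_s[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.2fs", name, report.timings_s[name])

    data: dict[str, list[Ensemble]] = {}
    contact_data: dict[str, list] = {}

    def load_and_superpose():
        for cond in config.conditions:
            main, cont = _load_condition(cond, config)
            fit_mask = io.select_atoms(main[0].topology, config.fit_selection)
            data[cond.name] = [analysis.superpose(e, fit_mask, "mean") for e in main]
            contact_data[cond.name] = cont

    _run("load", load_and_superpose)
    cond_names = [c.name for c in config.conditions]

    def rmsd_stage():
        rows = []
        for cname in cond_names:
            for ens in data[cname]:
                expr = config.fit_selection
                if config.exclude_selection:
                    expr = f"({expr}) and not ({config.exclude_selection})"
                mask = io.select_atoms(ens.topology, expr)
                series = analysis.rmsd_series(ens, reference="mean", mask=mask)
                for t, v in enumerate(series.values):
                    rows.append({"replica": ens.label, "frame": t, "rmsd_A": v})
        io.write_table(rows, out / "rmsd.csv")
        report.register(out / "rmsd.csv")

    def rmsf_stage():
        for cname in cond_names:
            mask = io.select_atoms(data[cname][0].topology, config.fit_selection)
            prof = analysis.rmsf_profile(data[cname], mask)
            path = out / f"rmsf_{cname}.csv"
            io.write_table(prof.to_frame(), path)
            report.register(path)
            report.summary[f"rmsf_mean_{cname}"] = float(prof.mean.mean())

    def cluster_stage():
        rows = []
        for cname in cond_names:
            ens = data[cname][0]
            mask = io.select_atoms(ens.topology, config.fit_selection)
            res = analysis.cluster_gromos(ens, mask, config.cluster_cutoff)
            for f, lab in enumerate(res.labels):
                rows.append({"condition": cname, "frame": f, "cluster": int(lab)})
            report.summary[f"clusters_{cname}"] = res.populations[:3]
            rep_path = out / f"cluster1_rep_{cname}.pdb"
            io.write_ensemble(ens.slice_frames(res.centroids[0], res.centroids[0] + 1),
                              rep_path)
            report.register(rep_path)
        io.write_table(rows, out / "clusters.csv")
        report.register(out / "clusters.csv")

    decs: dict[str, list[modes.ModeDecomposition]] = {}

    def pca_stage():
        rows = []
        for cname in cond_names:
            mask = io.select_atoms(data[cname][0].topology, config.fit_selection)
            decs[cname] = [modes.pca(e, mask) for e in data[cname]]
            base = modes.project(data[cname][0], decs[cname][0], 2)
            for j, ens in enumerate(data[cname][1:], start=2):
                other = modes.project(ens, decs[cname][0], 2)
                ov = modes.projection_overlap(base, other, config.overlap_bins)
                rows.append({"condition": cname, "pair": f"r1-r{j}", "overlap": ov})
        io.write_table(rows, out / "projection_overlap.csv")
        report.register(out / "projection_overlap.csv")
        if rows:
            report.summary["projection_overlap_mean"] = float(
                np.mean([r["overlap"] for r in rows]))

    def rmsip_stage():
        if not decs:
            pca_stage()
        d = config.rmsip_d
        rows = []
        baselines = {c: float(np.mean([modes.split_half_rmsip(
            e, io.select_atoms(e.topology, config.fit_selection), d)
            for e in data[c]])) for c in cond_names}
        for ci, ca in enumerate(cond_names):
            for cj in cond_names[ci:]:
                vals = []
                for i, da in enumerate(decs[ca]):
                    for j, db in enumerate(decs[cj]):
                        if ca == cj and j <= i:
                            continue
                        dd = min(d, da.n_modes, db.n_modes)
                        ov = modes.rmsip(da, db, dd, baseline=baselines[ca])
                        vals.append(ov.value)
                        rows.append({"pair": f"{ca}{i+1}-{cj}{j+1}", "d": dd,
                                     "rmsip": ov.value,
                                     "rmsip_normalized": ov.normalized,
                                     "scheme": ov.scheme})
                if vals:
                    tag = f"rmsip_{ca}_{cj}" if ca != cj else f"rmsip_within_{ca}"
                    report.summary[tag] = float(np.mean(vals))
        io.write_table(rows, out / "rmsip.csv")
        report.register(out / "rmsip.csv")

    def fma_stage():
        if not decs:
            pca_stage()
        for cname in cond_names:
            ens = data[cname][0]
            dec = decs[cname][0]
            kmax = max(config.fma_k_scan)
            proj = modes.project(ens, dec, min(kmax, dec.n_modes))
            ks = [k for k in config.fma_k_scan if k <= proj.k]
            # hinge distance -> linear FMA
            try:
                f_lin = fma.hinge_distance(ens, *config.hinge_residues)
            except InputError:
                warnings.warn(f"hinge residues {config.hinge_residues} not in "
                              f"{cname}; skipping linear FMA")
                f_lin = None
            if f_lin is not None:
                scan = fma.scan_basis_sizes(proj, f_lin, ks, "pearson",
                                            split=config.fma_split_linear)
                try:
                    k_sel = fma.select_basis_size(scan)
                except InputError as exc:
                    warnings.warn(f"linear FMA basis selection failed for {cname}: {exc}")
                    k_sel = ks[0]
                model = fma.fit_linear_fma(proj, f_lin, config.fma_split_linear, k_sel)
                io.write_table(scan.to_frame(), out / f"fma_linear_scan_{cname}.csv")
                report.register(out / f"fma_linear_scan_{cname}.csv")
                report.summary[f"fma_linear_{cname}"] = {
                    "k": model.k, "r_m": model.r_m, "r_c": model.r_c}
                rendered = fma.render_mode(model, dec, np.linspace(-3, 3, 7),
                                           topology=ens.topology.subset(
                                               dec.atom_indices)
                                           if dec.atom_indices is not None
                                           else None)
                io.write_ensemble(rendered, out / f"fma_linear_mode_{cname}.pdb")
                report.register(out / f"fma_linear_mode_{cname}.pdb")
            # active-site RMSD -> MI FMA
            if config.active_site_selection:
                site = io.select_atoms(ens.topology, config.active_site_selection)
                if len(site):
                    f_mi = fma.active_site_rmsd(ens, site, "mean")
                    model = fma.fit_mi_fma(
                        proj, f_mi, config.fma_split_mi,
                        k=min(ks[-1], proj.k), seed=config.seed,
                        k_cap=config.fma_k_cap, n_restarts=config.fma_restarts,
                        max_eval_points=config.fma_max_eval_points)
                    report.summary[f"fma_mi_{cname}"] = {
                        "k": model.k, "r_m": model.r_m, "r_c": model.r_c,
                        "mi_nats": model.mi_nats}
                    scatter = [{"frame": t, "f": f_mi.values[t],
                                "model": float(v), "segment":
                                    "model" if t < model.n_model else "cv"}
                               for t, v in enumerate(model.predict(proj.values))]
                    io.write_table(scatter, out / f"fma_mi_scatter_{cname}.csv")
                    report.register(out / f"fma_mi_scatter_{cname}.csv")

    hbond_tables: dict[str, list[list[contacts.ContactSeries]]] = {}

    def contacts_stage():
        rows = []
        for cname in cond_names:
            per_rep = []
            for ens, cont in zip(data[cname], contact_data[cname]):
                source = cont if cont is not None else ens
                try:
                    found = contacts.detect_hbonds(
                        source, config.hbond_d_max, config.hbond_angle_min,
                        min_frequency=config.contact_min_frequency)
                except ModeDiffError:
                    found = contacts.detect_hbonds(
                        source, config.hbond_d_max, config.hbond_angle_min,
                        min_frequency=config.contact_min_frequency, heavy_only=True)
                per_rep.append(found)
                for c in found:
                    if not c.converged:
                        warnings.warn(f"contact {c.label()} in {ens.label}: "
                                      "autocorrelation not converged")
                    rows.append({"condition": cname, "replica": ens.label,
                                 "contact": c.label(), "frequency_pct": c.frequency,
                                 "se_pct": c.se, "tau_frames": c.tau,
                                 "converged": c.converged, "note": c.note})
            hbond_tables[cname] = per_rep
        io.write_table(rows, out / "hbonds.csv")
        report.register(out / "hbonds.csv")

    def sasa_stage():
        for cname in cond_names:
            site = (io.select_atoms(data[cname][0].topology,
                                    config.active_site_selection)
                    if config.active_site_selection else None)
            prof = analysis.sasa_profile(data[cname], site,
                                         probe=config.sasa_probe,
                                         n_points=config.sasa_points)
            path = out / f"sasa_{cname}.csv"
            io.write_table(prof.to_frame(), path)
            report.register(path)
            report.summary[f"sasa_mean_{cname}"] = float(prof.mean.mean())

    def compare_stage():
        if len(cond_names) < 2 or not hbond_tables:
            return
        a, b = cond_names[0], cond_names[1]
        diff = contacts.compare_conditions(
            hbond_tables[a], hbond_tables[b], labels=(a, b),
            gain_loss_low=config.diff_gain_loss_low,
            gain_loss_high=config.diff_gain_loss_high,
            shift_threshold=config.diff_shift_threshold)
        io.write_table(diff.table, out / "condition_diff.csv")
        report.register(out / "condition_diff.csv")
        report.summary["condition_diff_flags"] = dict(
            diff.table["flag"].value_counts())

    stage_fns = {"rmsd": rmsd_stage, "rmsf": rmsf_stage, "cluster": cluster_stage,
                 "pca": pca_stage, "rmsip": rmsip_stage, "fma": fma_stage,
                 "contacts": contacts_stage, "sasa": sasa_stage,
                 "compare": compare_stage}
    for name in ALL_STAGES:
        if _stage(name):
            _run(name, stage_fns[name])

    report.warnings.extend(sorted({str(w.message) for w in caught}))
    report.save(out / "report.json")
    return report


# ------------------------------------------------------------------ fixture

def make_fixture(out_dir, seed: int = 0, replicas: int = 5, n_frames: int = 240,
                 n_residues: int = 40, contact_frames: int = 600) -> Path:
    """Write a synthetic two-condition x ``replicas`` dataset + config.

    Conditions share nothing but size: each has its own planted mode basis
    and spectrum (condition B more concentrated in its first mode), so
    cross-condition RMSIP is depressed relative to within-condition RMSIP
    and RMSF profiles differ. Four hydrogen-bond fragments are planted per
    replica with occupancies chosen to exercise every condition-difference
    flag: lost (92% -> 5%), gained (5% -> 92%), shifted (85% -> 50%) and
    unchanged (60% -> 60%). Ground truth lands in ``ground_truth.json``.

    Returns the path of the written config.yaml.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec_a = synthetic.EnsembleSpec(n_residues, [6.0, 4.0, 2.5, 1.5, 1.0], seed=11)
    spec_b = synthetic.EnsembleSpec(n_residues, [9.0, 3.0, 1.5, 1.0, 0.5], seed=77)
    ensembles = synthetic.generate_condition_set(
        spec_a, spec_b, replicas, n_frames, seed, labels=("WT", "MUT"))

    bond_plan = [  # (name, p_WT, p_MUT, expected flag WT->MUT)
        ("lost", 0.92, 0.05, "lost"),
        ("gained", 0.05, 0.92, "gained"),
        ("shifted", 0.85, 0.50, "shifted"),
        ("unchanged", 0.60, 0.60, "unchanged"),
    ]
    q = 0.5

    conds: list[ConditionSpec] = []
    for cname in ("WT", "MUT"):
        reps = []
        members = [e for e in ensembles if e.label.startswith(cname + "-")]
        for ri, ens in enumerate(members):
            top = out / f"{cname}_r{ri+1}.pdb"
            trj = out / f"{cname}_r{ri+1}.dcd"
            io.write_ensemble(ens, top, trj)
            frags = []
            for bi, (_, p_wt, p_mut, _) in enumerate(bond_plan):
                p = p_wt if cname == "WT" else p_mut
                cseed = seed + 10_000 + 100 * bi + 10 * ri + (0 if cname == "WT" else 5)
                frags.append(synthetic.plant_contact_dynamics(
                    synthetic.ContactPlantSpec(p=p, q=q, seed=cseed), contact_frames))
            combined = synthetic.combine_contact_fragments(frags)
            ctop = out / f"{cname}_r{ri+1}_contacts.pdb"
            ctrj = out / f"{cname}_r{ri+1}_contacts.dcd"
            io.write_ensemble(combined, ctop, ctrj)
            reps.append(ReplicaSpec(topology=str(top), trajectory=str(trj),
                                    window_ns=None,
                                    contacts_topology=str(ctop),
                                    contacts_trajectory=str(ctrj)))
        conds.append(ConditionSpec(name=cname, replicas=reps))

    cfg = AnalysisConfig(
        conditions=conds,
        fit_selection="name CA",
        exclude_selection="resid 1-3",
        active_site_selection="resid 10-16",
        hinge_residues=(5, n_residues - 5),
        cluster_cutoff=0.9,
        overlap_bins=10,
        rmsip_d=5,
        fma_k_scan=[2, 3, 5],
        fma_restarts=2,
        fma_max_eval_points=600,
        seed=seed,
        output_dir=str(out / "results"),
    )
    cfg_path = out / "config.yaml"
    cfg.to_yaml(cfg_path)

    truth = {
        "bonds": [{"name": nm, "p_WT": p_wt, "p_MUT": p_mut, "flag": flag,
                   "donor_resid": 1 + 2 * bi}  # fragments renumber 2 residues each
                  for bi, (nm, p_wt, p_mut, flag) in enumerate(bond_plan)],
        "eigenvalues_WT": spec_a.eigenvalues.tolist(),
        "eigenvalues_MUT": spec_b.eigenvalues.tolist(),
        "replicas": replicas, "n_frames": n_frames, "seed": seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return cfg_path
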