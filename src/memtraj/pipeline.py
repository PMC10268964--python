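"""Comparative study driver: run every analysis on labelled ensembles.

A study holds one entry per model (e.g. a ligand-bound complex vs its apo
receptor), each with one or more replica trajectories. Replica-level
matrices and profiles are averaged elementwise before domain aggregation;
differential domain matrices are computed between the replica-averaged
matrices of every model pair. Time series (angles, distances, contacts)
follow the first replica, the usual convention for time-resolved plots,
while scalar statistics are replica means. The manifest records every
parameter in effect, defaults included, so a rerun from the manifest is
exactly reproducible.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import correlation as corr_mod
from . import essential, geometry, interactions, solvation
from .core import DomainPartition, FrameSelection, Topology, Trajectory, select_frames
from .fitting import FluctuationProfile, rmsf_profile
from .io import read_partition, read_topology, read_trajectory

__all__ = ["ModelEntry", "AnalysisPlan", "StudyConfig", "replica_average",
           "run_study", "load_config"]

log = logging.getLogger("memtraj")


@dataclass
class ModelEntry:
    label: str
    topology: "Topology | str"
    trajectories: list
    partition: "DomainPartition | str"

    def load(self) -> tuple[Topology, DomainPartition, list[Trajectory]]:
        topo = (read_topology(self.topology)
                if isinstance(self.topology, str) else self.topology)
        part = (read_partition(self.partition)
                if isinstance(self.partition, str) else self.partition)
        trajs = [read_trajectory(t, topo) if isinstance(t, str) else t
                 for t in self.trajectories]
        for t in trajs:
            t.check_atoms(topo)
        return topo, part, trajs


@dataclass
class AnalysisPlan:
    """Toggles and parameters for the analysis stages.

    Selection arguments are keyword dictionaries for ``Topology.select``
    (e.g. ``{"chains": ["W"]}``). ``align_domains`` names the partition
    domains used as the superposition anchor for the correlation and RMSF
    stages; by default all domains are used.
    """

    correlation: bool = True
    align_domains: list[str] | None = None
    rmsf: bool = True
    pca: bool = True
    n_modes: int = 10
    crossing: tuple | None = None        # ((chain, first, last), (chain, first, last))
    tilt: dict | None = None             # {"tail": sel, "head": sel, "axis": "z"}
    com_distance: dict | None = None     # {"a": sel, "b": sel}
    hbonds: dict | None = None           # {"donors": sel, "acceptors": sel,
    #                                       "distance_cutoff": 3.0, "angle_cutoff": 135.0}
    contacts: dict | None = None         # {"a": sel, "b": sel, "cutoff": 4.5}
    rdf: dict | None = None              # {"centers": sel, "probes": sel,
    #                                       "bin_width": 0.1, "r_max": 10.0}


@dataclass
class StudyConfig:
    models: list[ModelEntry]
    output_dir: str
    frame_selection: FrameSelection = field(default_factory=FrameSelection)
    plan: AnalysisPlan = field(default_factory=AnalysisPlan)
    seed: int = 0

    def __post_init__(self):
        if not self.models:
            raise ValueError("a study needs at least one model")
        labels = [m.label for m in self.models]
        if len(set(labels)) != len(labels):
            raise ValueError("model labels must be unique")
        for m in self.models:
            if not m.trajectories:
                raise ValueError(f"model {m.label!r} has no replica trajectories")


def replica_average(objects: list):
    """Elementwise mean of same-shaped matrices or profiles."""
    if not objects:
        raise ValueError("nothing to average")
    first = objects[0]
    if isinstance(first, corr_mod.CorrelationMatrix):
        for o in objects[1:]:
            if (o.residue_indices.shape != first.residue_indices.shape
                    or np.any(o.residue_indices != first.residue_indices)):
                raise ValueError("residue maps differ between replicas")
        mat = np.mean([o.matrix for o in objects], axis=0)
        return corr_mod.CorrelationMatrix(
            first.residue_indices.copy(), list(first.labels), mat,
            is_difference=first.is_difference)
    if isinstance(first, corr_mod.DomainMatrix):
        for o in objects[1:]:
            if o.domain_names != first.domain_names:
                raise ValueError("domain names differ between replicas")
        mat = np.mean([o.matrix for o in objects], axis=0)
        return corr_mod.DomainMatrix(list(first.domain_names), mat,
                                     is_difference=first.is_difference)
    if isinstance(first, FluctuationProfile):
        for o in objects[1:]:
            if o.residue_labels != first.residue_labels:
                raise ValueError("residue labels differ between replicas")
        rmsf = np.mean([o.rmsf for o in objects], axis=0)
        bf = np.mean([o.bfactor for o in objects], axis=0)
        return FluctuationProfile(list(first.residue_labels), rmsf, bf)
    arrs = [np.asarray(o) for o in objects]
    for a in arrs[1:]:
        if a.shape != arrs[0].shape:
            raise ValueError("shapes differ between replicas")
    return np.mean(arrs, axis=0)


def _write_csv(path: str, df: pd.DataFrame, **kwargs) -> None:
    df.to_csv(path, float_format="%.10g", **kwargs)


def _anchor_atoms(plan: AnalysisPlan, topo: Topology, part: DomainPartition) -> np.ndarray:
    if plan.align_domains is None:
        doms = part.names
    else:
        doms = plan.align_domains
    per_dom = part.atom_indices(topo, names=["CA"])
    return np.sort(np.concatenate([per_dom[d] for d in doms]))


def _run_model(entry: ModelEntry, cfg: StudyConfig, outdir: str) -> dict:
    plan = cfg.plan
    topo, part, raw = entry.load()
    trajs = [select_frames(t, cfg.frame_selection) for t in raw]
    os.makedirs(outdir, exist_ok=True)
    results: dict = {"label": entry.label, "n_replicas": len(trajs)}

    protein_res = part.residue_indices(topo)
    protein_ca = np.sort(np.concatenate(
        [topo.select(names=["CA"], residues=r) for r in protein_res.values()]))
    anchor = _anchor_atoms(plan, topo, part)

    if plan.correlation:
        ccms = [corr_mod.dccm(t, topo, selection=protein_ca,
                              align_selection=anchor) for t in trajs]
        ccm = replica_average(ccms)
        dm = corr_mod.domain_matrix(ccm, part, topo)
        _write_csv(os.path.join(outdir, "dccm.csv"), ccm.to_frame())
        _write_csv(os.path.join(outdir, "domain_matrix.csv"), dm.to_frame())
        _write_csv(os.path.join(outdir, "domain_matrix_long.csv"),
                   dm.to_long(), index=False)
        results["ccm"] = ccm
        results["domain_matrix"] = dm

    if plan.rmsf:
        profs = [rmsf_profile(t, topo, align_selection=anchor,
                              report_selection=protein_ca) for t in trajs]
        prof = replica_average(profs)
        _write_csv(os.path.join(outdir, "rmsf.csv"), pd.DataFrame({
            "residue": prof.residue_labels, "rmsf_A": prof.rmsf,
            "bfactor_A2": prof.bfactor}), index=False)
        results["rmsf"] = prof

    if plan.pca:
        eig = essential.pca(trajs[0], topo, selection=protein_ca)
        k = min(plan.n_modes, eig.eigenvalues.size)
        _write_csv(os.path.join(outdir, "eigenvalues.csv"), pd.DataFrame({
            "mode": np.arange(1, k + 1),
            "eigenvalue_A2_amu": eig.eigenvalues[:k],
            "cumulative_variance": eig.cumulative_variance[:k]}), index=False)
        proj = essential.project(trajs[0], eig, 0)
        _write_csv(os.path.join(outdir, "projection_pc1.csv"), pd.DataFrame({
            "frame": np.arange(proj.values.size), "projection": proj.values}),
            index=False)
        results["eigensystem"] = eig

    if plan.crossing is not None:
        ha, hb = plan.crossing
        series = geometry.crossing_angle_series(trajs[0], topo,
                                                tuple(ha), tuple(hb))
        _write_csv(os.path.join(outdir, "crossing_angle.csv"), pd.DataFrame({
            "frame": np.arange(series.values.size),
            "angle_deg": series.values}), index=False)
        results["crossing_mean_deg"] = float(series.values.mean())

    if plan.tilt is not None:
        spec = geometry.VectorSpec.between(plan.tilt["tail"], plan.tilt["head"],
                                           label="tilt")
        series = geometry.axis_angle_series(trajs[0], topo, spec,
                                            axis=plan.tilt.get("axis", "z"))
        _write_csv(os.path.join(outdir, "tilt_angle.csv"), pd.DataFrame({
            "frame": np.arange(series.values.size),
            "angle_deg": series.values}), index=False)
        results["tilt_mean_deg"] = float(series.values.mean())

    if plan.com_distance is not None:
        sa = topo.select(**plan.com_distance["a"])
        sb = topo.select(**plan.com_distance["b"])
        per_rep = [geometry.com_distance_series(t, topo, sa, sb) for t in trajs]
        _write_csv(os.path.join(outdir, "com_distance.csv"), pd.DataFrame({
            "frame": np.arange(per_rep[0].size), "distance_A": per_rep[0]}),
            index=False)
        results["com_distance_mean_A"] = float(np.mean([s.mean() for s in per_rep]))

    if plan.hbonds is not None:
        donors = topo.select(**plan.hbonds["donors"])
        acceptors = topo.select(**plan.hbonds["acceptors"])
        crit = interactions.HBondCriterion(
            plan.hbonds.get("distance_cutoff", 3.0),
            plan.hbonds.get("angle_cutoff", 135.0))
        tables = []
        for t in trajs:
            bonds = interactions.detect_hbonds(t, topo, donors, acceptors, crit)
            tables.append(interactions.occupancy_table(bonds, topo))
        merged = (pd.concat(tables).groupby(["donor", "acceptor"], sort=True)
                  .agg(frames_present=("frames_present", "sum"),
                       frames_total=("frames_total", "sum"))
                  .reset_index())
        merged["occupancy_pct"] = (100.0 * merged.frames_present
                                   / merged.frames_total)
        _write_csv(os.path.join(outdir, "hbond_occupancy.csv"), merged,
                   index=False)
        results["hbond_occupancy"] = merged

    if plan.contacts is not None:
        sa = topo.select(**plan.contacts["a"])
        sb = topo.select(**plan.contacts["b"])
        cutoff = plan.contacts.get("cutoff", interactions.DEFAULT_CONTACT_CUTOFF)
        series = interactions.contact_count_series(trajs[0], topo, sa, sb, cutoff)
        df = series.to_frame()
        with open(os.path.join(outdir, "contacts.csv"), "w") as fh:
            fh.write(f"# contact cutoff: {cutoff} A\n")
            df.to_csv(fh, index=False, float_format="%.10g")
        results["contacts_mean"] = float(series.counts.mean())

    if plan.rdf is not None:
        centers = topo.select(**plan.rdf["centers"])
        probes = topo.select(**plan.rdf["probes"])
        prof = solvation.rdf(trajs[0], topo, centers, probes,
                             bin_width=plan.rdf.get("bin_width", 0.1),
                             r_max=plan.rdf.get("r_max", 10.0))
        _write_csv(os.path.join(outdir, "rdf.csv"), prof.to_frame(), index=False)
        results["rdf"] = prof

    return results


def run_study(cfg: StudyConfig) -> dict:
    """Run all enabled stages for every model; returns the report bundle.

    Per-stage failures are logged and recorded; the report's ``failed`` map
    is non-empty in that case (the CLI turns that into a non-zero exit).
    """
    os.makedirs(cfg.output_dir, exist_ok=True)
    report: dict = {"models": {}, "failed": {}, "differential": {}}
    for entry in cfg.models:
        outdir = os.path.join(cfg.output_dir, entry.label)
        try:
            report["models"][entry.label] = _run_model(entry, cfg, outdir)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            log.error("model %s failed: %s", entry.label, exc)
            report["failed"][entry.label] = str(exc)

    labels = [m.label for m in cfg.models
              if m.label in report["models"]
              and "domain_matrix" in report["models"][m.label]]
    diff_dir = os.path.join(cfg.output_dir, "differential")
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            dm = corr_mod.differential_matrix(
                report["models"][a]["domain_matrix"],
                report["models"][b]["domain_matrix"])
            os.makedirs(diff_dir, exist_ok=True)
            _write_csv(os.path.join(diff_dir, f"{a}-minus-{b}.csv"),
                       dm.to_frame())
            report["differential"][f"{a}-minus-{b}"] = dm

    manifest = {
        "seed": cfg.seed,
        "frame_selection": asdict(cfg.frame_selection),
        "plan": asdict(cfg.plan),
        "models": [
            {"label": m.label,
             "topology": m.topology if isinstance(m.topology, str) else "<in-memory>",
             "partition": m.partition if isinstance(m.partition, str) else "<in-memory>",
             "replicas": len(m.trajectories)}
            for m in cfg.models
        ],
        "failed": report["failed"],
    }
    with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report["manifest"] = manifest
    return report


def load_config(path: str) -> StudyConfig:
    """Study configuration from a YAML file (all paths relative to it)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(path))

    def _abs(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    models = [
        ModelEntry(m["label"], _abs(m["topology"]),
                   [_abs(t) for t in m["trajectories"]], _abs(m["partition"]))
        for m in data["models"]
    ]
    fs = data.get("frame_selection", {})
    frame_sel = FrameSelection(fs.get("start", 0.5), fs.get("end", 1.0),
                               fs.get("stride", 1))
    plan_data = data.get("analyses", {})
    plan = AnalysisPlan(**{k: v for k, v in plan_data.items()
                           if k in AnalysisPlan.__dataclass_fields__})
    if "crossing" in plan_data and plan_data["crossing"] is not None:
        plan.crossing = tuple(tuple(h) for h in plan_data["crossing"])
    out = data.get("output_dir", "memtraj_out")
    return StudyConfig(models, _abs(out), frame_sel, plan,
                       seed=int(data.get("seed", 0)))
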