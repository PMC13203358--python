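"""Pipeline orchestration: metrics -> interface -> consensus -> peptides
-> MM/GBSA -> SPR, driven by a single serialisable run configuration.

Every run writes its resolved configuration next to the results so that
re-running from that file reproduces all outputs byte for byte (given the
same inputs and seed); no timestamps enter any artifact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ppikit import synthetic_data
from ppikit.gbsa_scoring import GBSAConfig, binding_free_energy
from ppikit.interface_geometry import (GeometryCriteria, OccupancyTable,
                                       detect_frame, occupancy_over_ensemble)
from ppikit.replica_consensus import (ConsensusConfig, consensus_pairs,
                                      design_peptides, interface_clusters)
from ppikit.spr_kinetics import fit_1to1_global, percent_binding, subtract_peptide_only
from ppikit.structure_io import (TrajectoryEnsemble, assign_parameters,
                                 infer_chem_roles, read_parameter_table,
                                 read_pdb_models)
from ppikit.trajectory_metrics import (com_distance_series, rg_series,
                                       rmsd_series)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (fully serialisable)."""

    outdir: str = "ppikit_run"
    seed: int = 0
    # inputs: either explicit replica PDBs + parameter table, or a
    # generated fixture directory
    replica_pdbs: list[str] = field(default_factory=list)
    parameter_table: str = ""
    partner_chains: dict[str, str] = field(default_factory=dict)
    generate_fixtures: bool = True
    fixture_dir: str = ""
    n_frames: int = 50
    jitter_sigma: float = 0.1
    # analysis options
    rmsd_selection: str = "name CA"
    analysis_window_start: int = 0
    contact_cutoff: float = 3.5
    hbond_dist_cutoff: float = 3.5
    hbond_angle_cutoff: float = 30.0
    saltbridge_cutoff: float = 3.5
    n_replicas: int = 4
    min_replicas_present: int = 3
    presence_occupancy_min: float = 0.10
    linkage_gap: int = 4
    spatial_cutoff: float = 8.0
    peptide_flank: int = 4
    peptide_max_len: int = 20
    run_gbsa: bool = True
    gbsa_frame_stride: int = 25
    run_spr: bool = True

    def criteria(self) -> GeometryCriteria:
        return GeometryCriteria(self.contact_cutoff, self.hbond_dist_cutoff,
                                self.hbond_angle_cutoff,
                                self.saltbridge_cutoff)

    def consensus_config(self) -> ConsensusConfig:
        return ConsensusConfig(self.n_replicas, self.min_replicas_present,
                               self.presence_occupancy_min)


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)


def _resolve(path: str, outdir: Path) -> Path:
    """Relative input paths are resolved against the output directory."""
    p = Path(path)
    return p if p.is_absolute() or p.exists() else outdir / p


def _load_ensemble(cfg: RunConfig, outdir: Path,
                   ) -> tuple[TrajectoryEnsemble, dict | None]:
    if cfg.generate_fixtures:
        fixture_dir = Path(cfg.fixture_dir or (outdir / "fixtures"))
        recipe = synthetic_data.default_recipe(
            seed=cfg.seed, jitter_sigma=cfg.jitter_sigma,
            n_frames=cfg.n_frames)
        ens, manifest = synthetic_data.write_ensemble(recipe, fixture_dir)

        def rel(p: Path) -> str:
            # keep the resolved config portable across output directories
            try:
                return str(p.relative_to(outdir))
            except ValueError:
                return str(p)

        cfg.replica_pdbs = [rel(fixture_dir / f)
                            for f in manifest["files"]["replicas"]]
        cfg.parameter_table = rel(fixture_dir / "parameters.tsv")
        cfg.partner_chains = {"A": "A", "B": "B"}
        return ens, manifest
    if not cfg.replica_pdbs:
        raise ValueError("no replica PDBs configured and "
                         "generate_fixtures is off")
    partner = dict(cfg.partner_chains)
    ensembles = [read_pdb_models(_resolve(p, outdir), partner)
                 for p in cfg.replica_pdbs]
    topology = ensembles[0].topology
    frames = [e.replicas[0] for e in ensembles]
    return TrajectoryEnsemble(topology, frames), None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns the summary dictionary.

    Configuration errors (e.g. a consensus rule demanding more replicas
    than the input provides) surface before any heavy compute; a stage
    failure leaves a FAILED marker naming the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"package": "ppikit", "seed": cfg.seed, "stages": {}}
    cfg.consensus_config()  # validate thresholds up front
    cfg.criteria()
    if cfg.min_replicas_present > cfg.n_replicas:
        raise ValueError("min_replicas_present exceeds n_replicas")

    stage = "inputs"
    try:
        ens, manifest = _load_ensemble(cfg, outdir)
        if ens.n_replicas < cfg.n_replicas:
            raise ValueError(
                f"consensus expects {cfg.n_replicas} replicas, input has "
                f"{ens.n_replicas}")
        summary["stages"]["inputs"] = {
            "n_replicas": ens.n_replicas, "n_frames": ens.n_frames,
            "n_atoms": len(ens.topology)}

        stage = "metrics"
        mdir = outdir / "metrics"
        mdir.mkdir(exist_ok=True)
        rows = []
        for series_list, in [(rmsd_series(ens, cfg.rmsd_selection),),
                             (com_distance_series(ens),),
                             (rg_series(ens),)]:
            for s in series_list:
                for t, v in zip(s.times, s.values):
                    rows.append((s.metric_name, s.replica_id, t, v))
        pd.DataFrame(rows, columns=["metric", "replica", "time_ns",
                                    "value_A"]).to_csv(
            mdir / "metrics.csv", index=False, float_format="%.6f")
        summary["stages"]["metrics"] = {
            "selection": cfg.rmsd_selection,
            "file": "metrics/metrics.csv"}

        stage = "interface"
        idir = outdir / "interface"
        idir.mkdir(exist_ok=True)
        roles = infer_chem_roles(ens.topology)
        criteria = cfg.criteria()
        window = slice(cfg.analysis_window_start, None)
        occ = occupancy_over_ensemble(ens, roles, criteria, window)
        _write_occupancy_csv(occ, idir / "occupancy.csv")
        _write_frame_records_csv(ens, roles, criteria, idir
                                 / "interactions_frames.csv")
        summary["stages"]["interface"] = {
            "n_keys": len(occ.occupancy),
            "criteria": {"contact_cutoff": criteria.contact_cutoff,
                         "hbond_dist_cutoff": criteria.hbond_dist_cutoff,
                         "hbond_angle_cutoff": criteria.hbond_angle_cutoff,
                         "saltbridge_cutoff": criteria.saltbridge_cutoff,
                         "hbond_angle_convention":
                             "deviation of D->A from the D->H axis"},
            "file": "interface/occupancy.csv"}

        stage = "consensus"
        cdir = outdir / "consensus"
        cdir.mkdir(exist_ok=True)
        tbl = consensus_pairs(occ, cfg.consensus_config())
        _write_consensus_csv(tbl, cdir / "consensus.csv")
        clusters = interface_clusters(tbl, ens.topology, cfg.linkage_gap,
                                      cfg.spatial_cutoff)
        (cdir / "clusters.json").write_text(
            json.dumps({"partner_b_clusters": clusters}, sort_keys=True,
                       indent=2) + "\n")
        kept = [[r.kind, list(r.resA), list(r.resB)] for r in tbl.kept]
        summary["stages"]["consensus"] = {
            "kept": kept, "n_rows": len(tbl.rows),
            "rule": f"present in >= {cfg.min_replicas_present} of "
                    f"{cfg.n_replicas} replicas at occupancy >= "
                    f"{cfg.presence_occupancy_min}"}

        stage = "peptides"
        anchors = sorted(tbl.kept_partner_b_resids())
        specific = sorted({r.resB[1] for r in tbl.kept
                           if r.kind in ("hbond", "saltbridge")})
        anchors_used = specific or anchors
        designs = []
        if anchors_used:
            chain_b = [c for c, p in
                       (cfg.partner_chains or {"A": "A", "B": "B"}).items()
                       if p == "B"][0]
            designs = design_peptides(anchors_used, ens.topology, chain_b,
                                      cfg.peptide_flank, cfg.peptide_max_len,
                                      label_prefix="PT-BLK")
            with open(cdir / "peptides.fasta", "w") as fh:
                for d in designs:
                    anchor_str = ",".join(str(a) for a in d.anchors)
                    fh.write(f">{d.label}|{d.chain}|{d.start_resid}-"
                             f"{d.end_resid}|{anchor_str}\n{d.sequence}\n")
        summary["stages"]["peptides"] = {
            "anchors": anchors_used,
            "designs": [[d.label, d.start_resid, d.end_resid, d.sequence]
                        for d in designs]}

        if cfg.run_gbsa:
            stage = "gbsa"
            gdir = outdir / "gbsa"
            gdir.mkdir(exist_ok=True)
            table, formal = (read_parameter_table(
                _resolve(cfg.parameter_table, outdir))
                if cfg.parameter_table
                else synthetic_data.toy_parameter_table())
            topo = assign_parameters(ens.topology, table, formal)
            gens = TrajectoryEnsemble(topo, ens.replicas, ens.frame_times)
            result = binding_free_energy(gens, GBSAConfig(),
                                         frame_stride=cfg.gbsa_frame_stride)
            frames_df = pd.DataFrame(
                [(d.frame, d.species, d.e_coulomb, d.e_vdw, d.g_gb, d.g_sa,
                  d.g_total) for d in result.decompositions],
                columns=["frame", "species", "e_coulomb", "e_vdw", "g_gb",
                         "g_sa", "g_total"])
            frames_df.to_csv(gdir / "gbsa_frames.csv", index=False,
                             float_format="%.6f")
            (gdir / "gbsa_summary.json").write_text(json.dumps({
                "replica_means_kcal_mol": result.replica_means,
                "mean_kcal_mol": result.mean, "sd_kcal_mol": result.sd,
                "frame_stride": result.frame_stride,
                "protocol": "single-trajectory MM/GBSA (HCT radii, "
                            "gamma*SASA nonpolar, no entropy term)",
            }, sort_keys=True, indent=2) + "\n")
            summary["stages"]["gbsa"] = {
                "dG_mean_kcal_mol": result.mean,
                "dG_sd_kcal_mol": result.sd,
                "frame_stride": result.frame_stride}

        if cfg.run_spr:
            stage = "spr"
            sdir = outdir / "spr"
            sdir.mkdir(exist_ok=True)
            cond = synthetic_data.default_sensorgram_conditions()
            curves, smanifest = synthetic_data.generate_sensorgram_set(
                cond["ka"], cond["kd"], cond["Rmax"],
                cond["concentrations"], cond["noise_sigma"],
                cond["n_replicates"], seed=cfg.seed)
            fit = fit_1to1_global(curves)
            (sdir / "fit.json").write_text(json.dumps({
                "ka_per_M_s": fit.ka, "kd_per_s": fit.kd,
                "KD_M": fit.KD, "KD_nM": fit.KD * 1e9,
                "Rmax_RU": fit.Rmax, "rss": fit.rss,
                "converged": fit.converged, "n_starts": fit.n_starts,
                "true_KD_M": smanifest["KD"], "seed": cfg.seed,
            }, sort_keys=True, indent=2) + "\n")
            control, mixtures, peponly, imanifest = \
                synthetic_data.generate_inhibition_set(seed=cfg.seed + 1)
            corrected = [subtract_peptide_only(m, p)
                         for m, p in zip(mixtures, peponly)]
            inhib = percent_binding(corrected, control)
            pd.DataFrame(
                [(r.peptide_label, r.peptide_concentration,
                  r.percent_binding, r.sd) for r in inhib],
                columns=["label", "conc_M", "percent", "sd"]).to_csv(
                sdir / "inhibition.csv", index=False, float_format="%.6f")
            summary["stages"]["spr"] = {
                "KD_nM": fit.KD * 1e9, "true_KD_nM": smanifest["KD"] * 1e9,
                "percent_binding": [
                    [r.peptide_concentration, r.percent_binding]
                    for r in inhib]}
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") \
            from exc

    (outdir / "config.yaml").write_text(
        yaml.safe_dump(asdict(cfg), sort_keys=True))
    (outdir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2) + "\n")
    (outdir / "summary.md").write_text(_summary_markdown(summary))
    return summary


def _write_occupancy_csv(occ: OccupancyTable, path: Path) -> None:
    rows = []
    for key in sorted(occ.occupancy):
        kind, resA, resB = key[0], key[1], key[2]
        atoms = ""
        if kind == "hbond":
            atoms = "-".join(key[3]) + "/" + "-".join(key[4])
        rows.append([kind,
                     f"{resA[2]}{resA[1]}:{resA[0]}",
                     f"{resB[2]}{resB[1]}:{resB[0]}", atoms]
                    + [f"{v:.4f}" for v in occ.occupancy[key]])
    n = occ.n_replicas
    cols = ["kind", "resA", "resB", "atoms"] + [f"occ_rep{i + 1}"
                                                for i in range(n)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _write_frame_records_csv(ens, roles, criteria, path: Path) -> None:
    rows = []
    for r, frames in enumerate(ens.replicas):
        for f_i, frame in enumerate(frames):
            for rec in detect_frame(frame, ens.topology, roles, criteria,
                                    f_i):
                rows.append([r, f_i, rec.kind,
                             f"{rec.resA[2]}{rec.resA[1]}:{rec.resA[0]}",
                             f"{rec.resB[2]}{rec.resB[1]}:{rec.resB[0]}",
                             "-".join(rec.atomsA), "-".join(rec.atomsB),
                             f"{rec.geometry_distance:.3f}",
                             "" if rec.geometry_angle is None
                             else f"{rec.geometry_angle:.2f}"])
    pd.DataFrame(rows, columns=["replica", "frame", "kind", "resA", "resB",
                                "atomsA", "atomsB", "distance_A",
                                "angle_deg"]).to_csv(path, index=False)


def _write_consensus_csv(tbl, path: Path) -> None:
    rows = []
    for r in tbl.rows:
        atoms = ""
        if r.kind == "hbond":
            atoms = "-".join(r.key[3]) + "/" + "-".join(r.key[4])
        rows.append([r.kind,
                     f"{r.resA[2]}{r.resA[1]}:{r.resA[0]}",
                     f"{r.resB[2]}{r.resB[1]}:{r.resB[0]}", atoms]
                    + [int(p) for p in r.present]
                    + [r.n_present, "kept" if r.kept else "dropped"])
    n = len(tbl.rows[0].present) if tbl.rows else tbl.config.n_replicas
    cols = (["kind", "resA", "resB", "atoms"]
            + [f"present_rep{i + 1}" for i in range(n)]
            + ["n_present", "verdict"])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _summary_markdown(summary: dict) -> str:
    lines = ["# Pipeline summary", "",
             f"seed: {summary['seed']}", ""]
    for stage, info in summary["stages"].items():
        lines.append(f"## {stage}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(info, sort_keys=True, indent=2))
        lines.append("```")
        lines.append("")
    return "\n".join(lines)
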