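"""End-to-end orchestration: alignment -> DCA -> filters -> topology ->
annealing (-> evaluation), with all intermediate artifacts, logs and a
run manifest written into a run directory."""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np

import coevdock
from coevdock.alignment import read_alignment
from coevdock.config import RunConfig, module_seed
from coevdock.dca import run_dca, write_di_table
from coevdock.evaluate import evaluate_trajectory
from coevdock.filtering import filter_pipeline, write_provenance, write_restraints
from coevdock.mapping import (map_alignment_to_structure, map_ranking,
                              read_mapping_table, write_mapping)
from coevdock.sbm import build_topology
from coevdock.simulate import run_annealing, write_energy_log, write_trajectory_pdb
from coevdock.structure import (build_initial_pose, contact_map, read_pdb,
                                sasa, write_contact_map, write_pdb)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A module failure with pipeline-stage attribution."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapper
    return decorate


def run_pipeline(config: RunConfig, mode: str = "validate",
                 outdir: str | Path = "run") -> Path:
    """Execute the full pipeline and return the run directory.

    ``validate`` mode requires a two-chain native dimer structure and
    monitors/report RMSD against it; ``predict`` mode uses only a monomer
    (or the first chain of a dimer) and monitors restraint energy.
    """
    if mode not in ("predict", "validate"):
        raise ValueError("mode must be 'predict' or 'validate'")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("coevdock")
    root.addHandler(handler)
    manifest: dict = {"config": config.to_dict(), "mode": mode,
                      "version": coevdock.__version__,
                      "python": platform.python_version(),
                      "seeds": {m: module_seed(config.seed, m)
                                for m in ("dca", "pose", "simulate")}}
    try:
        msa = _stage("read_alignment")(read_alignment)(
            config.paths.alignment, config.paths.alignment_format)
        dimer = _stage("read_structure")(read_pdb)(
            config.paths.structure, config.paths.chains)
        chains = dimer.chains
        if mode == "validate" and len(chains) != 2:
            raise PipelineError("read_structure",
                                ValueError("validate mode requires a two-chain dimer"))
        monomer = dimer.select_chains([chains[0]])

        if config.paths.mapping_table:
            table = read_mapping_table(config.paths.mapping_table)
            mapping = _stage("mapping")(map_alignment_to_structure)(
                msa, monomer, method="external_table", table=table)
        else:
            mapping = _stage("mapping")(map_alignment_to_structure)(msa, monomer)
        write_mapping(mapping, out / "mapping.tsv")

        ranking, freq, coupling = _stage("dca")(run_dca)(
            msa, theta=config.dca.theta, lam=config.dca.lam,
            min_separation=config.dca.min_separation)
        write_di_table(ranking, out / "di.tsv")

        ranking_res = _stage("mapping")(map_ranking)(ranking, mapping)
        profile = _stage("sasa")(sasa)(monomer, probe=config.filter.sasa_probe,
                                       n_points=config.filter.sasa_points)
        monomer_map = contact_map(monomer, config.filter.monomer_cutoff)
        write_contact_map(monomer_map, out / "monomer_contacts.tsv")
        restraints = _stage("filtering")(filter_pipeline)(
            ranking_res, profile, monomer_map,
            sasa_threshold=config.filter.sasa_threshold,
            n_top=config.filter.n_top, dilation=config.filter.dilation)
        write_restraints(restraints, out / "restraints.tsv")
        write_provenance(restraints, out / "provenance.jsonl")
        manifest["n_restraint_pairs"] = len(restraints.pairs)

        if mode == "validate":
            second = dimer.select_chains([chains[1]])
        else:
            second = monomer
        topology = _stage("sbm")(build_topology)(
            monomer, second, restraints, params=config.build_sbm_params(),
            schedule=config.build_schedule())
        topology.to_json(out / "topology.json")

        if mode == "validate":
            pose_src = dimer
        else:
            from coevdock.structure import make_symmetry_mate
            pose_src = make_symmetry_mate(monomer, np.eye(3), np.zeros(3))
        pose = _stage("initial_pose")(build_initial_pose)(
            pose_src, separation=config.simulate.separation,
            rotate_axis=config.simulate.rotate_axis,
            angle_deg=config.simulate.rotate_angle_deg,
            seed=manifest["seeds"]["pose"])
        write_pdb(pose, out / "initial_pose.pdb")

        traj = _stage("simulate")(run_annealing)(
            pose, topology, config.build_schedule(),
            seed=manifest["seeds"]["simulate"],
            dt=config.simulate.dt, gamma=config.simulate.gamma,
            T=config.simulate.temperature,
            record_stride=config.simulate.record_stride,
            mode=mode, native=dimer if mode == "validate" else None)
        write_energy_log(traj, out / "energies.tsv")
        write_trajectory_pdb(traj, pose, out / "trajectory.pdb")
        manifest["stage_convergence"] = {str(k): bool(v) for k, v in
                                         traj.converged_stages.items()}
        if traj.n_frames:
            best = traj.coords[-1]
            write_pdb(pose, out / "final_pose.pdb", coords=best)

        if mode == "validate":
            report = _stage("evaluate")(evaluate_trajectory)(
                traj, dimer, interface_cutoff=config.evaluate.interface_cutoff,
                contact_cutoff=config.evaluate.contact_cutoff)
            with open(out / "report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            write_pdb(pose, out / "best_pose.pdb",
                      coords=traj.coords[report.rmsd_best_frame])
            manifest["rmsd_best"] = report.rmsd_best
            manifest["irmsd_best"] = report.irmsd_best

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
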