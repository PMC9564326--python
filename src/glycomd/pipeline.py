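"""End-to-end analysis pipeline: poses -> torsions/CHI -> hydrogen bonds ->
MM-GBSA energies -> entropies -> binding report.

Stages are individually skippable and write CSV tables plus a JSON summary.
An instability gate mirrors standard practice for unbound complexes: when
the ligand's positional RMSD exceeds the escape threshold in any run, the
energy and entropy stages are withheld and the summary is flagged
"unstable ligand - energies not reported".
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .conformation import (
    ChiCurveRegistry,
    assign_glycosidic_linkages,
    ring_pucker,
    torsion_angle,
    total_chi_series,
)
from .energetics import mmgbsa_interaction, per_group_decomposition
from .entropy import (
    assemble_entropy,
    entropy_window_series,
    extrapolate_entropy,
    torsional_entropy_kk,
)
from .interactions import hbond_occupancy
from .model import AnalysisConfig, ForceFieldParams, Trajectory
from .pose import cluster_poses, ligand_rmsd_series, pairwise_rmsd_matrix, representative_frame
from .report import assemble_binding, percent_contributions

__all__ = ["run_pipeline"]

_ALL_STAGES = ("poses", "torsions", "hbonds", "energy", "entropy", "report")

#: Default ligand moiety partition (group name -> topology group name).
DEFAULT_PARTITION = {
    "Neu5Ac": "Neu5Ac", "Gal": "Gal", "GlcNAc": "GlcNAc",
    "Fuc": "Fuc", "SO3": "SO3",
}


def _ensure_solute_group(topology):
    if "solute" not in topology.groups:
        solute = np.union1d(topology.group("receptor"), topology.group("ligand"))
        topology.set_group("solute", solute)


def run_pipeline(
    trajs: Sequence[Trajectory],
    params: ForceFieldParams,
    config: AnalysisConfig,
    outdir,
    label: str = "complex",
    registry: Optional[ChiCurveRegistry] = None,
    free_torsions: Optional[np.ndarray] = None,
    partition: Optional[Dict[str, str]] = None,
    stages: Sequence[str] = _ALL_STAGES,
    fit_selection: str = "receptor_ca",
    measure_selection: str = "ring_atoms",
) -> Dict:
    """Run the analysis stages on a set of replicate trajectories.

    ``free_torsions`` is the free-ligand glycosidic torsion ensemble
    (degrees) used for the conformational entropy term; without it the KK
    term is reported as unavailable. Returns the summary dict (also written
    as summary.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    topo = trajs[0].topology
    partition = dict(partition or {
        k: v for k, v in DEFAULT_PARTITION.items() if v in topo.groups
    })
    summary: Dict = {
        "label": label,
        "runs": [t.run_id for t in trajs],
        "n_frames": [t.n_frames for t in trajs],
        "config": dataclasses.asdict(config),
        "stages": {},
        "flags": [],
    }

    # --- stability gate (always evaluated) ------------------------------
    reference = trajs[0].frames[0]
    series = [
        ligand_rmsd_series(t, fit_selection, measure_selection, reference,
                           reference_label="frame0/run0")
        for t in trajs
    ]
    rmsd_df = pd.concat(
        [
            pd.DataFrame({"run_id": s.run_id, "time_ns": s.times, "rmsd": s.values})
            for s in series
        ],
        ignore_index=True,
    )
    rmsd_df.to_csv(outdir / "rmsd_series.csv", index=False)
    max_rmsd = float(rmsd_df["rmsd"].max())
    unstable = max_rmsd > config.escape_threshold
    summary["max_ligand_rmsd"] = max_rmsd
    summary["unstable"] = unstable
    if unstable:
        summary["flags"].append("unstable ligand - energies not reported")

    if "poses" in stages:
        mat, meta = pairwise_rmsd_matrix(
            trajs, measure_selection, stride_ns=config.pose_stride_ns,
            fit_selection=fit_selection,
        )
        np.savetxt(outdir / "pairwise_rmsd.csv", mat, delimiter=",", fmt="%.4f")
        assignment = cluster_poses(mat, cutoff=config.rmsd_cutoff, sample_meta=meta)
        pd.DataFrame(
            {
                "run_id": [m[0] for m in meta],
                "time_ns": [m[1] for m in meta],
                "pose": assignment.labels,
            }
        ).to_csv(outdir / "poses.csv", index=False)
        (rid, t_ns), rep = representative_frame(trajs, measure_selection,
                                                fit_selection=fit_selection)
        from .io import write_pdb

        write_pdb(outdir / "representative.pdb", topo, rep)
        summary["stages"]["poses"] = {
            "n_poses": assignment.n_poses,
            "populations": assignment.populations.tolist(),
            "representative": {"run_id": rid, "time_ns": t_ns},
        }

    linkages = None
    if "torsions" in stages:
        try:
            linkages = assign_glycosidic_linkages(topo, frame=trajs[0].frames[0])
        except Exception as exc:  # no glycan connectivity found
            summary["flags"].append(f"torsion stage skipped: {exc}")
            linkages = []
        if linkages:
            rows = []
            for traj in trajs:
                for frame in traj.frames:
                    for link in linkages:
                        rows.append(
                            {
                                "run_id": traj.run_id,
                                "time_ns": frame.time,
                                "linkage": link.label,
                                "phi": torsion_angle(frame, link.phi_quad),
                                "psi": torsion_angle(frame, link.psi_quad),
                            }
                        )
            pd.DataFrame(rows).to_csv(outdir / "torsions.csv", index=False)
            chi_info = {"linkages": [l.label for l in linkages]}
            if registry is not None:
                chi = pd.concat(
                    [
                        pd.DataFrame(
                            {
                                "run_id": t.run_id,
                                "time_ns": t.times,
                                "total_chi": total_chi_series(t, linkages, registry),
                            }
                        )
                        for t in trajs
                    ],
                    ignore_index=True,
                )
                chi.to_csv(outdir / "total_chi.csv", index=False)
                chi_info["max_total_chi"] = float(chi["total_chi"].max())
            summary["stages"]["torsions"] = chi_info
        # ring pucker of any pyranose rings present
        pucker_rows = []
        for gname in ("GlcNAc", "Gal", "Fuc"):
            if gname not in topo.groups:
                continue
            ring = [
                i for i in topo.groups[gname]
                if topo.atoms[i].name in ("O5", "C1", "C2", "C3", "C4", "C5")
            ]
            if len(ring) != 6:
                continue
            order = {"O5": 0, "C1": 1, "C2": 2, "C3": 3, "C4": 4, "C5": 5}
            ring.sort(key=lambda i: order[topo.atoms[i].name])
            for traj in trajs:
                for frame in traj.frames:
                    st = ring_pucker(frame, ring)
                    pucker_rows.append(
                        {"run_id": traj.run_id, "time_ns": frame.time,
                         "residue": gname, "Q": st.Q, "theta": st.theta,
                         "label": st.label}
                    )
        if pucker_rows:
            pd.DataFrame(pucker_rows).to_csv(outdir / "pucker.csv", index=False)

    if "hbonds" in stages:
        occ = hbond_occupancy(trajs, config.hbond, "receptor", "ligand")
        occ.to_csv(outdir / "hbond_occupancy.csv", index=False)
        summary["stages"]["hbonds"] = {
            "n_pairs": int(len(occ)),
            "n_stable": int(occ["stable"].sum()) if len(occ) else 0,
        }

    energy = None
    if "energy" in stages:
        if unstable:
            summary["stages"]["energy"] = {"skipped": "unstable ligand"}
        else:
            n_snap = min(config.n_snapshots, min(t.n_frames for t in trajs))
            energy = mmgbsa_interaction(
                trajs, params, "receptor", "ligand", n_snapshots=n_snap
            )
            energy.per_run.to_csv(outdir / "energy_per_run.csv")
            decomp = None
            if partition:
                decomp = per_group_decomposition(
                    trajs, params, "receptor", partition, n_snapshots=n_snap
                )
                decomp = percent_contributions(decomp, total=energy.total)
                decomp.to_csv(outdir / "per_group_energies.csv", index=False)
            summary["stages"]["energy"] = {
                "dg_mmgbsa": energy.mean,
                "sd": energy.sd,
                "components": {
                    "e_elec": energy.e_elec, "e_vdw": energy.e_vdw,
                    "dg_gb": energy.dg_gb, "dg_sasa": energy.dg_sasa,
                },
                "n_snapshots": n_snap,
            }

    entropy_est = None
    if "entropy" in stages:
        if unstable:
            summary["stages"]["entropy"] = {"skipped": "unstable ligand"}
        else:
            from .errors import InsufficientSamplingError

            for t in trajs:
                _ensure_solute_group(t.topology)
            intercepts = {"solute": [], "receptor": [], "ligand": []}
            try:
                for sel in intercepts:
                    masses = params.arrays_for(topo, topo.group(sel))["mass"]
                    for traj in trajs:
                        ser = entropy_window_series(
                            traj, sel, masses=masses, T=params.temperature,
                            n_windows=config.entropy_windows,
                        )
                        icpt, _, _ = extrapolate_entropy(ser)
                        intercepts[sel].append(icpt)
            except InsufficientSamplingError as exc:
                summary["stages"]["entropy"] = {"skipped": str(exc)}
                summary["flags"].append(f"entropy stage skipped: {exc}")
                intercepts = None
            if intercepts is not None:
                kk = 0.0
                kk_available = False
                if free_torsions is not None and linkages:
                    bound = []
                    for traj in trajs:
                        for frame in traj.frames:
                            bound.append(
                                [torsion_angle(frame, l.phi_quad) for l in linkages]
                                + [torsion_angle(frame, l.psi_quad) for l in linkages]
                            )
                    kk = torsional_entropy_kk(
                        np.asarray(bound), free_torsions, T=params.temperature
                    )
                    kk_available = True
                entropy_est = assemble_entropy(
                    intercepts["solute"], intercepts["receptor"], intercepts["ligand"],
                    kk, T=params.temperature,
                )
                summary["stages"]["entropy"] = {
                    "minus_t_ds_rtv": entropy_est.minus_t_ds_rtv,
                    "minus_t_ds_qc": entropy_est.minus_t_ds_qc,
                    "minus_t_ds_total": entropy_est.minus_t_ds_total,
                    "kk_available": kk_available,
                }
                if not kk_available:
                    summary["flags"].append(
                        "free-ligand torsion ensemble not supplied; -TdS_qC set to 0"
                    )

    if "report" in stages and energy is not None and entropy_est is not None:
        rep = assemble_binding(
            energy.mean, entropy_est.minus_t_ds_total,
            dg_sd=energy.sd, ds_sd=entropy_est.sd_total, label=label,
        )
        summary["stages"]["report"] = {
            "dg_mmgbsa": rep.dg_mmgbsa,
            "minus_t_ds": rep.minus_t_ds,
            "dg_binding": rep.dg_binding,
            "dg_binding_sd": rep.dg_binding_sd,
        }
        pd.DataFrame(
            [
                {"quantity": "dG_MM/GBSA", "value": rep.dg_mmgbsa, "sd": rep.dg_mmgbsa_sd},
                {"quantity": "-TdS", "value": rep.minus_t_ds, "sd": rep.minus_t_ds_sd},
                {"quantity": "dG_binding", "value": rep.dg_binding, "sd": rep.dg_binding_sd},
            ]
        ).to_csv(outdir / "binding_report.csv", index=False)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
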