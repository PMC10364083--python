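#!/usr/bin/env python
"""Generate the synthetic study system: monomer, tripeptides, poses, trajectory.

Everything downstream analyses consume is generated here from one seed:
an α-helical monomer with one surface and one shielded cysteine plus
lysines/aspartate for interface contacts, Gly–X–Gly tripeptide references,
three rigid C2 dimer poses at prescribed closest Sγ–Sγ distances, and a
jittered 25-frame ensemble. Coordinates go to scratch/ (regenerable);
a small summary table goes to results/.
"""

import json
from pathlib import Path

from crydimer import (
    make_dimer_pose,
    make_helix_monomer,
    make_tripeptide,
    synthesize_trajectory,
    write_pdb,
)
from crydimer.pipeline import PipelineConfig
from crydimer.synth import FixtureSpec

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "fixtures"
RESULTS = ROOT / "results"


def main(seed: int = 1) -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=seed)
    spec = FixtureSpec(
        helix_length=cfg.helix_length,
        cys_positions=cfg.cys_positions,
        lys_positions=cfg.lys_positions,
        asp_positions=cfg.asp_positions,
        buried_cys=cfg.buried_cys,
        seed=seed,
    )
    monomer = make_helix_monomer(spec)
    write_pdb(monomer, SCRATCH / "monomer.pdb")
    print(f"monomer: {monomer.n_atoms} atoms, "
          f"{len(cfg.cys_positions)} cysteines "
          f"({len(cfg.buried_cys)} shielded)")

    for res in ("ALA", "CYS", "LYS", "ASP"):
        write_pdb(make_tripeptide(res), SCRATCH / f"gly_{res.lower()}_gly.pdb")

    summary = {"seed": seed, "monomer_atoms": monomer.n_atoms, "poses": {}}
    for target in cfg.pose_targets:
        pose = make_dimer_pose(monomer, target, c2=True, seed=seed)
        name = f"pose_ss{target:.0f}.pdb"
        write_pdb(pose, SCRATCH / name)
        summary["poses"][name] = {"target_ss_A": target,
                                  "atoms": pose.n_atoms}
        print(f"pose at Sγ–Sγ {target:.0f} Å → {name}")

    traj_spec = FixtureSpec(
        helix_length=cfg.helix_length, cys_positions=cfg.cys_positions,
        lys_positions=cfg.lys_positions, asp_positions=cfg.asp_positions,
        buried_cys=cfg.buried_cys, seed=seed + 2, n_frames=cfg.n_frames,
        jitter_sigma=cfg.jitter_sigma,
        occupancy_schedule=cfg.occupancy_schedule,
    )
    pose5 = make_dimer_pose(monomer, 5.0, c2=True, seed=seed)
    ens = synthesize_trajectory(pose5, traj_spec)
    write_pdb(ens, SCRATCH / "trajectory.pdb")
    summary["trajectory_frames"] = ens.n_frames
    print(f"trajectory: {ens.n_frames} frames, jitter "
          f"{cfg.jitter_sigma} Å, scheduled contacts: "
          f"{len(cfg.occupancy_schedule)}")

    (RESULTS / "fixtures_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )


if __name__ == "__main__":
    main()
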