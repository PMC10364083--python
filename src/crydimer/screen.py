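"""Disulfide-feasibility screening of rigid-body homodimer poses.

A docked two-chain pose is screened on its inter-monomer cysteine
sulfur–sulfur distances: a pose whose closest Sγ–Sγ pair is within the
select cutoff (6 Å default) is a disulfide *candidate*; one whose closest
pair exceeds the reject cutoff (10 Å default) is *rejected*; in between it
is *marginal* — geometrically too far for a direct bond but close enough
that restrained refinement might rescue it (refinement itself is an MD
engine's job and out of scope here).

In-silico disulfide formation removes the thiol hydrogens (HG) of both
cysteines and records the bond; coordinates are otherwise untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import kabsch_superpose
from .structures import Structure

__all__ = [
    "ScreenPolicy",
    "CysPair",
    "DimerPose",
    "DisulfideRecord",
    "inter_cys_distances",
    "screen_pose",
    "rank_poses",
    "form_disulfide",
    "check_c2_symmetry",
]

_VERDICT_ORDER = {"candidate": 0, "marginal": 1, "rejected": 2}


@dataclass
class ScreenPolicy:
    """Distance thresholds for the three-band verdict."""

    select_cutoff: float = 6.0    # Å; min Sγ–Sγ ≤ this → candidate
    reject_cutoff: float = 10.0   # Å; min Sγ–Sγ > this → rejected
    distance_atom: str = "SG"     # "SG", or "CB" for models without Sγ

    def __post_init__(self):
        if self.select_cutoff > self.reject_cutoff:
            raise ValueError("select_cutoff must be <= reject_cutoff")
        if self.distance_atom not in ("SG", "CB"):
            raise ValueError("distance_atom must be 'SG' or 'CB'")


@dataclass(frozen=True)
class CysPair:
    residue_a: tuple[str, int]    # (chain, residue_seq)
    residue_b: tuple[str, int]
    distance: float               # Å


@dataclass
class DimerPose:
    """A screened two-chain pose."""

    structure: Structure
    chain_ids: tuple[str, str]
    cys_pairs: list[CysPair] = field(default_factory=list)
    min_ss_distance: float = float("inf")
    verdict: str = "unscreened"
    reason: str = ""
    symmetric: bool | None = None
    c2_rmsd: float | None = None
    pose_id: str = ""


@dataclass(frozen=True)
class DisulfideRecord:
    """SSBOND-style record of one formed S–S link."""

    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    distance: float

    def to_ssbond_line(self, serial: int = 1) -> str:
        (ca, ra), (cb, rb) = self.residue_a, self.residue_b
        return (
            f"SSBOND {serial:3d} CYS {ca:1s} {ra:4d}    "
            f"CYS {cb:1s} {rb:4d}"
        )


def inter_cys_distances(
    structure: Structure,
    chain_pair: tuple[str, str],
    distance_atom: str = "SG",
) -> list[CysPair]:
    """All cross-chain cysteine pairs with distances, sorted ascending."""
    a = structure.atoms
    pairs: list[CysPair] = []
    per_chain: dict[str, list[tuple[int, np.ndarray]]] = {}
    for cid in chain_pair:
        cys_mask = (a.chain_id == cid) & (a.res_name == "CYS")
        entries = []
        for res_id in np.unique(a.res_id[cys_mask]):
            m = cys_mask & (a.res_id == res_id) & (a.atom_name == distance_atom)
            idx = np.flatnonzero(m)
            if idx.size == 0:
                raise KeyError(
                    f"cysteine {cid}:{int(res_id)} lacks atom {distance_atom}"
                )
            entries.append((int(res_id), structure.coords[idx[0]].astype(float)))
        per_chain[cid] = entries
    ca, cb = chain_pair
    for res_a, xa in per_chain[ca]:
        for res_b, xb in per_chain[cb]:
            pairs.append(
                CysPair(
                    residue_a=(ca, res_a),
                    residue_b=(cb, res_b),
                    distance=float(np.linalg.norm(xa - xb)),
                )
            )
    pairs.sort(key=lambda p: p.distance)
    return pairs


def screen_pose(
    structure: Structure,
    chain_pair: tuple[str, str] | None = None,
    policy: ScreenPolicy | None = None,
    pose_id: str = "",
) -> DimerPose:
    """Screen one pose into candidate / marginal / rejected."""
    policy = policy or ScreenPolicy()
    if chain_pair is None:
        cids = structure.chain_ids
        if len(cids) != 2:
            raise ValueError(
                f"pose must have exactly 2 chains, found {len(cids)}"
            )
        chain_pair = (cids[0], cids[1])
    pairs = inter_cys_distances(structure, chain_pair, policy.distance_atom)
    pose = DimerPose(
        structure=structure,
        chain_ids=chain_pair,
        cys_pairs=pairs,
        pose_id=pose_id,
    )
    if not pairs:
        pose.verdict = "rejected"
        pose.reason = "no cysteine pairs"
        return pose
    pose.min_ss_distance = pairs[0].distance
    if pose.min_ss_distance <= policy.select_cutoff:
        pose.verdict = "candidate"
    elif pose.min_ss_distance > policy.reject_cutoff:
        pose.verdict = "rejected"
    else:
        pose.verdict = "marginal"
        pose.reason = (
            "between select and reject cutoffs; restrained refinement "
            "would be needed to close the bond"
        )
    return pose


def rank_poses(poses: list[DimerPose]) -> list[DimerPose]:
    """Stable sort: candidates first, then by ascending closest distance."""
    for p in poses:
        if p.verdict == "unscreened":
            raise ValueError(f"pose {p.pose_id!r} has not been screened")
    return sorted(
        poses, key=lambda p: (_VERDICT_ORDER[p.verdict], p.min_ss_distance)
    )


def poses_table(poses: list[DimerPose]) -> pd.DataFrame:
    """Summary table (pose id, closest pair, distance, verdict, C2 RMSD)."""
    rows = []
    for p in poses:
        best = p.cys_pairs[0] if p.cys_pairs else None
        rows.append(
            {
                "pose_id": p.pose_id,
                "min_ss_A": p.min_ss_distance if best else np.nan,
                "best_pair": (
                    f"{best.residue_a[0]}:{best.residue_a[1]}-"
                    f"{best.residue_b[0]}:{best.residue_b[1]}"
                    if best
                    else ""
                ),
                "verdict": p.verdict,
                "c2_rmsd_A": p.c2_rmsd if p.c2_rmsd is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def form_disulfide(
    structure: Structure,
    cys_a: tuple[str, int],
    cys_b: tuple[str, int],
    existing_bonds: list[DisulfideRecord] | None = None,
) -> tuple[Structure, DisulfideRecord]:
    """Deprotonate two cysteines and record an S–S bond.

    Removes the HG atom of each cysteine when present (already-deprotonated
    thiolates pass through unchanged) and returns the structure plus an
    SSBOND-style record. No coordinate relaxation is attempted: closing the
    bond to ~2.05 Å is left to downstream refinement.
    """
    a = structure.atoms
    key = frozenset([cys_a, cys_b])
    for rec in existing_bonds or []:
        if frozenset([rec.residue_a, rec.residue_b]) == key:
            raise ValueError(f"bond {cys_a}-{cys_b} already recorded")

    sg_coords = []
    drop = np.zeros(structure.n_atoms, dtype=bool)
    for chain_id, res_id in (cys_a, cys_b):
        res_mask = (a.chain_id == chain_id) & (a.res_id == res_id)
        if not res_mask.any():
            raise KeyError(f"residue {chain_id}:{res_id} not found")
        res_name = str(a.res_name[np.flatnonzero(res_mask)[0]])
        if res_name != "CYS":
            raise ValueError(
                f"{chain_id}:{res_id} is {res_name}, not CYS"
            )
        sg = np.flatnonzero(res_mask & (a.atom_name == "SG"))
        if sg.size == 0:
            raise KeyError(f"cysteine {chain_id}:{res_id} lacks SG")
        sg_coords.append(structure.coords[sg[0]].astype(float))
        drop |= res_mask & (a.atom_name == "HG")

    out = structure.mask(~drop)
    record = DisulfideRecord(
        residue_a=cys_a,
        residue_b=cys_b,
        distance=float(np.linalg.norm(sg_coords[0] - sg_coords[1])),
    )
    return out, record


def check_c2_symmetry(
    structure: Structure,
    chain_pair: tuple[str, str] | None = None,
    rmsd_tolerance: float = 1.0,
) -> tuple[bool, float]:
    """Two-fold symmetry check by chain-swap superposition.

    Swapping the chain labels of an exactly C2-symmetric dimer yields a
    rigid copy of itself, so the Kabsch RMSD between the original
    coordinates (chain A then B) and the swapped ones (chain B then A) is
    zero. Returns (RMSD ≤ tolerance, RMSD).
    """
    if chain_pair is None:
        cids = structure.chain_ids
        if len(cids) != 2:
            raise ValueError("need exactly 2 chains")
        chain_pair = (cids[0], cids[1])
    xa = structure.chain(chain_pair[0]).coords.astype(float)
    xb = structure.chain(chain_pair[1]).coords.astype(float)
    if xa.shape != xb.shape:
        raise ValueError(
            f"chain lengths differ: {xa.shape[0]} vs {xb.shape[0]} atoms"
        )
    original = np.vstack([xa, xb])
    swapped = np.vstack([xb, xa])
    sup = kabsch_superpose(swapped, original)
    # 1e-6 Å floor: float32 coordinates cannot resolve a tighter tolerance
    return sup.rmsd <= max(rmsd_tolerance, 1e-6), sup.rmsd
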