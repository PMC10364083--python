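"""Inter-chain hydrogen bonds and occupancy-filtered salt bridges.

A hydrogen bond is counted when the donor–acceptor heavy-atom distance is
below a ceiling (3.5 Å default) and the donor–hydrogen···acceptor angle is
above a floor (140° default). A salt bridge candidate is an (anionic group,
cationic group) residue pair across the interface; it is "present" in a
frame when the minimum distance between its charged-group heavy atoms is
at or below the contact ceiling (4.0 Å default), and it is *counted* only
when present in strictly more than the occupancy threshold fraction of
frames (10% default, strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import Ensemble, Structure

__all__ = [
    "HBondCriteria",
    "SaltBridgeCriteria",
    "HBond",
    "SaltBridge",
    "detect_hbonds",
    "detect_salt_bridges",
]


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond definition."""

    max_da_distance: float = 3.5     # donor–acceptor heavy atoms, Å
    min_dha_angle: float = 140.0     # donor–H–acceptor, degrees
    donor_elements: tuple[str, ...] = ("N", "O", "S")
    acceptor_elements: tuple[str, ...] = ("N", "O", "S")

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValueError("distance ceiling must be > 0")
        if not 0 <= self.min_dha_angle <= 180:
            raise ValueError("angle floor must be in [0, 180]")


@dataclass
class SaltBridgeCriteria:
    """Charged-group contact definition plus the frame-occupancy filter."""

    max_distance: float = 4.0
    occupancy_threshold: float = 0.10   # strict: retained iff occupancy > this
    include_histidine: bool = False

    anionic_atoms: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "ASP": ("OD1", "OD2"),
            "GLU": ("OE1", "OE2"),
        }
    )
    cationic_atoms: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "LYS": ("NZ",),
            "ARG": ("NH1", "NH2", "NE"),
        }
    )

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("contact ceiling must be > 0")
        if not 0 <= self.occupancy_threshold <= 1:
            raise ValueError("occupancy threshold must be in [0, 1]")
        if self.include_histidine and "HIS" not in self.cationic_atoms:
            self.cationic_atoms = {
                **self.cationic_atoms,
                "HIS": ("ND1", "NE2"),
            }


@dataclass(frozen=True)
class HBond:
    donor: tuple[str, int, str]      # (chain, residue_seq, atom name)
    hydrogen: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    distance: float                  # donor–acceptor, Å
    angle: float                     # D–H–A, degrees


@dataclass(frozen=True)
class SaltBridge:
    anionic: tuple[str, int, str]    # (chain, residue_seq, residue name)
    cationic: tuple[str, int, str]
    occupancy: float                 # fraction of frames in contact
    min_distance: float              # closest approach over frames, Å


def _atom_label(structure: Structure, i: int) -> tuple[str, int, str]:
    a = structure.atoms
    return (str(a.chain_id[i]), int(a.res_id[i]), str(a.atom_name[i]))


def _covalent_hydrogens(structure: Structure, heavy_idx: int) -> np.ndarray:
    """Hydrogens within covalent range (1.3 Å) of one heavy atom."""
    a = structure.atoms
    same_res = (
        (a.chain_id == a.chain_id[heavy_idx])
        & (a.res_id == a.res_id[heavy_idx])
        & (a.element == "H")
    )
    idx = np.flatnonzero(same_res)
    if idx.size == 0:
        return idx
    d = np.linalg.norm(
        structure.coords[idx].astype(float)
        - structure.coords[heavy_idx].astype(float),
        axis=1,
    )
    return idx[d < 1.3]


def detect_hbonds(
    frame: Structure,
    chain_pair: tuple[str, str],
    criteria: HBondCriteria | None = None,
    heavy_only_fallback: bool = False,
) -> list[HBond]:
    """Inter-chain hydrogen bonds in one frame.

    Donors are N/O/S atoms carrying at least one covalent hydrogen; the
    D–H–A angle is evaluated for every hydrogen on the donor and the best
    (largest) angle is reported. With ``heavy_only_fallback`` a structure
    without hydrogens is screened on the distance criterion alone.
    """
    criteria = criteria or HBondCriteria()
    a = frame.atoms
    coords = frame.coords.astype(float)
    has_h = bool(np.any(a.element == "H"))
    if not has_h and not heavy_only_fallback:
        raise ValueError(
            "no hydrogens present; enable heavy_only_fallback to screen on "
            "distance only"
        )

    out: list[HBond] = []
    seen_heavy_pairs: set[frozenset] = set()
    for ca, cb in ((chain_pair[0], chain_pair[1]),
                   (chain_pair[1], chain_pair[0])):
        don_mask = (a.chain_id == ca) & np.isin(
            a.element, criteria.donor_elements
        )
        acc_mask = (a.chain_id == cb) & np.isin(
            a.element, criteria.acceptor_elements
        )
        don_idx = np.flatnonzero(don_mask)
        acc_idx = np.flatnonzero(acc_mask)
        if don_idx.size == 0 or acc_idx.size == 0:
            continue
        tree = cKDTree(coords[acc_idx])
        near = tree.query_ball_point(
            coords[don_idx], r=criteria.max_da_distance
        )
        for k, js in enumerate(near):
            if not js:
                continue
            d_i = don_idx[k]
            h_idx = _covalent_hydrogens(frame, d_i) if has_h else np.array([], int)
            if has_h and h_idx.size == 0:
                continue  # heavy atom with no proton cannot donate
            for j in js:
                a_i = acc_idx[j]
                dist = float(np.linalg.norm(coords[a_i] - coords[d_i]))
                if has_h:
                    best_angle, best_h = -1.0, -1
                    for h in h_idx:
                        v1 = coords[d_i] - coords[h]
                        v2 = coords[a_i] - coords[h]
                        cosang = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2)
                        )
                        ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                        if ang > best_angle:
                            best_angle, best_h = ang, h
                    if best_angle < criteria.min_dha_angle:
                        continue
                    out.append(
                        HBond(
                            donor=_atom_label(frame, d_i),
                            hydrogen=_atom_label(frame, best_h),
                            acceptor=_atom_label(frame, a_i),
                            distance=dist,
                            angle=best_angle,
                        )
                    )
                else:
                    # distance-only screen cannot orient the pair: report
                    # each unordered contact once
                    key = frozenset([d_i, a_i])
                    if key in seen_heavy_pairs:
                        continue
                    seen_heavy_pairs.add(key)
                    out.append(
                        HBond(
                            donor=_atom_label(frame, d_i),
                            hydrogen=("", -1, ""),
                            acceptor=_atom_label(frame, a_i),
                            distance=dist,
                            angle=float("nan"),
                        )
                    )
    return out


def _charged_groups(
    structure: Structure,
    chain_id: str,
    table: dict[str, tuple[str, ...]],
) -> list[tuple[tuple[str, int, str], np.ndarray]]:
    """[(residue label, atom index array)] for charged groups of one chain."""
    a = structure.atoms
    groups = []
    chain_mask = a.chain_id == chain_id
    for res_name, atom_names in table.items():
        res_mask = chain_mask & (a.res_name == res_name)
        for res_id in np.unique(a.res_id[res_mask]):
            idx = np.flatnonzero(
                res_mask & (a.res_id == res_id) & np.isin(a.atom_name, atom_names)
            )
            if idx.size:
                groups.append(
                    ((chain_id, int(res_id), res_name), idx)
                )
    return groups


def detect_salt_bridges(
    ensemble: Ensemble,
    chain_pair: tuple[str, str],
    criteria: SaltBridgeCriteria | None = None,
    return_all: bool = False,
) -> list[SaltBridge]:
    """Occupancy-filtered inter-chain salt bridges over an ensemble.

    A candidate pair is in contact in a frame iff the minimum distance
    between its charged-group atoms is ≤ the ceiling; it is retained iff
    its occupancy (fraction of frames in contact) is strictly greater than
    the threshold. ``return_all`` reports every candidate with non-zero
    occupancy, bypassing the filter (for diagnostics).
    """
    criteria = criteria or SaltBridgeCriteria()
    topo = ensemble.topology
    ca, cb = chain_pair
    candidates = []
    for an_chain, cat_chain in ((ca, cb), (cb, ca)):
        for an_label, an_idx in _charged_groups(
            topo, an_chain, criteria.anionic_atoms
        ):
            for cat_label, cat_idx in _charged_groups(
                topo, cat_chain, criteria.cationic_atoms
            ):
                candidates.append((an_label, cat_label, an_idx, cat_idx))

    out = []
    n = ensemble.n_frames
    for an_label, cat_label, an_idx, cat_idx in candidates:
        hits = 0
        closest = np.inf
        for frame in ensemble:
            xa = frame.coords[an_idx].astype(float)
            xb = frame.coords[cat_idx].astype(float)
            dmin = float(
                np.min(np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2))
            )
            closest = min(closest, dmin)
            if dmin <= criteria.max_distance:
                hits += 1
        occ = hits / n
        keep = occ > criteria.occupancy_threshold if not return_all else occ > 0
        if keep:
            out.append(
                SaltBridge(
                    anionic=an_label,
                    cationic=cat_label,
                    occupancy=occ,
                    min_distance=closest,
                )
            )
    out.sort(key=lambda b: (-b.occupancy, b.anionic, b.cationic))
    return out
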