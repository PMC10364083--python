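"""Synthetic structures, ensembles and assay data for the pipeline.

Every generator here is a pure function of its seed and spec, so fixtures
are reproducible byte for byte and no coordinate files need to be shipped:
tests and analyses regenerate them on demand.

The fixtures are deliberately idealised — an α-helical monomer with
cysteines and lysines placed at chosen positions (residue templates taken
from the chemical component dictionary bundled with biotite), rigid dimer
poses with a prescribed closest Sγ–Sγ distance and optional exact two-fold
symmetry, ensembles with prescribed isotropic positional jitter and
deterministic contact-occupancy schedules, extended Gly–X–Gly tripeptides
for the exposure normalisation, and noisy Ellman calibration series. The
ground truth of each construction is therefore analytic, which is what the
downstream stages are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.info as bs_info
from scipy.optimize import brentq

from .structures import Ensemble, Structure

__all__ = [
    "FixtureSpec",
    "make_helix_monomer",
    "make_dimer_pose",
    "synthesize_trajectory",
    "make_tripeptide",
    "make_ellman_dataset",
]

# Ideal α-helix: 1.5 Å rise and 100° twist per residue; backbone N and C
# sit on a slightly tighter coaxial helix, offset in phase and height so
# consecutive C→N distances come out near peptide-bond length.
_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(100.0)
_CA_RADIUS = 2.3
_NC_RADIUS = 1.75
_NC_PHASE = np.deg2rad(26.0)
_NC_DZ = 0.9

# Terminal atoms of the free-amino-acid CCD templates that do not exist
# inside a chain.
_STRIP_ALWAYS = {"HXT"}
_STRIP_NONTERM_C = {"OXT"}
_STRIP_NONTERM_N = {"H2", "H3"}
# acid protons absent at neutral pH (side chains modelled as charged)
_STRIP_BY_RESIDUE = {"ASP": {"HD2"}, "GLU": {"HE2"}}

# Side-chain "tip" atom used for contact scheduling, per residue type.
_TIP_ATOM = {"ASP": "OD1", "GLU": "OE1", "LYS": "NZ", "ARG": "NH1",
             "CYS": "SG"}


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic monomer / trajectory.

    ``occupancy_schedule`` maps ``((chain_a, res_a), (chain_b, res_b))`` to
    the fraction of frames in which the two residues' charged-group tip
    atoms are in contact; frames are assigned deterministically by stride,
    so the realised occupancy is exactly ``round(occupancy * n_frames) /
    n_frames``.
    """

    helix_length: int = 20
    cys_positions: tuple[int, ...] = ()
    lys_positions: tuple[int, ...] = ()
    asp_positions: tuple[int, ...] = ()
    buried_cys: tuple[int, ...] = ()      # subset of cys_positions to shield
    seed: int = 0
    jitter_sigma: float = 0.0             # Å, isotropic per atom per frame
    n_frames: int = 1
    occupancy_schedule: dict = field(default_factory=dict)
    contact_distance: float = 3.5         # Å, tip–tip when in contact
    apart_distance: float = 6.5           # Å, tip–tip when not in contact

    def __post_init__(self):
        for pos in (
            *self.cys_positions, *self.lys_positions, *self.asp_positions
        ):
            if not 1 <= pos <= self.helix_length:
                raise ValueError(f"residue position {pos} outside helix")
        if not set(self.buried_cys) <= set(self.cys_positions):
            raise ValueError("buried_cys must be a subset of cys_positions")
        for occ in self.occupancy_schedule.values():
            if not 0.0 <= occ <= 1.0:
                raise ValueError("occupancies must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


def _template(res_name: str) -> struc.AtomArray:
    try:
        return bs_info.residue(res_name)
    except Exception as exc:
        raise KeyError(f"unknown residue code {res_name!r}") from exc


def _frame_from_backbone(n: np.ndarray, ca: np.ndarray, c: np.ndarray):
    """Orthonormal frame (origin at N) spanned by the N/CA/C triad."""
    e1 = c - n
    e1 = e1 / np.linalg.norm(e1)
    v = ca - n
    e2 = v - (v @ e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _place_residue(
    res_name: str,
    n_t: np.ndarray,
    ca_t: np.ndarray,
    c_t: np.ndarray,
    res_id: int,
    chain_id: str,
    terminal: str = "",
) -> struc.AtomArray:
    """CCD template rigidly mapped so its N/CA/C triad hits the targets."""
    tmpl = _template(res_name).copy()
    strip = _STRIP_ALWAYS | _STRIP_BY_RESIDUE.get(res_name, set())
    keep = ~np.isin(tmpl.atom_name, list(strip))
    if terminal != "C":
        keep &= ~np.isin(tmpl.atom_name, list(_STRIP_NONTERM_C))
    if terminal != "N":
        keep &= ~np.isin(tmpl.atom_name, list(_STRIP_NONTERM_N))
    tmpl = tmpl[keep]

    def _pos(name):
        idx = np.flatnonzero(tmpl.atom_name == name)
        if idx.size == 0:
            raise KeyError(f"{res_name} template lacks atom {name}")
        return tmpl.coord[idx[0]].astype(float)

    src = _frame_from_backbone(_pos("N"), _pos("CA"), _pos("C"))
    dst = _frame_from_backbone(n_t, ca_t, c_t)
    rot = dst @ src.T
    tmpl.coord = (tmpl.coord.astype(float) - _pos("N")) @ rot.T + n_t
    tmpl.res_id = np.full(tmpl.array_length(), res_id)
    tmpl.chain_id = np.full(tmpl.array_length(), chain_id, dtype="U4")
    tmpl.hetero = np.zeros(tmpl.array_length(), dtype=bool)
    return tmpl


def _helix_backbone(i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    phi = i * _HELIX_TWIST
    z = i * _HELIX_RISE
    ca = np.array([_CA_RADIUS * np.cos(phi), _CA_RADIUS * np.sin(phi), z])
    n = np.array(
        [
            _NC_RADIUS * np.cos(phi - _NC_PHASE),
            _NC_RADIUS * np.sin(phi - _NC_PHASE),
            z - _NC_DZ,
        ]
    )
    c = np.array(
        [
            _NC_RADIUS * np.cos(phi + _NC_PHASE),
            _NC_RADIUS * np.sin(phi + _NC_PHASE),
            z + _NC_DZ,
        ]
    )
    return n, ca, c


def _fibonacci_shell(center: np.ndarray, radius: float, n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - (2 * i + 1) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1 - z * z, 0, None))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return center + radius * pts


def make_helix_monomer(spec: FixtureSpec, chain_id: str = "A") -> Structure:
    """Idealised α-helical monomer with placed CYS/LYS/ASP residues.

    Side chains point outward from the helix axis, so non-buried cysteines
    are solvent exposed by construction. Cysteines listed in
    ``spec.buried_cys`` get a shell of carbon dummy atoms (residue name
    SHL, HETATM) around the side chain so their SASA is ≈ 0 — the analytic
    stand-in for a core-packed residue.
    """
    res_types = {}
    for p in spec.cys_positions:
        res_types[p] = "CYS"
    for p in spec.lys_positions:
        if p in res_types:
            raise ValueError(f"position {p} assigned twice")
        res_types[p] = "LYS"
    for p in spec.asp_positions:
        if p in res_types:
            raise ValueError(f"position {p} assigned twice")
        res_types[p] = "ASP"

    parts = []
    for i in range(spec.helix_length):
        res_id = i + 1
        name = res_types.get(res_id, "ALA")
        terminal = "N" if i == 0 else ("C" if i == spec.helix_length - 1 else "")
        n_t, ca_t, c_t = _helix_backbone(i)
        parts.append(_place_residue(name, n_t, ca_t, c_t, res_id, chain_id,
                                    terminal))
    body = struc.concatenate(parts)

    # overlapping-placement check on heavy atoms of non-adjacent residues
    heavy = body[body.element != "H"]
    coords = heavy.coord.astype(float)
    res_ids = heavy.res_id
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    far_pairs = np.abs(res_ids[:, None] - res_ids[None, :]) >= 2
    if np.any(d[far_pairs] < 1.2):
        raise ValueError("overlapping residue placements in helix fixture")

    shells = []
    next_res = spec.helix_length + 1
    for p in spec.buried_cys:
        cys = body[(body.res_id == p) & (body.res_name == "CYS")]
        cb = cys.coord[cys.atom_name == "CB"][0].astype(float)
        sg = cys.coord[cys.atom_name == "SG"][0].astype(float)
        center = 0.5 * (cb + sg)
        pts = _fibonacci_shell(center, 4.6, 80)
        keep = np.ones(len(pts), dtype=bool)
        body_heavy = body[body.element != "H"]
        for k, pt in enumerate(pts):
            dmin = np.min(
                np.linalg.norm(body_heavy.coord.astype(float) - pt, axis=1)
            )
            if dmin < 2.0:
                keep[k] = False
        pts = pts[keep]
        shell = struc.AtomArray(len(pts))
        shell.coord = pts.astype(np.float32)
        shell.element = np.full(len(pts), "C", dtype="U2")
        shell.atom_name = np.array(
            [f"C{k % 99:02d}" for k in range(len(pts))], dtype="U6"
        )
        shell.res_name = np.full(len(pts), "SHL", dtype="U5")
        shell.res_id = np.full(len(pts), next_res)
        shell.chain_id = np.full(len(pts), chain_id, dtype="U4")
        shell.hetero = np.ones(len(pts), dtype=bool)
        shells.append(shell)
        next_res += 1

    full = struc.concatenate([body, *shells]) if shells else body
    return Structure(full, title=f"synthetic helix monomer ({chain_id})")


def _min_inter_sg(struct_a: Structure, coords_b: np.ndarray,
                  sg_mask: np.ndarray) -> float:
    xa = struct_a.coords[sg_mask].astype(float)
    xb = coords_b[sg_mask]
    return float(
        np.min(np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2))
    )


def make_dimer_pose(
    monomer: Structure,
    target_ss: float,
    c2: bool = True,
    seed: int = 0,
    chain_ids: tuple[str, str] = ("A", "B"),
) -> Structure:
    """Two-chain pose with prescribed closest inter-chain Sγ–Sγ distance.

    The partner chain is generated by a 180° rotation about an axis placed
    outside the surface cysteine, which yields an exactly C2-symmetric pose
    whose closest Sγ–Sγ pair sits at ``target_ss`` (solved to < 0.01 Å).
    With ``c2=False`` the partner is additionally twisted by a seeded random
    rotation and re-shifted along the approach direction so the closest
    distance still equals ``target_ss`` but the symmetry is broken.
    """
    a = monomer.atoms
    sg_mask = (a.res_name == "CYS") & (a.atom_name == "SG")
    if not sg_mask.any():
        raise ValueError("monomer has no cysteine SG atoms")
    coords = monomer.coords.astype(float)
    centroid = coords.mean(axis=0)
    sg_coords = coords[sg_mask]
    # most outward cysteine defines the approach direction
    radial = np.linalg.norm(sg_coords[:, :2] - centroid[None, :2], axis=1)
    sg0 = sg_coords[np.argmax(radial)]
    u = sg0 - centroid
    u[2] = 0.0  # approach in the plane normal to the helix axis
    if np.linalg.norm(u) < 1e-6:
        u = np.array([1.0, 0.0, 0.0])
    u = u / np.linalg.norm(u)
    w = np.array([0.0, 0.0, 1.0])  # C2 axis parallel to the helix axis

    def _c2_partner(s: float) -> np.ndarray:
        p = sg0 + s * u
        rel = coords - p
        rot = 2 * (rel @ w)[:, None] * w[None, :] - rel  # 180° about w
        return p + rot

    def _gap(s: float) -> float:
        return _min_inter_sg(monomer, _c2_partner(s), sg_mask) - target_ss

    lo, hi = 0.05, target_ss + 60.0
    if _gap(lo) > 0:
        lo = 1e-4
    s_star = brentq(_gap, lo, hi, xtol=1e-6)
    partner = _c2_partner(s_star)

    if not c2:
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(12.0 + 8.0 * rng.random())
        k = axis
        cen = partner.mean(axis=0)
        rel = partner - cen
        partner = (
            cen
            + rel * np.cos(angle)
            + np.cross(k, rel) * np.sin(angle)
            + k[None, :] * (rel @ k)[:, None] * (1 - np.cos(angle))
        )

        def _gap2(s: float) -> float:
            return _min_inter_sg(monomer, partner + s * u, sg_mask) - target_ss

        g0 = _gap2(0.0)
        bracket = (-40.0, 40.0) if g0 > 0 else (0.0, 80.0)
        s2 = brentq(_gap2, *bracket, xtol=1e-6)
        partner = partner + s2 * u

    # hard-sphere feasibility
    heavy_a = a.element != "H"
    d_inter = np.linalg.norm(
        coords[heavy_a][:, None, :] - partner[heavy_a][None, :, :], axis=2
    )
    if d_inter.min() < 1.8:
        raise ValueError(
            f"infeasible target_ss={target_ss}: inter-chain clash at "
            f"{d_inter.min():.2f} Å"
        )

    arr_a = a.copy()
    arr_a.chain_id = np.full(arr_a.array_length(), chain_ids[0], dtype="U4")
    arr_b = a.copy()
    arr_b.chain_id = np.full(arr_b.array_length(), chain_ids[1], dtype="U4")
    arr_b.coord = partner.astype(np.float32)
    pose = Structure(
        struc.concatenate([arr_a, arr_b]),
        title=f"synthetic dimer pose target_ss={target_ss:.2f}",
    )
    achieved = _min_inter_sg(
        pose.chain(chain_ids[0]), pose.chain(chain_ids[1]).coords.astype(float),
        sg_mask,
    )
    if abs(achieved - target_ss) > 0.01:
        raise RuntimeError(
            f"pose construction missed target: {achieved:.4f} vs {target_ss}"
        )
    return pose


def _tip_index(structure: Structure, chain: str, res_seq: int) -> int:
    a = structure.atoms
    m = (a.chain_id == chain) & (a.res_id == res_seq)
    if not m.any():
        raise KeyError(f"schedule references absent residue {chain}:{res_seq}")
    res_name = str(a.res_name[np.flatnonzero(m)[0]])
    tip = _TIP_ATOM.get(res_name, "CA")
    idx = np.flatnonzero(m & (a.atom_name == tip))
    if idx.size == 0:
        raise KeyError(
            f"residue {chain}:{res_seq} ({res_name}) lacks tip atom {tip}"
        )
    return int(idx[0])


def synthesize_trajectory(pose: Structure, spec: FixtureSpec) -> Ensemble:
    """Ensemble of jittered copies with exact contact-occupancy schedules.

    Each frame is the pose plus i.i.d. isotropic Gaussian jitter of
    ``spec.jitter_sigma`` per atom. For every scheduled contact pair the
    partner tip atom is then pinned at ``contact_distance`` from the
    anchor tip in exactly ``round(occupancy * n_frames)`` frames (chosen by
    stride) and at ``apart_distance`` otherwise, making downstream
    occupancy measurements exact by construction.
    """
    rng = np.random.default_rng(spec.seed)
    base = pose.coords.astype(float)
    n = spec.n_frames

    pinned = []
    for (res_a, res_b), occ in spec.occupancy_schedule.items():
        ia = _tip_index(pose, *res_a)
        ib = _tip_index(pose, *res_b)
        k = int(round(occ * n))
        contact_frames = (
            set(np.floor(np.arange(k) * n / k).astype(int)) if k else set()
        )
        pinned.append((ia, ib, contact_frames))

    frames = []
    for f in range(n):
        jitter = (
            rng.normal(scale=spec.jitter_sigma, size=base.shape)
            if spec.jitter_sigma > 0
            else np.zeros_like(base)
        )
        coords = base + jitter
        for ia, ib, contact_frames in pinned:
            dist = (
                spec.contact_distance
                if f in contact_frames
                else spec.apart_distance
            )
            anchor = base[ia]
            direction = base[ib] - base[ia]
            nrm = np.linalg.norm(direction)
            direction = (
                direction / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
            )
            coords[ia] = anchor
            coords[ib] = anchor + dist * direction
        frame = pose.copy()
        frame.coords = coords
        frames.append(frame)
    return Ensemble(frames)


def make_tripeptide(residue: str, conformation: str = "extended") -> Structure:
    """Gly–X–Gly tripeptide in an extended backbone arrangement.

    The three CCD residue templates are chained head to tail along x with
    peptide-bond-length C→N steps; the central X keeps its template side
    chain. Used to build the maximum-SASA normalisation table.
    """
    if conformation != "extended":
        raise ValueError(f"unknown conformation {conformation!r}")
    residue = residue.upper()
    tmpl_check = _template(residue)
    if not {"N", "CA", "C"} <= set(tmpl_check.atom_name):
        raise KeyError(f"{residue!r} is not a peptide residue")
    seq = ["GLY", residue, "GLY"]
    x_hat = np.array([1.0, 0.0, 0.0])
    y_hat = np.array([0.0, 1.0, 0.0])
    parts = []
    n_anchor = np.zeros(3)
    for k, name in enumerate(seq):
        tmpl = _template(name)

        def _pos(nm, t=tmpl):
            return t.coord[np.flatnonzero(t.atom_name == nm)[0]].astype(float)

        span = np.linalg.norm(_pos("C") - _pos("N"))
        # alternate the side-chain direction for a zigzag extended chain
        flip = -1.0 if k % 2 else 1.0
        n_t = n_anchor
        c_t = n_anchor + span * x_hat
        # CA halfway along, offset perpendicular, preserving N–CA distance
        d_nca = np.linalg.norm(_pos("CA") - _pos("N"))
        along = min(span / 2.0, d_nca * 0.7)
        perp = np.sqrt(max(d_nca**2 - along**2, 0.04))
        ca_t = n_anchor + along * x_hat + flip * perp * y_hat
        terminal = "N" if k == 0 else ("C" if k == 2 else "")
        parts.append(
            _place_residue(name, n_t, ca_t, c_t, k + 1, "A", terminal)
        )
        n_anchor = c_t + 1.33 * x_hat
    return Structure(
        struc.concatenate(parts), title=f"Gly-{residue}-Gly extended"
    )


def make_ellman_dataset(
    true_slope: float = 0.012,
    noise_sigma: float = 0.0,
    concentrations=(0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    seed: int = 0,
    true_n_cys=(5.0,),
    protein_conc_um: float = 5.0,
):
    """Calibration series plus protein-sample absorbances with known truth.

    Calibration absorbance = slope × [free cysteine] + Gaussian noise; each
    sample absorbance = slope × (N_Cys × protein concentration) + noise,
    the Beer–Lambert forward model of the thiol assay.

    Returns ``(concentrations, calibration_absorbances, sample_absorbances)``.
    """
    if true_slope <= 0:
        raise ValueError("true_slope must be > 0")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    cal = true_slope * conc
    if noise_sigma > 0:
        cal = cal + rng.normal(scale=noise_sigma, size=conc.shape)
    samples = np.array(
        [true_slope * n * protein_conc_um for n in true_n_cys], dtype=float
    )
    if noise_sigma > 0:
        samples = samples + rng.normal(scale=noise_sigma, size=samples.shape)
    return conc, cal, samples
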