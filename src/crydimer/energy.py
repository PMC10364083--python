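"""Inter-monomer non-bonded interaction energy.

The monomer–monomer interaction energy E_tot is the sum of Lennard-Jones
12-6 and Coulomb terms over *inter-chain* atom pairs only (no bonded terms
are ever computed, so a disulfide's covalent contribution is excluded by
construction). Both terms are damped by the standard CHARMM-style switching
polynomial between the switch start (10 Å default) and the cutoff (12 Å
default), and are exactly zero beyond the cutoff:

    s(r) = (rc² − r²)² (rc² + 2r² − 3rs²) / (rc² − rs²)³   for rs < r ≤ rc

with s(rs) = 1, s(rc) = 0 and s'(rs) = s'(rc) = 0, so the switched energy
is C1-continuous everywhere.

Parameters are caller-supplied per atom (charge e, LJ ε kcal/mol and
r_min/2 Å). A minimal bundled assigner provides element-based LJ parameters
and residue-level formal charges placed on charged-group atoms, which is
sufficient for toy systems and trend analysis; no agreement with any
specific force field's absolute energies is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import Structure

__all__ = [
    "NonbondedParams",
    "switching_factor",
    "interaction_energy",
    "assign_minimal_params",
]

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)

# Element-keyed LJ parameters (ε kcal/mol, r_min/2 Å) of typical magnitude
# for protein heavy atoms; hydrogens are kept small but non-zero.
_ELEMENT_LJ = {
    "H": (0.030, 1.20),
    "C": (0.078, 2.04),
    "N": (0.170, 1.85),
    "O": (0.120, 1.70),
    "S": (0.450, 2.00),
    "P": (0.585, 2.15),
}

# Formal charges distributed over charged-group atoms (e).
_FORMAL_CHARGES = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
}


@dataclass
class NonbondedParams:
    """Per-atom non-bonded parameters plus the cutoff scheme.

    ``charge`` (e), ``epsilon`` (kcal/mol) and ``rmin2`` (r_min/2, Å) are
    arrays over all atoms of the structure the energy is evaluated on.
    """

    charge: np.ndarray
    epsilon: np.ndarray
    rmin2: np.ndarray
    cutoff: float = 12.0
    switch_start: float = 10.0
    dielectric: float = 1.0
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self):
        self.charge = np.asarray(self.charge, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.rmin2 = np.asarray(self.rmin2, dtype=float)
        if not (self.switch_start < self.cutoff):
            raise ValueError("switch_start must be < cutoff")
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be >= 0")


def switching_factor(
    r: np.ndarray, switch_start: float, cutoff: float
) -> np.ndarray:
    """CHARMM switching polynomial: 1 below the switch, 0 beyond the cutoff."""
    r = np.asarray(r, dtype=float)
    rs2, rc2 = switch_start**2, cutoff**2
    r2 = r * r
    s = (rc2 - r2) ** 2 * (rc2 + 2 * r2 - 3 * rs2) / (rc2 - rs2) ** 3
    return np.where(r2 <= rs2, 1.0, np.where(r2 >= rc2, 0.0, s))


def assign_minimal_params(
    structure: Structure,
    cutoff: float = 12.0,
    switch_start: float = 10.0,
) -> NonbondedParams:
    """Bundled minimal parameter set: element LJ + formal group charges."""
    n = structure.n_atoms
    eps = np.empty(n)
    rmin2 = np.empty(n)
    q = np.zeros(n)
    missing = []
    a = structure.atoms
    for i in range(n):
        if bool(a.hetero[i]):
            # cofactors and shielding dummies are geometric occluders only:
            # the minimal table has no physical parameters for them
            eps[i], rmin2[i] = 0.0, 1.0
            continue
        el = str(a.element[i]).upper()
        if el not in _ELEMENT_LJ:
            missing.append(f"{a.chain_id[i]}:{a.res_id[i]}:{a.atom_name[i]}")
            continue
        eps[i], rmin2[i] = _ELEMENT_LJ[el]
        q[i] = _FORMAL_CHARGES.get(
            (str(a.res_name[i]), str(a.atom_name[i])), 0.0
        )
    if missing:
        raise KeyError(
            "no LJ parameters for atoms: " + ", ".join(missing[:10])
        )
    return NonbondedParams(
        charge=q, epsilon=eps, rmin2=rmin2,
        cutoff=cutoff, switch_start=switch_start,
    )


def pair_energy(
    r,
    q1: float,
    q2: float,
    eps1: float,
    eps2: float,
    rmin2_1: float,
    rmin2_2: float,
    cutoff: float = 12.0,
    switch_start: float = 10.0,
    dielectric: float = 1.0,
    coulomb_constant: float = COULOMB_CONSTANT,
) -> tuple[np.ndarray, np.ndarray]:
    """Switched (vdW, electrostatic) energy of one atom pair at distance r.

    Float64 throughout; vectorised over ``r``. This is the exact kernel
    :func:`interaction_energy` sums over inter-chain pairs.
    """
    r = np.asarray(r, dtype=float)
    sw = switching_factor(r, switch_start, cutoff)
    eps = np.sqrt(eps1 * eps2)
    rmin = rmin2_1 + rmin2_2
    with np.errstate(divide="ignore"):
        ratio6 = (rmin / r) ** 6
        e_vdw = np.where(r < cutoff, sw * eps * (ratio6**2 - 2.0 * ratio6), 0.0)
        e_elec = np.where(
            r < cutoff,
            sw * coulomb_constant * q1 * q2 / (dielectric * r),
            0.0,
        )
    return e_vdw, e_elec


def interaction_energy(
    frame: Structure,
    chain_pair: tuple[str, str],
    params: NonbondedParams,
) -> tuple[float, float, float]:
    """(E_vdw, E_elec, E_tot) in kcal/mol over inter-chain pairs only.

    LJ uses the ε/r_min convention
    ``V = ε[(r_min/r)^12 − 2(r_min/r)^6]`` with Lorentz–Berthelot-style
    combination (ε geometric mean, r_min arithmetic sum of the two r_min/2);
    Coulomb is ``k q_i q_j / (D r)``. Both are multiplied by the switching
    factor and truncated at the cutoff.
    """
    if len(params.charge) != frame.n_atoms:
        raise ValueError(
            f"parameter table covers {len(params.charge)} atoms, "
            f"structure has {frame.n_atoms}"
        )
    ca, cb = chain_pair
    ia = np.flatnonzero(frame.atoms.chain_id == ca)
    ib = np.flatnonzero(frame.atoms.chain_id == cb)
    if ia.size == 0 or ib.size == 0:
        raise ValueError(f"chain pair {chain_pair} not found")
    if np.intersect1d(ia, ib).size:
        raise ValueError("chains are not disjoint atom sets")

    xa = frame.coords[ia].astype(float)
    xb = frame.coords[ib].astype(float)
    tree_b = cKDTree(xb)
    pairs = cKDTree(xa).query_ball_tree(tree_b, r=params.cutoff)

    e_vdw = 0.0
    e_elec = 0.0
    for k, js in enumerate(pairs):
        if not js:
            continue
        i = ia[k]
        j = ib[np.asarray(js)]
        d = np.linalg.norm(xb[np.asarray(js)] - xa[k], axis=1)
        inside = d < params.cutoff
        if not inside.any():
            continue
        j, d = j[inside], d[inside]
        sw = switching_factor(d, params.switch_start, params.cutoff)
        eps = np.sqrt(params.epsilon[i] * params.epsilon[j])
        rmin = params.rmin2[i] + params.rmin2[j]
        ratio6 = (rmin / d) ** 6
        e_vdw += float(np.sum(sw * eps * (ratio6 * ratio6 - 2.0 * ratio6)))
        e_elec += float(
            np.sum(
                sw
                * params.coulomb_constant
                * params.charge[i]
                * params.charge[j]
                / (params.dielectric * d)
            )
        )
    # (the per-pair terms equal pair_energy(d, ...) summed; kept vectorised
    # per neighbour list for speed)
    return e_vdw, e_elec, e_vdw + e_elec
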