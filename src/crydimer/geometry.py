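"""Rigid-body superposition and ensemble geometry metrics.

Kabsch superposition finds the proper rotation (reflections corrected via
the SVD determinant) and translation minimising the RMSD between two point
sets; RMSD series, RMSF and radius of gyration are the usual trajectory
summaries built on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Ensemble, Structure

__all__ = [
    "Superposition",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "backbone_mask",
    "carbon_mask",
]

# Atomic masses (u) for the elements the fixtures and typical proteins carry.
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
}

_BACKBONE = ("N", "CA", "C", "O")


def backbone_mask(structure: Structure) -> np.ndarray:
    """Protein backbone heavy atoms (N, CA, C, O)."""
    return np.isin(structure.atoms.atom_name, _BACKBONE)


def carbon_mask(structure: Structure, alpha_only: bool = False) -> np.ndarray:
    """All carbon atoms, or Cα only."""
    if alpha_only:
        return structure.atoms.atom_name == "CA"
    return structure.atoms.element == "C"


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray      # (3, 3), proper: det = +1
    translation: np.ndarray   # (3,)
    rmsd: float               # Å, after superposition

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Returns the rotation/translation such that ``R @ mobile + t`` best fits
    the reference in the (weighted) least-squares sense, and the residual
    RMSD. The rotation is always proper: if the best orthogonal transform is
    a reflection, the smallest singular direction is flipped.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape:
        raise ValueError(
            f"point count mismatch: {mob.shape} vs {ref.shape}"
        )
    if mob.ndim != 2 or mob.shape[1] != 3 or mob.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    if weights is None:
        w = np.ones(mob.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (mob.shape[0],) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("invalid weights")
    w = w / w.sum()

    mob_c = mob - w @ mob
    ref_c = ref - w @ ref
    h = (mob_c * w[:, None]).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = (w @ ref) - rot @ (w @ mob)
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - ref) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_series(
    ensemble: Ensemble,
    reference_frame: int = 0,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Per-frame backbone RMSD against one reference frame.

    ``selection`` is a boolean atom mask (default: backbone heavy atoms).
    Returns (per-frame RMSD array, mean, population SD).
    """
    if not 0 <= reference_frame < ensemble.n_frames:
        raise IndexError(f"reference frame {reference_frame} out of range")
    if selection is None:
        selection = backbone_mask(ensemble.topology)
    selection = np.asarray(selection, dtype=bool)
    if not selection.any():
        raise ValueError("empty atom selection")
    ref = ensemble[reference_frame].coords[selection].astype(float)
    vals = np.array(
        [
            kabsch_superpose(fr.coords[selection].astype(float), ref).rmsd
            for fr in ensemble
        ]
    )
    return vals, float(vals.mean()), float(vals.std())


def rmsf(
    ensemble: Ensemble,
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
    n_mean_passes: int = 2,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure, Å.

    Frames are superposed onto an iteratively refined average structure
    (superpose all frames onto the running mean, recompute the mean; two
    passes suffice for the jitter levels of interest), then
    ``RMSF_j = sqrt(<|r_j - r̄_j|²>)`` over frames for each selected atom.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if selection is None:
        selection = carbon_mask(ensemble.topology)
    selection = np.asarray(selection, dtype=bool)
    if not selection.any():
        raise ValueError("empty atom selection")
    # fit on all atoms by default: superposing on a small selection removes
    # 6 rigid degrees of freedom from few coordinates and biases RMSF low
    fit_sel = (
        np.asarray(fit_selection, dtype=bool)
        if fit_selection is not None
        else np.ones(ensemble.topology.n_atoms, dtype=bool)
    )

    coords = ensemble.coords().astype(float)
    mean = coords[0]
    for _ in range(n_mean_passes):
        fitted = np.empty_like(coords)
        for i in range(coords.shape[0]):
            sup = kabsch_superpose(coords[i][fit_sel], mean[fit_sel])
            fitted[i] = sup.apply(coords[i])
        mean = fitted.mean(axis=0)
        coords = fitted
    dev2 = np.sum((coords[:, selection] - mean[selection]) ** 2, axis=2)
    return np.sqrt(dev2.mean(axis=0))


def radius_of_gyration(
    structure: Structure, mass_weighted: bool = True
) -> float:
    """Radius of gyration: RMS (mass-weighted) distance from the centroid."""
    coords = structure.coords.astype(float)
    if mass_weighted:
        m = np.array(
            [ATOMIC_MASS.get(e.upper(), 0.0) for e in structure.atoms.element]
        )
        if m.sum() <= 0:
            raise ValueError("zero total mass")
    else:
        m = np.ones(len(coords))
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    return float(
        np.sqrt((m * np.sum((coords - com) ** 2, axis=1)).sum() / m.sum())
    )
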