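"""Dimer interface metric panel over a coordinate ensemble.

For a two-chain assembly the panel aggregates, frame by frame:

* E_tot — inter-monomer non-bonded (van der Waals + electrostatic) energy,
  kcal/mol; excludes all bonded terms, so a disulfide's covalent energy
  never enters.
* R_g — radius of gyration of the whole dimer, Å.
* RMSD — backbone RMSD against a caller-chosen reference frame, Å.
* RMSF — per-atom fluctuation about the ensemble mean structure, Å
  (reported as mean ± SD over the selected carbon atoms).
* A_IS — buried interface area: SASA(A) + SASA(B) − SASA(AB), Å².
* hydrogen bonds — mean inter-chain count per frame.
* salt bridges — number of candidate pairs whose frame occupancy exceeds
  the strict threshold (10% default).

Scalars are summarised as mean ± population SD over frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import (
    HBondCriteria,
    SaltBridge,
    SaltBridgeCriteria,
    detect_hbonds,
    detect_salt_bridges,
)
from .energy import NonbondedParams, assign_minimal_params, interaction_energy
from .geometry import backbone_mask, carbon_mask, radius_of_gyration, rmsd_series, rmsf
from .sasa import RadiiSet, shrake_rupley_sasa
from .structures import Ensemble, Structure, split_chains

__all__ = ["InterfacePanel", "interface_area", "build_interface_panel"]


def interface_area(
    frame: Structure,
    chain_pair: tuple[str, str],
    radii: RadiiSet | None = None,
) -> float:
    """Buried interface area A_IS = SASA(A) + SASA(B) − SASA(AB), Å².

    Non-negative by construction: separating the chains can only expose
    surface. Clipped at 0 to absorb lattice quantisation noise for barely
    touching chains.
    """
    radii = radii or RadiiSet()
    ca, cb = chain_pair
    mono_a = frame.chain(ca)
    mono_b = frame.chain(cb)
    both = frame.mask(np.isin(frame.atoms.chain_id, [ca, cb]))
    if mono_a.n_atoms + mono_b.n_atoms != both.n_atoms:
        raise ValueError("chains are not disjoint atom sets")
    sasa_a = shrake_rupley_sasa(mono_a, radii).sum()
    sasa_b = shrake_rupley_sasa(mono_b, radii).sum()
    sasa_ab = shrake_rupley_sasa(both, radii).sum()
    return max(0.0, float(sasa_a + sasa_b - sasa_ab))


@dataclass
class InterfacePanel:
    """One row of interface metrics with mean ± SD where applicable."""

    e_tot: tuple[float, float]           # (mean, SD), kcal/mol
    e_vdw: tuple[float, float]
    e_elec: tuple[float, float]
    r_g: tuple[float, float]             # Å
    rmsd: tuple[float, float]            # Å
    rmsf: tuple[float, float]            # mean ± SD over selected atoms, Å
    a_is: tuple[float, float]            # Å²
    hydrogen_bonds: float                # mean count per frame
    salt_bridges: int                    # count passing the occupancy filter
    salt_bridge_records: list[SaltBridge] = field(default_factory=list)
    n_frames: int = 0
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Single-row table in conventional column order (−E_tot first)."""
        fmt = lambda t: f"{t[0]:.1f} ± {t[1]:.1f}"
        return pd.DataFrame(
            [
                {
                    "minus_E_tot_kcal_mol": fmt((-self.e_tot[0], self.e_tot[1])),
                    "R_g_A": fmt(self.r_g),
                    "RMSD_A": fmt(self.rmsd),
                    "RMSF_A": fmt(self.rmsf),
                    "A_IS_A2": fmt(self.a_is),
                    "hydrogen_bonds": f"{self.hydrogen_bonds:.1f}",
                    "salt_bridges": self.salt_bridges,
                    "n_frames": self.n_frames,
                }
            ]
        )


def _mean_sd(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std())


def build_interface_panel(
    ensemble: Ensemble,
    chain_pair: tuple[str, str],
    params: NonbondedParams | None = None,
    radii: RadiiSet | None = None,
    hbond_criteria: HBondCriteria | None = None,
    salt_bridge_criteria: SaltBridgeCriteria | None = None,
    reference_frame: int = 0,
    rmsf_alpha_only: bool = False,
    hbond_heavy_only: bool = False,
) -> InterfacePanel:
    """Compute the full metric panel for a dimer ensemble.

    Deterministic for fixed inputs: every component (SASA lattice included)
    is seed-free. ``params`` defaults to the bundled minimal table.
    """
    radii = radii or RadiiSet()
    topo = ensemble.topology
    if params is None:
        params = assign_minimal_params(topo)
    hbc = hbond_criteria or HBondCriteria()
    sbc = salt_bridge_criteria or SaltBridgeCriteria()

    e_vdw, e_elec, e_tot, rg, ais, nhb = [], [], [], [], [], []
    for frame in ensemble:
        ev, ee, et = interaction_energy(frame, chain_pair, params)
        e_vdw.append(ev)
        e_elec.append(ee)
        e_tot.append(et)
        rg.append(radius_of_gyration(frame))
        ais.append(interface_area(frame, chain_pair, radii))
        nhb.append(
            len(
                detect_hbonds(
                    frame, chain_pair, hbc, heavy_only_fallback=hbond_heavy_only
                )
            )
        )

    _, rmsd_mean, rmsd_sd = rmsd_series(
        ensemble, reference_frame, backbone_mask(topo)
    )
    if ensemble.n_frames >= 2:
        rmsf_vals = rmsf(ensemble, carbon_mask(topo, alpha_only=rmsf_alpha_only))
        rmsf_stat = _mean_sd(rmsf_vals)
    else:
        rmsf_stat = (0.0, 0.0)

    bridges = detect_salt_bridges(ensemble, chain_pair, sbc)

    return InterfacePanel(
        e_tot=_mean_sd(e_tot),
        e_vdw=_mean_sd(e_vdw),
        e_elec=_mean_sd(e_elec),
        r_g=_mean_sd(rg),
        rmsd=(rmsd_mean, rmsd_sd),
        rmsf=rmsf_stat,
        a_is=_mean_sd(ais),
        hydrogen_bonds=float(np.mean(nhb)),
        salt_bridges=len(bridges),
        salt_bridge_records=bridges,
        n_frames=ensemble.n_frames,
        metadata={
            "hbond_distance_A": hbc.max_da_distance,
            "hbond_angle_deg": hbc.min_dha_angle,
            "salt_bridge_distance_A": sbc.max_distance,
            "salt_bridge_occupancy_threshold": sbc.occupancy_threshold,
            "cutoff_A": params.cutoff,
            "switch_start_A": params.switch_start,
            "reference_frame": reference_frame,
        },
    )
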