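"""Per-residue solvent exposure normalised by Gly–X–Gly references.

Raw SASA values are not comparable across residue types (a tryptophan has
far more surface than a glycine), so each residue's SASA is divided by the
maximum SASA (MSA) that residue type attains as the central X of a
Gly–X–Gly tripeptide:

    exposure_i = 100 * SASA_i / MSA(type_i)   [percent]

Exposure can exceed 100% when a conformation is more extended than the
tripeptide reference; such values are flagged, never clamped. The default
scope is the side chain only (the quantity that decides whether a cysteine
thiol can reach a partner); whole-residue exposure is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sasa import RadiiSet, shrake_rupley_sasa
from .structures import Ensemble, Structure

__all__ = [
    "MsaTable",
    "ExposureProfile",
    "compute_msa_reference",
    "residue_exposure",
    "time_average_exposure",
    "classify_cysteines",
]

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "H2", "H3", "HA", "HXT",
                   "HA2", "HA3"}


def _sidechain_mask(structure: Structure) -> np.ndarray:
    return ~np.isin(structure.atoms.atom_name, list(_BACKBONE_NAMES))


@dataclass
class MsaTable:
    """Maximum reference SASA per residue type, whole-residue and side chain.

    ``whole`` and ``sidechain`` map 3-letter codes to Å²; ``provenance``
    records how the table was generated (conformer count, mode, lattice).
    """

    whole: dict[str, float]
    sidechain: dict[str, float]
    provenance: str = ""

    def __post_init__(self):
        for table in (self.whole, self.sidechain):
            for res, v in table.items():
                if v <= 0:
                    raise ValueError(f"MSA for {res} must be > 0, got {v}")

    def get(self, res_name: str, scope: str) -> float:
        table = self.whole if scope == "whole_residue" else self.sidechain
        try:
            return table[res_name]
        except KeyError:
            raise KeyError(
                f"no MSA reference for residue type {res_name!r}"
            ) from None


@dataclass
class ExposureProfile:
    """Per-residue SASA and normalised exposure.

    ``table`` columns: chain, residue_seq, residue_name, sasa_abs (Å²,
    selected scope), msa (Å²), exposure_pct, over_reference (bool flag for
    exposure > 100%). ``n_frames`` records how many frames were averaged.
    """

    table: pd.DataFrame
    scope: str = "sidechain"
    n_frames: int = 1

    def exposure_of(self, chain: str, residue_seq: int) -> float:
        m = (self.table["chain"] == chain) & (
            self.table["residue_seq"] == residue_seq
        )
        if not m.any():
            raise KeyError(f"residue {chain}:{residue_seq} not in profile")
        return float(self.table.loc[m, "exposure_pct"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.3f")


def _per_residue_sasa(
    structure: Structure, atom_sasa: np.ndarray, scope: str
) -> pd.DataFrame:
    sel = np.ones(structure.n_atoms, dtype=bool)
    if scope == "sidechain":
        sel = _sidechain_mask(structure)
    elif scope != "whole_residue":
        raise ValueError(f"unknown scope {scope!r}")
    # hetero residues (cofactors, shielding dummies) occlude surface but get
    # no profile row: there is no tripeptide reference for them
    amino = ~structure.atoms.hetero
    df = pd.DataFrame(
        {
            "chain": structure.atoms.chain_id[amino],
            "residue_seq": structure.atoms.res_id[amino],
            "residue_name": structure.atoms.res_name[amino],
            "sasa": np.where(sel, atom_sasa, 0.0)[amino],
        }
    )
    grouped = (
        df.groupby(["chain", "residue_seq"], sort=False)
        .agg(residue_name=("residue_name", "first"), sasa_abs=("sasa", "sum"))
        .reset_index()
    )
    return grouped


def residue_exposure(
    atom_sasa: np.ndarray,
    structure: Structure,
    msa: MsaTable,
    scope: str = "sidechain",
) -> ExposureProfile:
    """Normalise per-atom SASA to per-residue percent exposure."""
    grouped = _per_residue_sasa(structure, atom_sasa, scope)
    grouped["msa"] = [
        msa.get(rn, scope) for rn in grouped["residue_name"]
    ]
    grouped["exposure_pct"] = 100.0 * grouped["sasa_abs"] / grouped["msa"]
    grouped["over_reference"] = grouped["exposure_pct"] > 100.0
    return ExposureProfile(table=grouped, scope=scope, n_frames=1)


def time_average_exposure(
    frames: Ensemble,
    radii: RadiiSet | None = None,
    msa: MsaTable | None = None,
    scope: str = "sidechain",
    average: str = "exposure",
) -> ExposureProfile:
    """Frame-averaged exposure over a trajectory stand-in.

    ``average="exposure"`` (default) computes exposure per frame and then
    averages; ``average="sasa"`` averages SASA first and divides once —
    identical for a fixed MSA, offered for sensitivity analysis.
    """
    if msa is None:
        raise ValueError("an MsaTable is required")
    radii = radii or RadiiSet()
    profiles = []
    for frame in frames:
        atom_sasa = shrake_rupley_sasa(frame, radii)
        profiles.append(residue_exposure(atom_sasa, frame, msa, scope))
    base = profiles[0].table.copy()
    sasa_stack = np.stack([p.table["sasa_abs"].to_numpy() for p in profiles])
    expo_stack = np.stack(
        [p.table["exposure_pct"].to_numpy() for p in profiles]
    )
    base["sasa_abs"] = sasa_stack.mean(axis=0)
    if average == "sasa":
        base["exposure_pct"] = 100.0 * base["sasa_abs"] / base["msa"]
    else:
        base["exposure_pct"] = expo_stack.mean(axis=0)
    base["over_reference"] = base["exposure_pct"] > 100.0
    return ExposureProfile(table=base, scope=scope, n_frames=frames.n_frames)


def compute_msa_reference(
    tripeptides: dict[str, Ensemble],
    radii: RadiiSet | None = None,
    mode: str = "max",
) -> MsaTable:
    """Reference MSA table from Gly–X–Gly tripeptide conformer ensembles.

    For each residue type X, the SASA of the central X residue is evaluated
    in every supplied conformer; the table entry is the maximum (default) or
    mean over conformers.
    """
    if mode not in ("max", "mean"):
        raise ValueError("mode must be 'max' or 'mean'")
    radii = radii or RadiiSet()
    agg = np.max if mode == "max" else np.mean
    whole: dict[str, float] = {}
    side: dict[str, float] = {}
    for res_name, ens in tripeptides.items():
        w_vals, s_vals = [], []
        for frame in ens:
            res_names = frame.atoms.res_name
            res_ids = frame.atoms.res_id
            uniq = pd.unique(res_ids)
            if len(uniq) != 3:
                raise ValueError(
                    f"{res_name}: expected a tripeptide, got {len(uniq)} residues"
                )
            central = uniq[1]
            if not np.all(res_names[res_ids == central] == res_name):
                raise ValueError(
                    f"central residue is not {res_name}: not a Gly-X-Gly fixture"
                )
            flank = np.isin(res_ids, [uniq[0], uniq[2]])
            if not np.all(res_names[flank] == "GLY"):
                raise ValueError(
                    f"{res_name}: flanking residues must be GLY"
                )
            atom_sasa = shrake_rupley_sasa(frame, radii)
            m_central = res_ids == central
            w_vals.append(atom_sasa[m_central].sum())
            s_vals.append(
                atom_sasa[m_central & _sidechain_mask(frame)].sum()
            )
        whole[res_name] = float(agg(w_vals))
        # glycine has no side chain: fall back to whole-residue reference
        s = float(agg(s_vals))
        side[res_name] = s if s > 0 else whole[res_name]
    return MsaTable(
        whole=whole,
        sidechain=side,
        provenance=f"Gly-X-Gly conformers, mode={mode}, "
        f"n_points={radii.n_sphere_points}, probe={radii.probe_radius}",
    )


def classify_cysteines(
    profile: ExposureProfile,
    exposed_threshold: float = 20.0,
    buried_threshold: float = 7.0,
) -> dict[str, list[tuple[str, int, float]]]:
    """Partition cysteines by side-chain exposure.

    Exposed means strictly above ``exposed_threshold`` (default 20%), buried
    strictly below ``buried_threshold`` (default 7%); everything else is
    intermediate. Each class lists (chain, residue_seq, exposure_pct) sorted
    by descending exposure.
    """
    if buried_threshold > exposed_threshold:
        raise ValueError("buried_threshold must be <= exposed_threshold")
    cys = profile.table[profile.table["residue_name"] == "CYS"]
    out: dict[str, list[tuple[str, int, float]]] = {
        "exposed": [],
        "intermediate": [],
        "buried": [],
    }
    for _, row in cys.iterrows():
        entry = (
            str(row["chain"]),
            int(row["residue_seq"]),
            float(row["exposure_pct"]),
        )
        if entry[2] > exposed_threshold:
            out["exposed"].append(entry)
        elif entry[2] < buried_threshold:
            out["buried"].append(entry)
        else:
            out["intermediate"].append(entry)
    for lst in out.values():
        lst.sort(key=lambda t: -t[2])
    return out
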