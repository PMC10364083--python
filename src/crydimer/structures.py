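"""Protein coordinate containers and PDB input/output.

A :class:`Structure` wraps a :class:`biotite.structure.AtomArray` — the
standard numpy-backed coordinate container — and an :class:`Ensemble` is an
ordered list of topology-identical frames standing in for a trajectory
(multi-model PDB files, one frame per ``MODEL`` block).

Coordinates are orthogonal ångströms throughout; ``CRYST1`` records are
ignored (ensembles are assumed whole-molecule and pre-imaged).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "PDBError",
    "PDBParseError",
    "TopologyError",
    "read_pdb",
    "write_pdb",
    "split_chains",
]

_WATER_NAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL", "DOD"}


class PDBError(ValueError):
    """Base class for PDB reading/writing problems."""


class PDBParseError(PDBError):
    """Malformed or unsupported PDB content."""


class TopologyError(PDBError):
    """Frames of a multi-model file do not share one topology."""


@dataclass(frozen=True)
class Atom:
    """A single atom record (a read-only view onto a :class:`Structure` row)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""


class Structure:
    """One set of coordinates: atoms grouped into residues and chains.

    Parameters
    ----------
    atoms : biotite.structure.AtomArray
        Backing array. ``occupancy`` and ``atom_id`` annotation categories
        are added if missing.
    title : str
        Free-text title carried through I/O.
    """

    def __init__(self, atoms: struc.AtomArray, title: str = ""):
        if atoms.array_length() == 0:
            raise PDBParseError("structure contains no atoms")
        if "occupancy" not in atoms.get_annotation_categories():
            atoms.set_annotation(
                "occupancy", np.ones(atoms.array_length(), dtype=float)
            )
        if "atom_id" not in atoms.get_annotation_categories():
            atoms.set_annotation(
                "atom_id", np.arange(1, atoms.array_length() + 1)
            )
        if not np.all(np.isfinite(atoms.coord)):
            raise PDBParseError("non-finite coordinates")
        self.atoms = atoms
        self.title = title

    @classmethod
    def from_arrays(
        cls,
        coords: np.ndarray,
        elements: Sequence[str],
        atom_names: Sequence[str] | None = None,
        res_names: Sequence[str] | None = None,
        res_ids: Sequence[int] | None = None,
        chain_ids: Sequence[str] | None = None,
        hetero: Sequence[bool] | None = None,
        title: str = "",
    ) -> "Structure":
        """Build a structure from plain arrays (fixtures and toy systems)."""
        coords = np.asarray(coords, dtype=np.float32).reshape(-1, 3)
        n = len(coords)
        arr = struc.AtomArray(n)
        arr.coord = coords
        arr.element = np.asarray(elements, dtype="U2")
        arr.atom_name = (
            np.asarray(atom_names, dtype="U6")
            if atom_names is not None
            else np.asarray(elements, dtype="U6")
        )
        arr.res_name = (
            np.asarray(res_names, dtype="U5")
            if res_names is not None
            else np.full(n, "UNK", dtype="U5")
        )
        arr.res_id = (
            np.asarray(res_ids, dtype=int)
            if res_ids is not None
            else np.ones(n, dtype=int)
        )
        arr.chain_id = (
            np.asarray(chain_ids, dtype="U4")
            if chain_ids is not None
            else np.full(n, "A", dtype="U4")
        )
        arr.hetero = (
            np.asarray(hetero, dtype=bool)
            if hetero is not None
            else np.zeros(n, dtype=bool)
        )
        return cls(arr, title=title)

    # -- basic accessors ---------------------------------------------------

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float coordinate array, Å."""
        return self.atoms.coord

    @coords.setter
    def coords(self, value: np.ndarray) -> None:
        self.atoms.coord = np.asarray(value, dtype=np.float32).reshape(-1, 3)

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for cid in self.atoms.chain_id:
            seen.setdefault(str(cid), None)
        return list(seen)

    def __len__(self) -> int:
        return self.n_atoms

    def __iter__(self) -> Iterator[Atom]:
        a = self.atoms
        for i in range(self.n_atoms):
            yield Atom(
                serial=int(a.atom_id[i]),
                name=str(a.atom_name[i]),
                element=str(a.element[i]),
                residue_name=str(a.res_name[i]),
                residue_seq=int(a.res_id[i]),
                chain_id=str(a.chain_id[i]),
                position=a.coord[i].copy(),
                occupancy=float(a.occupancy[i]),
            )

    def copy(self) -> "Structure":
        return Structure(self.atoms.copy(), title=self.title)

    # -- selection helpers -------------------------------------------------

    def mask(self, mask: np.ndarray) -> "Structure":
        """Sub-structure from a boolean atom mask (order preserved)."""
        return Structure(self.atoms[np.asarray(mask, dtype=bool)], self.title)

    def chain(self, chain_id: str) -> "Structure":
        m = self.atoms.chain_id == chain_id
        if not m.any():
            raise KeyError(f"no chain {chain_id!r}")
        return self.mask(m)

    def residue_mask(self, chain_id: str, residue_seq: int) -> np.ndarray:
        return (self.atoms.chain_id == chain_id) & (
            self.atoms.res_id == residue_seq
        )

    def atom_index(
        self, chain_id: str, residue_seq: int, atom_name: str
    ) -> int:
        """Index of a uniquely named atom; KeyError when absent."""
        m = self.residue_mask(chain_id, residue_seq) & (
            self.atoms.atom_name == atom_name
        )
        idx = np.flatnonzero(m)
        if idx.size == 0:
            raise KeyError(
                f"atom {atom_name} of {chain_id}:{residue_seq} not found"
            )
        return int(idx[0])

    def without_hydrogens(self) -> "Structure":
        return self.mask(self.atoms.element != "H")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly moved copy: ``x -> R x + t``."""
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out


class Ensemble:
    """Ordered frames over one topology (same atom count, names, order)."""

    def __init__(self, frames: Sequence[Structure]):
        frames = list(frames)
        if not frames:
            raise TopologyError("ensemble needs at least one frame")
        ref = frames[0]
        for k, fr in enumerate(frames[1:], start=2):
            if fr.n_atoms != ref.n_atoms:
                raise TopologyError(
                    f"frame {k} has {fr.n_atoms} atoms, expected {ref.n_atoms}"
                )
            if not (
                np.array_equal(fr.atoms.atom_name, ref.atoms.atom_name)
                and np.array_equal(fr.atoms.chain_id, ref.atoms.chain_id)
                and np.array_equal(fr.atoms.res_id, ref.atoms.res_id)
            ):
                raise TopologyError(f"frame {k} topology differs from frame 1")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def topology(self) -> Structure:
        return self.frames[0]

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Structure:
        return self.frames[i]

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([f.coords for f in self.frames])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _find_bad_atom_line(text: str) -> int | None:
    for ln, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError):
                return ln
    return None


def read_pdb(
    source,
    alt_loc_policy: str = "highest_occupancy",
    skip_waters: bool = False,
    strip_hydrogens: bool = False,
) -> Ensemble:
    """Read a PDB file or text into an :class:`Ensemble`.

    One frame per ``MODEL`` block; a file without ``MODEL`` records yields a
    single-frame ensemble. HETATM records (e.g. the FAD cofactor) are kept as
    their own residues; waters are dropped when ``skip_waters`` is set.

    ``alt_loc_policy`` resolves alternate locations: ``"first"`` keeps the
    first-listed conformer, ``"highest_occupancy"`` (default) the one with the
    largest occupancy, ties broken by first occurrence. Residue insertion
    codes are rejected: they would make (chain, residue number) keys ambiguous
    downstream.
    """
    if hasattr(source, "read"):
        text = source.read()
        if isinstance(text, bytes):
            text = text.decode()
    else:
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, TypeError):
            text = str(source)

    altloc = {"first": "first", "highest_occupancy": "occupancy"}.get(
        alt_loc_policy
    )
    if altloc is None:
        raise ValueError(f"unknown alt_loc_policy {alt_loc_policy!r}")

    try:
        pdb = PDBFile.read(io.StringIO(text))
        stack = pdb.get_structure(
            model=None, altloc=altloc, extra_fields=["occupancy", "atom_id"]
        )
    except Exception as exc:
        bad = _find_bad_atom_line(text)
        if bad is not None:
            raise PDBParseError(
                f"malformed ATOM/HETATM record at line {bad}"
            ) from exc
        if isinstance(exc, struc.BadStructureError) or "model" in str(exc).lower():
            raise TopologyError(str(exc)) from exc
        raise PDBParseError(f"cannot parse PDB input: {exc}") from exc

    if stack.array_length() == 0:
        raise PDBParseError("PDB input contains no atoms")
    if "ins_code" in stack.get_annotation_categories() and np.any(
        stack.ins_code != ""
    ):
        raise PDBParseError(
            "residue insertion codes are not supported; renumber the model"
        )

    title = " ".join(
        line[10:].strip()
        for line in text.splitlines()
        if line.startswith("TITLE")
    )

    keep = np.ones(stack.array_length(), dtype=bool)
    if skip_waters:
        keep &= ~np.isin(stack.res_name, list(_WATER_NAMES))
    if strip_hydrogens:
        keep &= stack.element != "H"
    stack = stack[..., keep]
    if stack.array_length() == 0:
        raise PDBParseError("no atoms remain after filtering")

    frames = [
        Structure(stack[i], title=title) for i in range(stack.stack_depth())
    ]
    return Ensemble(frames)


def write_pdb(ensemble: Ensemble | Structure, destination=None) -> str:
    """Render an ensemble (or single structure) as fixed-column PDB text.

    ``MODEL``/``ENDMDL`` blocks are emitted only for multi-frame ensembles;
    coordinates are written to 3 decimals. Returns the text; also writes it
    to ``destination`` (path or handle) when given.
    """
    if isinstance(ensemble, Structure):
        ensemble = Ensemble([ensemble])
    coords = ensemble.coords()
    if np.any(np.abs(coords) >= 10000.0):
        raise PDBError(
            "coordinate magnitude >= 10000 Å overflows fixed PDB columns"
        )
    pdb = PDBFile()
    if ensemble.n_frames == 1:
        pdb.set_structure(ensemble.topology.atoms)
    else:
        arrays = [f.atoms for f in ensemble.frames]
        stack = struc.stack(arrays)
        pdb.set_structure(stack)
    buf = io.StringIO()
    pdb.write(buf)
    text = buf.getvalue()
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w") as fh:
                fh.write(text)
    return text


def split_chains(structure: Structure) -> list[Structure]:
    """One sub-structure per chain identifier, atom order preserved.

    The outputs partition the input: their atom counts sum to the total and
    no atom appears twice (needed when buried interface area is computed from
    monomer and complex surface areas).
    """
    return [structure.chain(cid) for cid in structure.chain_ids]
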