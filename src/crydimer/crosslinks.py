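"""Cross-link and disulfide distance constraints on monomer/dimer models.

Cross-linking mass spectrometry identifies residue pairs joined by a
bifunctional linker; each identification implies a ceiling on the Cα–Cα
distance (≈27 Å for the lysine-reactive, MS-cleavable linkers DSSO and
DSBU, spacer plus two side chains). Disulfide identifications constrain
the Sγ–Sγ distance instead. For a homodimer each record can be realised
intra-chain (A–A, B–B) or inter-chain (A–B, B–A); all assignments are
evaluated and a record is *ambiguous* when both kinds satisfy the ceiling.

Self-pairs (a residue linked to its own sequence position, e.g. the
C412–C412 pattern) have no intra-chain realisation — a residue cannot link
to itself — so they are inter-only testable and, when found in the dimer
fraction, unequivocally intermolecular.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import Structure

__all__ = [
    "CrossLinkRecord",
    "ConstraintResult",
    "DEFAULT_CEILINGS",
    "parse_crosslink_table",
    "evaluate_constraint",
    "classify_links",
    "constraint_report",
    "write_dot",
]

# Default Cα–Cα / Sγ–Sγ ceilings, Å, per linker chemistry.
DEFAULT_CEILINGS = {"DSSO": 27.0, "DSBU": 27.0, "disulfide": 6.0}
# A formed disulfide (as opposed to a formable one) is essentially at bond
# length; used when mode="formed".
FORMED_DISULFIDE_CEILING = 2.5

_LINKER_RESIDUE = {"DSSO": "LYS", "DSBU": "LYS", "disulfide": "CYS"}
_LINKER_ATOM = {"DSSO": "CA", "DSBU": "CA", "disulfide": "SG"}

_PROVENANCES = {"monomer_fraction", "dimer_fraction", "both", "unknown"}


@dataclass
class CrossLinkRecord:
    """One identified residue-pair restraint."""

    residue_a: tuple[int, str]     # (residue_seq, residue_name)
    residue_b: tuple[int, str]
    linker: str                    # DSSO | DSBU | disulfide
    ceiling: float                 # Å
    provenance: str = "unknown"    # monomer_fraction | dimer_fraction | both
    assignment: str = "ambiguous"  # intra | inter | ambiguous (from provenance)

    def __post_init__(self):
        if self.linker not in DEFAULT_CEILINGS:
            raise ValueError(f"unknown linker {self.linker!r}")
        if self.ceiling <= 0:
            raise ValueError("ceiling must be > 0")
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def is_self_pair(self) -> bool:
        return self.residue_a[0] == self.residue_b[0]

    @property
    def measured_atom(self) -> str:
        return _LINKER_ATOM[self.linker]


@dataclass
class ConstraintResult:
    """Distance evaluation of one record on one model."""

    record: CrossLinkRecord
    intra_distances: dict[str, float] = field(default_factory=dict)  # chain → Å
    inter_distances: dict[str, float] = field(default_factory=dict)  # "A-B" → Å
    satisfied_as: set[str] = field(default_factory=set)  # ⊆ {intra, inter}
    verdict: str = "violated"     # satisfied | violated | ambiguous


def _residue_token(tok: str) -> tuple[int, str]:
    """'K152' → (152, 'LYS'); 'C412' → (412, 'CYS'); plain int → UNK."""
    one_to_three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    tok = tok.strip()
    if tok[:1].isalpha():
        code = one_to_three.get(tok[0].upper())
        if code is None:
            raise ValueError(f"unknown residue letter in {tok!r}")
        return int(tok[1:]), code
    return int(tok), "UNK"


def parse_crosslink_table(
    source,
    ceilings: dict[str, float] | None = None,
) -> list[CrossLinkRecord]:
    """Read a delimited cross-link table into validated records.

    Required columns: residue_a, residue_b, linker, provenance. Residues
    are one-letter-plus-number tokens ("K152") or bare sequence numbers.
    The delimiter (comma or tab) is sniffed. Residue-type compatibility
    with the linker chemistry is checked here for lettered tokens and again
    at model lookup.
    """
    ceilings = {**DEFAULT_CEILINGS, **(ceilings or {})}
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, TypeError):
            text = str(source)
    text = text.strip()
    if not text:
        return []
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, skipinitialspace=True)
    needed = {"residue_a", "residue_b", "linker", "provenance"}
    if not needed.issubset(df.columns):
        raise ValueError(
            f"missing columns: {sorted(needed - set(df.columns))}"
        )
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ra = _residue_token(str(row.residue_a))
            rb = _residue_token(str(row.residue_b))
            linker = str(row.linker).strip()
            rec = CrossLinkRecord(
                residue_a=ra,
                residue_b=rb,
                linker=linker,
                ceiling=ceilings[linker] if linker in ceilings else -1.0,
                provenance=str(row.provenance).strip(),
            )
            expected = _LINKER_RESIDUE[linker]
            for seq, name in (ra, rb):
                if name not in ("UNK", expected):
                    raise ValueError(
                        f"{name}{seq} is incompatible with linker {linker}"
                    )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed row at line {row_no}: {exc}") from exc
        records.append(rec)
    return records


def _locate(
    model: Structure, chain: str, residue_seq: int, atom_name: str
) -> np.ndarray:
    a = model.atoms
    m = (
        (a.chain_id == chain)
        & (a.res_id == residue_seq)
        & (a.atom_name == atom_name)
    )
    idx = np.flatnonzero(m)
    if idx.size == 0:
        raise KeyError(
            f"residue {chain}:{residue_seq} (atom {atom_name}) "
            "not resolvable in model"
        )
    return model.coords[idx[0]].astype(float)


def evaluate_constraint(
    model: Structure, record: CrossLinkRecord
) -> ConstraintResult:
    """Evaluate one record on a 1- or 2-chain model.

    For a homodimer all four chain assignments (A–A, B–B, A–B, B–A) are
    measured; ``satisfied_as`` collects every assignment *kind* whose
    distance is within the ceiling. Verdict: satisfied if any assignment
    passes, ambiguous if both intra and inter pass. Self-pairs skip the
    (undefined) intra assignment.
    """
    chains = model.chain_ids
    if len(chains) not in (1, 2):
        raise ValueError("model must have 1 or 2 chains")
    atom = record.measured_atom
    seq_a, seq_b = record.residue_a[0], record.residue_b[0]
    res = ConstraintResult(record=record)

    if not record.is_self_pair:
        for cid in chains:
            d = float(
                np.linalg.norm(
                    _locate(model, cid, seq_a, atom)
                    - _locate(model, cid, seq_b, atom)
                )
            )
            res.intra_distances[cid] = d
            if d <= record.ceiling:
                res.satisfied_as.add("intra")
    if len(chains) == 2:
        ca, cb = chains
        for (c1, c2) in ((ca, cb), (cb, ca)):
            d = float(
                np.linalg.norm(
                    _locate(model, c1, seq_a, atom)
                    - _locate(model, c2, seq_b, atom)
                )
            )
            res.inter_distances[f"{c1}-{c2}"] = d
            if d <= record.ceiling:
                res.satisfied_as.add("inter")

    if {"intra", "inter"} <= res.satisfied_as:
        res.verdict = "ambiguous"
    elif res.satisfied_as:
        res.verdict = "satisfied"
    else:
        res.verdict = "violated"
    return res


def classify_links(records: list[CrossLinkRecord]) -> list[CrossLinkRecord]:
    """Assign intra/inter from fraction provenance (in place, also returned).

    Links seen only in the dimer fraction are intermolecular; links also
    present in the monomer fraction lean intramolecular; self-pairs in the
    dimer fraction are intermolecular regardless (a residue cannot link to
    itself). Unknown provenance stays ambiguous.
    """
    for rec in records:
        if rec.provenance == "dimer_fraction":
            rec.assignment = "inter"
        elif rec.provenance in ("monomer_fraction", "both"):
            rec.assignment = "inter" if rec.is_self_pair else "intra"
        else:
            rec.assignment = "ambiguous"
    return records


def constraint_report(
    model: Structure, records: list[CrossLinkRecord]
) -> tuple[pd.DataFrame, dict]:
    """Per-record verdict table plus summary counts.

    Rows are ordered by residue_a sequence number (then residue_b) for
    deterministic output. The summary dict reports counts per verdict and
    the fraction satisfied (ambiguous counts as satisfied: some assignment
    works).
    """
    classify_links(records)
    rows = []
    for rec in sorted(records, key=lambda r: (r.residue_a[0], r.residue_b[0])):
        result = evaluate_constraint(model, rec)
        intra_min = (
            min(result.intra_distances.values())
            if result.intra_distances
            else np.nan
        )
        inter_min = (
            min(result.inter_distances.values())
            if result.inter_distances
            else np.nan
        )
        rows.append(
            {
                "residue_a": f"{rec.residue_a[1]}{rec.residue_a[0]}",
                "residue_b": f"{rec.residue_b[1]}{rec.residue_b[0]}",
                "linker": rec.linker,
                "ceiling_A": rec.ceiling,
                "provenance": rec.provenance,
                "assignment": rec.assignment,
                "intra_min_A": intra_min,
                "inter_min_A": inter_min,
                "satisfied_as": "+".join(sorted(result.satisfied_as)) or "none",
                "verdict": result.verdict,
                "self_pair_inter_only": rec.is_self_pair,
            }
        )
    table = pd.DataFrame(rows)
    n = len(table)
    summary = {
        "n_records": n,
        "satisfied": int((table["verdict"] != "violated").sum()) if n else 0,
        "violated": int((table["verdict"] == "violated").sum()) if n else 0,
        "ambiguous": int((table["verdict"] == "ambiguous").sum()) if n else 0,
        "fraction_satisfied": (
            float((table["verdict"] != "violated").mean()) if n else float("nan")
        ),
    }
    return table, summary


def write_dot(records: list[CrossLinkRecord], path=None) -> str:
    """Cross-link network in DOT format (nodes = residues, edges = links)."""
    lines = ["graph crosslinks {", "  node [shape=circle];"]
    for rec in records:
        a = f"{rec.residue_a[1]}{rec.residue_a[0]}"
        b = f"{rec.residue_b[1]}{rec.residue_b[0]}"
        style = {
            "inter": "solid",
            "intra": "dashed",
            "ambiguous": "dotted",
        }[rec.assignment]
        lines.append(
            f'  "{a}" -- "{b}" [label="{rec.linker}", style={style}];'
        )
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
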