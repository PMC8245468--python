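"""Readers and validators for the file formats the pipeline consumes.

Structures come as legacy fixed-column PDB (parsed through :mod:`gemmi`),
secondary structure and accessibility as classic DSSP text output, sequence
profiles as PSI-BLAST ``-out_ascii_pssm`` files, sequences as FASTA, and the
variant list as a tab-separated table with header
``protein_id  chain  seq_pos  struct_pos  wt  mut  [label]``.

All 20-vectors (PSSM rows) are normalised to the canonical residue order
``ARNDCQEGHILKMFPSTWYV``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .residue_classes import AMINO_ACIDS, THREE_TO_ONE


class FormatError(ValueError):
    """Raised when an input file does not follow its declared format."""


class ValidationError(ValueError):
    """Raised when a record is syntactically fine but semantically invalid."""


# ---------------------------------------------------------------------------
# structures

@dataclass(frozen=True)
class Atom:
    """One coordinate record of a structure model (author numbering)."""

    chain_id: str
    residue_seq: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    b_factor: float
    is_hetero: bool

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureModel:
    """An ordered collection of atoms with unique (chain, seq, name) keys."""

    def __init__(self, atoms: Iterable[Atom]):
        self.atoms: list[Atom] = list(atoms)
        if not self.atoms:
            raise FormatError("structure model contains no atoms")
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_seq, a.atom_name)
            if key in seen:
                raise ValidationError(f"duplicate atom {key} in model")
            seen.add(key)

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def get_atom(self, chain_id: str, residue_seq: int, atom_name: str) -> Atom | None:
        for a in self.atoms:
            if (a.chain_id, a.residue_seq, a.atom_name) == (chain_id, residue_seq, atom_name):
                return a
        return None

    def __len__(self) -> int:
        return len(self.atoms)

    def is_water(self, atom: Atom) -> bool:
        return atom.residue_name.upper() in _WATER_NAMES

    def is_protein(self, atom: Atom) -> bool:
        """Standard amino-acid residue recorded as a polymer (ATOM) atom."""
        return (not atom.is_hetero) and atom.residue_name.upper() in THREE_TO_ONE


def parse_pdb(path: str | Path) -> StructureModel:
    """Parse a legacy fixed-column PDB file into a :class:`StructureModel`.

    Only the first model of a multi-model file is read. Alternate locations
    collapse to the highest-occupancy conformer (first wins ties). Insertion
    codes are rejected: author numbering must be unambiguous because variant
    positions are matched against it.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # pre-scan so a malformed coordinate line is reported with its line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    raise FormatError(
                        f"{path.name}: malformed coordinate record at line {lineno}"
                    ) from None

    structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(structure) == 0:
        raise FormatError(f"{path.name}: no model found")
    model = structure[0]

    best: dict[tuple[str, int, str], tuple[float, int, Atom]] = {}
    order = 0
    for chain in model:
        for res in chain:
            icode = str(res.seqid.icode).strip()
            if icode:
                raise ValidationError(
                    f"{path.name}: insertion code {icode!r} at {chain.name}{res.seqid.num} "
                    "is not supported (author numbering must be unambiguous)"
                )
            is_het = res.het_flag == "H"
            for at in res:
                atom = Atom(
                    chain_id=chain.name,
                    residue_seq=res.seqid.num,
                    residue_name=res.name,
                    atom_name=at.name,
                    element=at.element.name,
                    x=at.pos.x, y=at.pos.y, z=at.pos.z,
                    b_factor=at.b_iso,
                    is_hetero=is_het,
                )
                key = (chain.name, res.seqid.num, at.name)
                occ = at.occ
                if key not in best or occ > best[key][0]:
                    if key not in best:
                        best[key] = (occ, order, atom)
                        order += 1
                    else:
                        best[key] = (occ, best[key][1], atom)
    atoms = [a for _, _, a in sorted(best.values(), key=lambda t: t[1])]
    if not atoms:
        raise FormatError(f"{path.name}: empty model")
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# DSSP

SS8_STATES = ("H", "B", "E", "G", "I", "T", "S", "other")


@dataclass(frozen=True)
class DsspResidue:
    """One residue line of classic DSSP output.

    ``aa_code`` keeps DSSP's lowercase letters, which label half-cystines of
    a disulfide bridge. ``nh_o_energy`` / ``o_hn_energy`` are the first-listed
    (strongest) backbone H-bond energies in kcal/mol; the second-listed pair
    is retained for the summed-energy variant.
    """

    chain_id: str
    residue_seq: int
    aa_code: str
    ss8: str
    acc: float
    nh_o_energy: float
    o_hn_energy: float
    nh_o_energy_2: float = 0.0
    o_hn_energy_2: float = 0.0

    def __post_init__(self):
        if self.ss8 not in SS8_STATES:
            raise ValidationError(f"ss8 {self.ss8!r} outside the 8-state alphabet")
        if self.acc < 0:
            raise ValidationError("accessibility must be non-negative")

    @property
    def is_half_cystine(self) -> bool:
        return self.aa_code.islower()


def normalize_ss8(symbol: str) -> str:
    """Map any DSSP secondary-structure symbol into the closed 8-state set.

    Blank (loop) and every symbol outside {H,B,E,G,I,T,S} — including the
    newer polyproline "P" state — become ``"other"``.
    """
    return symbol if symbol in SS8_STATES[:7] else "other"


def _hb_energy(fieldtext: str) -> float:
    parts = fieldtext.split(",")
    if len(parts) != 2:
        raise FormatError(f"malformed H-bond field {fieldtext!r}")
    return float(parts[1])


def parse_dssp(path: str | Path) -> list[DsspResidue]:
    """Parse classic DSSP text output into per-residue records.

    Chain-break lines (``!`` in the amino-acid column) are skipped.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise FormatError(f"{path.name}: DSSP residue header ('#  RESIDUE') not found")

    records: list[DsspResidue] = []
    for line in lines[start:]:
        if len(line) < 38 or line[13] == "!":
            continue
        records.append(
            DsspResidue(
                chain_id=line[11].strip(),
                residue_seq=int(line[5:10]),
                aa_code=line[13],
                ss8=normalize_ss8(line[16]),
                acc=float(line[34:38]),
                nh_o_energy=_hb_energy(line[39:50]),
                o_hn_energy=_hb_energy(line[50:61]),
                nh_o_energy_2=_hb_energy(line[61:72]) if len(line) >= 72 else 0.0,
                o_hn_energy_2=_hb_energy(line[72:83]) if len(line) >= 83 else 0.0,
            )
        )
    return records


# ---------------------------------------------------------------------------
# PSSM

@dataclass
class PssmProfile:
    """PSI-BLAST profile: per-position log-odds and observed percentages.

    Columns follow the canonical order ``ARNDCQEGHILKMFPSTWYV``. Positions are
    1-based in the public accessors.
    """

    sequence: str
    log_odds: np.ndarray  # (L, 20) float
    obs_pct: np.ndarray   # (L, 20) float, rows sum to ~100

    def __post_init__(self):
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.obs_pct = np.asarray(self.obs_pct, dtype=float)
        L = len(self.sequence)
        if self.log_odds.shape != (L, 20) or self.obs_pct.shape != (L, 20):
            raise ValidationError("profile blocks do not match sequence length")
        if (self.obs_pct < 0).any():
            raise ValidationError("observed percentages must be non-negative")

    def __len__(self) -> int:
        return len(self.sequence)

    def log_odds_at(self, pos: int, residue: str) -> float:
        """Log-odds score of ``residue`` at 1-based position ``pos``."""
        return float(self.log_odds[pos - 1, AMINO_ACIDS.index(residue)])


def parse_pssm(path: str | Path) -> PssmProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file."""
    path = Path(path)
    lines = path.read_text().splitlines()

    header_order: list[str] | None = None
    seq: list[str] = []
    lods: list[list[float]] = []
    pcts: list[list[float]] = []
    for line in lines:
        tokens = line.split()
        if header_order is None:
            if len(tokens) >= 40 and all(len(t) == 1 and t.isalpha() for t in tokens[:40]):
                header_order = tokens[:20]
            continue
        if len(tokens) >= 42 and tokens[0].isdigit() and len(tokens[1]) == 1:
            seq.append(tokens[1])
            lods.append([float(v) for v in tokens[2:22]])
            pcts.append([float(v) for v in tokens[22:42]])
        elif len(tokens) >= 22 and tokens[0].isdigit() and len(tokens[1]) == 1:
            raise FormatError(f"{path.name}: percentage block missing on row {tokens[0]}")
    if header_order is None:
        raise FormatError(f"{path.name}: PSSM column header not found")
    if not seq:
        raise FormatError(f"{path.name}: no profile rows found")
    if len(lods) != len(pcts):
        raise FormatError(f"{path.name}: block row counts differ")

    # normalise column order to ARNDCQEGHILKMFPSTWYV
    perm = [header_order.index(a) for a in AMINO_ACIDS]
    log_odds = np.array(lods)[:, perm]
    obs_pct = np.array(pcts)[:, perm]
    return PssmProfile("".join(seq), log_odds, obs_pct)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> str:
    """First sequence of a FASTA file, uppercased."""
    for rec in SeqIO.parse(str(path), "fasta"):
        return str(rec.seq).upper()
    raise FormatError(f"{Path(path).name}: no FASTA record found")


# ---------------------------------------------------------------------------
# SAV tables

LABELS = ("cancer", "neutral", "unknown")


@dataclass(frozen=True)
class SAVRecord:
    """One single amino acid variant.

    ``seq_pos`` indexes the SAV sequence (1-based); ``struct_pos`` is the
    author residue number in the matched structure.
    """

    protein_id: str
    chain_id: str
    seq_pos: int
    struct_pos: int
    wt: str
    mut: str
    label: str = "unknown"

    def __post_init__(self):
        if self.wt not in AMINO_ACIDS or self.mut not in AMINO_ACIDS:
            raise ValidationError(
                f"{self.protein_id}: residues must be standard 1-letter codes, "
                f"got wt={self.wt!r} mut={self.mut!r}"
            )
        if self.wt == self.mut:
            raise ValidationError(f"{self.protein_id}: wild-type equals mutant ({self.wt})")
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")
        if self.seq_pos < 1 or self.struct_pos < 1:
            raise ValidationError("positions are 1-based and must be >= 1")


SAV_COLUMNS = ["protein_id", "chain", "seq_pos", "struct_pos", "wt", "mut", "label"]


def read_sav_table(path: str | Path) -> list[SAVRecord]:
    """Read the tab-separated SAV list (label column optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = SAV_COLUMNS[:-1]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"SAV table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        label = row.get("label")
        if label is None or (isinstance(label, float) and math.isnan(label)):
            label = "unknown"
        records.append(
            SAVRecord(
                protein_id=row["protein_id"],
                chain_id=row["chain"],
                seq_pos=int(row["seq_pos"]),
                struct_pos=int(row["struct_pos"]),
                wt=row["wt"],
                mut=row["mut"],
                label=str(label),
            )
        )
    return records


def write_sav_table(records: Sequence[SAVRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.protein_id, r.chain_id, r.seq_pos, r.struct_pos, r.wt, r.mut, r.label)
            for r in records
        ],
        columns=SAV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# substitution matrices

class SubstitutionMatrix:
    """Symmetric 20x20 residue substitution score table."""

    def __init__(self, name: str, table):
        self.name = name
        self._table = table

    def score(self, a: str, b: str) -> float:
        return float(self._table[a, b])

    def __call__(self, a: str, b: str) -> float:
        return self.score(a, b)


_MATRICES = ("BLOSUM62", "PAM250")


def load_substitution_matrix(name: str) -> SubstitutionMatrix:
    """Load a standard NCBI substitution matrix (``BLOSUM62`` or ``PAM250``)."""
    if name not in _MATRICES:
        raise ValueError(f"unknown matrix {name!r}; available: {', '.join(_MATRICES)}")
    return SubstitutionMatrix(name, substitution_matrices.load(name))
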