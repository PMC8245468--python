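"""Seeded generators for toy structures, profiles, and labeled SAV datasets.

These emulate the *formats and statistical shape* of real inputs so every
pipeline stage runs offline: idealized extended-chain geometry with 3.8-A
Calpha spacing (not folded protein), synthetic DSSP records written in the
classic text layout (states and accessibilities are drawn, not computed from
the coordinates), profile files in the PSI-BLAST ASCII layout, and planted
class-conditional Gaussian descriptor matrices whose informative columns are
known ground truth for feature-selection benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import Atom, DsspResidue, PssmProfile, SAVRecord, StructureModel
from .microenv_descriptors import MICROENV_FEATURE_NAMES
from .residue_classes import AMINO_ACIDS, ONE_TO_THREE
from .seq_descriptors import SEQUENCE_FEATURE_NAMES
from .struct_descriptors import MAX_ASA, STRUCTURE_FEATURE_NAMES

ALL_FEATURE_NAMES: dict[str, list[str]] = {
    "sequence": SEQUENCE_FEATURE_NAMES,
    "structure": STRUCTURE_FEATURE_NAMES,
    "microenvironment": MICROENV_FEATURE_NAMES,
}

_SS_SYMBOLS = "HBEGITS "  # blank = loop ("other")


# ---------------------------------------------------------------------------
# toy structures + DSSP

def make_toy_structure(
    n_res: int,
    n_chains: int = 1,
    het_atoms: int = 0,
    seed: int = 0,
) -> tuple[StructureModel, list[DsspResidue]]:
    """Idealized multi-chain peptide with self-consistent DSSP records.

    Chains run along x with 3.8-A Calpha spacing and are stacked 8 A apart in
    y. Each residue carries N, CA, C, O and (except glycine) CB atoms with
    small seeded jitter. ``het_atoms`` adds a ligand ("LIG") near the first
    chain's midpoint. DSSP states, accessibilities and H-bond energies are
    drawn from the seeded stream, not computed from geometry.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues per chain")
    rng = np.random.default_rng(seed)
    chain_ids = [chr(ord("A") + c) for c in range(n_chains)]
    atoms: list[Atom] = []
    dssp: list[DsspResidue] = []
    serial_dssp = 1
    for c, chain in enumerate(chain_ids):
        y0 = 8.0 * c
        for i in range(n_res):
            aa1 = AMINO_ACIDS[rng.integers(0, 20)]
            res3 = ONE_TO_THREE[aa1]
            x0 = 3.8 * i
            b = float(np.round(rng.uniform(5, 60), 2))
            jitter = lambda: float(rng.normal(0, 0.15))
            # Calpha positions are exact so backbone spacing is exactly 3.8 A
            placements = [
                ("N", "N", x0 - 1.2 + jitter(), y0 + 0.8 + jitter(), jitter()),
                ("CA", "C", x0, y0, 0.0),
                ("C", "C", x0 + 1.2 + jitter(), y0 - 0.7 + jitter(), jitter()),
                ("O", "O", x0 + 1.3 + jitter(), y0 - 1.9 + jitter(), jitter()),
            ]
            if aa1 != "G":
                placements.append(
                    ("CB", "C", x0 + jitter(), y0 + 1.4 + jitter(), 1.1 + jitter())
                )
            for name, elem, x, y, z in placements:
                atoms.append(
                    Atom(chain, i + 1, res3, name, elem, x, y, z, b, is_hetero=False)
                )
            ss = _SS_SYMBOLS[rng.integers(0, len(_SS_SYMBOLS))]
            aa_code = aa1.lower() if (aa1 == "C" and rng.random() < 0.5) else aa1
            dssp.append(
                DsspResidue(
                    chain_id=chain,
                    residue_seq=i + 1,
                    aa_code=aa_code,
                    ss8=ss if ss.strip() else "other",
                    acc=float(np.round(rng.uniform(0, MAX_ASA[res3]), 0)),
                    nh_o_energy=float(np.round(rng.uniform(-3.0, 0.0), 1)),
                    o_hn_energy=float(np.round(rng.uniform(-3.0, 0.0), 1)),
                )
            )
            serial_dssp += 1
    mid = 3.8 * (n_res - 1) / 2
    for h in range(het_atoms):
        atoms.append(
            Atom(
                "X", 900 + h, "LIG", f"C{h + 1}", "C",
                mid + float(rng.normal(0, 2)),
                -6.0 + float(rng.normal(0, 1)),
                float(rng.normal(0, 1)),
                30.0,
                is_hetero=True,
            )
        )
    return StructureModel(atoms), dssp


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model as fixed-column legacy PDB."""
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"{record}{i:5d} {name}{'':1s}{a.residue_name:>3s} {a.chain_id:1s}"
            f"{a.residue_seq:4d}{'':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.00:6.2f}{a.b_factor:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


_DSSP_HEADER = (
    "==== Secondary Structure Definition, synthetic fixture ====\n"
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
    "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA"
)


def write_dssp(records: Sequence[DsspResidue], path: str | Path) -> None:
    """Write records in the classic DSSP text layout."""
    lines = [_DSSP_HEADER]
    ss_out = {s: (s if s != "other" else " ") for s in
              ("H", "B", "E", "G", "I", "T", "S", "other")}
    for i, r in enumerate(records, start=1):
        hb1 = f"{0:4d},{r.nh_o_energy:5.1f} "
        hb2 = f"{0:4d},{r.o_hn_energy:5.1f} "
        hb3 = f"{0:4d},{r.nh_o_energy_2:5.1f} "
        hb4 = f"{0:4d},{r.o_hn_energy_2:5.1f} "
        lines.append(
            f"{i:5d}{r.residue_seq:5d} {r.chain_id:1s} {r.aa_code:1s}  "
            f"{ss_out[r.ss8]:1s}                 {r.acc:4.0f} "
            f"{hb1}{hb2}{hb3}{hb4}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# toy PSSM

def make_toy_pssm(
    sequence: str,
    conservation: Sequence[float] | float = 0.5,
    seed: int = 0,
) -> PssmProfile:
    """Profile whose observed percentages interpolate uniform (conservation 0)
    to one-hot on the sequence residue (conservation 1), with sign-consistent
    integer log-odds."""
    if np.isscalar(conservation):
        conservation = [float(conservation)] * len(sequence)
    if len(conservation) != len(sequence):
        raise ValueError("conservation length must match sequence length")
    L = len(sequence)
    obs = np.empty((L, 20))
    for i, (aa, c) in enumerate(zip(sequence, conservation)):
        if not 0.0 <= c <= 1.0:
            raise ValueError("conservation values must lie in [0, 1]")
        row = np.full(20, 100.0 * (1.0 - c) / 20.0)
        row[AMINO_ACIDS.index(aa)] += 100.0 * c
        obs[i] = row
    with np.errstate(divide="ignore"):
        lods = np.where(obs > 0, 2.0 * np.log2(np.maximum(obs, 1e-12) / 5.0), -9.0)
    lods = np.clip(np.round(lods), -9, 12)
    return PssmProfile(sequence, lods, obs)


def write_pssm(profile: PssmProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ``-out_ascii_pssm`` ASCII layout."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(AMINO_ACIDS) + "   "
        + "   ".join(AMINO_ACIDS),
    ]
    for i, aa in enumerate(profile.sequence):
        lod = " ".join(f"{int(v):3d}" for v in profile.log_odds[i])
        pct = " ".join(f"{v:5.1f}" for v in profile.obs_pct[i])
        lines.append(f"{i + 1:5d} {aa} {lod}  {pct}  0.50 0.10")
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# planted-feature labeled datasets

@dataclass
class SyntheticSpec:
    """Study conditions for a planted-feature benchmark dataset.

    Defaults mirror a small training group: 60 cancer-related and 120 neutral
    SAVs, two informative microenvironment descriptors whose class means are
    separated by 3 pooled standard deviations, unit noise elsewhere.
    """

    n_cancer: int = 60
    n_neutral: int = 120
    informative_descriptors: tuple[str, ...] = ("wcn_ca_chain", "wcn_o_chain")
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0
    wt: str = "A"
    mut_choices: tuple[str, ...] = ("V",)

    def __post_init__(self):
        if self.n_cancer <= 0 or self.n_neutral <= 0:
            raise ValueError("class counts must be positive")
        if self.effect_size < 0:
            raise ValueError("effect size must be non-negative")
        known = {n for names in ALL_FEATURE_NAMES.values() for n in names}
        unknown = set(self.informative_descriptors) - known
        if unknown:
            raise ValueError(f"unknown descriptors: {sorted(unknown)}")


@dataclass
class SyntheticDataset:
    records: list[SAVRecord]
    features: dict[str, pd.DataFrame]  # feature set -> (n, m) frame
    informative: tuple[str, ...]       # ground truth for recovery checks

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if r.label == "cancer" else 0 for r in self.records])


def make_synthetic_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Planted class-conditional Gaussian dataset over all 89 descriptors.

    Informative columns get class means +/- effect_size * noise_sd / 2 (cancer
    high); every other column is pure noise N(0, noise_sd).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cancer + spec.n_neutral
    y = np.array([1] * spec.n_cancer + [0] * spec.n_neutral)
    perm = rng.permutation(n)
    y = y[perm]
    shift = spec.effect_size * spec.noise_sd / 2.0
    features: dict[str, pd.DataFrame] = {}
    for fs, names in ALL_FEATURE_NAMES.items():
        X = rng.normal(0.0, spec.noise_sd, size=(n, len(names)))
        for j, name in enumerate(names):
            if name in spec.informative_descriptors:
                X[:, j] += np.where(y == 1, shift, -shift)
        features[fs] = pd.DataFrame(X, columns=names)
    records = []
    for i in range(n):
        mut = spec.mut_choices[int(rng.integers(0, len(spec.mut_choices)))]
        records.append(
            SAVRecord(
                protein_id=f"SYN{i:04d}",
                chain_id="A",
                seq_pos=i + 1,
                struct_pos=i + 1,
                wt=spec.wt,
                mut=mut,
                label="cancer" if y[i] == 1 else "neutral",
            )
        )
    return SyntheticDataset(records, features, spec.informative_descriptors)
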