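"""The 44 sequence-based descriptors of one SAV.

Three substitution indices (BLOSUM62, PAM250, PSSM log-odds of the mutant),
15 per-position Shannon entropies over a window of 7 residues on either side
of the SAV, the window-averaged entropies over 15 and 5 residues, and 24
amino-acid-composition fractions over the six physicochemical classification
schemes (H, V, Z, P, F, E).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_formats import PssmProfile, SAVRecord, load_substitution_matrix
from .residue_classes import AMINO_ACIDS, CLASS_SCHEMES, SCHEME_CLASS_PAIRS

ENTROPY_OFFSETS = range(-7, 8)

SEQUENCE_FEATURE_NAMES: list[str] = (
    ["sub_blosum62", "sub_pam250", "sub_pssm"]
    + [f"entropy_{o:+d}" for o in ENTROPY_OFFSETS]
    + ["entropy_avg15", "entropy_avg5"]
    + [f"aac_{scheme}_{cls}" for scheme, cls in SCHEME_CLASS_PAIRS]
)
assert len(SEQUENCE_FEATURE_NAMES) == 44

_BLOSUM62 = load_substitution_matrix("BLOSUM62")
_PAM250 = load_substitution_matrix("PAM250")


def substitution_indices(
    wt: str,
    mut: str,
    pssm: PssmProfile,
    pos: int,
    *,
    pssm_mode: str = "mutant",
) -> np.ndarray:
    """``[BLOSUM62(wt,mut), PAM250(wt,mut), PSSM log-odds]`` at 1-based ``pos``.

    ``pssm_mode="mutant"`` (default) uses the mutant's log-odds score;
    ``pssm_mode="difference"`` uses mutant minus wild-type.
    """
    if not 1 <= pos <= len(pssm):
        raise IndexError(f"position {pos} outside profile of length {len(pssm)}")
    if pssm.sequence[pos - 1] != wt:
        warnings.warn(
            f"wild-type {wt} does not match profile residue "
            f"{pssm.sequence[pos - 1]} at position {pos}",
            stacklevel=2,
        )
    score = pssm.log_odds_at(pos, mut)
    if pssm_mode == "difference":
        score -= pssm.log_odds_at(pos, wt)
    elif pssm_mode != "mutant":
        raise ValueError(f"unknown pssm_mode {pssm_mode!r}")
    return np.array([_BLOSUM62.score(wt, mut), _PAM250.score(wt, mut), score])


def position_entropy(pssm: PssmProfile, pos: int) -> float:
    """Shannon entropy (bits) of the observed-percentage distribution at ``pos``.

    Zero-probability residues contribute nothing; an all-zero row (a profile
    position with no observations) has entropy 0.
    """
    row = pssm.obs_pct[pos - 1]
    total = row.sum()
    if total <= 0:
        return 0.0
    p = row / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum()) + 0.0


def entropy_profile(pssm: PssmProfile, pos: int) -> np.ndarray:
    """17 conservation values around the SAV at 1-based ``pos``.

    Entries 0–14 are the entropies at offsets −7…+7; entry 15 averages the
    15-residue window, entry 16 the 5-residue window (offsets −2…+2). Offsets
    falling outside the sequence contribute a sentinel 0 and are excluded from
    the averages' denominators.
    """
    if not 1 <= pos <= len(pssm):
        raise IndexError(f"position {pos} outside profile of length {len(pssm)}")
    values = np.zeros(15)
    in_range = np.zeros(15, dtype=bool)
    for k, off in enumerate(ENTROPY_OFFSETS):
        p = pos + off
        if 1 <= p <= len(pssm):
            values[k] = position_entropy(pssm, p)
            in_range[k] = True
    avg15 = values[in_range].mean() if in_range.any() else 0.0
    mid = in_range[5:10]
    avg5 = values[5:10][mid].mean() if mid.any() else 0.0
    return np.concatenate([values, [avg15, avg5]])


def aac_features(sequence: str, pos: int) -> np.ndarray:
    """24 class-composition fractions of the 15-residue window centred at ``pos``.

    The window spans 7 residues on either side of the SAV and includes the SAV
    itself; at the termini it is truncated and fractions are taken over the
    actual window length, so each scheme's fractions still sum to 1.
    """
    if not 1 <= pos <= len(sequence):
        raise IndexError(f"position {pos} outside sequence of length {len(sequence)}")
    lo = max(0, pos - 1 - 7)
    hi = min(len(sequence), pos + 7)
    window = sequence[lo:hi]
    n = len(window)
    out = np.empty(len(SCHEME_CLASS_PAIRS))
    for i, (scheme, cls) in enumerate(SCHEME_CLASS_PAIRS):
        members = CLASS_SCHEMES[scheme][cls]
        out[i] = sum(1 for r in window if r in members) / n
    return out


def sequence_features(
    sav: SAVRecord,
    sequence: str,
    pssm: PssmProfile,
    *,
    pssm_mode: str = "mutant",
) -> pd.Series:
    """Assemble the named 44-vector for one SAV (table order: indices,
    entropies, AAC)."""
    if len(sequence) != len(pssm):
        raise ValueError("sequence and profile lengths differ")
    idx = substitution_indices(sav.wt, sav.mut, pssm, sav.seq_pos, pssm_mode=pssm_mode)
    ent = entropy_profile(pssm, sav.seq_pos)
    aac = aac_features(sequence, sav.seq_pos)
    return pd.Series(np.concatenate([idx, ent, aac]), index=SEQUENCE_FEATURE_NAMES)
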