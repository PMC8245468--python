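"""The 13 structure-based descriptors of one SAV.

B-factor of the SAV Calpha, relative solvent accessibility, a one-hot over the
eight DSSP secondary-structure states (H, B, E, G, I, T, S, other), the
strongest backbone H-bond acceptor and donor energies, and a disulfide flag.
"""

from __future__ import annotations

import pandas as pd

from .io_formats import DsspResidue, SAVRecord, StructureModel, SS8_STATES
from .residue_classes import ONE_TO_THREE

STRUCTURE_FEATURE_NAMES: list[str] = (
    ["b_factor", "rsa"]
    + [f"ss_{s}" for s in SS8_STATES]
    + ["hb_acceptor_energy", "hb_donor_energy", "disulfide"]
)
assert len(STRUCTURE_FEATURE_NAMES) == 13

# Theoretical maximum accessible surface areas (A^2) per residue,
# Tien et al. 2013 "theoretical" column.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def relative_accessibility(acc: float, residue_name: str) -> float:
    """Absolute DSSP accessibility divided by the residue's maximum ASA.

    Values above 1 (possible with theoretical maxima) are capped at 1.
    """
    name = residue_name.upper()
    if name not in MAX_ASA:
        raise KeyError(f"no maximum ASA tabulated for residue {residue_name!r}")
    return min(acc / MAX_ASA[name], 1.0)


def structure_features(
    sav: SAVRecord,
    model: StructureModel,
    dssp: list[DsspResidue],
    *,
    hb_mode: str = "strongest",
) -> pd.Series:
    """Assemble the named 13-vector for one SAV.

    ``hb_mode="strongest"`` (default) takes the first-listed acceptor/donor
    energies; ``"sum"`` adds the second-listed partners.
    """
    ca = model.get_atom(sav.chain_id, sav.struct_pos, "CA")
    if ca is None:
        raise KeyError(
            f"no Calpha atom for {sav.protein_id} chain {sav.chain_id} "
            f"residue {sav.struct_pos}"
        )
    rec = next(
        (r for r in dssp if r.chain_id == sav.chain_id and r.residue_seq == sav.struct_pos),
        None,
    )
    if rec is None:
        raise KeyError(
            f"no DSSP record for chain {sav.chain_id} residue {sav.struct_pos}"
        )
    if hb_mode == "strongest":
        acceptor, donor = rec.nh_o_energy, rec.o_hn_energy
    elif hb_mode == "sum":
        acceptor = rec.nh_o_energy + rec.nh_o_energy_2
        donor = rec.o_hn_energy + rec.o_hn_energy_2
    else:
        raise ValueError(f"unknown hb_mode {hb_mode!r}")

    values = {
        "b_factor": ca.b_factor,
        "rsa": relative_accessibility(rec.acc, ONE_TO_THREE[sav.wt]),
        **{f"ss_{s}": float(rec.ss8 == s) for s in SS8_STATES},
        "hb_acceptor_energy": acceptor,
        "hb_donor_energy": donor,
        "disulfide": float(rec.is_half_cystine),
    }
    return pd.Series(values, index=STRUCTURE_FEATURE_NAMES, dtype=float)
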