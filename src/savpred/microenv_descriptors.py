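"""The 32 weighted-contact-number (WCN) microenvironment descriptors.

WCN of the SAV's Calpha atom is the packing-density measure
``WCN_i = sum_{j != i} 1 / r_ij^2`` with no cutoff radius; the 32 descriptors
differ only in which atoms *j* enter the sum: Calpha/nitrogen/oxygen atoms in
the SAV's own chain or the whole protein, Calpha atoms of other protein
chains, heavy atoms of other molecules (ligands, nucleic acids, metal ions;
waters excluded), and Calpha atoms restricted to each class of the six
physicochemical schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Atom, SAVRecord, StructureModel
from .residue_classes import CLASS_SCHEMES, SCHEME_CLASS_PAIRS, THREE_TO_ONE

MICROENV_FEATURE_NAMES: list[str] = (
    ["wcn_ca_chain", "wcn_n_chain", "wcn_o_chain",
     "wcn_ca_protein", "wcn_n_protein", "wcn_o_protein",
     "wcn_ca_other_chains", "wcn_other_molecules"]
    + [f"wcn_{scheme}_{cls}" for scheme, cls in SCHEME_CLASS_PAIRS]
)
assert len(MICROENV_FEATURE_NAMES) == 32

ATOM_KINDS = ("CA", "N", "O", "heavy")
SOURCES = ("same-chain", "whole-protein", "other-chains", "other-molecules")


@dataclass(frozen=True)
class AtomSelector:
    """Which atoms *j* enter the WCN sum.

    ``atom_kind``: ``"CA"`` (Calpha atoms), ``"N"``/``"O"`` (all nitrogen or
    oxygen atoms of amino acids, side chains included), or ``"heavy"`` (any
    non-hydrogen atom — only meaningful with the other-molecules source).
    ``residue_class`` restricts Calpha atoms to residues of one
    physicochemical class and only combines with ``atom_kind="CA"``.
    """

    atom_kind: str
    source: str
    residue_class: frozenset | None = None

    def __post_init__(self):
        if self.atom_kind not in ATOM_KINDS:
            raise ValueError(f"unknown atom_kind {self.atom_kind!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.residue_class is not None and self.atom_kind != "CA":
            raise ValueError("residue_class only combines with atom_kind='CA'")

    def matches(self, atom: Atom, model: StructureModel, target: Atom) -> bool:
        if self.source == "other-molecules":
            # hetero records and non-protein polymers; waters never count
            if model.is_protein(atom) or model.is_water(atom):
                return False
            return atom.element not in ("H", "D")
        if not model.is_protein(atom):
            return False
        if self.source == "same-chain" and atom.chain_id != target.chain_id:
            return False
        if self.source == "other-chains" and atom.chain_id == target.chain_id:
            return False
        if self.atom_kind == "CA":
            if atom.atom_name != "CA":
                return False
            if self.residue_class is not None:
                one = THREE_TO_ONE.get(atom.residue_name.upper())
                if one not in self.residue_class:
                    return False
            return True
        return atom.element == self.atom_kind  # N or O, backbone or side chain


def wcn(model: StructureModel, target: Atom, selector: AtomSelector) -> float:
    """Sum of inverse squared distances from ``target`` to matching atoms.

    The target itself is excluded; other atoms of its residue count when they
    match. An empty selection yields 0. A distinct atom coincident with the
    target is a structural clash and raises.
    """
    tpos = target.pos
    total = 0.0
    tkey = (target.chain_id, target.residue_seq, target.atom_name)
    for atom in model.atoms:
        if (atom.chain_id, atom.residue_seq, atom.atom_name) == tkey:
            continue
        if not selector.matches(atom, model, target):
            continue
        d2 = float(np.sum((atom.pos - tpos) ** 2))
        if d2 == 0.0:
            raise ValueError(
                f"atom {atom.chain_id}/{atom.residue_seq}/{atom.atom_name} "
                f"coincides with the target atom"
            )
        total += 1.0 / d2
    return total


def _selectors() -> list[AtomSelector]:
    sel = [
        AtomSelector("CA", "same-chain"),
        AtomSelector("N", "same-chain"),
        AtomSelector("O", "same-chain"),
        AtomSelector("CA", "whole-protein"),
        AtomSelector("N", "whole-protein"),
        AtomSelector("O", "whole-protein"),
        AtomSelector("CA", "other-chains"),
        AtomSelector("heavy", "other-molecules"),
    ]
    for scheme, cls in SCHEME_CLASS_PAIRS:
        sel.append(AtomSelector("CA", "whole-protein", CLASS_SCHEMES[scheme][cls]))
    return sel


def microenv_features(sav: SAVRecord, model: StructureModel) -> pd.Series:
    """Assemble the named 32-vector for one SAV (target = its Calpha atom)."""
    target = model.get_atom(sav.chain_id, sav.struct_pos, "CA")
    if target is None or not model.is_protein(target):
        raise KeyError(
            f"no protein Calpha atom for {sav.protein_id} chain {sav.chain_id} "
            f"residue {sav.struct_pos}"
        )
    values = [wcn(model, target, sel) for sel in _selectors()]
    return pd.Series(values, index=MICROENV_FEATURE_NAMES)
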