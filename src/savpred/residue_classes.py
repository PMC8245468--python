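"""Physicochemical classification schemes of the 20 standard amino acids.

Six schemes partition the residue alphabet and are shared by the
amino-acid-composition descriptors (sequence feature set) and the
class-restricted weighted-contact-number descriptors (microenvironment
feature set):

* **H** — hydrophobicity: polar / neutral / hydrophobic
* **V** — volume: small / medium / large
* **Z** — polarizability: low / medium / high
* **P** — polarity: low / neutral / high
* **F** — four-class chemistry: acidic / basic / polar / nonpolar
* **E** — eight-class chemistry: acidic / basic / aromatic / amide /
  small hydroxyl / sulfur-containing / aliphatic 1 / aliphatic 2

Each scheme's classes are disjoint and jointly cover the whole alphabet.
"""

from __future__ import annotations

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
"""Canonical residue order for every 20-vector (PSI-BLAST PSSM column order)."""

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# scheme -> ordered (class_name -> member residues)
CLASS_SCHEMES: dict[str, dict[str, frozenset[str]]] = {
    "H": {
        "polar": frozenset("RKEDQN"),
        "neutral": frozenset("GASTPHY"),
        "hydrophobic": frozenset("CVLIMFW"),
    },
    "V": {
        "small": frozenset("GASCTPD"),
        "medium": frozenset("NVEQIL"),
        "large": frozenset("MHKFRYW"),
    },
    "Z": {
        "low": frozenset("GASDT"),
        "medium": frozenset("CPNVEQIL"),
        "high": frozenset("KMHFRYW"),
    },
    "P": {
        "low": frozenset("LIFWCMVY"),
        "neutral": frozenset("PATGS"),
        "high": frozenset("HQRKNED"),
    },
    "F": {
        "acidic": frozenset("DE"),
        "basic": frozenset("HKR"),
        "polar": frozenset("CGNQSTY"),
        "nonpolar": frozenset("AFILMPVW"),
    },
    "E": {
        "acidic": frozenset("DE"),
        "basic": frozenset("HKR"),
        "aromatic": frozenset("FWY"),
        "amide": frozenset("NQ"),
        "hydroxyl": frozenset("ST"),
        "sulfur": frozenset("CM"),
        "aliphatic1": frozenset("AGP"),
        "aliphatic2": frozenset("ILV"),
    },
}

#: Flat ordered list of the 24 (scheme, class) pairs used by both feature sets.
SCHEME_CLASS_PAIRS: list[tuple[str, str]] = [
    (scheme, cls) for scheme, classes in CLASS_SCHEMES.items() for cls in classes
]


def class_members(scheme: str, cls: str) -> frozenset[str]:
    """Residues (1-letter) belonging to ``cls`` of ``scheme``."""
    return CLASS_SCHEMES[scheme][cls]
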