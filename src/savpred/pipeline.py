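"""Batch feature extraction: SAV table + per-protein input files -> the three
descriptor matrices (89 columns total) aligned to the SAV records."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .io_formats import (
    SAVRecord,
    parse_dssp,
    parse_pdb,
    parse_pssm,
    read_fasta,
)
from .microenv_descriptors import microenv_features
from .seq_descriptors import sequence_features
from .struct_descriptors import structure_features


def extract_features(
    records: Sequence[SAVRecord],
    pdb_dir: str | Path,
    dssp_dir: str | Path,
    pssm_dir: str | Path,
    fasta_dir: str | Path,
) -> dict[str, pd.DataFrame]:
    """Compute all descriptors for every SAV.

    Per-protein inputs are looked up as ``<dir>/<protein_id>.{pdb,dssp,pssm,
    fasta}`` and parsed once per protein. Returns feature-set name ->
    DataFrame with one row per record, in record order.
    """
    pdb_dir, dssp_dir = Path(pdb_dir), Path(dssp_dir)
    pssm_dir, fasta_dir = Path(pssm_dir), Path(fasta_dir)
    cache: dict[str, tuple] = {}
    seq_rows, struct_rows, micro_rows = [], [], []
    for r in records:
        if r.protein_id not in cache:
            cache[r.protein_id] = (
                parse_pdb(pdb_dir / f"{r.protein_id}.pdb"),
                parse_dssp(dssp_dir / f"{r.protein_id}.dssp"),
                parse_pssm(pssm_dir / f"{r.protein_id}.pssm"),
                read_fasta(fasta_dir / f"{r.protein_id}.fasta"),
            )
        model, dssp, pssm, seq = cache[r.protein_id]
        seq_rows.append(sequence_features(r, seq, pssm))
        struct_rows.append(structure_features(r, model, dssp))
        micro_rows.append(microenv_features(r, model))
    return {
        "sequence": pd.DataFrame(seq_rows).reset_index(drop=True),
        "structure": pd.DataFrame(struct_rows).reset_index(drop=True),
        "microenvironment": pd.DataFrame(micro_rows).reset_index(drop=True),
    }


def write_feature_tables(
    features: dict[str, pd.DataFrame], prefix: str | Path
) -> list[Path]:
    paths = []
    for fs, df in features.items():
        p = Path(f"{prefix}_{fs}.tsv")
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


def read_feature_tables(prefix: str | Path) -> dict[str, pd.DataFrame]:
    return {
        fs: pd.read_csv(f"{prefix}_{fs}.tsv", sep="\t")
        for fs in ("sequence", "structure", "microenvironment")
    }
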