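"""Bundled reference tables: published group sizes, CV confusion counts and
case-study scores used as worked-example inputs for the evaluation machinery."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("savpred").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def group_counts() -> pd.DataFrame:
    """Per-wild-type cancer/neutral counts and printed delta (plus TOTAL)."""
    return _load("reference_group_counts.tsv")


def cv_confusion() -> pd.DataFrame:
    """Per-wild-type five-fold CV confusion counts with printed metrics."""
    return _load("reference_cv_confusion.tsv")


def pi3k_predictions() -> pd.DataFrame:
    """Case-study scores and confusion calls for 14 PI3K SAVs."""
    return _load("reference_pi3k_predictions.tsv")
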