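"""Desk-scale planted-feature benchmarks of the selection and stacking stages.

The study conditions are fixed by :class:`~savpred.synthetic.SyntheticSpec`
defaults: 60 cancer-related + 120 neutral SAVs, two informative
microenvironment descriptors separated by 3 pooled standard deviations. GA
population/generations and the hyperparameter grid are scaled for a single
CPU; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .ga_select import GAConfig, evolve
from .predictor import FEATURE_SETS, TrainConfig, _cv_fitness_factory, cross_validate_system
from .synthetic import SyntheticSpec, make_synthetic_dataset

RECOVERY_GA = dict(population_size=12, generations=10)
RECOVERY_EXPONENTS = (-5, 0, 5)
SYSTEM_CONFIG = dict(
    ga_population=6, ga_generations=4, grid_min=-3, grid_max=3, grid_step=3
)


def planted_recovery_trial(seed: int, spec: SyntheticSpec | None = None) -> bool:
    """One GA feature-selection run on the planted dataset.

    Runs the first-level training path for the feature set holding the
    informative descriptors (MCC fitness, grid-searched CV SVM) and reports
    whether the selected mask keeps *both* informative descriptors.
    """
    spec = spec or SyntheticSpec(seed=seed)
    ds = make_synthetic_dataset(spec)
    by_set = {
        fs: [n for n in ds.features[fs].columns if n in ds.informative]
        for fs in FEATURE_SETS
    }
    (fs, names), = [(k, v) for k, v in by_set.items() if v]
    X = ds.features[fs].to_numpy()
    cols = [list(ds.features[fs].columns).index(n) for n in names]
    fitness = _cv_fitness_factory(
        X, ds.labels, "MCC", 1.0, list(RECOVERY_EXPONENTS), 5, seed
    )
    mask, _, _ = evolve(X.shape[1], fitness, GAConfig(seed=seed, **RECOVERY_GA))
    return all(mask[c] == 1 for c in cols)


def planted_system_cv_mcc(seed: int, spec: SyntheticSpec | None = None) -> float:
    """Five-fold CV MCC of the full grouped two-level system on the planted
    dataset (groups and models rebuilt inside every training split)."""
    spec = spec or SyntheticSpec(seed=seed)
    ds = make_synthetic_dataset(spec)
    config = TrainConfig(seed=seed, **SYSTEM_CONFIG)
    feats = {fs: ds.features[fs].to_numpy() for fs in FEATURE_SETS}
    _, metrics = cross_validate_system(ds.records, feats, config, k=5)
    return metrics.mcc
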