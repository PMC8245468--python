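"""Genetic-algorithm feature selection on a planted dataset.

Generates 60 cancer-related + 120 neutral synthetic variants where exactly two
microenvironment descriptors carry signal, then lets the GA maximise the
cross-validated MCC of an RBF SVM over descriptor masks.
"""

import numpy as np

import savpred as sp
from savpred.ga_select import GAConfig, evolve
from savpred.predictor import grid_search

ds = sp.make_synthetic_dataset(sp.SyntheticSpec(seed=1))
X = ds.features["microenvironment"].to_numpy()
names = list(ds.features["microenvironment"].columns)
y = ds.labels


def fitness(mask):
    cols = mask.astype(bool)
    _, _, fit = grid_search(X[:, cols], y, "MCC", exponents=[-5, 0, 5], seed=1)
    return fit


mask, best_fit, trace = evolve(X.shape[1], fitness, GAConfig(
    population_size=12, generations=10, seed=1))

selected = [n for n, b in zip(names, mask) if b]
print(f"planted informative descriptors: {list(ds.informative)}")
print(f"GA-selected mask keeps {mask.sum()}/32 descriptors, CV MCC = {best_fit:.3f}")
print(f"both informative descriptors kept: {set(ds.informative) <= set(selected)}")
print(f"best-fitness trace (first 5 generations): {np.round(trace[:5], 3)}")
print(
    "\nThe trace is non-decreasing (elitism); a CV MCC near 1 means the masked"
    "\nSVM separates the planted classes almost perfectly."
)
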