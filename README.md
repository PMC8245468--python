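# savpred

Structure-based prediction of whether a single amino acid variant (SAV) in a
human protein is cancer-related or neutral.

Missense variants reported in cancer samples vastly outnumber the ones we can
interpret. When a variant's protein has a solved structure, its local packing,
solvent exposure and evolutionary conservation carry signal about functional
impact that sequence alone misses. `savpred` is a library (plus a thin CLI)
for researchers who want to train and apply such a predictor on their own
variant sets, or to reuse its building blocks: descriptor extraction, genetic
algorithm (GA) feature selection, imbalance-aware evaluation, and a stacked
SVM classifier.

## The method

For every SAV the package computes **89 descriptors** in three sets:

* **Sequence (44)** — substitution indices BLOSUM62(wt, mut), PAM250(wt, mut)
  and the PSI-BLAST PSSM log-odds of the mutant; per-position Shannon
  entropies H(i) = −Σₐ pₐ(i) log₂ pₐ(i) at offsets −7…+7 around the SAV with
  window averages over 15 and 5 residues; and 24 amino-acid-composition
  fractions of the 15-residue window under six physicochemical classification
  schemes (H, V, Z, P, F, E).
* **Structure (13)** — Cα B-factor, relative solvent accessibility
  (DSSP accessibility / max ASA), a one-hot over the eight DSSP secondary
  structure states {H, B, E, G, I, T, S, other}, strongest backbone H-bond
  acceptor and donor energies, and a disulfide flag.
* **Microenvironment (32)** — weighted contact numbers
  WCNᵢ = Σ_{j≠i} 1/r²ᵢⱼ of the SAV's Cα against selectable atom sources:
  Cα/N/O atoms of the SAV's chain or the whole protein, Cα atoms of other
  chains, heavy atoms of other molecules (ligands, nucleic acids, ions;
  waters excluded), and Cα atoms restricted to each physicochemical class.

Training data are grouped by wild-type residue (mode `w`) or by wild-type and
mutant type (mode `wm`, subgroups under 30 SAVs merged along positive BLOSUM62
scores between mutant types, leftovers falling back to the `w` group). Each
group's model is a two-level stack: 12 first-level RBF SVMs — one per
(feature set × fitness function) pair, where a GA over binary descriptor
masks (mutation threshold μ₀ = 0.1, crossover threshold μ₁ = 0.5, elitist
selection) maximises the 5-fold cross-validated fitness, with (C, γ)
grid-searched over 2⁻¹⁵…2¹⁵ — feeding a second-level RBF SVM that emits
P(cancer). The four fitness functions are accuracy, MCC, F1 and the
imbalance-aware **Hybrid = sensitivity + δ·specificity**, δ being the group's
cancer:neutral count ratio. A variant is called cancer-related iff
P(cancer) ≥ 0.5.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/02_metrics.py` recomputes the published cysteine-group
worked example and the corpus totals from their confusion counts:

```
CYS: TP=43 TN=93 FP=4 FN=2
  accuracy=0.9577 sensitivity=0.9556 specificity=0.9588
  MCC=0.9040 precision=0.9149 F1=0.9348
  Hybrid (sens + 0.4639 x spec) = 1.4003

TOTAL: TP=2247 TN=7111 FP=451 FN=620
  accuracy=0.8973 sensitivity=0.7837 specificity=0.9404
  MCC=0.7382 precision=0.8328 F1=0.8075
```

and `python examples/03_ga_selection.py` runs GA feature selection on a
planted synthetic dataset (60 cancer-related + 120 neutral variants, two
informative microenvironment descriptors):

```
planted informative descriptors: ['wcn_ca_chain', 'wcn_o_chain']
GA-selected mask keeps 9/32 descriptors, CV MCC = 0.962
both informative descriptors kept: True
```

A CV MCC near 1 on the masked SVM means the GA found the descriptors that
actually separate the classes.

The CLI mirrors the library:

```sh
savpred simulate structure --n-res 30 --n-chains 2 --seed 1 --out toy
savpred extract --sav savs.tsv --pdb-dir . --dssp-dir . --pssm-dir . \
    --fasta-dir . --out features
savpred train --features features --sav savs.tsv --config config.json --out bundles
savpred predict --features features --sav savs.tsv --bundles bundles --out pred.tsv
savpred evaluate --predictions pred.tsv --out metrics.json
```

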