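# Methods

This note documents the models and procedures `savpred` implements, the
parameters that matter, the numerical conventions, and what the synthetic
test surface does and does not show.

## Descriptors

**Sequence set (44).** Substitution indices are BLOSUM62(wt, mut),
PAM250(wt, mut) (standard NCBI tables via Biopython) and the mutant's PSSM
log-odds score at the SAV position. An alternative reading of the PSSM index
— mutant minus wild-type log-odds — is available via
`substitution_indices(..., pssm_mode="difference")`; the mutant score is the
default. Conservation is the Shannon entropy (bits) of the PSSM's weighted
observed percentage distribution, normalised per position; log-odds are not
used for entropy because they are not a probability distribution and can be
negative. Positions outside the sequence contribute a sentinel 0 and are
excluded from the denominators of the 15- and 5-residue window averages, so
termini do not fabricate conservation signal. The 5-residue average covers
offsets −2…+2 centred on the SAV. Amino-acid composition uses the 15-residue
window including the SAV; at termini the window truncates and fractions are
taken over the actual window length, preserving the per-scheme sum-to-1
property. The six classification schemes partition the 20 residues as:
H polar/neutral/hydrophobic (RKEDQN / GASTPHY / CVLIMFW), V small/medium/
large (GASCTPD / NVEQIL / MHKFRYW), Z low/medium/high polarizability
(GASDT / CPNVEQIL / KMHFRYW), P low/neutral/high polarity (LIFWCMVY / PATGS /
HQRKNED), F acidic/basic/polar/nonpolar (DE / HKR / CGNQSTY / AFILMPVW),
E acidic/basic/aromatic/amide/hydroxyl/sulfur/aliphatic1/aliphatic2
(DE / HKR / FWY / NQ / ST / CM / AGP / ILV), 24 classes in all; where two
printed variants of a class membership disagree, the scheme definitions
above are authoritative throughout the package.

**Structure set (13).** The Cα B-factor is used raw; downstream per-feature
scaling handles magnitude. Relative solvent accessibility divides DSSP's
absolute accessibility by the residue's theoretical maximum ASA (Tien et al.
2013 values, bundled in `struct_descriptors.MAX_ASA`) and caps at 1.
Secondary structure is a one-hot over DSSP's 8 states; any symbol outside
{H,B,E,G,I,T,S} — blank loop markers and the newer polyproline "P" state —
maps to "other". H-bond energies default to the first-listed (strongest)
acceptor/donor partners, with a `sum` switch adding the second-listed pair.
DSSP's null convention (energy 0.0 when no partner) passes through.
A lowercase DSSP amino-acid code marks a half-cystine and sets the disulfide
flag.

**Microenvironment set (32).** WCNᵢ = Σ_{j≠i} 1/r²ᵢⱼ with no cutoff radius;
the target is always the SAV's Cα and only the target itself is excluded
(other atoms of the SAV's own residue count when the selector matches).
Nitrogen/oxygen selectors include side-chain atoms. "Other molecules" means
heavy atoms of hetero records and non-protein polymers — ligands, nucleic
acids, metal ions — with waters excluded; hydrogens never count.
Class-restricted WCNs sum over Cα atoms of residues of one class in any
protein chain, so per scheme they partition the whole-protein Cα WCN exactly
(an identity the tests assert).

## Genetic algorithm

Solutions are binary masks over one feature set's descriptors. Per
generation: elitist selection (the best of each population half, including
the previous incumbent, fills the next population alternately), then
mutation (first half: every bit flips independently with probability
μ₀ = 0.1; second half: exactly one uniformly chosen bit flips), then
one-point crossover of adjacent pairs with probability μ₁ = 0.5 at a uniform
internal cut. Incumbents start as the all-zero mask with fitness −∞, and the
fitness adapter scores all-zero candidates −∞, so the returned mask always
keeps at least one descriptor. Fitness evaluations are cached by mask bits
because selection duplicates masks heavily. Elitism makes the best-so-far
trace non-decreasing; population size and generation count are not part of
the published operator set and default to N = 40 / 50 generations,
configurable.

## Two-level SVM system

Grouping mode `w` builds one model per wild-type residue; mode `wm` splits
by mutant type and merges subgroups under `min_subgroup_size = 30` into the
same-wild-type subgroup with the highest positive BLOSUM62 score between
their mutant types (ties by alphabetically first mutant; merging iterates
until every subgroup is large enough or no positive partner remains;
leftovers fall back to the `w`-level group and predictions through them are
flagged).

Each group trains 12 first-level units = 3 feature sets × 4 fitness
functions (Acc, MCC, F1, Hybrid with the group's own δ). A unit's GA fitness
is the best 5-fold stratified CV value of an RBF SVM over the exponential
(C, γ) grid 2⁻¹⁵…2¹⁵ (step 2 exponent units; range and step configurable);
ties break toward smaller C, then smaller γ. Features are scaled per fold to
[−1, 1] by training-fold min/max only — test folds reuse the training
parameters, so there is no scaling leakage. The second level consumes the 12
units' *out-of-fold* probability estimates (not hard labels), avoiding
optimistic stacking, and is itself a grid-searched RBF SVM optimised by MCC.
Probabilities come from Platt scaling; the decision rule is cancer iff
P(cancer) ≥ 0.5. Bundles serialize as a directory of JSON metadata (masks as
0/1 strings, scaler ranges, hyperparameters, δ) plus one classifier file per
unit, with a format version checked on load.

## Evaluation

Accuracy, sensitivity, specificity, precision, F1, MCC and
Hybrid = sensitivity + δ·specificity are computed from confusion counts with
bounded zero-denominator conventions: precision 0 when no positive calls,
MCC 0 when a marginal is empty, F1 0 when precision + sensitivity = 0. These
conventions never fire on the bundled reference rows, whose printed values
reproduce to 4 decimal places (round-half-up). δ is the group's
cancer:neutral count ratio. The two-sample z statistic is the Welch form
z = (x̄₁−x̄₂)/√(s₁²/n₁ + s₂²/n₂) with unbiased variances and significance at
|z| > 1.96; the variance terms are *added* under the radical — a subtracted
form would be imaginary for typical inputs and is treated as a typographical
slip in the printed formula. Stratified folds and ROC AUC delegate to
scikit-learn.

## Dataset-construction rules

Structure matching keeps hits with e-value < 1e−50, identity > 80%, subject
coverage > 95% (coverage measured over the structure), organism Homo
sapiens, and a consistent SAV position — all strict inequalities — and
prefers X-ray entries over other methods among a query's survivors rather
than hard-filtering on method. The position-consistency criterion is
consumed as a precomputed flag since verifying it needs the pairwise
alignment. CD-HIT is not executed; its `.clstr` output is parsed and one
representative (longest, ties by identifier) is kept per cluster.

## Synthetic data and what the tests show

The generators emulate *formats and statistical shape*, not physics: toy
structures are extended chains (3.8 Å Cα spacing) with jittered side-chain
atoms and optional ligands; DSSP records are drawn from the seeded stream in
the classic text layout rather than computed from geometry (the pipeline's
contract is with DSSP's format, not its algorithm); profiles interpolate
uniform→one-hot observed percentages. The planted dataset is
class-conditional Gaussian over all 89 descriptor names: informative columns
separate the classes by `effect_size` pooled SDs, everything else is noise.
Defaults are 60 cancer-related + 120 neutral variants, two informative
microenvironment descriptors at effect size 3.

Passing the planted-recovery surface therefore shows that the selection and
stacking machinery *finds and exploits* signal under known conditions — it
says nothing about real-corpus accuracy, which depends on descriptor
informativeness in real structures and on corpus construction. Corpus-level
performance figures are reproduced only as worked examples from their
published confusion counts.

## Desk-scale problem sizes

The acceptance surface runs on one CPU, so stochastic checks use reduced
search sizes chosen once: GA recovery uses N = 12 / 10 generations with the
(C, γ) exponent grid {−5, 0, 5}; the full-system cross-validation uses
N = 6 / 4 generations with exponents {−3, 0, 3} inside each of 5 outer
folds, 10 seeds for recovery and 5 for the system MCC. With effect size 3
the planted signal is strong enough that these sizes are not the binding
constraint; enlarging them raises runtime roughly linearly without changing
the qualitative outcome.

## Known limitations

* Legacy fixed-column PDB only; mmCIF, insertion codes and multi-model
  ensembles (beyond taking the first model) are out of scope.
* The PSSM "substitution index" reading, H-bond aggregation, and the exact
  merge order for undersized subgroups are documented choices where the
  published description is silent; alternatives sit behind switches.
* Probabilities are Platt estimates from the second-level SVM; no further
  calibration is applied.
* The supplementary roster of exact published subgroup models is not
  reconstructible without the original corpus; the grouping *rule* is the
  contract, not the roster.
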