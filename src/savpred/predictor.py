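"""Two-level SVM prediction of cancer-related SAVs.

Training data are grouped either by wild-type residue alone (mode ``"w"``,
up to 20 groups) or by wild-type plus mutant type (mode ``"wm"``); ``wm``
subgroups with fewer than ``min_subgroup_size`` members merge into a same
wild-type subgroup whose mutant types score above zero under BLOSUM62, and
unmergeable ones fall back to the wild-type-level group.

Each group's model is a stack: twelve first-level RBF-SVM classifiers — one
per (feature set x fitness function) pair, with a GA-selected descriptor mask
and a grid-searched (C, gamma) — feed their probability outputs to a
second-level RBF SVM that emits the final cancer probability. The decision
rule takes the larger probability (cancer iff p >= 0.5).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .evaluation import (
    FITNESS_ATTR,
    ConfusionCounts,
    class_ratio,
    compute_metrics,
    counts_from_predictions,
    stratified_folds,
)
from .ga_select import GAConfig, evolve
from .io_formats import SAVRecord, SubstitutionMatrix, load_substitution_matrix

FEATURE_SETS = ("sequence", "structure", "microenvironment")
FITNESS_NAMES = ("Acc", "MCC", "F1", "Hybrid")

BUNDLE_FORMAT_VERSION = 1



def _fit_svc(svm: SVC, X: np.ndarray, y: np.ndarray) -> SVC:
    # scikit-learn >= 1.9 warns that SVC(probability=True) is deprecated;
    # Platt-scaled probabilities are what the stacking design consumes.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        svm.fit(X, y)
    return svm


class TrainSizeError(ValueError):
    """A class is too small to train this group; fall back to mode 'w'."""


# ---------------------------------------------------------------------------
# configuration

@dataclass
class TrainConfig:
    mode: str = "wm"
    ga_population: int = 40
    ga_generations: int = 50
    grid_min: int = -15
    grid_max: int = 15
    grid_step: int = 2
    min_subgroup_size: int = 30
    cv_folds: int = 5
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainConfig":
        """Config JSON keys: mode, ga {N, generations, seed}, grid {range, step},
        min_subgroup_size."""
        raw = json.loads(Path(path).read_text())
        kwargs: dict = {}
        if "mode" in raw:
            kwargs["mode"] = raw["mode"]
        ga = raw.get("ga", {})
        if "N" in ga:
            kwargs["ga_population"] = ga["N"]
        if "generations" in ga:
            kwargs["ga_generations"] = ga["generations"]
        if "seed" in ga:
            kwargs["seed"] = ga["seed"]
        grid = raw.get("grid", {})
        if "range" in grid:
            kwargs["grid_min"], kwargs["grid_max"] = grid["range"]
        if "step" in grid:
            kwargs["grid_step"] = grid["step"]
        if "min_subgroup_size" in raw:
            kwargs["min_subgroup_size"] = raw["min_subgroup_size"]
        return cls(**kwargs)

    @property
    def exponents(self) -> list[int]:
        return list(range(self.grid_min, self.grid_max + 1, self.grid_step))


# ---------------------------------------------------------------------------
# grouping

@dataclass(frozen=True)
class GroupKey:
    """wt alone (``muts`` None) or wt plus a set of mutant residues."""

    wt: str
    muts: frozenset[str] | None = None

    def __str__(self) -> str:
        if self.muts is None:
            return self.wt
        return f"{self.wt}->{''.join(sorted(self.muts))}"

    @classmethod
    def parse(cls, text: str) -> "GroupKey":
        if "->" in text:
            wt, muts = text.split("->")
            return cls(wt, frozenset(muts))
        return cls(text)


@dataclass
class Group:
    key: GroupKey
    records: list[SAVRecord]
    fallback: bool = False  # holds members of unmergeable wm subgroups


def _subgroup_score(
    muts_a: frozenset[str], muts_b: frozenset[str], blosum: SubstitutionMatrix
) -> float:
    return max(blosum.score(a, b) for a in muts_a for b in muts_b)


def build_groups(
    dataset: Sequence[SAVRecord],
    mode: str = "wm",
    blosum: SubstitutionMatrix | None = None,
    min_size: int = 30,
) -> list[Group]:
    """Partition SAV records into training groups.

    Mode ``"w"``: one group per wild-type residue present. Mode ``"wm"``:
    per-(wt, mut) subgroups; a subgroup below ``min_size`` merges into the
    same-wt subgroup with the highest positive BLOSUM62 score between their
    mutant types (ties by alphabetically first mutant), iterating until every
    subgroup reaches ``min_size`` or no positive-scoring partner remains;
    leftovers go to a wild-type-level fallback group.
    """
    if not dataset:
        raise ValueError("empty dataset")
    if mode not in ("w", "wm"):
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "w":
        by_wt: dict[str, list[SAVRecord]] = {}
        for r in dataset:
            by_wt.setdefault(r.wt, []).append(r)
        return [Group(GroupKey(wt), recs) for wt, recs in sorted(by_wt.items())]

    blosum = blosum or load_substitution_matrix("BLOSUM62")
    groups: list[Group] = []
    by_wt_mut: dict[str, dict[frozenset[str], list[SAVRecord]]] = {}
    for r in dataset:
        by_wt_mut.setdefault(r.wt, {}).setdefault(frozenset(r.mut), []).append(r)

    for wt in sorted(by_wt_mut):
        subs = dict(by_wt_mut[wt])
        merged = True
        while merged:
            merged = False
            undersized = sorted(
                (k for k, v in subs.items() if len(v) < min_size),
                key=lambda k: (len(subs[k]), sorted(k)),
            )
            for k in undersized:
                partners = [
                    (other, _subgroup_score(k, other, blosum))
                    for other in subs
                    if other is not k and other != k
                ]
                partners = [(o, s) for o, s in partners if s > 0]
                if not partners:
                    continue
                partners.sort(key=lambda t: (-t[1], sorted(t[0])))
                target = partners[0][0]
                subs[target | k] = subs.pop(target) + subs.pop(k)
                merged = True
                break
        fallback_records: list[SAVRecord] = []
        for muts, recs in sorted(subs.items(), key=lambda t: sorted(t[0])):
            if len(recs) >= min_size:
                groups.append(Group(GroupKey(wt, muts), recs))
            else:
                fallback_records.extend(recs)
        if fallback_records:
            groups.append(Group(GroupKey(wt), fallback_records, fallback=True))
    return groups


# ---------------------------------------------------------------------------
# scaling

class MinMaxScaler:
    """Per-feature affine map of the training range onto [-1, 1].

    Constant features map to 0. Fitted on training data only; test vectors
    reuse the training parameters (values may exceed [-1, 1] out of range).
    """

    def __init__(self, data_min: np.ndarray | None = None, data_max: np.ndarray | None = None):
        self.data_min = data_min
        self.data_max = data_max

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        self.data_min = X.min(axis=0)
        self.data_max = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        span = self.data_max - self.data_min
        safe = np.where(span > 0, span, 1.0)
        out = -1.0 + 2.0 * (X - self.data_min) / safe
        out[:, span == 0] = 0.0
        return out


# ---------------------------------------------------------------------------
# hyperparameter grid search

def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    fitness_name: str = "MCC",
    delta: float = 1.0,
    seed: int = 0,
    exponents: Iterable[int] = range(-15, 16, 2),
    k: int = 5,
) -> tuple[float, float, float]:
    """Exponential (C, gamma) grid search by stratified k-fold CV.

    Returns the (C, gamma, cv_fitness) maximising the named fitness measure
    (Acc, MCC, F1 or Hybrid with the supplied delta); ties break toward the
    smaller C, then the smaller gamma.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs both classes present")
    attr = FITNESS_ATTR[fitness_name]
    folds = stratified_folds(y, k=k, seed=seed)
    # fold-wise scaling is hyperparameter-independent: precompute once
    prepared = []
    for f in range(k):
        tr, te = folds != f, folds == f
        scaler = MinMaxScaler().fit(X[tr])
        prepared.append((scaler.transform(X[tr]), y[tr], scaler.transform(X[te]), te))

    exponents = list(exponents)
    best: tuple[float, float, float] | None = None
    for ce in exponents:
        for ge in exponents:
            C, gamma = 2.0 ** ce, 2.0 ** ge
            pred = np.empty_like(y)
            for Xtr, ytr, Xte, te in prepared:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(Xtr, ytr)
                pred[te] = clf.predict(Xte)
            fit = compute_metrics(counts_from_predictions(y, pred), delta).get(attr)
            if best is None or fit > best[2]:
                best = (C, gamma, fit)
    return best


# ---------------------------------------------------------------------------
# model containers

@dataclass
class FirstLevelUnit:
    feature_set: str
    fitness_name: str
    mask: np.ndarray  # uint8
    scaler: MinMaxScaler
    svm: SVC
    C: float
    gamma: float
    cv_fitness: float

    def probability(self, x: np.ndarray) -> float:
        """P(cancer) for one raw (unmasked) feature vector."""
        xm = np.asarray(x, dtype=float)[self.mask.astype(bool)]
        xs = self.scaler.transform(xm.reshape(1, -1))
        p = self.svm.predict_proba(xs)[0]
        return float(p[list(self.svm.classes_).index(1)])


@dataclass
class ModelBundle:
    key: GroupKey
    units: list[FirstLevelUnit]
    second_scaler: MinMaxScaler
    second_svm: SVC
    delta: float
    training_counts: tuple[int, int]  # (n_cancer, n_neutral)

    def __post_init__(self):
        if len(self.units) != len(FEATURE_SETS) * len(FITNESS_NAMES):
            raise ValueError("a bundle must contain exactly 12 first-level units")


@dataclass
class Prediction:
    probability_cancer: float
    label: str
    group_used: GroupKey
    fallback_used: bool


# ---------------------------------------------------------------------------
# training

def _unit_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % (2**31))


def _cv_fitness_factory(X, y, fitness_name, delta, exponents, k, seed):
    def fitness(mask) -> float:
        cols = mask.astype(bool)
        _, _, fit = grid_search(
            X[:, cols], y, fitness_name, delta, seed=seed, exponents=exponents, k=k
        )
        return fit

    return fitness


def train_group(
    labels: np.ndarray,
    features: Mapping[str, np.ndarray],
    config: TrainConfig,
    key: GroupKey | None = None,
) -> ModelBundle:
    """Train one group's two-level model.

    ``labels``: 1 = cancer-related, 0 = neutral. ``features`` maps each of
    the three feature-set names to an aligned (n, m) matrix. For every
    (feature set x fitness function) pair the GA maximises the grid-searched
    CV fitness of an RBF SVM on the masked descriptors; the twelve fitted
    units' out-of-fold probabilities then train the second-level SVM.
    """
    y = np.asarray(labels, dtype=int)
    n_cancer = int((y == 1).sum())
    n_neutral = int((y == 0).sum())
    if min(n_cancer, n_neutral) < config.cv_folds:
        raise TrainSizeError(
            f"group {key}: class counts {n_cancer}/{n_neutral} below "
            f"{config.cv_folds}; fall back to mode 'w'"
        )
    delta = class_ratio(n_cancer, n_neutral)
    exps = config.exponents
    units: list[FirstLevelUnit] = []
    for fs_i, fs in enumerate(FEATURE_SETS):
        X = np.asarray(features[fs], dtype=float)
        for fn_i, fname in enumerate(FITNESS_NAMES):
            unit_idx = fs_i * len(FITNESS_NAMES) + fn_i
            seed = _unit_seed(config.seed, unit_idx)
            fitness = _cv_fitness_factory(
                X, y, fname, delta, exps, config.cv_folds, seed
            )
            ga_cfg = GAConfig(
                population_size=config.ga_population,
                generations=config.ga_generations,
                seed=seed,
            )
            mask, _, _ = evolve(X.shape[1], fitness, ga_cfg)
            cols = mask.astype(bool)
            C, gamma, cvfit = grid_search(
                X[:, cols], y, fname, delta, seed=seed, exponents=exps, k=config.cv_folds
            )
            scaler = MinMaxScaler().fit(X[:, cols])
            svm = SVC(C=C, gamma=gamma, kernel="rbf", probability=True, random_state=seed)
            _fit_svc(svm, scaler.transform(X[:, cols]), y)
            units.append(FirstLevelUnit(fs, fname, mask, scaler, svm, C, gamma, cvfit))

    # out-of-fold first-level probabilities -> second-level training matrix
    folds = stratified_folds(y, k=config.cv_folds, seed=config.seed)
    meta = np.zeros((len(y), len(units)))
    for f in range(config.cv_folds):
        tr, te = folds != f, folds == f
        for u_i, unit in enumerate(units):
            cols = unit.mask.astype(bool)
            X = np.asarray(features[unit.feature_set], dtype=float)
            scaler = MinMaxScaler().fit(X[tr][:, cols])
            svm = SVC(
                C=unit.C, gamma=unit.gamma, kernel="rbf",
                probability=True, random_state=config.seed,
            )
            _fit_svc(svm, scaler.transform(X[tr][:, cols]), y[tr])
            p = svm.predict_proba(scaler.transform(X[te][:, cols]))
            meta[te, u_i] = p[:, list(svm.classes_).index(1)]

    C2, g2, _ = grid_search(
        meta, y, "MCC", delta, seed=config.seed, exponents=exps, k=config.cv_folds
    )
    second_scaler = MinMaxScaler().fit(meta)
    second_svm = SVC(C=C2, gamma=g2, kernel="rbf", probability=True,
                     random_state=config.seed)
    _fit_svc(second_svm, second_scaler.transform(meta), y)
    return ModelBundle(
        key=key or GroupKey("?"),
        units=units,
        second_scaler=second_scaler,
        second_svm=second_svm,
        delta=delta,
        training_counts=(n_cancer, n_neutral),
    )


# ---------------------------------------------------------------------------
# prediction

def route(sav: SAVRecord, bundles: Mapping[GroupKey, ModelBundle]) -> tuple[GroupKey, bool]:
    """Most specific applicable bundle: wm subgroup first, else wt fallback."""
    for k in bundles:
        if k.muts is not None and k.wt == sav.wt and sav.mut in k.muts:
            return k, False
    for k in bundles:
        if k.muts is None and k.wt == sav.wt:
            return k, True
    raise KeyError(
        f"no model bundle applies to {sav.protein_id} {sav.wt}{sav.seq_pos}{sav.mut}"
    )


def predict(
    sav: SAVRecord,
    features: Mapping[str, np.ndarray],
    bundles: Mapping[GroupKey, ModelBundle],
) -> Prediction:
    """Predict cancer-relatedness of one SAV from its three feature vectors."""
    key, fallback = route(sav, bundles)
    bundle = bundles[key]
    meta = np.array([u.probability(features[u.feature_set]) for u in bundle.units])
    p = bundle.second_svm.predict_proba(bundle.second_scaler.transform(meta.reshape(1, -1)))[0]
    p_cancer = float(p[list(bundle.second_svm.classes_).index(1)])
    return Prediction(
        probability_cancer=p_cancer,
        label="cancer" if p_cancer >= 0.5 else "neutral",
        group_used=key,
        fallback_used=fallback,
    )


def decide(probability_cancer: float) -> str:
    """The largest-probability decision rule: cancer iff p >= 0.5."""
    return "cancer" if probability_cancer >= 0.5 else "neutral"


# ---------------------------------------------------------------------------
# persistence

def save_bundle(bundle: ModelBundle, directory: str | Path) -> None:
    """Write a bundle as a directory: human-readable metadata.json plus one
    serialized classifier file per unit and for the second level."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "group": str(bundle.key),
        "delta": bundle.delta,
        "training_counts": list(bundle.training_counts),
        "second_level": {
            "C": bundle.second_svm.C,
            "gamma": bundle.second_svm.gamma,
            "scaler_min": bundle.second_scaler.data_min.tolist(),
            "scaler_max": bundle.second_scaler.data_max.tolist(),
        },
        "units": [
            {
                "index": i,
                "feature_set": u.feature_set,
                "fitness": u.fitness_name,
                "mask": "".join(map(str, u.mask.tolist())),
                "C": u.C,
                "gamma": u.gamma,
                "cv_fitness": u.cv_fitness,
                "scaler_min": u.scaler.data_min.tolist(),
                "scaler_max": u.scaler.data_max.tolist(),
            }
            for i, u in enumerate(bundle.units)
        ],
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    for i, u in enumerate(bundle.units):
        joblib.dump(u.svm, directory / f"unit_{i:02d}.joblib")
    joblib.dump(bundle.second_svm, directory / "second_level.joblib")


def load_bundle(directory: str | Path) -> ModelBundle:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    if meta.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"bundle format version {meta.get('format_version')} != "
            f"{BUNDLE_FORMAT_VERSION}"
        )
    units = []
    for m in meta["units"]:
        path = directory / f"unit_{m['index']:02d}.joblib"
        if not path.exists():
            raise FileNotFoundError(
                f"bundle incomplete: missing classifier for unit {m['index']} "
                f"({m['feature_set']}/{m['fitness']})"
            )
        units.append(
            FirstLevelUnit(
                feature_set=m["feature_set"],
                fitness_name=m["fitness"],
                mask=np.array([int(c) for c in m["mask"]], dtype=np.uint8),
                scaler=MinMaxScaler(
                    np.array(m["scaler_min"]), np.array(m["scaler_max"])
                ),
                svm=joblib.load(path),
                C=m["C"],
                gamma=m["gamma"],
                cv_fitness=m["cv_fitness"],
            )
        )
    sl = meta["second_level"]
    return ModelBundle(
        key=GroupKey.parse(meta["group"]),
        units=units,
        second_scaler=MinMaxScaler(np.array(sl["scaler_min"]), np.array(sl["scaler_max"])),
        second_svm=joblib.load(directory / "second_level.joblib"),
        delta=meta["delta"],
        training_counts=tuple(meta["training_counts"]),
    )


# ---------------------------------------------------------------------------
# end-to-end cross-validation

def cross_validate_system(
    records: Sequence[SAVRecord],
    features: Mapping[str, np.ndarray],
    config: TrainConfig,
    k: int = 5,
):
    """Stratified k-fold CV of the full grouped two-level system.

    Groups are rebuilt and retrained on each training split; test-split SAVs
    are routed to their group's bundle. Groups too small to train in a split
    fall back to the wild-type-level group. Returns (counts, metrics).
    """
    y = np.array([1 if r.label == "cancer" else 0 for r in records])
    feats = {fs: np.asarray(features[fs], dtype=float) for fs in FEATURE_SETS}
    folds = stratified_folds(y, k=k, seed=config.seed)
    total = ConfusionCounts(0, 0, 0, 0)
    for f in range(k):
        tr_idx = np.flatnonzero(folds != f)
        te_idx = np.flatnonzero(folds == f)
        tr_records = [records[i] for i in tr_idx]
        groups = build_groups(tr_records, config.mode, min_size=config.min_subgroup_size)
        pos_of = {id(r): i for i, r in zip(tr_idx, tr_records)}
        bundles: dict[GroupKey, ModelBundle] = {}
        for g in groups:
            idx = np.array([pos_of[id(r)] for r in g.records])
            try:
                bundles[g.key] = train_group(
                    y[idx],
                    {fs: feats[fs][idx] for fs in FEATURE_SETS},
                    config,
                    key=g.key,
                )
            except TrainSizeError:
                continue
        preds = np.empty(len(te_idx), dtype=int)
        for j, i in enumerate(te_idx):
            p = predict(records[i], {fs: feats[fs][i] for fs in FEATURE_SETS}, bundles)
            preds[j] = 1 if p.label == "cancer" else 0
        total = total + counts_from_predictions(y[te_idx], preds)
    delta = class_ratio(int((y == 1).sum()), int((y == 0).sum()))
    return total, compute_metrics(total, delta)
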