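"""Grouping, grid search, two-level training, routing and persistence."""

import numpy as np
import pytest

import savpred as sp
from savpred.predictor import (
    FEATURE_SETS,
    FITNESS_NAMES,
    GroupKey,
    TrainConfig,
    TrainSizeError,
    build_groups,
    decide,
    grid_search,
    load_bundle,
    predict,
    route,
    save_bundle,
    train_group,
)
from savpred.reference import pi3k_predictions
from savpred.synthetic import SyntheticSpec, make_synthetic_dataset

TINY = TrainConfig(
    ga_population=4, ga_generations=2, grid_min=0, grid_max=0, grid_step=2, seed=5
)


def sav(wt, mut, i=0, label="unknown"):
    return sp.SAVRecord(f"P{i}", "A", i + 1, i + 1, wt, mut, label)


@pytest.fixture(scope="module")
def trained_bundle():
    ds = make_synthetic_dataset(SyntheticSpec(n_cancer=15, n_neutral=25, seed=3))
    feats = {fs: ds.features[fs].to_numpy() for fs in FEATURE_SETS}
    bundle = train_group(ds.labels, feats, TINY, key=GroupKey("A", frozenset("V")))
    return ds, feats, bundle


class TestBuildGroups:
    def test_mode_w_one_group_per_wildtype(self):
        records = [sav(wt, "A" if wt != "A" else "V", i)
                   for i, wt in enumerate("ARNDCQEGHILKMFPSTWYV")]
        groups = build_groups(records, "w")
        assert len(groups) == 20
        assert all(g.key.muts is None for g in groups)

    def test_undersized_subgroup_merges_by_blosum(self):
        # D->E with 29 members, D->Q with 50: BLOSUM62(E,Q)=2>0 -> merged
        records = [sav("D", "E", i) for i in range(29)]
        records += [sav("D", "Q", 100 + i) for i in range(50)]
        groups = build_groups(records, "wm", min_size=30)
        assert len(groups) == 1
        assert groups[0].key == GroupKey("D", frozenset("EQ"))
        assert len(groups[0].records) == 79
        assert not groups[0].fallback

    def test_unmergeable_subgroup_routed_to_fallback(self):
        # BLOSUM62(P,W) < 0: the small P subgroup cannot merge with W
        records = [sav("D", "W", i) for i in range(40)]
        records += [sav("D", "P", 100 + i) for i in range(5)]
        groups = build_groups(records, "wm", min_size=30)
        keys = {str(g.key): g for g in groups}
        assert keys["D->W"].fallback is False
        assert keys["D"].fallback is True
        assert len(keys["D"].records) == 5

    def test_empty_dataset(self):
        with pytest.raises(ValueError):
            build_groups([], "w")


class TestGridSearch:
    def test_separable_data_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 20 + [1] * 20)
        X = rng.normal(size=(40, 2)) + np.where(y == 1, 8.0, -8.0)[:, None]
        C, gamma, fit = grid_search(X, y, "Acc", exponents=[-3, 0, 3], seed=1)
        assert fit == 1.0

    def test_determinism(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 40)
        y[:10] = 1; y[10:20] = 0
        X = rng.normal(size=(40, 3))
        a = grid_search(X, y, "MCC", exponents=[-3, 0, 3], seed=7)
        b = grid_search(X, y, "MCC", exponents=[-3, 0, 3], seed=7)
        assert a == b

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            grid_search(np.zeros((10, 2)), np.ones(10), "Acc")


class TestTrainGroup:
    def test_bundle_contains_twelve_units(self, trained_bundle):
        _, _, bundle = trained_bundle
        assert len(bundle.units) == 12
        combos = {(u.feature_set, u.fitness_name) for u in bundle.units}
        assert combos == {(fs, fn) for fs in FEATURE_SETS for fn in FITNESS_NAMES}

    def test_delta_matches_group_ratio(self, trained_bundle):
        _, _, bundle = trained_bundle
        assert bundle.delta == pytest.approx(15 / 25)
        assert bundle.training_counts == (15, 25)

    def test_hyperparameters_inside_grid(self, trained_bundle):
        _, _, bundle = trained_bundle
        for u in bundle.units:
            assert 2.0**-15 <= u.C <= 2.0**15
            assert 2.0**-15 <= u.gamma <= 2.0**15
            assert u.mask.any()

    def test_too_small_class_raises(self):
        ds = make_synthetic_dataset(SyntheticSpec(n_cancer=3, n_neutral=30, seed=1))
        feats = {fs: ds.features[fs].to_numpy() for fs in FEATURE_SETS}
        with pytest.raises(TrainSizeError, match="fall back"):
            train_group(ds.labels, feats, TINY)


class TestPredict:
    def test_routes_to_subgroup_and_probability_bounds(self, trained_bundle):
        ds, feats, bundle = trained_bundle
        bundles = {bundle.key: bundle}
        p = predict(ds.records[0], {fs: feats[fs][0] for fs in FEATURE_SETS}, bundles)
        assert 0.0 <= p.probability_cancer <= 1.0
        assert p.group_used == bundle.key and not p.fallback_used
        assert p.label == decide(p.probability_cancer)

    def test_fallback_routing_flagged(self, trained_bundle):
        ds, feats, bundle = trained_bundle
        fallback = sp.ModelBundle(
            key=GroupKey("A"), units=bundle.units,
            second_scaler=bundle.second_scaler, second_svm=bundle.second_svm,
            delta=bundle.delta, training_counts=bundle.training_counts,
        )
        bundles = {GroupKey("A"): fallback}
        other_mut = sav("A", "T", 500)
        key, used_fallback = route(other_mut, bundles)
        assert key == GroupKey("A") and used_fallback

    def test_no_applicable_bundle_error(self, trained_bundle):
        _, _, bundle = trained_bundle
        with pytest.raises(KeyError, match="W"):
            route(sav("W", "R", 1), {bundle.key: bundle})

    @pytest.mark.parametrize("row", pi3k_predictions().to_dict("records"),
                             ids=lambda r: r["sav"])
    def test_decision_rule_on_reference_scores(self, row):
        """The >= 0.5 rule reproduces every published case-study call."""
        label = decide(row["score"])
        expected = {"TP": "cancer", "FP": "cancer", "TN": "neutral", "FN": "neutral"}
        assert label == expected[row["call"]]


class TestPersistence:
    def test_round_trip_predictions_identical(self, trained_bundle, tmp_path):
        ds, feats, bundle = trained_bundle
        save_bundle(bundle, tmp_path / "b")
        loaded = load_bundle(tmp_path / "b")
        bundles_a = {bundle.key: bundle}
        bundles_b = {loaded.key: loaded}
        for i in range(20):
            fv = {fs: feats[fs][i] for fs in FEATURE_SETS}
            pa = predict(ds.records[i], fv, bundles_a)
            pb = predict(ds.records[i], fv, bundles_b)
            assert pa.probability_cancer == pytest.approx(pb.probability_cancer, abs=1e-12)

    def test_metadata_lists_twelve_units(self, trained_bundle, tmp_path):
        import json

        _, _, bundle = trained_bundle
        save_bundle(bundle, tmp_path / "b")
        meta = json.loads((tmp_path / "b" / "metadata.json").read_text())
        assert len(meta["units"]) == 12
        assert all(set(u["mask"]) <= {"0", "1"} for u in meta["units"])

    def test_missing_unit_file_named(self, trained_bundle, tmp_path):
        _, _, bundle = trained_bundle
        save_bundle(bundle, tmp_path / "b")
        (tmp_path / "b" / "unit_03.joblib").unlink()
        with pytest.raises(FileNotFoundError, match="unit 3"):
            load_bundle(tmp_path / "b")

    def test_version_mismatch(self, trained_bundle, tmp_path):
        import json

        _, _, bundle = trained_bundle
        save_bundle(bundle, tmp_path / "b")
        meta = json.loads((tmp_path / "b" / "metadata.json").read_text())
        meta["format_version"] = 99
        (tmp_path / "b" / "metadata.json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="version"):
            load_bundle(tmp_path / "b")
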