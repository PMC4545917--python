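import numpy as np
import pandas as pd
import pytest

from mammoscope.classify import (
    ALL_FEATURE_NAMES,
    DecisionTree,
    Leaf,
    TreeNode,
    classify_site,
    grow_tree,
    loocv_fixed_structure,
    prune_tree,
    published_tree,
    rank_parameters,
    resubstitution,
    single_parameter_roc,
    tree_roc,
    welch_t,
)


def pair_counting_auc(values, labels):
    """Oracle: AUC = P(score_pos > score_neg) with ties counted 1/2."""
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def make_table(rows):
    """Feature table with all 33 columns (unset features NaN)."""
    out = []
    for r in rows:
        row = {f: float("nan") for f in ALL_FEATURE_NAMES}
        row.update(r)
        out.append(row)
    df = pd.DataFrame(out)
    if "site_id" not in df:
        df.insert(0, "site_id", [f"s{i}" for i in range(len(df))])
    return df


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0
        assert p == pytest.approx(1.0)

    def test_reference_values(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0213, abs=2e-3)

    def test_antisymmetry(self):
        t1, _, p1 = welch_t([1, 2, 3], [4, 5, 7])
        t2, _, p2 = welch_t([4, 5, 7], [1, 2, 3])
        assert t1 == -t2
        assert p1 == p2

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError):
            welch_t([2, 2, 2], [5, 5, 5])


class TestSingleParameterROC:
    def test_perfect_separation(self):
        roc = single_parameter_roc(
            np.array([1, 2, 3, 10, 11, 12]),
            np.array([False, False, False, True, True, True]),
        )
        assert roc.auc == 1.0
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.integers(0, 8, 30).astype(float)  # ties likely
            y = rng.random(30) < 0.4
            if y.all() or not y.any():
                continue
            roc = single_parameter_roc(v, y)
            expected = pair_counting_auc(v, y)
            assert roc.auc == pytest.approx(max(expected, 1 - expected), abs=1e-12)

    def test_uninformative_large_sample(self):
        rng = np.random.default_rng(42)
        v = rng.normal(size=10_000)
        y = rng.random(10_000) < 0.5
        roc = single_parameter_roc(v, y)
        assert roc.auc == pytest.approx(0.5, abs=0.02)

    def test_reversed_scores_mirror_auc(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=50) + np.linspace(0, 1.5, 50)
        y = np.linspace(0, 1, 50) > 0.5
        a1 = single_parameter_roc(v, y).auc
        a2 = single_parameter_roc(-v, y).auc
        assert a1 == pytest.approx(a2)  # direction sweep keeps auc >= 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            single_parameter_roc(np.array([1.0, 2.0]), np.array([True, True]))


class TestRankParameters:
    def build(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(30):
            malignant = i < 12
            rows.append(
                {
                    "diagnosis": "idc" if malignant else "fibrous",
                    "class_label": "malignant" if malignant else "benign",
                    "std_ind": (3 if malignant else 15) + rng.normal(0, 1),
                    "mean_ind": rng.normal(20, 5),  # uninformative
                    "area_fraction": 0.5,           # constant
                }
            )
        return make_table(rows)

    def test_discriminative_feature_ranks_first(self):
        ranked = rank_parameters(self.build())
        grp = ranked[ranked.group == "A_nuclear_all_sites"]
        assert grp.iloc[0].feature == "std_ind"
        assert grp.iloc[0].auc > 0.95

    def test_constant_feature_auc_half(self):
        ranked = rank_parameters(self.build())
        grp = ranked[ranked.group == "A_nuclear_all_sites"]
        assert grp[grp.feature == "area_fraction"].iloc[0].auc == 0.5

    def test_duct_features_absent_from_nonduct_group(self):
        ranked = rank_parameters(self.build())
        assert not (ranked.group == "D_ductal_duct_sites").any()  # no duct sites
        assert "n_lumens" not in set(
            ranked[ranked.group == "B_nuclear_nonduct_sites"].feature
        )


class TestGrowTree:
    def test_separable_single_split_at_midpoint(self):
        t = make_table(
            [
                {"class_label": "benign", "diagnosis": "fibrous", "std_ind": v}
                for v in (10.0, 11.0, 12.0)
            ]
            + [
                {"class_label": "malignant", "diagnosis": "idc", "std_ind": v}
                for v in (2.0, 3.0, 4.0)
            ]
        )
        tree = grow_tree(t)
        assert isinstance(tree.root, TreeNode)
        assert tree.root.feature == "std_ind"
        assert tree.root.cutoff == pytest.approx((4 + 10) / 2)
        assert resubstitution(tree, t)["accuracy"] == 1.0

    def test_pure_input_single_leaf(self):
        t = make_table(
            [{"class_label": "benign", "diagnosis": "fibrous", "std_ind": v} for v in (1.0, 2.0)]
        )
        tree = grow_tree(t)
        assert isinstance(tree.root, Leaf)
        assert tree.root.label == "benign"

    def test_gini_tie_breaks_lexicographically(self):
        rows = []
        for v, lbl in [(1, "malignant"), (2, "malignant"), (8, "benign"), (9, "benign")]:
            rows.append(
                {
                    "class_label": lbl,
                    "diagnosis": "idc" if lbl == "malignant" else "fibrous",
                    "std_ind": float(v),
                    "iqr_ind": float(v),  # identical separating power
                }
            )
        tree = grow_tree(make_table(rows))
        assert tree.root.feature == "iqr_ind"  # 'iqr_ind' < 'std_ind'

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            grow_tree(make_table([]))


class TestPruneTree:
    def build_repeat_table(self):
        # std_ind separates most sites; a second std_ind split would be
        # needed to purify the right branch, which pruning must collapse
        rows = []
        vals_mal = [1, 2, 3, 11]
        vals_ben = [8, 9, 10, 12, 13]
        for v in vals_mal:
            rows.append({"class_label": "malignant", "diagnosis": "idc", "std_ind": float(v)})
        for v in vals_ben:
            rows.append({"class_label": "benign", "diagnosis": "fibrous", "std_ind": float(v)})
        return make_table(rows)

    def test_repeated_feature_collapsed(self):
        t = self.build_repeat_table()
        tree = grow_tree(t)
        feats = [n.feature for n, _ in tree.internal_nodes()]
        assert feats.count("std_ind") > 1  # grown tree reuses the feature
        pruned = prune_tree(tree, t)
        feats = [n.feature for n, _ in pruned.internal_nodes()]
        assert len(feats) == len(set(feats))

    def test_compliant_tree_unchanged(self):
        t = make_table(
            [
                {"class_label": "malignant", "diagnosis": "idc", "std_ind": 2.0, "n_lumens": 0},
                {"class_label": "malignant", "diagnosis": "dcis", "std_ind": 9.0, "n_lumens": 3},
                {"class_label": "benign", "diagnosis": "fibrous", "std_ind": 10.0, "n_lumens": 0},
                {"class_label": "benign", "diagnosis": "normal_duct", "std_ind": 11.0, "n_lumens": 1},
            ]
        )
        tree = published_tree()
        pruned = prune_tree(tree, t)
        assert pruned.to_dict() == tree.to_dict()

    def test_malignant_leaf_budget_enforced(self):
        rng = np.random.default_rng(0)
        rows = []
        # four malignant islands along one feature force >3 malignant leaves
        for k, (lo, hi) in enumerate([(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)]):
            lbl = "malignant" if k % 2 == 0 else "benign"
            for _ in range(4):
                rows.append(
                    {
                        "class_label": lbl,
                        "diagnosis": "idc" if lbl == "malignant" else "fibrous",
                        "std_ind": float(rng.uniform(lo, hi)),
                        "mean_ind": float(rng.uniform(0, 10)),
                        "iqr_ind": float(rng.uniform(0, 10)),
                        "range_ind": float(rng.uniform(0, 10)),
                    }
                )
        t = make_table(rows)
        pruned = prune_tree(grow_tree(t), t)
        n_mal = sum(1 for leaf in pruned.leaves() if leaf.label == "malignant")
        assert n_mal <= 3
        feats = [n.feature for n, _ in pruned.internal_nodes()]
        assert len(feats) == len(set(feats))

    def test_pruning_never_adds_nodes(self):
        t = self.build_repeat_table()
        tree = grow_tree(t)
        assert prune_tree(tree, t).n_nodes() <= tree.n_nodes()


class TestPublishedTreeRouting:
    @pytest.mark.parametrize(
        "std_ind, lumens, expected",
        [
            (5.0, 0, "malignant"),   # low StdIND branch
            (8.0, 3, "malignant"),   # multi-lumen branch
            (8.0, 1, "benign"),      # remaining sites
        ],
    )
    def test_branch_logic(self, std_ind, lumens, expected):
        tree = published_tree()
        assert classify_site(tree, {"std_ind": std_ind, "n_lumens": lumens}) == expected

    def test_missing_lumens_treated_as_zero(self):
        tree = published_tree()
        assert classify_site(tree, {"std_ind": 8.0}) == "benign"
        assert classify_site(tree, {"std_ind": 8.0, "n_lumens": float("nan")}) == "benign"

    def test_serialization_roundtrip(self, tmp_path):
        tree = published_tree()
        p = tmp_path / "model.json"
        tree.save(p)
        assert DecisionTree.load(p).to_dict() == tree.to_dict()


class TestLOOCV:
    def build(self):
        rows = []
        for v in (1.0, 2.0, 3.0, 4.0):
            rows.append({"class_label": "malignant", "diagnosis": "idc", "std_ind": v, "n_lumens": 0})
        for v in (10.0, 11.0, 12.0, 13.0):
            rows.append({"class_label": "benign", "diagnosis": "fibrous", "std_ind": v, "n_lumens": 0})
        return make_table(rows)

    def test_stable_cutoff_equals_resubstitution(self):
        t = self.build()
        tree = published_tree()
        preds, conf = loocv_fixed_structure(t, tree)
        assert conf["sensitivity"] == 1.0 and conf["specificity"] == 1.0
        # every fold finds a cutoff in the same (4, 10) gap
        assert ((preds["root_cutoff"] > 4) & (preds["root_cutoff"] < 10)).all()

    def test_deterministic(self):
        t = self.build()
        p1, c1 = loocv_fixed_structure(t)
        p2, c2 = loocv_fixed_structure(t)
        pd.testing.assert_frame_equal(p1, p2)
        assert c1 == c2

    def test_outlier_becomes_false_negative_in_its_fold(self):
        # refitting without the near-benign malignant outlier drops the
        # cutoff below it, so only its own fold misclassifies it
        t = self.build()
        t.loc[0, "std_ind"] = 9.5
        preds, conf = loocv_fixed_structure(t)
        assert preds.loc[0, "prediction"] == "benign"
        assert preds.loc[0, "root_cutoff"] < 9.5
        assert conf["fn"] == 1
        # the clearly separated malignant folds are unaffected
        assert (preds["prediction"].iloc[1:4] == "malignant").all()


class TestTreeROC:
    def test_fully_separated_auc_one(self):
        t = TestLOOCV().build()
        roc = tree_roc(t)
        assert roc.auc == 1.0

    def test_lumen_floor_lifts_tpr_at_smallest_cutoff(self):
        rows = [
            {"class_label": "malignant", "diagnosis": "dcis", "std_ind": 20.0, "n_lumens": 4},
            {"class_label": "malignant", "diagnosis": "idc", "std_ind": 2.0, "n_lumens": 0},
            {"class_label": "benign", "diagnosis": "fibrous", "std_ind": 15.0, "n_lumens": 0},
            {"class_label": "benign", "diagnosis": "fibrous", "std_ind": 16.0, "n_lumens": 0},
        ]
        roc = tree_roc(make_table(rows))
        # at cutoff -inf only the lumen rule fires: tpr floor = 1/2, fpr 0
        assert roc.tpr[np.flatnonzero(roc.fpr == 0)].max() >= 0.5

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(400):
            rows.append(
                {
                    "class_label": "malignant" if rng.random() < 0.5 else "benign",
                    "diagnosis": "idc",
                    "std_ind": float(rng.normal(10, 3)),
                    "n_lumens": 0,
                }
            )
        roc = tree_roc(make_table(rows))
        assert roc.auc == pytest.approx(0.5, abs=0.07)

    def test_points_monotone(self):
        t = TestLOOCV().build()
        roc = tree_roc(t)
        assert (np.diff(roc.fpr) >= 0).all()
        assert (np.diff(roc.tpr) >= 0).all()
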