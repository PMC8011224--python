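import numpy as np
import pandas as pd
import pytest

from sexlabel import sexinfer
from sexlabel.sexinfer import (
    SexModel,
    assign_labels,
    build_study_groups,
    construct_train_test,
    enet_logistic,
    nested_cv_fit,
    platform_qc,
    predict_scores,
    threshold_sweep,
)


def membership(pairs):
    return pd.DataFrame(pairs, columns=["sample_id", "study_id"])


class TestStudyGroups:
    def test_shared_sample_merges(self):
        m = membership([("s1", "A"), ("s1", "B"), ("s2", "C")])
        g = build_study_groups(m)
        assert g.group_of["A"] == g.group_of["B"]
        assert g.group_of["C"] != g.group_of["A"]

    def test_no_sharing_each_own_group(self):
        m = membership([("s1", "A"), ("s2", "B"), ("s3", "C")])
        g = build_study_groups(m)
        assert len({g.group_of[s] for s in "ABC"}) == 3

    def test_hub_study_removed(self):
        rows = [("hub_s%d" % i, "HUB") for i in range(6)]
        rows += [("hub_s%d" % i, "ST%d" % i) for i in range(6)]
        rows += [("x", "LONER")]
        g = build_study_groups(membership(rows))
        assert "HUB" in g.removed_studies
        assert "HUB" not in g.group_of
        # the six satellites no longer connect through the hub
        assert len({g.group_of["ST%d" % i] for i in range(6)}) == 6

    def test_five_shared_not_removed(self):
        rows = [("s%d" % i, "HUB") for i in range(5)]
        rows += [("s%d" % i, "ST%d" % i) for i in range(5)]
        g = build_study_groups(membership(rows))
        assert g.removed_studies == set()
        assert len({g.group_of[s] for s in g.group_of}) == 1

    def test_transitive_chain(self):
        m = membership([("s1", "A"), ("s1", "B"), ("s2", "B"), ("s2", "C")])
        g = build_study_groups(m)
        assert len({g.group_of[s] for s in "ABC"}) == 1

    def test_empty_error(self):
        with pytest.raises(ValueError):
            build_study_groups(membership([]))


def _labeled_samples(n_studies=30, per_study=8, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_studies):
        for j in range(per_study):
            rows.append((f"s{s}.{j}", f"ST{s}",
                         "male" if rng.random() < 0.5 else "female"))
    return pd.DataFrame(rows, columns=["sample_id", "study_id", "sex"])


class TestSplit:
    def test_no_group_spans_both(self):
        df = _labeled_samples()
        groups = build_study_groups(df[["sample_id", "study_id"]])
        train, test = construct_train_test(df, groups, seed=1)
        assert set(train["group"]) & set(test["group"]) == set()

    def test_max_per_study(self):
        df = _labeled_samples(per_study=20)
        groups = build_study_groups(df[["sample_id", "study_id"]])
        train, test = construct_train_test(df, groups, max_per_study=5, seed=1)
        both = pd.concat([train, test])
        assert both.groupby("study_id").size().max() <= 5

    def test_balance_band(self):
        df = _labeled_samples(n_studies=50)
        groups = build_study_groups(df[["sample_id", "study_id"]])
        train, test = construct_train_test(df, groups, seed=2)
        for split in (train, test):
            frac = (split["sex"] == "male").mean()
            assert 0.45 <= frac <= 0.55

    def test_deterministic(self):
        df = _labeled_samples()
        groups = build_study_groups(df[["sample_id", "study_id"]])
        a = construct_train_test(df, groups, seed=3)
        b = construct_train_test(df, groups, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_impossible_balance_errors(self):
        df = _labeled_samples(n_studies=4)
        df["sex"] = "male"
        groups = build_study_groups(df[["sample_id", "study_id"]])
        with pytest.raises(ValueError):
            construct_train_test(df, groups, seed=1, max_tries=10)


class TestAssignLabels:
    @pytest.mark.parametrize("score,label", [
        (0.85, "male"), (0.70, "male"), (0.50, "unlabeled"),
        (0.69, "unlabeled"), (0.31, "unlabeled"), (0.30, "female"), (0.10, "female"),
    ])
    def test_thresholds(self, score, label):
        assert assign_labels(pd.Series([score]))[0] == label


class TestPredict:
    def test_mean_features_give_intercept_score(self):
        model = SexModel(genes=["a", "b"], coef=np.array([1.0, -2.0]),
                         intercept=0.3, alpha=1.0, lam=0.1,
                         feature_means=np.array([5.0, 2.0]),
                         feature_sds=np.array([1.0, 1.0]))
        m = pd.DataFrame({"a": [5.0], "b": [2.0]}, index=["x"])
        score = model.score(m)["x"]
        assert score == pytest.approx(1 / (1 + np.exp(-0.3)))

    def test_duplicated_rows_identical_scores(self):
        model = SexModel(genes=["a"], coef=np.array([1.0]), intercept=0.0,
                         alpha=1.0, lam=0.1, feature_means=np.array([0.0]),
                         feature_sds=np.array([1.0]))
        m = pd.DataFrame({"a": [2.0, 2.0]}, index=["x", "y"])
        s = model.score(m)
        assert s["x"] == s["y"]

    def test_missing_gene_imputed_with_mean(self):
        model = SexModel(genes=["a", "b"], coef=np.array([1.0, 5.0]),
                         intercept=0.0, alpha=1.0, lam=0.1,
                         feature_means=np.array([1.0, 9.0]),
                         feature_sds=np.array([1.0, 2.0]))
        m = pd.DataFrame({"a": [1.0]}, index=["x"])  # b absent -> standardized 0
        assert model.score(m)["x"] == pytest.approx(0.5)

    def test_zero_overlap_errors(self):
        model = SexModel(genes=["a"], coef=np.array([1.0]), intercept=0.0,
                         alpha=1.0, lam=0.1, feature_means=np.array([0.0]),
                         feature_sds=np.array([1.0]))
        with pytest.raises(ValueError):
            model.score(pd.DataFrame({"zzz": [1.0]}, index=["x"]))

    def test_json_roundtrip(self, tmp_path):
        model = SexModel(genes=["a", "b"], coef=np.array([1.0, -1.0]),
                         intercept=0.2, alpha=0.5, lam=0.03,
                         feature_means=np.array([1.0, 2.0]),
                         feature_sds=np.array([0.5, 1.5]), seed=9)
        p = tmp_path / "model.json"
        model.to_json(p)
        back = SexModel.from_json(p)
        m = pd.DataFrame({"a": [3.0], "b": [1.0]}, index=["x"])
        assert back.score(m)["x"] == pytest.approx(model.score(m)["x"])


class TestSweep:
    def test_perfect_scores_full_concordance(self):
        df = pd.DataFrame({
            "score": [0.01] * 10 + [0.99] * 10,
            "metadata_sex": ["female"] * 10 + ["male"] * 10,
        })
        sweep = threshold_sweep(df)
        assert (sweep["concordance"] == 1.0).all()

    def test_coverage_maximal_at_half(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "score": rng.random(200),
            "metadata_sex": rng.choice(["female", "male"], 200),
        })
        sweep = threshold_sweep(df)
        assert sweep.iloc[0]["threshold"] == 0.5
        assert sweep["fraction_labeled"].iloc[0] == sweep["fraction_labeled"].max()

    def test_monotone_tradeoff_against_recomputation(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "score": np.clip(rng.normal(0.5, 0.35, 300), 0, 1),
            "metadata_sex": rng.choice(["female", "male"], 300),
        })
        sweep = threshold_sweep(df)
        assert (np.diff(sweep["fraction_labeled"]) <= 1e-12).all()
        # direct recomputation at two thresholds
        for t in (0.6, 0.8):
            labels = np.where(df["score"] >= t, "male",
                              np.where(df["score"] <= 1 - t, "female", "unlabeled"))
            mask = labels != "unlabeled"
            expect = (labels[mask] == df["metadata_sex"][mask]).mean()
            row = sweep[np.isclose(sweep["threshold"], t)].iloc[0]
            assert row["concordance"] == pytest.approx(expect)


class TestPlatformQC:
    def _scores(self, conc, n, platform):
        meta = ["male"] * n
        labels = ["male"] * int(round(conc * n)) + ["female"] * (n - int(round(conc * n)))
        return pd.DataFrame({"label": labels, "metadata_sex": meta,
                             "platform": [platform] * n})

    def test_low_accuracy_platform_excluded(self):
        df = pd.concat([self._scores(0.6, 100, "bad"), self._scores(0.95, 100, "good")])
        table, excluded = platform_qc(df)
        assert excluded == {"bad"}

    def test_insufficient_platform_flagged(self):
        df = pd.concat([self._scores(0.0, 5, "tiny"), self._scores(0.9, 50, "ok")])
        table, excluded = platform_qc(df, min_n=20)
        row = table[table["platform"] == "tiny"].iloc[0]
        assert row["status"] == "insufficient"
        assert "tiny" not in excluded

    def test_boundary_70_not_excluded(self):
        df = self._scores(0.70, 100, "edge")
        _, excluded = platform_qc(df)
        assert excluded == set()


# ---------------------------------------------------------------------------
# Nested CV
# ---------------------------------------------------------------------------

def toy_training_set(n_groups=12, per_group=5, effect=3.0, seed=0):
    rng = np.random.default_rng(seed)
    rows, ys, gs = [], [], []
    for g in range(n_groups):
        for j in range(per_group):
            y = rng.integers(0, 2)
            x = rng.normal(0, 1, 4)
            x[0] += effect * y
            x[1] -= effect * y
            rows.append(x)
            ys.append(y)
            gs.append(f"G{g:02d}")
    X = pd.DataFrame(rows, columns=["y1", "y2", "x1", "x2"],
                     index=[f"s{i}" for i in range(len(rows))])
    return X, np.array(ys), np.array(gs)


class TestNestedCV:
    def test_separable_low_error_and_orientation(self, trained):
        corpus, model, train, test = trained
        assert model.cv_table["val_error"].median() <= 0.02
        chrom = corpus.genes.set_index("gene_id")
        for g, c in zip(model.genes, model.coef):
            if c == 0:
                continue
            if chrom.loc[g, "chromosome"] == "Y":
                assert c > 0
            elif chrom.loc[g, "xi_status"] == "escape":
                assert c < 0

    def test_sparsity(self, trained):
        _, model, _, _ = trained
        nnz = int((model.coef != 0).sum())
        assert nnz <= len(model.coef)
        if model.alpha >= 0.5:
            assert nnz < len(model.coef)

    def test_no_leakage(self, trained):
        _, _, train, test = trained
        assert set(train["group"]) & set(test["group"]) == set()
        assert set(train["sample_id"]) & set(test["sample_id"]) == set()

    def test_single_class_errors(self):
        X, y, g = toy_training_set()
        with pytest.raises(ValueError):
            nested_cv_fit(X, np.zeros_like(y), g, alpha_grid=(1.0,), n_lambda=5)

    def test_nonfinite_errors(self):
        X, y, g = toy_training_set()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            nested_cv_fit(X, y, g, alpha_grid=(1.0,), n_lambda=5)

    def test_autosomal_feature_rejected(self):
        X, y, g = toy_training_set()
        genes = pd.DataFrame({"gene_id": ["y1", "y2", "x1", "x2"],
                              "chromosome": ["Y", "X", "X", "autosome"],
                              "xi_status": ["unknown"] * 4})
        with pytest.raises(ValueError, match="autosomal"):
            nested_cv_fit(X, y, g, feature_table=genes, alpha_grid=(1.0,), n_lambda=5)

    def test_alpha_tie_break_prefers_larger(self):
        # strongly separable toy data: several alphas tie at zero median error
        X, y, g = toy_training_set(effect=5.0, seed=2)
        model = nested_cv_fit(X, y, g, alpha_grid=(0.3, 0.6, 1.0), n_lambda=8, seed=0)
        med = model.cv_table.groupby("alpha")["val_error"].median()
        winners = med[med <= med.min() + 1e-12].index
        assert model.alpha == max(winners)


def oracle_nested_cv(X, y, groups, alpha_grid, n_folds=6, n_lambda=8):
    """Independent brute-force re-implementation of the selection rule."""
    Xv = X.to_numpy(float)
    mu, sd = Xv.mean(0), Xv.std(0)
    Z = (Xv - mu) / np.where(sd > 0, sd, 1.0)

    sizes = {}
    for g in groups:
        sizes[g] = sizes.get(g, 0) + 1
    order = sorted(sizes, key=lambda g: (-sizes[g], g))
    fold_of, load = {}, [0] * n_folds
    for g in order:
        f = load.index(min(load))
        fold_of[g] = f
        load[f] += sizes[g]
    fold = np.array([fold_of[g] for g in groups])

    results = {}
    for alpha in alpha_grid:
        grad = Z.T @ (y - y.mean()) / len(y)
        lam_max = max(np.abs(grad).max() / max(alpha, 1e-3), 1e-6)
        lambdas = np.geomspace(lam_max, lam_max * 1e-3, n_lambda)
        fold_lams, fold_errs = [], []
        for f in range(n_folds):
            inner = [v for v in range(n_folds) if v != f]
            errs = np.zeros((len(inner), len(lambdas)))
            for vi, v in enumerate(inner):
                tr = (fold != f) & (fold != v)
                va = fold == v
                coef, b0 = None, 0.0
                for li, lam in enumerate(lambdas):
                    coef, b0 = enet_logistic(Z[tr], y[tr], alpha, lam,
                                             coef0=coef, intercept0=b0)
                    p = 1 / (1 + np.exp(-(b0 + Z[va] @ coef)))
                    p = np.clip(p, 1e-10, 1 - 1e-10)
                    errs[vi, li] = -2 * np.mean(
                        y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p))
            mean_err = errs.mean(0)
            se = errs.std(0, ddof=1) / np.sqrt(len(inner))
            i_min = int(np.argmin(mean_err))
            ok = np.nonzero(mean_err <= mean_err[i_min] + se[i_min])[0]
            lam_f = float(lambdas[ok[0]])
            coef, b0 = enet_logistic(Z[fold != f], y[fold != f], alpha, lam_f)
            pred = (b0 + Z[fold == f] @ coef > 0).astype(int)
            fold_errs.append(float(np.mean(pred != y[fold == f])))
            fold_lams.append(lam_f)
        results[alpha] = (float(np.median(fold_errs)), float(np.median(fold_lams)))
    best_err = min(e for e, _ in results.values())
    best_alpha = max(a for a, (e, _) in results.items() if e <= best_err + 1e-12)
    return best_alpha, results[best_alpha][1]


def test_nested_cv_matches_bruteforce_oracle():
    X, y, g = toy_training_set(n_groups=12, per_group=5, effect=2.0, seed=1)
    assert len(X) == 60
    alpha_grid = (0.4, 1.0)
    model = nested_cv_fit(X, y, g, alpha_grid=alpha_grid, n_lambda=8, seed=0)
    o_alpha, o_lam = oracle_nested_cv(X, y, g, alpha_grid)
    assert model.alpha == o_alpha
    assert model.lam == pytest.approx(o_lam, rel=1e-12)


def test_single_alpha_reduces_to_lambda_1se():
    X, y, g = toy_training_set(n_groups=12, per_group=5, effect=2.0, seed=4)
    model = nested_cv_fit(X, y, g, alpha_grid=(1.0,), n_lambda=8, seed=0)
    _, o_lam = oracle_nested_cv(X, y, g, (1.0,))
    assert model.lam == pytest.approx(o_lam, rel=1e-12)
    assert model.alpha == 1.0
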