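"""Discriminant classification, its oracles, and the derived statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from sealvoc.classify import (
    accuracy_ci,
    chance_levels,
    cohens_kappa,
    fit_lda,
    ld_contributions,
    loocv_classify,
    parameter_stability,
    predict_lda,
    prune_correlated,
    variance_explained,
    welch_anova,
)
from sealvoc.repertoire import decompose_label, load_call_feature_stats


def correlated_feature_fixture(n=2000, seed=0) -> pd.DataFrame:
    """Twelve-parameter table with an engineered correlation structure:

    a latent frequency factor ties F25/Fcenter/F75/F95 (r ~ 0.96) and,
    more loosely, F5 (r ~ 0.73) and AE (r ~ 0.78); DUR90 tracks DUR
    (r ~ 0.98); the rest are independent.
    """
    rng = np.random.default_rng(seed)
    L = rng.standard_normal(n)
    dur = rng.standard_normal(n)
    return pd.DataFrame(
        {
            "DUR": dur,
            "DUR90": 0.95 * dur + 0.1 * L + 0.15 * rng.standard_normal(n),
            "F5": 0.75 * L + 0.66 * rng.standard_normal(n),
            "F25": L + 0.2 * rng.standard_normal(n),
            "Fcenter": L + 0.2 * rng.standard_normal(n),
            "BDW50": rng.standard_normal(n),
            "F75": L + 0.2 * rng.standard_normal(n),
            "F95": L + 0.2 * rng.standard_normal(n),
            "BDW90": rng.standard_normal(n),
            "Fpeak": rng.standard_normal(n),
            "AE": 0.78 * L + 0.6 * rng.standard_normal(n),
        }
    )


class TestPruneCorrelated:
    def test_reproduces_published_removal_set(self):
        X = correlated_feature_fixture()
        kept = prune_correlated(X, 0.7, always_keep=("AE",))
        assert set(kept) == {"DUR", "F5", "BDW50", "BDW90", "Fpeak", "AE"}
        assert set(X.columns) - set(kept) == {
            "Fcenter", "F25", "F75", "F95", "DUR90"
        }

    def test_always_keep_protects_correlated_parameter(self):
        X = correlated_feature_fixture()
        # AE correlates ~0.78 with the frequency family but must survive
        assert "AE" in prune_correlated(X, 0.7, always_keep=("AE",))

    def test_uncorrelated_matrix_untouched(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((500, 4)), columns=list("abcd"))
        assert prune_correlated(X, 0.7) == list("abcd")

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="'a'"):
            prune_correlated(X)


def fisher_direction(X, y):
    """Closed-form two-class Fisher discriminant: Sw^-1 (mu1 - mu0)."""
    labels = np.unique(y)
    x0, x1 = X[y == labels[0]], X[y == labels[1]]
    sw = ((len(x0) - 1) * np.cov(x0, rowvar=False)
          + (len(x1) - 1) * np.cov(x1, rowvar=False)) / (len(X) - 2)
    w = np.linalg.solve(sw, x1.mean(axis=0) - x0.mean(axis=0))
    return w / np.linalg.norm(w)


class TestFitLda:
    def test_recovers_fisher_direction(self):
        rng = np.random.default_rng(2)
        x0 = rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 1]], 200)
        x1 = rng.multivariate_normal([2.5, 1.0], [[1, 0.3], [0.3, 1]], 200)
        X = pd.DataFrame(np.vstack([x0, x1]), columns=["a", "b"])
        y = pd.Series(["u"] * 200 + ["v"] * 200)
        model = fit_lda(X, y)
        w = model.coefs[:, 0] / np.linalg.norm(model.coefs[:, 0])
        ref = fisher_direction(X.to_numpy(), y.to_numpy())
        assert abs(float(w @ ref)) > 0.99

    def test_two_classes_single_discriminant(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
        y = pd.Series(["u"] * 20 + ["v"] * 20)
        model = fit_lda(X, y)
        assert model.n_discriminants == 1
        assert variance_explained(model) == [pytest.approx(100.0)]

    def test_axes_stable_under_class_swap(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((60, 2)), columns=["a", "b"])
        X.iloc[:30] += 2.0
        y = pd.Series(["u"] * 30 + ["v"] * 30)
        m1 = fit_lda(X, y)
        m2 = fit_lda(X, y.map({"u": "v", "v": "u"}))
        cos = m1.coefs[:, 0] @ m2.coefs[:, 0] / (
            np.linalg.norm(m1.coefs[:, 0]) * np.linalg.norm(m2.coefs[:, 0])
        )
        assert abs(float(cos)) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="two classes"):
            fit_lda(X, pd.Series(["u"] * 4))
        with pytest.raises(ValueError, match="at least two rows"):
            fit_lda(X, pd.Series(["u", "u", "u", "v"]))


def naive_loocv_oracle(X, y):
    """Refit-per-row LOOCV by explicit loops (independent code path)."""
    Xv, yv = np.asarray(X, float), np.asarray(y)
    n, p = Xv.shape
    preds = []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        Xt, yt = Xv[keep], yv[keep]
        classes = sorted(set(yt))
        means, priors = {}, {}
        sw = np.zeros((p, p))
        for c in classes:
            xc = Xt[yt == c]
            means[c] = xc.mean(axis=0)
            priors[c] = len(xc) / len(Xt)
            for row in xc:
                d = (row - means[c])[:, None]
                sw += d @ d.T
        sw /= len(Xt) - len(classes)
        inv = np.linalg.inv(sw)
        best, best_score = None, -np.inf
        for c in classes:
            score = (
                Xv[i] @ inv @ means[c]
                - 0.5 * means[c] @ inv @ means[c]
                + np.log(priors[c])
            )
            if score > best_score:
                best, best_score = c, score
        preds.append(best)
    return np.array(preds)


class TestLoocv:
    def test_matches_naive_refit_oracle_small_n(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(
            np.vstack(
                [
                    rng.normal(0, 1, (4, 2)),
                    rng.normal(2, 1, (4, 2)),
                    rng.normal([0, 4], 1, (4, 2)),
                ]
            ),
            columns=["a", "b"],
        )
        y = pd.Series(["p"] * 4 + ["q"] * 4 + ["r"] * 4)
        report = loocv_classify(X, y)
        oracle_preds = naive_loocv_oracle(X, y)
        oracle_cm = pd.DataFrame(
            0, index=report.classes, columns=report.classes, dtype=int
        )
        for t, pr in zip(y, oracle_preds):
            oracle_cm.loc[t, pr] += 1
        assert report.confusion_counts.equals(oracle_cm)

    def test_matches_sklearn_per_fold(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        X.iloc[10:20] += 1.5
        X.iloc[20:] -= 1.5
        y = pd.Series(["p"] * 10 + ["q"] * 10 + ["r"] * 10)
        mine = []
        theirs = []
        for i in range(len(y)):
            mask = np.ones(len(y), bool)
            mask[i] = False
            model = fit_lda(X[mask], y[mask])
            mine.append(predict_lda(model, X.iloc[[i]])[0])
            clf = sklearn.LinearDiscriminantAnalysis()
            clf.fit(X[mask], y[mask])
            theirs.append(clf.predict(X.iloc[[i]])[0])
        assert mine == theirs

    def test_perfect_separation(self):
        X = pd.DataFrame(
            {"a": [0.0, 0.1, 0.2, 10.0, 10.1, 10.2],
             "b": [0.0, 0.2, 0.1, 0.0, 0.2, 0.1]}
        )
        y = pd.Series(["u"] * 3 + ["v"] * 3)
        report = loocv_classify(X, y)
        assert report.accuracy == 100.0
        assert report.kappa == pytest.approx(1.0)

    def test_shuffled_labels_near_proportional_chance(self):
        rng = np.random.default_rng(7)
        n, k = 500, 10
        X = pd.DataFrame(rng.standard_normal((n, 4)),
                         columns=list("abcd"))
        sizes = [n // k] * k
        y = pd.Series(np.repeat([f"c{i}" for i in range(k)], sizes))
        y = pd.Series(rng.permutation(y.to_numpy()))
        report = loocv_classify(X, y)
        props = np.array(sizes) / n
        chance_pct = 100.0 * float((props**2).sum())  # 10% for 10 even classes
        assert report.accuracy == pytest.approx(chance_pct, abs=3.0)

    def test_invariant_to_row_order_and_column_scaling(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
        X.iloc[20:] += 2.0
        y = pd.Series(["u"] * 20 + ["v"] * 20)
        ref = loocv_classify(X, y)
        perm = rng.permutation(40)
        shuf = loocv_classify(
            X.iloc[perm].reset_index(drop=True),
            y.iloc[perm].reset_index(drop=True),
        )
        assert shuf.accuracy == ref.accuracy
        assert shuf.kappa == pytest.approx(ref.kappa)
        scaled = X.copy()
        scaled["b"] = 100.0 * scaled["b"] - 7.0
        res = loocv_classify(scaled, y)
        assert res.accuracy == ref.accuracy


class TestKappaAndCi:
    def test_kappa_examples(self):
        assert cohens_kappa(np.diag([5, 7, 9])) == pytest.approx(1.0)
        marg = np.outer([0.6, 0.4], [0.7, 0.3]) * 100
        assert cohens_kappa(marg) == pytest.approx(0.0, abs=1e-12)
        # hand formula: po=0.7, pe=0.5 -> kappa=0.4
        assert cohens_kappa(np.array([[40, 10], [20, 30]])) == pytest.approx(0.4)

    def test_kappa_against_sklearn(self):
        metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(9)
        yt = rng.integers(0, 3, 200)
        yp = np.where(rng.uniform(size=200) < 0.6, yt, rng.integers(0, 3, 200))
        cm = np.zeros((3, 3), int)
        for t, p in zip(yt, yp):
            cm[t, p] += 1
        assert cohens_kappa(cm) == pytest.approx(
            metrics.cohen_kappa_score(yt, yp)
        )

    def test_ci_bounds(self):
        lo, hi = accuracy_ci(0, 50)
        assert lo == 0.0
        lo, hi = accuracy_ci(50, 50)
        assert hi == 100.0

    def test_ci_matches_beta_quantile_oracle(self):
        c, n = 248, 394
        lo, hi = accuracy_ci(c, n)
        assert lo == pytest.approx(100 * sstats.beta.ppf(0.025, c, n - c + 1))
        assert hi == pytest.approx(100 * sstats.beta.ppf(0.975, c + 1, n - c))


class TestChanceLevels:
    def test_published_class_sizes(self):
        sizes = dict(load_call_feature_stats()["n"])
        ch = chance_levels(sizes)
        assert ch["Growl"] == 26  # 102 / 394
        assert ch["Moan"] == 10  # 40 / 394
        assert ch["Whoop"] == 29
        assert ch["Croak"] == 21

    def test_equal_classes(self):
        assert chance_levels({"a": 5, "b": 5, "c": 5, "d": 5}) == {
            "a": 25, "b": 25, "c": 25, "d": 25
        }


class TestDiscriminantStatistics:
    def test_variance_shares_sum_to_100(self, loocv_report):
        assert sum(loocv_report.variance_explained) == pytest.approx(100.0)
        assert loocv_report.variance_explained == sorted(
            loocv_report.variance_explained, reverse=True
        )

    def test_planted_dominant_axis(self):
        rng = np.random.default_rng(10)
        n = 90
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        y = pd.Series(np.repeat(["p", "q", "r"], n // 3))
        X.loc[y == "q", "a"] += 6.0
        X.loc[y == "r", "a"] += 12.0
        X.loc[y == "r", "b"] += 1.0
        model = fit_lda(X, y)
        shares = variance_explained(model)
        assert shares[0] > shares[1]
        contrib = ld_contributions(model)
        assert contrib["LD1"].idxmax() == "a"
        assert contrib["LD1"]["a"] > 90.0

    def test_contributions_sum_to_100_per_axis(self, loocv_report):
        contrib = loocv_report.contributions
        assert np.allclose(contrib.sum(axis=0), 100.0)


def welch_oracle(groups):
    """Direct Welch formula."""
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    w = n / v
    mw = (w * m).sum() / w.sum()
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    tmp = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    den = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
    F = num / den
    df2 = (k**2 - 1) / (3 * tmp)
    p = sstats.f.sf(F, k - 1, df2)
    return F, p


class TestWelchAnova:
    def test_identical_means(self):
        rng = np.random.default_rng(11)
        g = [rng.normal(5, 1, 50) for _ in range(3)]
        for arr in g:
            arr -= arr.mean() - 5
        F, p = welch_anova(g)
        assert F == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_two_groups_equals_squared_welch_t(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 20)
        F, p = welch_anova([a, b])
        t, pt = sstats.ttest_ind(a, b, equal_var=False)
        assert F == pytest.approx(t**2)
        assert p == pytest.approx(pt)

    def test_matches_hand_formula(self):
        groups = [
            np.array([1.0, 2.0, 3.0, 4.0, 2.5]),
            np.array([4.0, 5.5, 6.0, 5.0]),
            np.array([8.0, 9.0, 7.5, 10.0, 8.5, 9.5]),
        ]
        F, p = welch_anova(groups)
        Fo, po = welch_oracle(groups)
        assert F == pytest.approx(Fo)
        assert p == pytest.approx(po)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([np.ones(5), np.ones(5)])
        with pytest.raises(ValueError):
            welch_anova([np.array([1.0, 2.0])])


class TestParameterStability:
    def test_constant_measurements_zero_cv(self):
        df = pd.DataFrame(
            {"label": ["Moan"] * 4, "site": ["A", "A", "B", "B"],
             "DUR": [0.5, 0.5, 0.5, 0.5]}
        )
        rep = parameter_stability(df, ["DUR"])
        assert (rep.cv_table["cv"] == 0).all()

    def test_noisy_parameter_ranks_higher(self):
        rng = np.random.default_rng(13)
        rows = []
        for site in "ABC":
            for _ in range(30):
                rows.append(
                    {"label": "Growl", "site": site,
                     "DUR": rng.normal(3.0, 0.9),
                     "Fpeak": rng.normal(246.0, 5.0)}
                )
        rep = parameter_stability(pd.DataFrame(rows), ["DUR", "Fpeak"])
        assert rep.medians["DUR"] > rep.medians["Fpeak"]

    def test_cv_scale_invariance(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(
            {"label": "Moan", "site": "A", "DUR": rng.normal(1.0, 0.1, 20)}
        )
        a = parameter_stability(df, ["DUR"]).medians["DUR"]
        df10 = df.assign(DUR=df["DUR"] * 10)
        b = parameter_stability(df10, ["DUR"]).medians["DUR"]
        assert a == pytest.approx(b)


class TestStructuralFindings:
    """The published classification structure, reproduced on feature draws
    at the published class means/sds and sample sizes."""

    def test_moan_is_best_classified_elemental(self, loocv_report):
        rep = loocv_report
        elementals = [
            c for c in rep.classes if not decompose_label(c).is_combinational
        ]
        best = max(elementals, key=lambda c: rep.per_class_correct[c])
        assert best == "Moan"
        assert rep.per_class_correct["Moan"] >= 90.0

    def test_combinational_calls_confused_with_constituents(self, loocv_report):
        rep = loocv_report
        cm = rep.confusion_counts
        elementals = [
            c for c in rep.classes if not decompose_label(c).is_combinational
        ]
        agg_cons, agg_non = 0, 0
        per_class_ok = 0
        combos = [c for c in rep.classes if decompose_label(c).is_combinational]
        for c in combos:
            units = set(decompose_label(c).units)
            cons = [e for e in elementals if e in units]
            non = [e for e in elementals if e not in units]
            mis = cm.loc[c].drop(c)
            agg_cons += int(mis[cons].sum())
            agg_non += int(mis[non].sum())
            if mis[cons].max() >= (mis[non].max() if non else 0):
                per_class_ok += 1
        # misclassification mass flows into constituent elementals
        assert agg_cons > agg_non
        assert per_class_ok >= len(combos) - 1

    def test_above_chance_except_smallest_classes(self, loocv_report):
        rep = loocv_report
        sizes = rep.confusion_counts.sum(axis=1)
        for c in rep.classes:
            if sizes[c] >= 8:
                assert rep.per_class_correct[c] > rep.chance[c]
        above = sum(
            rep.per_class_correct[c] > rep.chance[c] for c in rep.classes
        )
        assert above >= 8
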