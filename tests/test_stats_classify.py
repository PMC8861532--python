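import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spermraman.spectra_io import CellRecord, RamanSpectrum
from spermraman.stats_classify import (
    classify,
    exclude_outliers,
    frequency_histogram,
    hotelling_t2,
    mann_whitney,
    normality_check,
    roc_analysis,
    run_pca,
    split_groups,
)


def _table(x_scores, y_scores, feature="I785"):
    rows = [(f"x{i}", "X", v) for i, v in enumerate(x_scores)]
    rows += [(f"y{i}", "Y", v) for i, v in enumerate(y_scores)]
    df = pd.DataFrame(rows, columns=["cell_id", "label", feature])
    df["area_714_1162"] = df[feature]
    return df


def _two_class_cells(n_a=6, n_b=6, gap=100.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    wn = np.arange(650.0, 1801.0)
    peak = np.exp(-0.5 * ((wn - 785.0) / 14.0) ** 2)
    cells = []
    for i in range(n_a):
        it = (1000.0 + gap) * peak + noise * rng.normal(size=wn.size)
        cells.append(CellRecord(f"a{i}", RamanSpectrum(wn, it), "X"))
    for i in range(n_b):
        it = 1000.0 * peak + noise * rng.normal(size=wn.size)
        cells.append(CellRecord(f"b{i}", RamanSpectrum(wn, it), "Y"))
    return cells


class TestRunPca:
    def test_two_separated_classes_dominated_by_pc1(self):
        cells = _two_class_cells(noise=0.5, seed=1)
        p = run_pca(cells)
        assert p.explained_variance[0] > 0.99

    def test_scores_centered_and_loadings_orthonormal(self):
        cells = _two_class_cells(noise=2.0, seed=2)
        p = run_pca(cells)
        scale = np.abs(p.scores).max()
        assert np.abs(p.scores.mean(axis=0)).max() < 1e-9 * scale
        gram = p.loadings @ p.loadings.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-9)

    def test_explained_variance_nonincreasing_and_bounded(self):
        p = run_pca(_two_class_cells(noise=3.0, seed=3))
        assert np.all(np.diff(p.explained_variance) <= 1e-12)
        assert p.explained_variance.sum() <= 1.0 + 1e-9

    def test_deterministic_sign_convention(self):
        a = run_pca(_two_class_cells(noise=1.0, seed=4))
        b = run_pca(_two_class_cells(noise=1.0, seed=4))
        np.testing.assert_array_equal(a.loadings, b.loadings)
        for comp in a.loadings:
            assert comp[np.abs(comp).argmax()] > 0

    def test_degenerate_input_rejected(self):
        wn = np.arange(650.0, 1801.0)
        cells = [CellRecord(f"c{i}", RamanSpectrum(wn, np.ones(wn.size)), "X")
                 for i in range(5)]
        with pytest.raises(ValueError):
            run_pca(cells)
        with pytest.raises(ValueError, match="3 cells"):
            run_pca(cells[:2])


class TestOutliers:
    def test_planted_tenfold_outlier_exactly_excluded(self):
        cells = _two_class_cells(n_a=10, n_b=10, noise=1.0, seed=5)
        wn = cells[0].spectrum.wavenumbers
        big = CellRecord(
            "outlier",
            RamanSpectrum(wn, 10.0 * cells[0].spectrum.intensities), "X",
        )
        p = run_pca(cells + [big])
        out = exclude_outliers(p, alpha=0.025)
        assert out.excluded_ids == ("outlier",)
        assert "outlier" not in out.cell_ids

    def test_alpha_zero_limit_excludes_nothing(self):
        p = run_pca(_two_class_cells(noise=1.0, seed=6))
        out = exclude_outliers(p, alpha=0.0)
        assert out.excluded_ids == ()
        assert out is p

    def test_t2_values_nonnegative(self):
        p = run_pca(_two_class_cells(noise=1.0, seed=7))
        assert np.all(hotelling_t2(p) >= 0)


class TestSplitGroups:
    def test_planted_partition_recovered_exactly(self):
        cells = _two_class_cells(n_a=5, n_b=7, noise=0.5, seed=8)
        p = run_pca(cells)
        i785 = {c.cell_id: c.spectrum.intensities.max() for c in cells}
        out = split_groups(p, i785)
        for cid, group in out.group_assignment.items():
            assert group == ("A" if cid.startswith("a") else "B")

    def test_cluster_sizes_partition_cells(self):
        p = run_pca(_two_class_cells(noise=1.0, seed=9))
        out = split_groups(p)
        groups = list(out.group_assignment.values())
        assert groups.count("A") + groups.count("B") == len(p.cell_ids)

    def test_repeat_runs_identical(self):
        cells = _two_class_cells(noise=2.0, seed=10)
        p = run_pca(cells)
        assert split_groups(p).group_assignment == split_groups(p).group_assignment


class TestNormalityCheck:
    def test_gaussian_samples_usually_pass(self):
        """Shapiro-Wilk keeps the parametric verdict for most normal draws."""
        verdicts = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            r = normality_check({"g": rng.standard_normal(500)})
            verdicts.append(r["verdict"] == "parametric")
        assert np.mean(verdicts) >= 0.90

    def test_bimodal_sample_flagged_nonparametric(self, rng):
        v = np.concatenate([rng.normal(-5, 0.3, 250), rng.normal(5, 0.3, 250)])
        assert normality_check({"g": v})["verdict"] == "nonparametric"

    def test_constant_group_flagged(self):
        r = normality_check({"g": [2.0, 2.0, 2.0, 2.0]})
        assert r["verdict"] == "nonparametric"
        assert r["groups"]["g"]["constant"]
        assert np.isnan(r["groups"]["g"]["p_value"])


class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        """U=0 and exact two-sided p = 2/C(6,3) = 0.1."""
        r = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert r.u == 0.0
        assert r.method == "exact"
        assert r.p_value == pytest.approx(0.1, rel=1e-12)

    def test_identical_multisets_give_central_u(self):
        vals = [1.0, 2.0, 2.0, 3.0, 7.0]
        r = mann_whitney(vals, vals)
        assert r.u == pytest.approx(len(vals) ** 2 / 2.0)

    def test_exact_p_matches_scipy_for_all_small_splits(self, rng):
        """Independent oracle: scipy's exact Mann-Whitney distribution."""
        for nx in range(1, 6):
            for ny in range(1, 6):
                vals = rng.permutation(np.arange(1.0, nx + ny + 1.0))
                x, y = vals[:nx], vals[nx:]
                ours = mann_whitney(x, y)
                ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact")
                assert ours.method == "exact"
                assert ours.u == ref.statistic
                assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_sample_p_matches_permutation_oracle(self, rng):
        x = rng.normal(0.4, 1.0, 50)
        y = rng.normal(0.0, 1.0, 50)
        r = mann_whitney(x, y)
        assert r.method == "normal_approx"
        pooled = np.concatenate([x, y])
        perm_rng = np.random.default_rng(99)
        center = 50 * 50 / 2.0
        obs_dev = abs(r.u - center)
        hits = 0
        n_perm = 20000
        for _ in range(n_perm):
            pooled = perm_rng.permutation(pooled)
            ranks = sps.rankdata(pooled)
            u = ranks[:50].sum() - 50 * 51 / 2.0
            hits += abs(u - center) >= obs_dev - 1e-9
        p_perm = hits / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(r.p_value - p_perm) < max(4 * se, 0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_group_summaries_reported(self):
        r = mann_whitney([1.0, 2.0, 9.0], [0.0, 1.0], feature="I785")
        assert r.feature == "I785"
        assert (r.n_x, r.n_y) == (3, 2)
        assert r.median_x == 2.0 and r.median_y == 0.5


class TestRoc:
    def test_interleaved_example(self):
        """3 of 4 (X, Y) pairs concordant -> AUC = 0.75."""
        r = roc_analysis(_table([3.0, 5.0], [1.0, 4.0]), "I785")
        assert r.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        r = roc_analysis(_table([10.0, 11.0, 12.0], [1.0, 2.0]), "I785")
        assert r.auc == 1.0
        assert 2.0 < r.cutoff < 10.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_youden_cutoff_exhaustive_enumeration(self):
        r = roc_analysis(_table([10.0, 20.0, 30.0], [5.0, 15.0]), "I785")
        assert r.cutoff == pytest.approx(17.5)
        assert r.sensitivity - (1.0 - r.specificity) == pytest.approx(2.0 / 3.0)

    def test_curve_monotone_in_threshold(self, rng):
        r = roc_analysis(_table(rng.normal(1, 1, 30), rng.normal(0, 1, 20)), "I785")
        assert np.all(np.diff(r.tpr) >= 0)
        assert np.all(np.diff(r.fpr) >= 0)
        assert r.cutoff in r.thresholds

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            x = rng.normal(0.5, 1, 15)
            y = rng.normal(0, 1, 10)
            t = _table(x, y)
            ours = roc_analysis(t, "I785").auc
            ref = roc_auc_score((t.label == "X").astype(int), t.I785)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_single_class_rejected(self):
        t = _table([1.0, 2.0], [])
        with pytest.raises(ValueError):
            roc_analysis(t, "I785")


class TestHistogram:
    def test_simple_counts(self):
        t = _table([1.0, 2.0, 3.0, 11.0, 12.0, 13.0], [])
        t2 = t.copy()
        t2.loc[3:, "label"] = "Y"  # make both labels present
        h = frequency_histogram(t2, "I785", bin_width=10.0)
        assert list(h.counts["X"]) == [3, 0]
        assert list(h.counts["Y"]) == [0, 3]

    def test_disjoint_supports_full_cdf_gap(self):
        h = frequency_histogram(_table([20.0, 25.0], [1.0, 5.0]), "I785",
                                bin_width=10.0)
        assert h.cdf_gap == pytest.approx(1.0)
        assert 5.0 <= h.breakpoint < 20.0

    def test_breakpoint_matches_linear_scan_oracle(self, rng):
        x = rng.normal(30.0, 10.0, 40)
        y = rng.normal(20.0, 10.0, 25)
        h = frequency_histogram(_table(x, y), "I785", bin_width=5.0)
        gaps = [abs((x <= e).mean() - (y <= e).mean()) for e in h.edges]
        assert h.cdf_gap == pytest.approx(max(gaps), rel=1e-12)

    def test_bin_width_validation(self):
        with pytest.raises(ValueError):
            frequency_histogram(_table([1.0], [2.0]), "I785", bin_width=0.0)


class TestClassify:
    def test_cutoff_below_all_predicts_all_x(self):
        t = _table([5.0, 6.0], [3.0, 4.0])
        pred, conf = classify(t, cutoff=0.0, feature="I785")
        assert set(pred) == {"X"}
        assert conf == {"tp": 2, "fp": 2, "fn": 0, "tn": 0, "accuracy": 0.5}

    def test_youden_cutoff_on_separated_cohort_is_perfect(self):
        t = _table([10.0, 11.0], [1.0, 2.0])
        roc = roc_analysis(t, "I785")
        _, conf = classify(t, roc.cutoff, "I785")
        assert conf["accuracy"] == 1.0

    def test_unknown_labels_excluded_from_confusion(self):
        t = _table([5.0], [1.0])
        t.loc[len(t)] = ["u0", "unknown", 9.0, 9.0]
        pred, conf = classify(t, cutoff=3.0, feature="I785")
        assert pred.loc["u0"] == "X"
        assert conf["tp"] + conf["fp"] + conf["fn"] + conf["tn"] == 2

    def test_infinite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            classify(_table([1.0], [0.0]), np.inf, "I785")
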