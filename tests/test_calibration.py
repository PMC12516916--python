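"""Calibration machinery: PCC, stepped ROC + cutoff selection, confusion,
Wilcoxon, subset search, regression fitting, and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest

from dimerqa.calibration import (
    LabeledScoreTable,
    calibrate_pipeline,
    combined_columns,
    confusion,
    fit_lasso,
    fit_linear,
    normalized_frame,
    pcc,
    roc,
    subset_search,
    wsr_test,
)
from dimerqa.errors import CalibrationError
from dimerqa.model import Method


def table_from(scores: dict, dockq: np.ndarray) -> LabeledScoreTable:
    frame = pd.DataFrame(scores)
    frame["model_id"] = [f"m{i}" for i in range(len(dockq))]
    frame["dockq"] = dockq
    return LabeledScoreTable(frame)


def synth_table(n=400, seed=0, noise=0.05, with_voroif=True) -> LabeledScoreTable:
    """Direct synthetic score table (no structures): scores track a latent
    quality, DockQ is a monotone function of it."""
    rng = np.random.default_rng(seed)
    q = rng.uniform(0, 1, n)
    frame = {
        "iplddt": np.clip(40 + 55 * q + rng.normal(0, 100 * noise, n), 0, 100),
        "ipae": np.clip(28 * (1 - q) + 2 + rng.normal(0, 30 * noise, n), 0, 31.75),
        "ptm": np.clip(q + rng.normal(0, noise, n), 0, 1),
        "iptm": np.clip(q + rng.normal(0, noise, n), 0, 1),
    }
    if with_voroif:
        frame["voroif"] = np.clip(q + rng.normal(0, noise, n), 0, 1)
    dockq = np.clip(1.1 * q - 0.15 + rng.normal(0, noise / 2, n), 0, 1)
    return table_from(frame, dockq)


class TestPcc:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert pcc(x, 2 * x + 1) == pytest.approx(1.0)
        assert pcc(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=50), rng.normal(size=50)
        expected = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert pcc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_error(self):
        with pytest.raises(CalibrationError):
            pcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRoc:
    def test_perfectly_separated_unit_score(self):
        """Scores {0.9, 0.8 | 0.2, 0.1}: AUC 1, cutoff the most permissive
        0.05-grid point with perfect separation — enumerated by hand, the
        tie-break picks 0.25 (first grid point inside (0.2, 0.8])."""
        t = table_from({"iptm": [0.9, 0.8, 0.2, 0.1]}, np.array([0.9, 0.9, 0.0, 0.0]))
        r = roc(t, "iptm")
        assert r.auc == 1.0
        assert 0.2 < r.best_cutoff <= 0.8
        assert r.best_cutoff == pytest.approx(0.25)
        assert r.best_distance == pytest.approx(1.0)

    def test_pae_family_direction(self):
        """Lower iPAE is better: correct models at 3-4 Å, incorrect at 20 Å."""
        t = table_from({"ipae": [3.0, 4.0, 20.0, 22.0]}, np.array([0.9, 0.9, 0.0, 0.0]))
        r = roc(t, "ipae")
        assert r.auc == 1.0
        assert 4.0 <= r.best_cutoff < 20.0
        cm = confusion(t, "ipae", r.best_cutoff)
        assert cm.accuracy == 1.0

    def test_shuffled_labels_auc_half(self):
        rng = np.random.default_rng(0)
        n = 10_000
        scores = rng.uniform(0, 1, n)
        dockq = rng.permutation(np.r_[np.full(n // 2, 0.9), np.full(n // 2, 0.0)])
        r = roc(table_from({"iptm": scores}, dockq), "iptm")
        assert r.auc == pytest.approx(0.5, abs=0.02)
        assert not r.reliable

    def test_auc_invariant_under_monotone_transform(self):
        t = synth_table(n=300, seed=5)
        base = roc(t, "iptm").auc
        f = t.frame.copy()
        f["iptm"] = np.exp(3 * f["iptm"])  # strictly increasing transform
        assert roc(LabeledScoreTable(f), "iptm").auc == pytest.approx(base, abs=1e-12)

    def test_best_cutoff_is_grid_argmax(self):
        """Exhaustive grid enumeration is the oracle for the selected cutoff."""
        t = synth_table(n=200, seed=7)
        r = roc(t, "iptm")
        labels, values = t.labels, t.scores("iptm")
        grid = np.arange(0.0, values.max() + 0.1, 0.05)
        best_j, best_c = -np.inf, None
        for c in grid:
            pred = values >= c
            j = (pred & labels).sum() / labels.sum() - (pred & ~labels).sum() / (~labels).sum()
            if j > best_j + 1e-12:
                best_j, best_c = j, c
        assert r.best_cutoff == pytest.approx(best_c)
        assert r.best_distance == pytest.approx(best_j)

    def test_degenerate_inputs(self):
        t = table_from({"iptm": [0.5, 0.5, 0.5]}, np.array([0.9, 0.9, 0.0]))
        with pytest.raises(CalibrationError, match="constant"):
            roc(t, "iptm")
        t2 = table_from({"iptm": [0.5, 0.6, 0.7]}, np.array([0.9, 0.9, 0.9]))
        with pytest.raises(CalibrationError, match="label"):
            roc(t2, "iptm")


class TestConfusion:
    def test_hand_counted(self):
        # TP=3 TN=2 FP=1 FN=2 at cutoff 0.5
        values = [0.9, 0.8, 0.7, 0.6, 0.2, 0.1, 0.3, 0.4]
        dockq = [0.9, 0.9, 0.9, 0.0, 0.0, 0.0, 0.9, 0.9]
        cm = confusion(table_from({"iptm": values}, np.array(dockq)), "iptm", 0.5)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (3, 2, 1, 2)
        assert cm.accuracy == pytest.approx(0.625)
        assert cm.precision == pytest.approx(0.75)

    def test_perfect_classifier(self):
        t = table_from({"iptm": [0.9, 0.8, 0.1, 0.2]}, np.array([0.9, 0.9, 0.0, 0.0]))
        cm = confusion(t, "iptm", 0.5)
        assert cm.accuracy == cm.precision == cm.recall == cm.specificity == 1.0

    def test_empty_positive_predictions(self):
        t = table_from({"iptm": [0.1, 0.2, 0.3, 0.4]}, np.array([0.9, 0.9, 0.0, 0.0]))
        cm = confusion(t, "iptm", 0.99)
        assert cm.precision is None


class TestWsr:
    def test_identical_pairs_degenerate(self):
        r = wsr_test([1.0] * 10, [1.0] * 10)
        assert r.degenerate and r.p_value == 1.0 and not r.significant

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        r = wsr_test(a + 5.0, a)
        assert r.p_value < 0.001 and r.significant

    def test_too_few_informative(self):
        with pytest.raises(CalibrationError, match="informative"):
            wsr_test([1.0, 2.0, 3.0, 1.0], [1.0, 2.0, 3.0, 2.0])

    def test_type_one_error_rate(self):
        """Under the null (symmetric zero-median differences), rejection at
        α=0.05 stays near nominal."""
        rng = np.random.default_rng(123)
        reject = 0
        reps = 500
        for _ in range(reps):
            d = rng.normal(0, 1, 20)
            if wsr_test(d, np.zeros(20)).p_value < 0.05:
                reject += 1
        assert 0.02 <= reject / reps <= 0.08


class TestSubsetSearch:
    def test_leaderboard_size(self):
        board = subset_search(synth_table(n=100, seed=1))
        assert len(board) == 31  # 2^5 − 1 non-empty subsets

    def test_planted_pair_wins(self):
        """DockQ equal to the mean of two normalized candidates → that pair
        tops the leaderboard with PCC 1."""
        t = synth_table(n=200, seed=2)
        norm = normalized_frame(t)
        f = t.frame.copy()
        f["dockq"] = (norm["iptm"] + norm["voroif"]) / 2
        board = subset_search(LabeledScoreTable(f))
        assert board.iloc[0]["subset"] == "iptm+voroif"
        assert board.iloc[0]["pcc"] == pytest.approx(1.0)

    def test_single_informative_candidate_wins(self):
        rng = np.random.default_rng(4)
        n = 300
        q = rng.uniform(0, 1, n)
        t = table_from(
            {
                "iplddt": rng.uniform(0, 100, n),
                "ipae": rng.uniform(0, 30, n),
                "ptm": rng.uniform(0, 1, n),
                "iptm": np.clip(q, 0, 1),
                "voroif": rng.uniform(0, 1, n),
            },
            q,
        )
        board = subset_search(t)
        assert board.iloc[0]["subset"] == "iptm"


class TestRegression:
    def test_noiseless_recovery(self):
        t = synth_table(n=100, seed=3)
        norm = normalized_frame(t)
        f = t.frame.copy()
        f["dockq"] = 0.3 * norm["iplddt"] + 0.7 * norm["iptm"] + 0.1
        w = fit_linear(LabeledScoreTable(f), features=("iplddt", "iptm"))
        assert w.weights["iplddt"] == pytest.approx(0.3, abs=1e-8)
        assert w.weights["iptm"] == pytest.approx(0.7, abs=1e-8)
        assert w.bias == pytest.approx(0.1, abs=1e-8)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(6)
        n = 1000
        t = synth_table(n=n, seed=6, noise=0.2)
        norm = normalized_frame(t)
        f = t.frame.copy()
        true = {"iplddt": 0.25, "ipae": 0.15, "ptm": 0.1, "iptm": 0.35, "voroif": 0.15}
        f["dockq"] = sum(c * norm[k] for k, c in true.items()) + 0.05 + rng.normal(0, 0.05, n)
        w = fit_linear(LabeledScoreTable(f))
        for k, c in true.items():
            assert w.weights[k] == pytest.approx(c, abs=0.03)

    def test_residual_orthogonality(self):
        t = synth_table(n=300, seed=8)
        w = fit_linear(t)
        norm = normalized_frame(t)
        X = norm[list(w.weights)].to_numpy()
        resid = t.frame["dockq"].to_numpy() - (X @ np.array(list(w.weights.values())) + w.bias)
        assert np.abs(X.T @ resid).max() <= 1e-8 * len(resid)

    def test_underdetermined_error(self):
        t = synth_table(n=3, seed=1)
        with pytest.raises(CalibrationError, match="rows"):
            fit_linear(t)

    def test_collinear_error(self):
        t = synth_table(n=100, seed=9)
        f = t.frame.copy()
        f["iptm"] = f["ptm"]  # exact duplication after clipping? force it
        with pytest.raises(CalibrationError, match="collinear|rank"):
            fit_linear(LabeledScoreTable(f), features=("ptm", "iptm"))

    def test_lasso_limits(self):
        t = synth_table(n=400, seed=10)
        w0 = fit_lasso(t, penalty=0.0)
        wl = fit_linear(t)
        for k in wl.weights:
            assert w0.weights[k] == pytest.approx(wl.weights[k], abs=1e-6)
        wbig = fit_lasso(t, penalty=1e3)
        assert all(v == 0.0 for v in wbig.weights.values())
        assert wbig.bias == pytest.approx(t.frame["dockq"].mean())

    def test_lasso_sparsity(self):
        """Noise features shrink to exactly zero at moderate penalty."""
        rng = np.random.default_rng(11)
        n = 500
        q = rng.uniform(0, 1, n)
        t = table_from(
            {
                "iplddt": np.clip(100 * q + rng.normal(0, 2, n), 0, 100),
                "iptm": np.clip(q + rng.normal(0, 0.02, n), 0, 1),
                "ipae": rng.uniform(0, 30, n),
                "ptm": rng.uniform(0, 1, n),
                "voroif": rng.uniform(0, 1, n),
            },
            np.clip(q + rng.normal(0, 0.02, n), 0, 1),
        )
        w = fit_lasso(t, penalty=0.02)
        assert w.weights["ipae"] == 0.0
        assert w.weights["ptm"] == 0.0
        assert w.weights["voroif"] == 0.0
        assert w.weights["iplddt"] > 0 or w.weights["iptm"] > 0


class TestPipeline:
    def test_separable_table(self):
        """Cleanly separated synthetic data: every AUC is 1 and every cutoff
        sits between the class supports."""
        rng = np.random.default_rng(12)
        n = 120
        good = rng.uniform(0.8, 0.95, n // 2)
        bad = rng.uniform(0.05, 0.2, n // 2)
        q = np.r_[good, bad]
        jitter = lambda s: rng.normal(0, s, n)  # tiny, keeps classes separated
        t = table_from(
            {
                "iplddt": 40 + 55 * q + jitter(0.5),
                "ipae": 28 * (1 - q) + 2 + jitter(0.2),
                "ptm": np.clip(q + jitter(0.005), 0, 1),
                "iptm": np.clip(q + jitter(0.005), 0, 1),
                "voroif": np.clip(q + jitter(0.005), 0, 1),
            },
            np.where(q > 0.5, 0.9, 0.05),
        )
        cal = calibrate_pipeline(t, Method.CF_T)
        assert (cal.report["auc"] == 1.0).all()
        iptm = t.frame["iptm"]
        assert iptm[~t.labels].max() < cal.cutoffs["iptm"] <= iptm[t.labels].min()
        assert cal.wsr_vs_unweighted.p_value <= 1.0

    def test_recalibration_recovers_classification(self):
        train = synth_table(n=400, seed=13)
        test = synth_table(n=400, seed=14)
        cal = calibrate_pipeline(train, Method.CF_F)
        ext = LabeledScoreTable(combined_columns(test, cal.weights))
        cm = confusion(ext, "c2qscore", cal.cutoffs["c2qscore"])
        assert cm.accuracy >= 0.9

    def test_label_shuffled_flagged_unreliable(self):
        t = synth_table(n=800, seed=15)
        f = t.frame.copy()
        rng = np.random.default_rng(15)
        f["dockq"] = rng.permutation(f["dockq"].to_numpy())
        cal = calibrate_pipeline(LabeledScoreTable(f), Method.AF3)
        raw = cal.report[cal.report["score"].isin(["iplddt", "ipae", "ptm", "iptm"])]
        assert (raw["auc"] - 0.5).abs().max() < 0.1
        assert not raw["reliable"].any()
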