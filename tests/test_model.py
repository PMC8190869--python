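import itertools

import numpy as np
import pandas as pd
import pytest

from methdmr import (ParameterError, PredictiveModel, final_model, fit_lasso,
                     loocv_scores, predict_proba, roc_summary,
                     score_external, select_candidates)

from conftest import make_window_matrix


def _labelled_wm(seed=0, n_windows=60, n_pos=8, n_neg=12, effect=0.35,
                 planted=(0, 1, 2), coverage=25):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    base = rng.uniform(0.2, 0.5, size=(n_windows, 1))
    mean = np.broadcast_to(base, (n_windows, n)).copy()
    if len(planted):
        mean[np.array(planted)[:, None], np.arange(n_pos)] += effect
    cov = rng.integers(coverage, coverage + 15, size=(n_windows, n))
    meth = rng.binomial(cov, np.clip(mean, 0.02, 0.98))
    wm = make_window_matrix(meth, cov)
    labels = pd.Series([True] * n_pos + [False] * n_neg, index=wm.samples)
    return wm, labels


class TestSelectCandidates:
    def test_recovers_planted_windows(self):
        wm, labels = _labelled_wm()
        cands = select_candidates(wm, labels)
        planted = {f"chr1:{i * 1000 + 1}-{(i + 1) * 1000}" for i in range(3)}
        assert planted <= set(cands)

    def test_null_data_yields_no_candidates(self):
        wm, labels = _labelled_wm(seed=5, planted=(), effect=0.0)
        assert select_candidates(wm, labels) == []

    def test_open_gates_return_all_testable(self):
        wm, labels = _labelled_wm()
        assert len(select_candidates(wm, labels, q_max=1.0,
                                     min_abs_diff=0.0)) == wm.n_windows

    def test_single_class_rejected(self):
        wm, labels = _labelled_wm()
        positives = [s for s in labels.index if labels[s]]
        with pytest.raises(ParameterError):
            select_candidates(wm, labels, sample_ids=positives)


class TestFitLasso:
    def test_separating_column_selected_among_noise(self):
        rng = np.random.default_rng(7)
        n = 40
        y = pd.Series([True] * 20 + [False] * 20)
        X = pd.DataFrame(rng.random((n, 51)),
                         columns=[f"w{i}" for i in range(51)])
        X["w0"] = np.r_[rng.uniform(0.7, 1.0, 20), rng.uniform(0.0, 0.3, 20)]
        model = fit_lasso(X, y, seed=0)
        assert "w0" in model.markers
        j = model.markers.index("w0")
        assert model.coefficients[j] > 0

    def test_pure_noise_null_model_predicts_prevalence(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.random((40, 5)),
                         columns=[f"w{i}" for i in range(5)])
        y = pd.Series([True] * 10 + [False] * 30, index=X.index)
        model = fit_lasso(X, y, seed=0)
        if len(model.markers) == 0:          # heavy penalty won
            p = predict_proba(model, X)
            assert np.allclose(p, 0.25)

    def test_duplicated_column_leaves_prediction_invariant(self):
        rng = np.random.default_rng(3)
        y = pd.Series([True] * 15 + [False] * 15)
        base = np.r_[rng.uniform(0.6, 1.0, 15), rng.uniform(0.0, 0.4, 15)]
        X = pd.DataFrame({"a": base, "n1": rng.random(30)})
        Xdup = X.assign(b=base)
        m1 = fit_lasso(X, y, seed=0)
        m2 = fit_lasso(Xdup, y, seed=0)
        p1 = predict_proba(m1, X)
        p2 = predict_proba(m2, Xdup)
        np.testing.assert_allclose(p1, p2, atol=0.06)

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).random((10, 3)))
        X.columns = ["a", "b", "c"]
        with pytest.raises(ParameterError):
            fit_lasso(X, pd.Series([True] * 10, index=X.index))

    def test_json_round_trip(self, tmp_path):
        wm, labels = _labelled_wm()
        cands = select_candidates(wm, labels)
        model = fit_lasso(wm.levels_frame().T[cands], labels, seed=1)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PredictiveModel.from_json(path)
        assert back.markers == model.markers
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        assert back.intercept == model.intercept


class TestRocSummary:
    def test_perfect_separation(self):
        roc = roc_summary([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_constant_scores_are_chance(self):
        roc = roc_summary([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert roc.auc == 0.5

    def test_hand_counted_pairs(self):
        roc = roc_summary([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.75)   # 3 of 4 concordant pairs

    def test_equals_exhaustive_pair_counting(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 25))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            conc = half = tot = 0
            for i, j in itertools.product(range(n), range(n)):
                if labels[i] and not labels[j]:
                    tot += 1
                    conc += scores[i] > scores[j]
                    half += scores[i] == scores[j]
            expect = (conc + 0.5 * half) / tot
            assert roc_summary(scores, labels).auc == pytest.approx(expect)

    def test_points_monotone(self):
        rng = np.random.default_rng(1)
        roc = roc_summary(rng.random(30), rng.integers(0, 2, 30).astype(bool))
        assert (np.diff(roc.points["fpr"]) >= 0).all()
        assert (np.diff(roc.points["tpr"]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_summary([0.1, 0.2], [1, 1])


class TestLoocv:
    def test_planted_signal_scores_high(self):
        wm, labels = _labelled_wm(seed=2, n_pos=10, n_neg=14, effect=0.4)
        scores, flags = loocv_scores(wm, labels, seed=0)
        roc = roc_summary(scores.to_numpy(), labels)
        assert roc.auc > 0.85

    def test_two_sample_cohort_degenerate(self):
        wm, labels = _labelled_wm(n_pos=1, n_neg=1)
        scores, flags = loocv_scores(wm, labels, seed=0)
        assert (flags == "single_class").all()

    def test_no_leakage_from_held_out_sample(self):
        """Corrupting a held-out sample cannot change its fold's training
        artifacts (candidates, coefficients, penalty)."""
        wm, labels = _labelled_wm(seed=4, n_pos=6, n_neg=8, n_windows=40)
        _, _, details = loocv_scores(wm, labels, seed=0, return_details=True)
        victim = wm.samples[0]
        col = wm.sample_columns([victim])[0]
        wm2 = make_window_matrix(wm.meth.copy(), wm.cov.copy())
        wm2.meth[:, col] = 0
        wm2.cov[:, col] = 1
        _, _, details2 = loocv_scores(wm2, labels, seed=0,
                                      return_details=True)
        d1 = next(d for d in details if d["held_out"] == victim)
        d2 = next(d for d in details2 if d["held_out"] == victim)
        assert d1["candidates"] == d2["candidates"]
        m1, m2 = d1["model"], d2["model"]
        assert m1.markers == m2.markers and m1.C == m2.C
        np.testing.assert_allclose(m1.coefficients, m2.coefficients)
        np.testing.assert_allclose(m1.means, m2.means)
        assert m1.intercept == m2.intercept


class TestFinalModelAndExternal:
    def test_final_model_recovers_planted_markers(self):
        wm, labels = _labelled_wm(seed=6, n_pos=10, n_neg=14, effect=0.4)
        model, table = final_model(wm, labels, seed=0)
        planted = {f"chr1:{i * 1000 + 1}-{(i + 1) * 1000}" for i in range(3)}
        assert planted <= set(model.markers)
        assert set(table.columns) >= {"chrom", "start", "end", "direction",
                                      "gene_context", "gene_name"}
        assert set(table["direction"]) <= {"hyper", "hypo"}

    def test_zero_candidates_yields_empty_model(self):
        wm, labels = _labelled_wm(seed=5, planted=(), effect=0.0)
        model, table = final_model(wm, labels, seed=0)
        assert model.markers == [] and len(table) == 0
        assert "warning" in table.attrs

    def test_policies_coincide_when_all_markers_available(self):
        wm, labels = _labelled_wm(seed=6, n_pos=10, n_neg=14, effect=0.4)
        model, _ = final_model(wm, labels, seed=0)
        feats = wm.levels_frame().T
        a, _, ia = score_external(model, feats, missing_policy="mean_impute")
        b, _, ib = score_external(model, feats, missing_policy="drop_renorm")
        pd.testing.assert_series_equal(a, b)
        assert ia["n_available"] == ia["n_markers"]

    def test_missing_markers_drop_their_standardized_terms(self):
        wm, labels = _labelled_wm(seed=6, n_pos=10, n_neg=14, effect=0.4)
        model, _ = final_model(wm, labels, seed=0)
        assert len(model.markers) >= 2
        feats = wm.levels_frame().T
        full = predict_proba(model, feats)
        drop = feats.drop(columns=model.markers[:2])
        part, _, info = score_external(model, drop)
        assert info["n_available"] == len(model.markers) - 2
        # reconstruct by subtracting the two standardized terms by hand
        eta_full = np.log(full / (1 - full))
        z = [(feats[m] - model.means[j]) / model.scales[j]
             for j, m in enumerate(model.markers[:2])]
        eta_exp = (eta_full - model.coefficients[0] * z[0]
                   - model.coefficients[1] * z[1])
        np.testing.assert_allclose(np.log(part / (1 - part)), eta_exp,
                                   atol=1e-10)

    def test_all_markers_missing_rejected(self):
        wm, labels = _labelled_wm(seed=6, n_pos=10, n_neg=14, effect=0.4)
        model, _ = final_model(wm, labels, seed=0)
        bogus = pd.DataFrame({"zzz": [0.5, 0.6]})
        with pytest.raises(ParameterError):
            score_external(model, bogus)
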