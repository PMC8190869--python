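"""Liver-metastasis risk model: candidate selection, L1 logistic regression,
leave-one-out cross-validation and ROC evaluation.

The estimator is an L1-penalized (LASSO) logistic regression on window
methylation levels.  Candidate windows are re-selected inside every
training set (differential methylation between LIM-positive and
LIM-negative training samples at q <= 0.05 and |diff| >= 20 pp), features
are standardized to zero mean / unit variance on the training data, and the
penalty is chosen by stratified 10-fold cross-validated deviance at its
minimum.  Leave-one-out cross-validation repeats the entire procedure with
each sample held out once, so no information from the held-out sample ever
reaches candidate selection, standardization or penalty choice.  The pooled
held-out probabilities give the ROC; the reported operating point maximizes
Youden's J (ties resolved toward higher specificity).

External samples missing some markers are scored either by training-mean
imputation (a missing standardized term contributes zero) or by dropping the
missing coefficients and recentering by their training-mean contribution —
which, in standardized coordinates, is the same number; both policies are
kept because they are stated independently and diverge for any future
non-centered parameterization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._errors import ParameterError
from .tiling import WindowMatrix, adjust_fdr, dmr_table, filter_dmrs

DEFAULT_Q_MAX = 0.05
DEFAULT_MIN_ABS_DIFF = 20.0
_CS = np.logspace(-2.5, 2.5, 15)


@dataclass
class PredictiveModel:
    """L1-selected marker windows with their penalized coefficients.

    ``means``/``scales`` are the training standardization of each marker;
    the linear predictor is intercept + sum(coef * (x - mean) / scale).
    """

    markers: list[str]
    coefficients: np.ndarray
    intercept: float
    means: np.ndarray
    scales: np.ndarray
    threshold: float = 0.5
    C: float | None = None
    n_candidates: int | None = None

    def to_json(self, path=None) -> str:
        doc = {
            "markers": list(self.markers),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "means": [float(m) for m in self.means],
            "scales": [float(s) for s in self.scales],
            "threshold": float(self.threshold),
            "C": None if self.C is None else float(self.C),
            "n_candidates": self.n_candidates,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "PredictiveModel":
        try:
            doc = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                doc = json.load(fh)
        return cls(
            markers=list(doc["markers"]),
            coefficients=np.asarray(doc["coefficients"], dtype=float),
            intercept=float(doc["intercept"]),
            means=np.asarray(doc["means"], dtype=float),
            scales=np.asarray(doc["scales"], dtype=float),
            threshold=float(doc["threshold"]),
            C=doc.get("C"),
            n_candidates=doc.get("n_candidates"),
        )


@dataclass
class RocSummary:
    points: pd.DataFrame      # columns threshold, fpr, tpr
    auc: float
    threshold: float
    sensitivity: float
    specificity: float


def select_candidates(
    wm: WindowMatrix,
    labels: pd.Series,
    sample_ids: Sequence[str] | None = None,
    q_max: float = DEFAULT_Q_MAX,
    min_abs_diff: float = DEFAULT_MIN_ABS_DIFF,
) -> list[str]:
    """Candidate marker windows from the training samples only.

    ``labels`` maps sample_id -> bool (LIM positive).  Runs the windowed
    differential test positive-vs-negative on ``sample_ids`` (default: all
    labelled samples), BH-adjusts, and applies the q/effect-size gates.
    """
    ids = list(labels.index if sample_ids is None else sample_ids)
    pos = [s for s in ids if bool(labels[s])]
    neg = [s for s in ids if not bool(labels[s])]
    if len(pos) < 2 or len(neg) < 2:
        raise ParameterError("need >= 2 samples per class to select candidates")
    table = dmr_table(wm, pos, neg)
    table["q"] = adjust_fdr(table["p"].to_numpy())
    kept = filter_dmrs(table, q_max=q_max, min_abs_diff=min_abs_diff)
    return list(kept["chrom"].astype(str) + ":" + kept["start"].astype(str)
                + "-" + kept["end"].astype(str))


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = np.nanmean(X, axis=0)
    filled = np.where(np.isnan(X), means, X)
    scales = filled.std(axis=0, ddof=0)
    scales = np.where(scales > 0, scales, 1.0)
    return means, scales


def _apply_standardize(X, means, scales) -> np.ndarray:
    filled = np.where(np.isnan(X), means, X)
    return (filled - means) / scales


def fit_lasso(
    features: pd.DataFrame,
    labels: pd.Series,
    n_folds: int = 10,
    seed: int | None = None,
) -> PredictiveModel:
    """Fit the L1 logistic model on a training feature matrix.

    ``features``: samples x candidate-window levels (NaN allowed; imputed
    with the training column mean).  The penalty is picked by stratified
    ``n_folds``-fold cross-validated log-loss at its minimum; the penalized
    coefficients at that penalty are reported without refitting.  ``seed``
    only controls the inner fold shuffle.
    """
    y = labels.loc[features.index].astype(bool).to_numpy()
    if y.all() or not y.any():
        raise ParameterError("training data must contain both classes")
    X = features.to_numpy(dtype=float)
    means, scales = _standardize_fit(X)
    Z = _apply_standardize(X, means, scales)
    n_min = min(int(y.sum()), int((~y).sum()))
    folds = max(2, min(n_folds, n_min))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    # large intercept_scaling makes liblinear's intercept penalty negligible
    clf = LogisticRegressionCV(
        Cs=_CS, cv=cv, penalty="l1", solver="liblinear",
        intercept_scaling=100.0, scoring="neg_log_loss", max_iter=2000,
        random_state=0 if seed is None else seed, refit=True,
    )
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(Z, y)
    coef = clf.coef_.ravel()
    nz = np.flatnonzero(coef)
    intercept = float(clf.intercept_[0])
    if nz.size == 0:
        # the penalized MLE with a free intercept is the null model at the
        # training prevalence
        prev = float(np.mean(y))
        intercept = float(np.log(prev / (1.0 - prev)))
    return PredictiveModel(
        markers=[features.columns[i] for i in nz],
        coefficients=coef[nz],
        intercept=intercept,
        means=means[nz],
        scales=scales[nz],
        C=float(clf.C_[0]),
        n_candidates=features.shape[1],
    )


def predict_proba(
    model: PredictiveModel,
    features: pd.DataFrame,
    missing_policy: str = "mean_impute",
) -> pd.Series:
    """Probability of the positive class for each sample row.

    Markers absent from ``features`` (or NaN in a sample) are handled per
    ``missing_policy``: ``mean_impute`` substitutes the training mean (the
    standardized term is 0); ``drop_renorm`` removes the coefficient and
    recenters by its training-mean contribution.  At least one model marker
    must be measurable.
    """
    if missing_policy not in ("mean_impute", "drop_renorm"):
        raise ParameterError(f"unknown missing_policy {missing_policy!r}")
    present = [m for m in model.markers if m in features.columns
               and features[m].notna().any()]
    if len(model.markers) and not present:
        raise ParameterError("no model marker measurable in these samples")
    eta = np.full(len(features), model.intercept)
    for j, m in enumerate(model.markers):
        if m not in present:
            if missing_policy == "mean_impute":
                continue               # standardized term is 0
            # drop + recenter by the training-mean contribution, which is 0
            # for a mean-centered term
            continue
        x = features[m].to_numpy(dtype=float)
        z = np.where(np.isnan(x), 0.0,
                     (np.where(np.isnan(x), model.means[j], x)
                      - model.means[j]) / model.scales[j])
        eta = eta + model.coefficients[j] * z
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=features.index)


def loocv_scores(
    wm: WindowMatrix,
    labels: pd.Series,
    q_max: float = DEFAULT_Q_MAX,
    min_abs_diff: float = DEFAULT_MIN_ABS_DIFF,
    n_folds: int = 10,
    seed: int | None = None,
    return_details: bool = False,
):
    """Pooled held-out probability scores from leave-one-out CV.

    For every labelled sample: candidates are re-selected on the remaining
    samples, the LASSO is fit there, and the held-out sample's probability
    is recorded.  Folds whose training set loses a class, or that yield no
    candidates, score the held-out sample at the training prevalence and are
    flagged.  Returns (scores, flags) as Series aligned to sample ids, plus
    a per-fold details list when ``return_details``.
    """
    ids = list(labels.index)
    lv = wm.levels_frame().T        # samples x windows
    scores, flags, details = {}, {}, []
    for held in ids:
        train = [s for s in ids if s != held]
        y_train = labels.loc[train]
        detail = {"held_out": held}
        if y_train.astype(bool).nunique() < 2:
            prev = float(y_train.astype(bool).mean())
            scores[held], flags[held] = prev, "single_class"
            details.append(detail)
            continue
        try:
            cands = select_candidates(wm, labels, train, q_max, min_abs_diff)
        except ParameterError:
            cands = []
        detail["candidates"] = cands
        if not cands:
            # an uninformative 0.5, NOT the training prevalence: with one
            # sample held out the prevalence moves opposite to that sample's
            # label, which biases a pooled ROC toward 0 under the null
            scores[held], flags[held] = 0.5, "no_candidates"
            details.append(detail)
            continue
        feats = lv.loc[train, cands]
        model = fit_lasso(feats, y_train, n_folds=n_folds, seed=seed)
        detail.update(model=model)
        scores[held] = float(
            predict_proba(model, lv.loc[[held], cands]).iloc[0]
        )
        flags[held] = "ok"
        details.append(detail)
    s = pd.Series(scores).loc[ids]
    f = pd.Series(flags).loc[ids]
    return (s, f, details) if return_details else (s, f)


def roc_summary(scores: Sequence[float], labels: Sequence[bool]) -> RocSummary:
    """ROC points, trapezoidal AUC and the Youden-optimal operating point.

    The AUC equals the Mann–Whitney concordant-pair fraction with ties
    counted 0.5.  Thresholds sweep the unique scores (positive call when
    score >= threshold); Youden ties resolve to the higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ParameterError("both classes required for a ROC curve")
    auc = float(roc_auc_score(y, s))
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    rows = []
    best = None
    for thr in np.unique(s)[::-1]:
        call = s >= thr
        tpr = float((call & y).sum()) / n_pos
        fpr = float((call & ~y).sum()) / n_neg
        rows.append((float(thr), fpr, tpr))
        j = tpr - fpr
        spec = 1.0 - fpr
        cand = (j, spec, float(thr), tpr)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    points = pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])
    points = pd.concat([
        pd.DataFrame([(np.inf, 0.0, 0.0)], columns=points.columns), points,
    ], ignore_index=True)
    j, spec, thr, tpr = best
    return RocSummary(points, auc, thr, tpr, spec)


def final_model(
    wm: WindowMatrix,
    labels: pd.Series,
    q_max: float = DEFAULT_Q_MAX,
    min_abs_diff: float = DEFAULT_MIN_ABS_DIFF,
    n_folds: int = 10,
    seed: int | None = None,
    annotation=None,
) -> tuple[PredictiveModel, pd.DataFrame]:
    """Fit once on the full cohort and annotate the selected markers.

    Returns (model, marker table) where the table carries the window
    coordinates, hyper/hypo direction from the full-cohort group difference
    and — when a :class:`methdmr.annotation.GenomeAnnotation` is given — the
    gene context and gene name.  With zero candidates an empty model is
    returned with a warning flag in the table attrs.
    """
    ids = list(labels.index)
    cands = select_candidates(wm, labels, ids, q_max, min_abs_diff)
    empty_cols = ["chrom", "start", "end", "coefficient", "direction",
                  "gene_context", "gene_name"]
    if not cands:
        table = pd.DataFrame(columns=empty_cols)
        table.attrs["warning"] = "no candidate windows at these thresholds"
        model = PredictiveModel([], np.array([]), 0.0, np.array([]),
                                np.array([]), n_candidates=0)
        return model, table
    lv = wm.levels_frame().T
    model = fit_lasso(lv.loc[ids, cands], labels.loc[ids],
                      n_folds=n_folds, seed=seed)
    pos = [s for s in ids if bool(labels[s])]
    neg = [s for s in ids if not bool(labels[s])]
    full = dmr_table(wm, pos, neg)
    full_keys = (full["chrom"].astype(str) + ":" + full["start"].astype(str)
                 + "-" + full["end"].astype(str))
    diff = dict(zip(full_keys, full["meth_diff"]))
    rows = []
    for m, c in zip(model.markers, model.coefficients):
        chrom, span = m.rsplit(":", 1)
        start, end = (int(x) for x in span.split("-"))
        d = diff.get(m, np.nan)
        ctx, name = ("intergenic", pd.NA)
        if annotation is not None:
            ctx, name = annotation.classify(chrom, start, end)
        rows.append((chrom, start, end, float(c),
                     "hyper" if d > 0 else "hypo", ctx, name))
    table = pd.DataFrame(rows, columns=empty_cols)
    return model, table


def score_external(
    model: PredictiveModel,
    features: pd.DataFrame,
    labels: pd.Series | None = None,
    missing_policy: str = "mean_impute",
) -> tuple[pd.Series, RocSummary | None, dict]:
    """Score external samples with possibly missing markers.

    Returns (probabilities, ROC summary against ``labels`` if given, info)
    where info records the policy and which markers were unavailable.
    """
    probs = predict_proba(model, features, missing_policy=missing_policy)
    missing = [m for m in model.markers
               if m not in features.columns or features[m].isna().all()]
    info = {
        "missing_policy": missing_policy,
        "n_markers": len(model.markers),
        "n_available": len(model.markers) - len(missing),
        "missing_markers": missing,
    }
    roc = None
    if labels is not None:
        roc = roc_summary(probs.to_numpy(), labels.loc[probs.index])
    return probs, roc, info
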