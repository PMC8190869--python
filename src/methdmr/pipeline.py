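"""End-to-end workflow: tiling -> DMR -> trend -> promoter -> intersection
-> LOOCV -> final model -> external scoring -> survival.

The prognostic branch (stage II unfavorable vs favorable, stage-trend and
promoter filters) and the predictive branch (LIM-risk LOOCV/LASSO) share the
tiled window matrix but no selection state, so disabling one never changes
the other.  Every default threshold is the protocol value: candidate DMRs at
q <= 0.05 with |diff| >= 10 pp (prognostic) or >= 20 pp (predictive), trend
alpha 0.05, confounder screen at q < 0.1, 1000-bp windows, per-site
coverage >= 2, promoters 1500 bp up / 500 bp down of the TSS.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import io as mio
from . import model as mdl
from . import prognostic as prog
from . import survival as surv
from . import trend as trd
from ._errors import MethdmrError
from .tiling import adjust_fdr, dmr_table, filter_dmrs, tile_windows


@dataclass
class PipelineConfig:
    coverage_dir: str = "."
    sample_sheet: str = "samples.tsv"
    gtf: str | None = None
    outdir: str = "methdmr_out"
    window_size: int = 1000
    min_site_coverage: int = 2
    prognostic_q: float = 0.05
    prognostic_diff: float = 10.0
    predictive_q: float = 0.05
    predictive_diff: float = 20.0
    trend_alpha: float = 0.05
    confounder_q: float = 0.1
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    seed: int = 0

    def __post_init__(self):
        for name in ("prognostic_q", "predictive_q", "trend_alpha",
                     "confounder_q"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise MethdmrError(f"{name} must be in [0, 1], got {v}")
        if self.window_size <= 0:
            raise MethdmrError("window_size must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def summarize_cohort(samples: pd.DataFrame) -> dict:
    """Clinical summary of the primary-tumor cohort (counts and percents).

    Percentages are over the patient cohort; per-stage metastasis rates are
    within-stage, matching the layout of a clinical characteristics table.
    """
    prim = samples[samples["tissue"] == "primary"]
    n = len(prim)

    def pct(k, d=None):
        return round(100.0 * k / (d if d else n), 1)

    ages = prim["age"].dropna()
    out = {
        "n_patients": n,
        "median_age": float(ages.median()),
        "age_range": (float(ages.min()), float(ages.max())),
        "age_lt60": {"n": int((ages < 60).sum()),
                     "pct": pct(int((ages < 60).sum()))},
        "age_ge60": {"n": int((ages >= 60).sum()),
                     "pct": pct(int((ages >= 60).sum()))},
        "male": {"n": int((prim["sex"] == "male").sum()),
                 "pct": pct(int((prim["sex"] == "male").sum()))},
        "female": {"n": int((prim["sex"] == "female").sum()),
                   "pct": pct(int((prim["sex"] == "female").sum()))},
        "smoker": {"n": int((prim["smoker"] == "yes").sum()),
                   "pct": pct(int((prim["smoker"] == "yes").sum()))},
        "non_smoker": {"n": int((prim["smoker"] == "no").sum()),
                       "pct": pct(int((prim["smoker"] == "no").sum()))},
        "smoker_unknown": {"n": int(prim["smoker"].isna().sum()),
                           "pct": pct(int(prim["smoker"].isna().sum()))},
        "no_metastasis": {
            "n": int((~(prim["lim"].fillna(False)
                        | prim["lum"].fillna(False))).sum()),
            "pct": pct(int((~(prim["lim"].fillna(False)
                              | prim["lum"].fillna(False))).sum())),
        },
    }
    out["stage"] = {}
    for st in ("I", "II", "IV"):
        sub = prim[prim["stage"] == st]
        entry = {"n": len(sub), "pct": pct(len(sub))}
        if len(sub):
            entry["lim"] = {"n": int(sub["lim"].fillna(False).sum()),
                            "pct": pct(int(sub["lim"].fillna(False).sum()),
                                       len(sub))}
            entry["lum"] = {"n": int(sub["lum"].fillna(False).sum()),
                            "pct": pct(int(sub["lum"].fillna(False).sum()),
                                       len(sub))}
        out["stage"][st] = entry
    return out


def _load_coverage(config: PipelineConfig, sheet: pd.DataFrame) -> dict:
    cov = {}
    cdir = Path(config.coverage_dir)
    for sid in sheet["sample_id"]:
        path = cdir / f"{sid}.cov"
        if not path.exists() and path.with_suffix(".cov.gz").exists():
            path = path.with_suffix(".cov.gz")
        if not path.exists():
            raise MethdmrError(f"stage io: no coverage file for {sid!r} "
                               f"under {cdir}")
        cov[sid] = mio.read_bismark_coverage(path)
    return cov


def run_all(config: PipelineConfig, write: bool = True) -> dict:
    """Run the whole pipeline; returns the result bundle.

    The bundle carries the prognostic set, LOOCV scores and ROC, the final
    model with its annotated markers, optional external-sample ROC, survival
    curves and the funnel report (every filter-gate count).  With ``write``
    the key outputs land in ``config.outdir``.
    """
    sheet = mio.read_sample_sheet(config.sample_sheet)
    cov = _load_coverage(config, sheet)
    wm = tile_windows(cov, window_size=config.window_size,
                      min_site_coverage=config.min_site_coverage)
    funnel: dict = {"n_windows_tiled": int(wm.n_windows)}

    prim = sheet[sheet["tissue"] == "primary"]
    stage2 = prim[prim["stage"] == "II"]
    test_ids = list(stage2.loc[stage2["prognosis"] == "unfavorable",
                               "sample_id"])
    ctrl_ids = list(stage2.loc[stage2["prognosis"] == "favorable",
                               "sample_id"])

    # --- prognostic branch -------------------------------------------------
    dmr_tbl = dmr_table(wm, test_ids, ctrl_ids)
    dmr_tbl["q"] = adjust_fdr(dmr_tbl["p"].to_numpy())
    funnel["n_windows_tested"] = int((~dmr_tbl["untestable"]).sum())
    candidates = filter_dmrs(dmr_tbl, q_max=config.prognostic_q,
                             min_abs_diff=config.prognostic_diff)
    funnel["n_candidate_dmrs"] = int(len(candidates))

    trend_keys, trend_tbl = trd.trend_filter(
        wm, sheet, alpha=config.trend_alpha, seed=config.seed)
    funnel["n_trend_significant"] = int(len(trend_keys))
    funnel["n_trend_untestable"] = int(trend_tbl["untestable"].sum())

    annot = None
    promoter_keys: set = set()
    if config.gtf is not None:
        genes = mio.read_gtf_genes(config.gtf)
        promoters = ann.extract_promoters(
            genes, upstream=config.promoter_upstream,
            downstream=config.promoter_downstream)
        in_prom = ann.promoter_filter(wm.windows, promoters)
        promoter_keys = set(
            in_prom["chrom"].astype(str) + ":" + in_prom["start"].astype(str)
            + "-" + in_prom["end"].astype(str))
        annot = ann.GenomeAnnotation(promoters, genes)
    funnel["n_promoter_overlap"] = int(len(promoter_keys))

    pset = prog.intersect_filters(candidates, trend_keys, promoter_keys,
                                  window_size=config.window_size)
    funnel["venn"] = pset.counts
    funnel["n_prognostic"] = int(len(pset.markers))
    funnel["n_hyper"] = pset.n_hyper
    funnel["n_hypo"] = pset.n_hypo
    markers_annot = (ann.classify_windows(pset.markers, annot.promoters,
                                          None) if annot is not None
                     and len(pset.markers) else pset.markers)

    confounders = {}
    if len(pset.markers):
        lv = wm.levels_frame()
        keys = [k for k in pset.keys]
        mlv = lv.loc[sorted(keys), list(stage2["sample_id"])]
        for split in ("age_median", "smoking"):
            try:
                _, n_sig = prog.confounder_wilcoxon(
                    mlv, stage2, split, q_max=config.confounder_q)
                confounders[split] = n_sig
            except MethdmrError:
                confounders[split] = None
    funnel["confounder_significant"] = confounders

    # --- predictive branch -------------------------------------------------
    labels = prim.set_index("sample_id")["lim"].astype(bool)
    scores, flags = mdl.loocv_scores(
        wm, labels, q_max=config.predictive_q,
        min_abs_diff=config.predictive_diff, seed=config.seed)
    roc = mdl.roc_summary(scores.to_numpy(), labels.loc[scores.index])
    funnel["loocv_auc"] = float(roc.auc)
    funnel["loocv_flagged_folds"] = int((flags != "ok").sum())

    fmodel, marker_tbl = mdl.final_model(
        wm, labels, q_max=config.predictive_q,
        min_abs_diff=config.predictive_diff, seed=config.seed,
        annotation=annot)
    fmodel.threshold = float(roc.threshold)
    funnel["n_predictive_candidates"] = (
        0 if fmodel.n_candidates is None else int(fmodel.n_candidates))
    funnel["n_predictive_markers"] = len(fmodel.markers)

    external = None
    met = sheet[sheet["tissue"] == "metastatic"]
    if len(met) and len(fmodel.markers):
        lv = wm.levels_frame()
        feats = lv[list(met["sample_id"])].T
        feats.columns = lv.index
        ext_labels = met.set_index("sample_id")["lim"].astype(bool)
        ext_roc = None
        probs, ext_roc, info = mdl.score_external(
            fmodel, feats,
            labels=ext_labels if ext_labels.nunique() == 2 else None)
        external = {"scores": probs, "roc": ext_roc, "info": info}
        funnel["external_n_markers_available"] = info["n_available"]
        if ext_roc is not None:
            funnel["external_auc"] = float(ext_roc.auc)

    # --- survival ----------------------------------------------------------
    predicted_pos = scores >= roc.threshold
    survival = surv.lim_free_survival(sheet, groups=predicted_pos)
    funnel["one_year_lim_free_pct"] = round(
        100.0 * survival["overall"].rate_at(surv.DAYS_PER_YEAR), 1)
    funnel["median_lim_free_days"] = (
        None if np.isinf(survival["overall"].median)
        else float(survival["overall"].median))
    chi, p, degen = survival["logrank"]
    funnel["logrank_p"] = None if degen else float(p)

    bundle = {
        "config": config,
        "cohort_summary": summarize_cohort(sheet),
        "window_matrix": wm,
        "dmr_table": dmr_tbl,
        "prognostic_set": pset,
        "prognostic_markers": markers_annot,
        "trend_table": trend_tbl,
        "loocv_scores": scores,
        "loocv_flags": flags,
        "roc": roc,
        "model": fmodel,
        "model_markers": marker_tbl,
        "external": external,
        "survival": survival,
        "funnel": funnel,
    }
    if write:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_dmr_table(candidates, out / "candidate_dmrs.tsv")
        mio.write_dmr_table(markers_annot, out / "prognostic_markers.tsv")
        fmodel.to_json(out / "model.json")
        marker_tbl.to_csv(out / "predictive_markers.tsv", sep="\t",
                          index=False, na_rep="NA")
        scores.rename("score").to_frame().assign(flag=flags).to_csv(
            out / "loocv_scores.tsv", sep="\t", index_label="sample_id")
        roc.points.to_csv(out / "roc_points.tsv", sep="\t", index=False)
        survival["overall"].to_frame().to_csv(out / "km_overall.tsv",
                                              sep="\t", index=False)
        with open(out / "funnel.json", "w") as fh:
            json.dump(funnel, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return bundle
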