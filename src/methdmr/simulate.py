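"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a targeted-bisulfite study of colorectal tumors:

* a cohort of 59 primary tumors (11 stage I, 38 stage II, 10 stage IV) with
  22 eventual liver metastases (LIM) and 37 LIM-free patients, 11
  tumor-adjacent samples and 11 metastatic samples (6 LIM, 5 LUM), matching
  the published clinical margins (sex, age split, smoking, per-stage
  metastasis counts);
* per-CpG methylated/unmethylated counts: window-level baseline means from a
  low/high mixture (promoter-like ~0.1, gene-body-like ~0.8), per-CpG
  methylation fractions beta-distributed around the window mean
  (overdispersion ``bb_dispersion``, 0 = pure binomial), read depths
  negative-binomial with a floor;
* planted signal windows — group-differential ("dmr"), stage-trend
  ("trend"), both plus guaranteed promoter overlap ("prognostic"), and
  LIM-differential ("predictive", also separating LIM from LUM metastatic
  samples) — recorded in a truth table;
* censored LIM-free survival: exponential event times for LIM patients
  (scale 500 days, giving ~81% one-year LIM-free survival at the cohort's
  22/59 event fraction), uniform 1500–3000 day censoring otherwise.

Everything is reproducible from ``SimulationConfig.seed``: the same config
writes byte-identical files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ParameterError

_STAGE_STEP = {"adjacent": 0, "I": 1, "II": 2, "IV": 3}


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.  All sizes mirror the
    published cohort; methylation-model parameters are in natural units
    (fractions in [0,1], effects in percentage points, coverage in reads)."""

    # cohort layout
    n_adjacent: int = 11
    n_stage_i: int = 11
    n_stage_ii: int = 38
    n_stage_iv: int = 10
    n_met_lim: int = 6
    n_met_lum: int = 5
    # genome / counts
    n_windows: int = 2000
    window_size: int = 1000
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr3")
    cpgs_per_window: float = 10.0          # mean sites per window (min 1)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0       # negative-binomial size parameter
    coverage_floor: int = 1
    baseline_low: float = 0.1
    baseline_high: float = 0.8
    low_fraction: float = 0.3
    bb_dispersion: float = 0.02            # intra-CpG beta overdispersion rho
    # planted signal
    n_planted_prognostic: int = 30
    n_planted_dmr: int = 30
    n_planted_trend: int = 30
    n_planted_predictive: int = 20
    dmr_effect: float = 30.0               # pp, unfavorable vs favorable
    predictive_effect: float = 30.0        # pp, LIM+ vs LIM-
    trend_increment: float = 0.12          # per stage step
    hyper_fraction: float = 0.85
    # survival
    lim_event_scale_days: float = 500.0
    censor_low_days: float = 1500.0
    censor_high_days: float = 3000.0
    seed: int = 0

    def __post_init__(self):
        counts = [self.n_adjacent, self.n_stage_i, self.n_stage_ii,
                  self.n_stage_iv, self.n_windows]
        if any(c <= 0 for c in counts):
            raise ParameterError("all cohort/window counts must be positive")
        planted = (self.n_planted_prognostic + self.n_planted_dmr
                   + self.n_planted_trend + self.n_planted_predictive)
        if planted > self.n_windows:
            raise ParameterError("more planted windows than windows")
        top = max(self.dmr_effect, self.predictive_effect) / 100.0
        if not (0.02 <= self.baseline_low + top <= 0.98
                and 0.02 <= self.baseline_high - top <= 0.98):
            raise ParameterError(
                "planted effects push window means outside [0.02, 0.98]")
        if not (0.02 <= self.baseline_low + 3 * self.trend_increment <= 0.98):
            raise ParameterError("trend increments leave [0.02, 0.98]")


def build_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic cohort sheet matching the published clinical margins."""
    n_pat = config.n_stage_i + config.n_stage_ii + config.n_stage_iv
    stages = (["I"] * config.n_stage_i + ["II"] * config.n_stage_ii
              + ["IV"] * config.n_stage_iv)
    # metastasis layout: stage I 1 LIM + 1 LUM; stage II 11 LIM + 6 LUM;
    # stage IV all LIM, 2 also LUM
    lim = np.zeros(n_pat, dtype=bool)
    lum = np.zeros(n_pat, dtype=bool)
    i0 = 0
    lim[i0] = True
    lum[i0 + 1] = True
    ii0 = config.n_stage_i
    lim[ii0:ii0 + 11] = True
    lum[ii0 + 11:ii0 + 17] = True
    iv0 = ii0 + config.n_stage_ii
    lim[iv0:] = True
    lum[iv0:iv0 + 2] = True
    unfavorable = lim | lum
    # ages: 32 < 60 and 27 >= 60, range 40-78, median 59
    low = list(np.round(np.linspace(40, 58, 29)).astype(int)) + [59, 59, 59]
    high = list(np.round(np.linspace(60, 78, 27)).astype(int))
    ages_sorted = low + high
    rng = np.random.default_rng(config.seed + 101)
    ages = np.array(ages_sorted)[rng.permutation(n_pat)]
    sex = np.array(["male"] * 36 + ["female"] * 23)[rng.permutation(n_pat)]
    smoker = np.array(["yes"] * 16 + ["no"] * 42 + [pd.NA], dtype=object)[
        rng.permutation(n_pat)]
    # survival
    surv_rng = np.random.default_rng(config.seed + 202)
    followup = np.where(
        lim,
        np.round(surv_rng.exponential(config.lim_event_scale_days, n_pat)) + 1,
        np.round(surv_rng.uniform(config.censor_low_days,
                                  config.censor_high_days, n_pat)),
    )
    rows = []
    for i in range(n_pat):
        pid = f"P{i + 1:02d}"
        rows.append(dict(
            sample_id=f"{pid}_T", patient_id=pid, tissue="primary",
            stage=stages[i],
            prognosis="unfavorable" if unfavorable[i] else "favorable",
            lim=bool(lim[i]), lum=bool(lum[i]),
            followup_days=float(followup[i]), lim_event=bool(lim[i]),
            age=int(ages[i]), sex=sex[i], smoker=smoker[i],
        ))
    adj_idx = np.round(np.linspace(0, n_pat - 1, config.n_adjacent)).astype(int)
    for i in adj_idx:
        pid = f"P{i + 1:02d}"
        rows.append(dict(
            sample_id=f"{pid}_N", patient_id=pid, tissue="adjacent",
            stage="adjacent", prognosis=pd.NA, lim=bool(lim[i]),
            lum=bool(lum[i]), followup_days=float(followup[i]),
            lim_event=bool(lim[i]), age=int(ages[i]), sex=sex[i],
            smoker=smoker[i],
        ))
    lim_idx = [i for i in range(n_pat) if lim[i]][-config.n_met_lim:]
    lum_only = [i for i in range(n_pat) if lum[i] and not lim[i]]
    lum_idx = lum_only[:config.n_met_lum]
    for i in lim_idx + lum_idx:
        pid = f"P{i + 1:02d}"
        rows.append(dict(
            sample_id=f"{pid}_M", patient_id=pid, tissue="metastatic",
            stage=stages[i],
            prognosis="unfavorable", lim=bool(lim[i]), lum=bool(lum[i]),
            followup_days=float(followup[i]), lim_event=bool(lim[i]),
            age=int(ages[i]), sex=sex[i], smoker=smoker[i],
        ))
    return pd.DataFrame(rows)


def _window_grid(config: SimulationConfig) -> pd.DataFrame:
    per = int(np.ceil(config.n_windows / len(config.chroms)))
    chroms, starts = [], []
    left = config.n_windows
    for c in config.chroms:
        k = min(per, left)
        chroms += [c] * k
        starts += [j * config.window_size + 1 for j in range(k)]
        left -= k
        if left == 0:
            break
    df = pd.DataFrame({"chrom": chroms, "start": starts})
    df["end"] = df["start"] + config.window_size - 1
    return df


def _plant(config: SimulationConfig, rng: np.random.Generator,
           windows: pd.DataFrame) -> pd.DataFrame:
    kinds = (["prognostic"] * config.n_planted_prognostic
             + ["dmr"] * config.n_planted_dmr
             + ["trend"] * config.n_planted_trend
             + ["predictive"] * config.n_planted_predictive)
    idx = rng.choice(len(windows), size=len(kinds), replace=False)
    hyper = rng.random(len(kinds)) < config.hyper_fraction
    rows = []
    for w, kind, hy in zip(idx, kinds, hyper):
        effect = {"prognostic": config.dmr_effect, "dmr": config.dmr_effect,
                  "trend": 100 * 3 * config.trend_increment,
                  "predictive": config.predictive_effect}[kind]
        rows.append(dict(
            window=int(w), chrom=windows["chrom"].iloc[w],
            start=int(windows["start"].iloc[w]),
            end=int(windows["end"].iloc[w]), kind=kind,
            effect_pp=float(effect),
            direction="hyper" if (hy or kind == "trend") else "hypo",
        ))
    return pd.DataFrame(rows)


def simulate_cohort(
    config: SimulationConfig,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate (sample sheet, per-sample coverage frames, truth table).

    When ``outdir`` is given, also writes ``samples.tsv``, one
    ``<sample_id>.cov`` per sample and ``truth.tsv`` (all plain TSV,
    byte-identical for identical configs).
    """
    rng = np.random.default_rng(config.seed)
    sheet = build_sample_sheet(config)
    windows = _window_grid(config)
    truth = _plant(config, rng, windows)
    w = len(windows)

    # per-window CpG layout (shared across samples, like a fixed panel)
    n_sites = 1 + rng.poisson(max(config.cpgs_per_window - 1, 0.0), size=w)
    site_window = np.repeat(np.arange(w), n_sites)
    offsets = rng.integers(0, config.window_size, size=site_window.size)
    pos = windows["start"].to_numpy()[site_window] + offsets
    order = np.lexsort((pos, site_window))
    site_window, pos = site_window[order], pos[order]
    site_chrom = windows["chrom"].to_numpy()[site_window]

    base = np.where(rng.random(w) < config.low_fraction,
                    config.baseline_low, config.baseline_high)
    # planted windows start from the side that leaves room for the shift
    for t in truth.itertuples(index=False):
        if t.kind == "trend":
            base[t.window] = config.baseline_low
        else:
            base[t.window] = (config.baseline_low if t.direction == "hyper"
                              else config.baseline_high)
    sign = {"hyper": 1.0, "hypo": -1.0}

    coverage_p = (config.coverage_dispersion
                  / (config.coverage_dispersion + config.coverage_mean))
    covs: dict[str, pd.DataFrame] = {}
    for row in sheet.itertuples(index=False):
        mean_w = base.copy()
        step = _STAGE_STEP[row.stage] if row.tissue != "metastatic" else 0
        is_primary = row.tissue == "primary"
        is_met = row.tissue == "metastatic"
        for t in truth.itertuples(index=False):
            if t.kind in ("trend", "prognostic") and row.tissue != "metastatic":
                # the stage trend runs in the window's planted direction
                mean_w[t.window] += (sign[t.direction] * step
                                     * config.trend_increment)
            if t.kind in ("dmr", "prognostic") and is_primary \
                    and row.prognosis == "unfavorable":
                mean_w[t.window] += sign[t.direction] * config.dmr_effect / 100
            if t.kind == "predictive" and (is_primary or is_met) and row.lim:
                mean_w[t.window] += (sign[t.direction]
                                     * config.predictive_effect / 100)
        mean_w = np.clip(mean_w, 0.02, 0.98)
        mu = mean_w[site_window]
        if config.bb_dispersion > 0:
            s = (1.0 - config.bb_dispersion) / config.bb_dispersion
            p_site = rng.beta(mu * s, (1.0 - mu) * s)
        else:
            p_site = mu
        cov = rng.negative_binomial(config.coverage_dispersion,
                                    coverage_p, size=mu.size)
        cov = np.maximum(cov, config.coverage_floor)
        meth = rng.binomial(cov, p_site)
        covs[row.sample_id] = pd.DataFrame({
            "chrom": site_chrom,
            "pos": pos,
            "meth_count": meth,
            "unmeth_count": cov - meth,
        })

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False,
                     na_rep="NA")
        truth.drop(columns="window").to_csv(
            outdir / "truth.tsv", sep="\t", index=False)
        for sid, df in covs.items():
            pct = np.where(
                df["meth_count"] + df["unmeth_count"] > 0,
                100.0 * df["meth_count"]
                / np.maximum(df["meth_count"] + df["unmeth_count"], 1),
                0.0,
            )
            out = pd.DataFrame({
                "chrom": df["chrom"], "start": df["pos"], "end": df["pos"],
                "pct": np.round(pct, 4), "meth": df["meth_count"],
                "unmeth": df["unmeth_count"],
            })
            out.to_csv(outdir / f"{sid}.cov", sep="\t", index=False,
                       header=False, float_format="%.4f")
    return sheet, covs, truth


def simulate_annotation(
    config: SimulationConfig,
    truth: pd.DataFrame | None = None,
    promoter_fraction: float = 0.4,
    path: str | Path | None = None,
) -> str:
    """Toy GTF whose promoters (1500/500 rule) cover ``promoter_fraction``
    of windows plus every planted prognostic window; genes alternate
    strands.  Returns the GTF text (and writes it when ``path`` given)."""
    rng = np.random.default_rng(config.seed + 7)
    windows = _window_grid(config)
    chosen = set(rng.choice(
        len(windows), size=int(round(promoter_fraction * len(windows))),
        replace=False).tolist())
    if truth is not None:
        chosen |= set(truth.loc[truth["kind"] == "prognostic", "window"])
    lines = []
    for gi, w in enumerate(sorted(chosen)):
        chrom = windows["chrom"].iloc[w]
        start = int(windows["start"].iloc[w])
        strand = "+" if gi % 2 == 0 else "-"
        if strand == "+":
            tss = start + 700
            g_start, g_end = tss, tss + 3000
        else:
            tss = start + 300
            g_start, g_end = max(1, tss - 3000), tss
        gid = f"SIMG{gi + 1:05d}"
        attrs = f'gene_id "{gid}"; gene_name "{gid}";'
        for feat in ("gene", "transcript"):
            lines.append("\t".join([
                chrom, "methdmr_sim", feat, str(g_start), str(g_end),
                ".", strand, ".", attrs,
            ]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
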