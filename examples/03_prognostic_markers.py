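"""Select prognostic markers: DMR x stage-trend x promoter intersection.

Three independent filters are intersected: (a) stage II unfavorable-vs-
favorable DMRs, (b) windows with a significant Jonckheere-Terpstra
methylation trend across adjacent -> I -> II -> IV (70 samples), and (c)
windows overlapping a promoter (1500 bp upstream / 500 bp downstream of a
TSS).
"""

from pathlib import Path
import tempfile

from methdmr import (SimulationConfig, adjust_fdr, dmr_table,
                     extract_promoters, filter_dmrs, intersect_filters,
                     promoter_filter, read_gtf_genes, simulate_annotation,
                     simulate_cohort, tile_windows, trend_filter)

config = SimulationConfig(seed=42, n_windows=400)
sheet, coverage, truth = simulate_cohort(config)
wm = tile_windows(coverage)

stage2 = sheet[(sheet.tissue == "primary") & (sheet.stage == "II")]
table = dmr_table(wm,
                  list(stage2[stage2.prognosis == "unfavorable"].sample_id),
                  list(stage2[stage2.prognosis == "favorable"].sample_id))
table["q"] = adjust_fdr(table["p"].to_numpy())
candidates = filter_dmrs(table, q_max=0.05, min_abs_diff=10.0)

trend_keys, _ = trend_filter(wm, sheet, alpha=0.05, seed=0)

with tempfile.TemporaryDirectory() as tmp:
    gtf = Path(tmp) / "annotation.gtf"
    simulate_annotation(config, truth, path=gtf)
    promoters = extract_promoters(read_gtf_genes(gtf))
in_promoter = promoter_filter(wm.windows, promoters)
promoter_keys = set(in_promoter.chrom + ":" + in_promoter.start.astype(str)
                    + "-" + in_promoter.end.astype(str))

pset = intersect_filters(candidates, trend_keys, promoter_keys)
print("filter funnel:", pset.counts)
print(f"final prognostic markers: {len(pset.markers)} "
      f"({pset.n_hyper} hyper, {pset.n_hypo} hypo)")
planted = truth[truth.kind == "prognostic"]
planted_keys = set(planted.chrom + ":" + planted.start.astype(str) + "-"
                   + planted.end.astype(str))
print(f"planted prognostic windows recovered: "
      f"{len(planted_keys & pset.keys)}/{len(planted_keys)}")
# Every count in the funnel mirrors one gate of the marker-selection Venn.
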