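"""Generate a synthetic bisulfite cohort and look at what was planted.

The generator emulates a 59-patient colorectal study (11 stage I, 38 stage
II, 10 stage IV; 22 eventual liver metastases) plus 11 tumor-adjacent and
11 metastatic samples, with group-differential, stage-trend and
LIM-predictive windows planted at known locations.
"""

from methdmr import SimulationConfig, simulate_cohort, summarize_cohort

config = SimulationConfig(seed=42, n_windows=400)
sheet, coverage, truth = simulate_cohort(config)

summary = summarize_cohort(sheet)
print(f"patients: {summary['n_patients']}, "
      f"stage II: {summary['stage']['II']['n']} "
      f"({summary['stage']['II']['pct']}%), "
      f"median age {summary['median_age']:.0f}")
print(f"samples sequenced: {len(sheet)} "
      f"({(sheet.tissue == 'adjacent').sum()} adjacent, "
      f"{(sheet.tissue == 'metastatic').sum()} metastatic)")
print(f"planted windows by kind:\n{truth['kind'].value_counts().to_string()}")
one = next(iter(coverage.values()))
print(f"per-sample CpG sites: {len(one)}  (mean coverage "
      f"{(one.meth_count + one.unmeth_count).mean():.1f} reads)")
# Each planted 'prognostic' window differs between unfavorable and
# favorable stage II tumors, trends across stages, and sits in a promoter.
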