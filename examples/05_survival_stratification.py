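"""Kaplan-Meier LIM-free survival, stratified by predicted risk.

Fits the product-limit curve for the 59 patients, reports the 1-year
liver-metastasis-free rate, and compares predicted-positive vs
predicted-negative patients with a log-rank test.
"""

from methdmr import (SimulationConfig, lim_free_survival, loocv_scores,
                     roc_summary, simulate_cohort, tile_windows)

sheet, coverage, _ = simulate_cohort(SimulationConfig(seed=42,
                                                      n_windows=300))
wm = tile_windows(coverage)
primaries = sheet[sheet.tissue == "primary"]
labels = primaries.set_index("sample_id")["lim"].astype(bool)
scores, _ = loocv_scores(wm, labels, seed=0)
roc = roc_summary(scores.to_numpy(), labels.loc[scores.index])

result = lim_free_survival(sheet, groups=scores >= roc.threshold)
overall = result["overall"]
print(f"patients: {result['n']}, LIM events: {int(overall.events.sum())}")
print(f"1-year LIM-free rate: {100 * overall.rate_at(365):.1f}%")
chi, p, degenerate = result["logrank"]
print(f"log-rank (predicted LIM+ vs LIM-): chi2 = {chi:.2f}, p = {p:.2e}")
print(overall.to_frame().head().to_string(index=False))
# survival is the product-limit estimate just after each event time;
# a small log-rank p means predicted-positive patients metastasize sooner.
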