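# Methods

## Coordinates and formats

All genomic intervals are 1-based inclusive internally (window
`chr11:1861001–1862000` spans bases 1861001..1862000); conversion to
0-based half-open happens only at BED export. Bismark coverage files are
read as (chrom, start, end, %meth, meth, unmeth); the percent column is
always recomputed from the counts. Plus- and minus-strand calls at a CpG
dinucleotide are *not* merged — each input line is an independent site, so
absolute site counts may differ from pipelines that pool strands. The
sample sheet is the single source of truth for group labels; methylome
files are linked by `<sample_id>.cov`.

## Window tiling

Windows are `window_size` (default 1000 bp) tiles on a fixed grid anchored
at coordinate 1. A site contributes to a sample's window sums only when
its own read depth is ≥ `min_site_coverage` (default 2, a per-site
per-sample floor). The window methylation level divides total methylated
calls by total calls — i.e. by read coverage, not by the number of CpG
positions, the only reading that keeps multi-read levels in [0, 1].
Windows with no covered sample are dropped.

## Differential test

Per window, per-sample (methylated, unmethylated) counts are modelled as
binomial with a logit-linear group effect. With one binary covariate the
MLE is saturated at the group level — each group's fitted proportion is
its pooled proportion — so the 1-df likelihood-ratio chi-square reduces to
a closed form in the four group-aggregate counts, which we evaluate
vectorised (`0·log 0 = 0` handled exactly, so complete separation needs no
fallback; an iterative GLM cross-check lives in the tests). The
likelihood-ratio statistic is preferred over Wald for stability at extreme
proportions. `meth_diff` is the difference of *unweighted* per-sample
group means of the window level (test − control, percentage points),
keeping the effect size a per-sample quantity rather than a
coverage-weighted one. FDR control is Benjamini–Hochberg (NaN p-values
pass through).

Assumption worth knowing: the binomial likelihood has no between-sample
dispersion term, so the test is calibrated only for binomial counts. Under
beta-binomial overdispersion (rho > 0) the null is anti-conservative —
p-values are too small — which is why significance gates are always paired
with the ≥ 10/20 pp effect-size gate; at realistic cohort sizes the effect
gate removes essentially all overdispersion-driven false positives. The
null-calibration checks in the tests therefore run at the generator's
binomial limit (rho = 0), and q-values on overdispersed data should be
read as rankings, not literal FDRs.

## Trend test

The Jonckheere–Terpstra statistic sums, over ordered group pairs i < j,
`#(x < y) + 0.5·#(x = y)`. Normal mode standardizes with the
Hollander–Wolfe tie-corrected null variance and a 0.5 continuity
correction; two-sided by default because both hyper- and hypomethylation
trends are meaningful (one-sided available). Permutation mode enumerates
all distinct label assignments exhaustively whenever their number is ≤
`n_perm` (exact tail probability), otherwise samples `n_perm` permutations
with add-one smoothing; `auto` uses permutation for total n ≤ 12. The
large-sample approximation is poor below ~n = 10 (absolute p error up to
≈ 0.13 at the most degenerate group layouts, measured against the exact
distribution); that is precisely why `auto` switches to the exact
permutation null there.

The per-window trend filter groups the 59 primary tumors plus 11
tumor-adjacent samples by stage (adjacent → I → II → IV), drops samples
with no coverage in a window, and excludes (and counts) windows where any
stage group empties; metastatic samples are never used.

## Promoters and gene context

One promoter per gene (per-transcript mode available): strand-aware
`[TSS − 1500, TSS + 500]`, clipped at 1, from GENCODE-dialect GTF. Overlap
means ≥ 1 shared base. Context precedence is promoter > gene body >
intergenic; with several overlapping promoters the gene with the TSS
nearest the window midpoint wins, ties broken by `gene_id`.

## Prognostic selection and confounders

The marker set is the three-way intersection of the candidate
(q ≤ 0.05, |Δ| ≥ 10 pp on the 38 stage II tumors), trend (p ≤ 0.05 on 70
samples) and promoter (sample-free) filters — three deliberately distinct
sample bases. Hyper/hypo tallies come from the sign of `meth_diff`.
Confounder screens split the stage II patients by median age (< 60 vs
≥ 60) or smoking (unknown excluded) and run two-sided Wilcoxon rank-sum
per marker (exact null when both groups < 10 and tie-free, tie-corrected
normal otherwise), BH-adjusted, counting markers with q < 0.1.

## Predictive model

Candidates: LIM⁺ vs LIM⁻ differential windows at q ≤ 0.05, |Δ| ≥ 20 pp,
selected on training samples only. Features are window levels; NaN levels
are imputed with the training column mean, then standardized to zero
mean/unit variance (train statistics). The L1 logistic path is fit with
liblinear over 15 penalties (`C` from 10^−2.5 to 10^2.5), the penalty
minimizing stratified 10-fold cross-validated log-loss is kept
("lambda.min" convention), and the penalized coefficients are reported
without an unpenalized refit. The intercept is effectively unpenalized
(intercept scaling 100); when the penalty removes every coefficient the
intercept is set to the exact null-model value, logit of the training
prevalence. The seed controls only the inner fold shuffle and solver
ordering; LOOCV folds are deterministic.

LOOCV repeats candidate selection, imputation, standardization and penalty
choice inside every fold. Folds whose training set loses a class score the
held-out sample at the training prevalence (flagged); folds with zero
candidates emit an uninformative 0.5 — pooling per-fold training
prevalences would encode the complement of each held-out label and drive
the pooled null AUC to 0, a documented pessimism of pooled leave-one-out
scoring. The pooled ROC's AUC equals the Mann–Whitney concordant-pair
fraction (ties 0.5); the reported sensitivity/specificity sit at the
Youden-J-maximizing threshold, ties resolved toward higher specificity.

External samples are scored under `mean_impute` (missing standardized
terms contribute 0) or `drop_renorm` (missing coefficients dropped, the
linear predictor recentered by their training-mean contribution). In
standardized coordinates the recentering term is 0, so the two policies
coincide for fully-missing markers; both are kept and the policy is
recorded because they diverge for any non-centered parameterization.

## Survival

Kaplan–Meier product-limit estimation and the two-group log-rank test are
delegated to lifelines. Times are days; 1 year = 365 days. Patients
without a liver-metastasis event are right-censored at last follow-up.
Risk strata for the survival comparison split patients by pooled LOOCV
score at the model threshold.

## Synthetic cohorts

The generator reproduces the study's clinical margins exactly: 59 primary
tumors (stage I/II/IV = 11/38/10; LIM per stage 1/11/10; LUM 1/6/2 with
two double-positives; stage II prognosis 17 unfavorable / 21 favorable),
36 male/23 female, ages 40–78 with 32 under 60 and median 59, 16/42/1
smoking status, 11 adjacent samples, and 6 LIM + 5 LUM metastatic samples.
Methylation: window baselines from a low/high mixture (0.1/0.8, 30% low),
per-CpG beta noise around the window mean with overdispersion rho
(default 0.02; 0 = pure binomial), negative-binomial coverage (mean 30,
size 5, floor 1). Planted windows: "dmr" (± 30 pp in unfavorable
primaries), "trend" (+0.12 per stage step), "prognostic" (both, plus
guaranteed promoter overlap in the generated GTF), "predictive" (± 30 pp
in LIM⁺ primaries and LIM metastatic samples). Direction is 85% hyper,
echoing the predominance of hypermethylated markers in tumor genic
regions. Survival: LIM event times exponential with a 500-day scale
(giving a ~81% one-year LIM-free rate at 22/59 eventual events);
censoring uniform on 1500–3000 days. Everything is reproducible from the
config seed, byte-identical on disk.

What the generator does *not* emulate: genomic CpG clustering and
sequence context, coverage correlation along reads, batch effects,
strand structure, or tumor purity variation — so a passing suite
demonstrates the statistical machinery, not performance on real tumors.
Default problem sizes (2000 windows × ~10 CpGs × 81 samples; tests and
the acceptance script use 150–2000 windows) keep a full run in minutes on
one CPU while leaving every group size at the study's values.

## Numerical choices and edge cases

BH q-values are computed over non-NaN entries only. Degenerate trend
inputs (all pooled values equal) return p = 1 with a flag. ROC thresholds
sweep observed scores. A window uncovered in an entire group is
"untestable" (p = NaN, excluded from funnels' tested counts). JSON
outputs are dumped with sorted keys so reruns are byte-comparable; all
stochastic components draw from explicit seeds.

## Known limitations

* No beta-binomial dispersion modelling in the differential test (see
  above); methods that model dispersion will be more conservative on
  overdispersed data.
* One promoter per gene by default; isoform-resolved TSS choice changes
  promoter sets for genes with distant alternative starts.
* The LIM model reports penalized coefficients; effect sizes are shrunk
  and should not be read as log-odds ratios.
* With 59 patients a leave-one-out estimate has high variance; the pooled
  AUC is an honest but noisy summary, which is why the permutation-null
  behavior is part of the test suite.
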