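"""Final prognostic-marker selection and confounder checks.

The prognostic marker set is the three-way intersection of
(a) windows differentially methylated between unfavorable- and
favorable-prognosis stage II tumors (q <= 0.05, |diff| >= 10 pp),
(b) windows with a significant Jonckheere stage trend across
adjacent -> I -> II -> IV (p <= 0.05), and
(c) windows overlapping a gene promoter.  Each input set has its own sample
basis: (a) uses the stage II tumors only, (b) all primary tumors plus the
tumor-adjacent samples, and (c) is sample-free.

Confounder screening asks whether marker methylation separates patients by
age (median split) or smoking history rather than prognosis: a two-sided
Wilcoxon rank-sum per marker, BH-adjusted across markers, counting markers
with q below the threshold (0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from ._errors import ParameterError, ValidationError
from .tiling import adjust_fdr, parse_window_key


@dataclass
class PrognosticSet:
    """Three-way intersection of the candidate / trend / promoter filters."""

    markers: pd.DataFrame          # DMR rows (with context if annotated)
    counts: dict = field(default_factory=dict)
    n_hyper: int = 0
    n_hypo: int = 0

    @property
    def keys(self) -> set[str]:
        return set(
            self.markers["chrom"].astype(str) + ":"
            + self.markers["start"].astype(str) + "-"
            + self.markers["end"].astype(str)
        )


def _validate_grid(keys: set[str], window_size: int) -> None:
    for k in keys:
        _, start, end = parse_window_key(k)
        if (start - 1) % window_size or end - start + 1 != window_size:
            raise ValidationError(
                f"window {k} is not on the {window_size}-bp grid"
            )


def intersect_filters(
    candidate_dmrs: pd.DataFrame,
    trend_keys: set[str],
    promoter_keys: set[str],
    window_size: int = 1000,
) -> PrognosticSet:
    """Intersect the three prognostic filters into the final marker set.

    ``candidate_dmrs`` is a filtered DMR table (rows carry meth_diff for
    direction tallies); the other two filters are window-key sets.  Raises
    if any set strays off the common window grid.
    """
    ckeys = (candidate_dmrs["chrom"].astype(str) + ":"
             + candidate_dmrs["start"].astype(str) + "-"
             + candidate_dmrs["end"].astype(str))
    _validate_grid(set(ckeys), window_size)
    _validate_grid(trend_keys, window_size)
    _validate_grid(promoter_keys, window_size)
    in_all = ckeys.isin(trend_keys) & ckeys.isin(promoter_keys)
    markers = candidate_dmrs.loc[in_all.to_numpy()].reset_index(drop=True)
    n_hyper = int((markers["meth_diff"] > 0).sum())
    n_hypo = int((markers["meth_diff"] < 0).sum())
    counts = {
        "candidate": int(len(candidate_dmrs)),
        "trend": int(len(trend_keys)),
        "promoter": int(len(promoter_keys)),
        "candidate_and_trend": int((ckeys.isin(trend_keys)).sum()),
        "candidate_and_promoter": int((ckeys.isin(promoter_keys)).sum()),
        "trend_and_promoter": int(len(trend_keys & promoter_keys)),
        "intersection": int(len(markers)),
    }
    return PrognosticSet(markers, counts, n_hyper, n_hypo)


def confounder_wilcoxon(
    marker_levels: pd.DataFrame,
    samples: pd.DataFrame,
    split: str,
    q_max: float = 0.1,
    age_cut: float = 60.0,
) -> tuple[pd.DataFrame, int]:
    """Wilcoxon rank-sum screen of markers against a clinical split.

    Parameters
    ----------
    marker_levels
        Markers x samples methylation-level frame (window keys as index).
    samples
        Sample sheet rows for the cohort to split (e.g. the stage II tumors).
    split
        ``"age_median"`` (< age_cut vs >= age_cut) or ``"smoking"``
        (smoker vs non-smoker; unknown status excluded).

    Returns the per-marker (p, q) table and the number of markers with
    q < ``q_max``.  Uses the exact null when both groups have < 10 samples
    and no ties, the tie-corrected normal approximation otherwise.
    """
    sub = samples.set_index("sample_id")
    sub = sub.loc[[s for s in marker_levels.columns if s in sub.index]]
    if split == "age_median":
        valid = sub["age"].notna()
        grp_a = sub.index[valid & (sub["age"] < age_cut)]
        grp_b = sub.index[valid & (sub["age"] >= age_cut)]
    elif split == "smoking":
        grp_a = sub.index[sub["smoker"] == "yes"]
        grp_b = sub.index[sub["smoker"] == "no"]
    else:
        raise ParameterError(f"unknown split {split!r}")
    if len(grp_a) == 0 or len(grp_b) == 0:
        raise ParameterError(f"split {split!r} yields an empty group")
    ps = []
    for _, row in marker_levels.iterrows():
        a = row[grp_a].to_numpy(dtype=float)
        b = row[grp_b].to_numpy(dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) == 0 or len(b) == 0 or (
            np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0])
        ):
            ps.append(1.0)
            continue
        pooled = np.concatenate([a, b])
        exact = (len(a) < 10 and len(b) < 10
                 and len(np.unique(pooled)) == len(pooled))
        method = "exact" if exact else "asymptotic"
        ps.append(float(mannwhitneyu(a, b, alternative="two-sided",
                                     method=method).pvalue))
    table = pd.DataFrame({"p": ps}, index=marker_levels.index)
    table["q"] = adjust_fdr(table["p"].to_numpy())
    return table, int((table["q"] < q_max).sum())
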