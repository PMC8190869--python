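"""Fixed-grid tiling of CpG counts and window-level differential methylation.

The covered genome is tiled into non-overlapping windows of ``window_size``
bp on a grid anchored at coordinate 1, so window k on a chromosome spans
``[k*window_size + 1, (k+1)*window_size]`` (1-based inclusive).  A CpG site
contributes to a sample's window sums only when its own read coverage meets
``min_site_coverage``.  The methylation level of a window in a sample is the
total methylated calls divided by the total calls over its contributing
sites.

Differential methylation between two sample groups is tested per window with
a binomial logistic regression of per-sample (methylated, unmethylated)
counts on the group indicator.  With a single binary covariate the maximum
likelihood fit is saturated at the group level — each group's fitted
proportion is its pooled count proportion — so the 1-df likelihood-ratio
chi-square has a closed form in the group aggregate counts and is evaluated
vectorised over all windows.  The reported effect size ``meth_diff`` is the
difference of unweighted per-group means of sample-level window methylation,
in percentage points (test minus control; positive = hypermethylated in the
test group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2

from ._errors import ParameterError, ValidationError

DEFAULT_WINDOW_SIZE = 1000
DEFAULT_MIN_SITE_COVERAGE = 2


def window_key(chrom: str, start: int, end: int) -> str:
    """Canonical window name, e.g. ``chr11:1861001-1862000``."""
    return f"{chrom}:{start}-{end}"


def parse_window_key(key: str) -> tuple[str, int, int]:
    chrom, span = key.rsplit(":", 1)
    start, end = span.split("-")
    return chrom, int(start), int(end)


@dataclass
class WindowMatrix:
    """Aggregated per-window, per-sample methylation counts.

    ``meth``, ``cov`` and ``n_sites`` are (windows x samples) integer arrays;
    ``windows`` is a DataFrame with columns chrom/start/end aligned to the
    rows.  ``levels`` is meth/cov with NaN where a sample has no coverage in
    a window.
    """

    windows: pd.DataFrame
    samples: list[str]
    meth: np.ndarray
    cov: np.ndarray
    n_sites: np.ndarray
    window_size: int = DEFAULT_WINDOW_SIZE
    _sample_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def levels(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            lv = self.meth / self.cov
        return np.where(self.cov > 0, lv, np.nan)

    def keys(self) -> pd.Series:
        w = self.windows
        return (w["chrom"].astype(str) + ":" + w["start"].astype(str)
                + "-" + w["end"].astype(str))

    def sample_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self._sample_index]
        if missing:
            raise ParameterError(f"unknown sample ids: {missing}")
        return np.array([self._sample_index[s] for s in sample_ids], dtype=int)

    def levels_frame(self) -> pd.DataFrame:
        """Window-by-sample methylation levels, indexed by window key."""
        return pd.DataFrame(self.levels, index=self.keys().to_numpy(),
                            columns=self.samples)

    def subset_windows(self, mask: np.ndarray) -> "WindowMatrix":
        return WindowMatrix(
            self.windows.loc[mask].reset_index(drop=True), list(self.samples),
            self.meth[mask], self.cov[mask], self.n_sites[mask],
            self.window_size,
        )


def tile_windows(
    sites: dict[str, pd.DataFrame],
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_site_coverage: int = DEFAULT_MIN_SITE_COVERAGE,
    min_sites_per_window: int = 1,
) -> WindowMatrix:
    """Aggregate per-sample CpG counts onto the fixed window grid.

    Parameters
    ----------
    sites
        Mapping sample_id -> coverage frame (columns chrom, pos, meth_count,
        unmeth_count) as returned by :func:`methdmr.io.read_bismark_coverage`.
    window_size
        Tile width in bp (default 1000).
    min_site_coverage
        Per-site read-depth floor; shallower sites are ignored (default 2).
    min_sites_per_window
        A sample's window aggregate is kept only if at least this many sites
        contributed; shallower aggregates are zeroed (treated as uncovered).

    Only windows where at least one sample has coverage are emitted, sorted
    by (chrom, start).
    """
    if window_size <= 0:
        raise ParameterError("window_size must be positive")
    if min_site_coverage < 0:
        raise ParameterError("min_site_coverage must be >= 0")
    samples = list(sites)
    pieces = []
    for sid in samples:
        df = sites[sid]
        if len(df) == 0:
            continue
        covr = df["meth_count"].to_numpy() + df["unmeth_count"].to_numpy()
        keep = covr >= min_site_coverage
        if not keep.any():
            continue
        sub = df.loc[keep]
        start = ((sub["pos"].to_numpy() - 1) // window_size) * window_size + 1
        pieces.append(pd.DataFrame({
            "chrom": sub["chrom"].to_numpy(),
            "start": start,
            "meth": sub["meth_count"].to_numpy(),
            "cov": covr[keep],
            "sample": sid,
        }))
    if not pieces:
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        z = np.zeros((0, len(samples)), dtype=np.int64)
        return WindowMatrix(empty, samples, z, z.copy(), z.copy(), window_size)
    allp = pd.concat(pieces, ignore_index=True)
    agg = allp.groupby(["chrom", "start", "sample"], sort=False).agg(
        meth=("meth", "sum"), cov=("cov", "sum"), n=("cov", "size"),
    ).reset_index()
    if min_sites_per_window > 1:
        thin = agg["n"] < min_sites_per_window
        agg.loc[thin, ["meth", "cov", "n"]] = 0
    wins = (agg[["chrom", "start"]].drop_duplicates()
            .sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True))
    widx = {(c, s): i for i, (c, s) in enumerate(
        zip(wins["chrom"], wins["start"]))}
    sidx = {s: j for j, s in enumerate(samples)}
    shape = (len(wins), len(samples))
    meth = np.zeros(shape, dtype=np.int64)
    cov = np.zeros(shape, dtype=np.int64)
    nsite = np.zeros(shape, dtype=np.int64)
    rows = np.fromiter(
        (widx[k] for k in zip(agg["chrom"], agg["start"])),
        dtype=int, count=len(agg),
    )
    cols = agg["sample"].map(sidx).to_numpy()
    meth[rows, cols] = agg["meth"].to_numpy()
    cov[rows, cols] = agg["cov"].to_numpy()
    nsite[rows, cols] = agg["n"].to_numpy()
    covered = cov.sum(axis=1) > 0
    wins["end"] = wins["start"] + window_size - 1
    wins = wins[["chrom", "start", "end"]]
    wm = WindowMatrix(wins, samples, meth, cov, nsite, window_size)
    return wm.subset_windows(covered)


def _group_loglik(m: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, m / np.maximum(n, 1), 0.0)
    return xlogy(m, p) + xlogy(n - m, 1.0 - p)


def dmr_table(
    wm: WindowMatrix,
    test_ids: Sequence[str],
    control_ids: Sequence[str],
) -> pd.DataFrame:
    """Test every window for differential methylation (test vs control).

    Returns a DataFrame with columns ``chrom, start, end, meth_diff, p, q,
    direction`` (q filled with NaN here; use :func:`adjust_fdr`).  Windows
    where either group is entirely uncovered get p = NaN and an ``untestable``
    flag.
    """
    t = wm.sample_columns(test_ids)
    c = wm.sample_columns(control_ids)
    if len(t) == 0 or len(c) == 0:
        raise ParameterError("both groups need at least one sample")
    if set(test_ids) & set(control_ids):
        raise ParameterError("test and control groups overlap")
    mt = wm.meth[:, t].sum(axis=1).astype(float)
    nt = wm.cov[:, t].sum(axis=1).astype(float)
    mc = wm.meth[:, c].sum(axis=1).astype(float)
    nc = wm.cov[:, c].sum(axis=1).astype(float)
    lrt = 2.0 * (
        _group_loglik(mt, nt) + _group_loglik(mc, nc)
        - _group_loglik(mt + mc, nt + nc)
    )
    lrt = np.maximum(lrt, 0.0)
    p = chi2.sf(lrt, df=1)
    untestable = (nt == 0) | (nc == 0)
    p = np.where(untestable, np.nan, p)

    lv = wm.levels
    import warnings
    with warnings.catch_warnings():
        # an all-NaN group is flagged untestable below; silence the slice
        warnings.simplefilter("ignore", RuntimeWarning)
        diff = 100.0 * (np.nanmean(lv[:, t], axis=1)
                        - np.nanmean(lv[:, c], axis=1))
    diff = np.where(untestable, np.nan, diff)
    out = wm.windows.copy()
    out["meth_diff"] = diff
    out["p"] = p
    out["q"] = np.nan
    out["direction"] = np.where(diff > 0, "hyper", "hypo")
    out.loc[np.isnan(diff), "direction"] = pd.NA
    out["untestable"] = untestable
    return out


def dmr_test(
    meth_by_sample: dict[str, tuple[int, int]],
    test_ids: Sequence[str],
    control_ids: Sequence[str],
) -> dict:
    """Single-window convenience wrapper around :func:`dmr_table`.

    ``meth_by_sample`` maps sample_id -> (meth_sum, cov_sum) for one window.
    Returns a dict with meth_diff (percentage points), p and direction.
    """
    samples = list(meth_by_sample)
    meth = np.array([[meth_by_sample[s][0]] for s in samples]).T
    cov = np.array([[meth_by_sample[s][1]] for s in samples]).T
    wins = pd.DataFrame({"chrom": ["w"], "start": [1], "end": [1000]})
    wm = WindowMatrix(wins, samples, meth, cov, np.ones_like(meth))
    row = dmr_table(wm, test_ids, control_ids).iloc[0]
    return {
        "meth_diff": float(row["meth_diff"]),
        "p": float(row["p"]) if pd.notna(row["p"]) else np.nan,
        "direction": row["direction"],
        "untestable": bool(row["untestable"]),
    }


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN entries pass through as NaN."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if finite.sum():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def filter_dmrs(
    results: pd.DataFrame,
    q_max: float = 0.05,
    min_abs_diff: float = 10.0,
) -> pd.DataFrame:
    """Keep windows with q <= q_max and \\|meth_diff\\| >= min_abs_diff (pp)."""
    keep = ((results["q"] <= q_max)
            & (results["meth_diff"].abs() >= min_abs_diff))
    return results.loc[keep.fillna(False)]
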