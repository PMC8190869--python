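"""Jonckheere–Terpstra test for a monotone trend across ordered groups.

The statistic is the sum of pairwise Mann–Whitney counts over all ordered
group pairs (i < j): #{x in g_i, y in g_j : x < y} + 0.5 * #{x = y}.  Under
the null it has mean (N^2 - sum n_i^2)/4; the normal mode standardizes with
the tie-corrected Hollander–Wolfe null variance and applies a 0.5 continuity
correction, reporting a two-sided p.  The permutation mode permutes pooled
values across group labels (sizes preserved): when the number of distinct
assignments does not exceed ``n_perm`` it enumerates them exhaustively and
returns the exact two-sided tail probability, otherwise it samples with
add-one smoothing.  ``auto`` uses permutation for total n <= 12.

The test is two-sided by default because both increasing (hypermethylated)
and decreasing (hypomethylated) stage trends are biologically meaningful;
a one-sided alternative is available via ``alternative``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._errors import ParameterError

STAGE_ORDER = ("adjacent", "I", "II", "IV")


@dataclass
class TrendResult:
    jt_stat: float
    z: float
    p: float
    n_per_group: tuple[int, ...]
    degenerate: bool = False
    mode_used: str = "normal"


def _jt_statistic(pooled: np.ndarray, gidx: np.ndarray) -> float:
    """J = sum over cross-group pairs (lower group index first) of
    1[x<y] + 0.5*1[x==y]."""
    lt = pooled[:, None] < pooled[None, :]
    eq = pooled[:, None] == pooled[None, :]
    pair = gidx[:, None] < gidx[None, :]
    return float(np.sum(lt & pair) + 0.5 * np.sum(eq & pair))


def _null_moments(n_i: np.ndarray, pooled: np.ndarray) -> tuple[float, float]:
    n = float(n_i.sum())
    mean = (n * n - float((n_i.astype(float) ** 2).sum())) / 4.0
    _, t = np.unique(pooled, return_counts=True)
    t = t.astype(float)
    ni = n_i.astype(float)
    term1 = (n * (n - 1) * (2 * n + 5)
             - np.sum(ni * (ni - 1) * (2 * ni + 5))
             - np.sum(t * (t - 1) * (2 * t + 5))) / 72.0
    if n > 2:
        term2 = (np.sum(ni * (ni - 1) * (ni - 2))
                 * np.sum(t * (t - 1) * (t - 2))
                 / (36.0 * n * (n - 1) * (n - 2)))
    else:
        term2 = 0.0
    term3 = (np.sum(ni * (ni - 1)) * np.sum(t * (t - 1))
             / (8.0 * n * (n - 1)))
    return mean, term1 + term2 + term3


def _n_assignments(n_i: np.ndarray) -> float:
    total = int(n_i.sum())
    count = 1.0
    rem = total
    for n in n_i:
        count *= math.comb(rem, int(n))
        rem -= int(n)
    return count


def _enumerate_assignments(pooled: np.ndarray, n_i: np.ndarray):
    """Yield the group-index vector of every distinct assignment of pooled
    positions to groups of the given sizes."""
    n = len(pooled)

    def rec(avail: tuple, sizes: list[int], gidx: np.ndarray, g: int):
        if not sizes:
            yield gidx.copy()
            return
        for combo in itertools.combinations(avail, sizes[0]):
            gidx[list(combo)] = g
            rest = tuple(a for a in avail if a not in combo)
            yield from rec(rest, sizes[1:], gidx, g + 1)

    yield from rec(tuple(range(n)), [int(x) for x in n_i],
                   np.empty(n, dtype=int), 0)


def jonckheere_test(
    groups: list,
    mode: str = "auto",
    n_perm: int = 10000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> TrendResult:
    """Jonckheere–Terpstra test of a monotone trend across ordered groups.

    Parameters
    ----------
    groups
        Ordered list (>= 2) of non-empty numeric collections, in the
        hypothesized trend order.
    mode
        "normal" (tie-corrected large-sample approximation), "permutation",
        or "auto" (permutation when total n <= 12).
    n_perm, seed
        Permutation-count budget and RNG seed for the Monte-Carlo branch.
    alternative
        "two-sided" (default), "increasing" or "decreasing".
    """
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrs):
        raise ParameterError("all groups must be non-empty")
    if mode not in ("auto", "normal", "permutation"):
        raise ParameterError(f"unknown mode {mode!r}")
    n_i = np.array([len(a) for a in arrs])
    pooled = np.concatenate(arrs)
    gidx = np.repeat(np.arange(len(arrs)), n_i)
    total = int(n_i.sum())
    jt = _jt_statistic(pooled, gidx)
    mean, var = _null_moments(n_i, pooled)
    if var <= 0:  # all pooled values identical
        return TrendResult(jt, 0.0, 1.0, tuple(int(x) for x in n_i),
                           degenerate=True, mode_used=mode)
    use = mode if mode != "auto" else ("permutation" if total <= 12 else "normal")

    if use == "normal":
        sd = math.sqrt(var)
        dev = jt - mean
        zc = max(abs(dev) - 0.5, 0.0) / sd
        if alternative == "two-sided":
            p = min(1.0, 2.0 * norm.sf(zc))
        elif alternative == "increasing":
            p = norm.sf(math.copysign(zc, dev)) if dev != 0 else norm.sf(0.0)
        else:
            p = norm.cdf(math.copysign(zc, dev)) if dev != 0 else norm.cdf(0.0)
        return TrendResult(jt, dev / sd, p, tuple(int(x) for x in n_i),
                           mode_used="normal")

    # permutation branch
    obs_dev = jt - mean
    if _n_assignments(n_i) <= n_perm:
        stats = np.array([
            _jt_statistic(pooled, g)
            for g in _enumerate_assignments(pooled, n_i)
        ])
        if alternative == "two-sided":
            p = float(np.mean(np.abs(stats - mean) >= abs(obs_dev) - 1e-12))
        elif alternative == "increasing":
            p = float(np.mean(stats >= jt - 1e-12))
        else:
            p = float(np.mean(stats <= jt + 1e-12))
        used = "permutation-exhaustive"
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            s = _jt_statistic(perm, gidx)
            if alternative == "two-sided":
                count += abs(s - mean) >= abs(obs_dev) - 1e-12
            elif alternative == "increasing":
                count += s >= jt - 1e-12
            else:
                count += s <= jt + 1e-12
        p = (1 + count) / (n_perm + 1)
        used = "permutation"
    return TrendResult(jt, obs_dev / math.sqrt(var), float(p),
                       tuple(int(x) for x in n_i), mode_used=used)


def trend_table(
    wm,
    samples: pd.DataFrame,
    order: tuple[str, ...] = STAGE_ORDER,
    mode: str = "normal",
    n_perm: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-window Jonckheere trend test of methylation level across stages.

    Samples are grouped by the ``stage`` column in the given order;
    metastatic-tissue samples are never included.  A sample with no coverage
    in a window (NaN level) is dropped for that window; windows left with an
    empty group are flagged ``untestable`` (p = NaN).
    """
    use = samples[samples["tissue"] != "metastatic"]
    use = use[use["stage"].isin(order)]
    ids = [s for s in use["sample_id"] if s in set(wm.samples)]
    sub = use.set_index("sample_id").loc[ids]
    cols = wm.sample_columns(ids)
    stage_idx = np.array([order.index(s) for s in sub["stage"]])
    lv = wm.levels[:, cols]
    out = wm.windows.copy()
    jt_s, z_s, p_s, unt = [], [], [], []
    for i in range(wm.n_windows):
        row = lv[i]
        ok = ~np.isnan(row)
        gi = stage_idx[ok]
        if len(np.unique(gi)) < len(order) or not ok.any():
            jt_s.append(np.nan), z_s.append(np.nan), p_s.append(np.nan)
            unt.append(True)
            continue
        # compact group indices preserve the order
        res = jonckheere_test(
            [row[ok][gi == g] for g in range(len(order))],
            mode=mode, n_perm=n_perm, seed=seed,
        )
        jt_s.append(res.jt_stat), z_s.append(res.z), p_s.append(res.p)
        unt.append(False)
    out["jt_stat"] = jt_s
    out["z"] = z_s
    out["p"] = p_s
    out["untestable"] = unt
    return out


def trend_filter(
    wm,
    samples: pd.DataFrame,
    order: tuple[str, ...] = STAGE_ORDER,
    alpha: float = 0.05,
    mode: str = "normal",
    seed: int | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Windows whose stage trend is significant at ``alpha``.

    Returns (set of window keys, full per-window trend table).  Untestable
    windows (an empty stage group after NA dropping) are excluded from the
    selected set.
    """
    table = trend_table(wm, samples, order=order, mode=mode, seed=seed)
    keys = (table["chrom"].astype(str) + ":" + table["start"].astype(str)
            + "-" + table["end"].astype(str))
    sel = (table["p"] <= alpha) & ~table["untestable"]
    return set(keys[sel.fillna(False)]), table
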