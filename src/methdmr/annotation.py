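"""Promoter derivation and gene-context classification of windows.

A promoter is the strand-relative interval from 1500 bp upstream to 500 bp
downstream of a gene's transcription start site (TSS): for a + strand gene
the TSS is the gene start and the promoter is [TSS-1500, TSS+500]; for a -
strand gene the TSS is the gene end and the promoter is [TSS-500, TSS+1500].
Coordinates are clipped at 1.  Overlap means >= 1 shared base between
1-based inclusive intervals.  Context precedence is
promoter > gene body > intergenic; among several overlapping promoters the
gene whose TSS is nearest the window midpoint wins (ties broken by gene_id).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._errors import ValidationError

DEFAULT_UPSTREAM = 1500
DEFAULT_DOWNSTREAM = 500

PROMOTER_COLUMNS = ["gene_id", "gene_name", "chrom", "start", "end",
                    "strand", "tss"]


def extract_promoters(
    genes: pd.DataFrame,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    feature: str = "gene",
) -> pd.DataFrame:
    """Derive one promoter interval per annotation record.

    ``genes`` is the frame from :func:`methdmr.io.read_gtf_genes`; only rows
    of the requested ``feature`` ("gene" by default, "transcript" for
    per-transcript promoters) are used.
    """
    if "feature" in genes.columns:
        sub = genes[genes["feature"] == feature]
    else:
        sub = genes
    if sub["strand"].isna().any() or (~sub["strand"].isin(["+", "-"])).any():
        raise ValidationError("every record needs strand + or -")
    plus = sub["strand"].to_numpy() == "+"
    tss = np.where(plus, sub["start"].to_numpy(), sub["end"].to_numpy())
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    out = pd.DataFrame({
        "gene_id": sub["gene_id"].to_numpy(),
        "gene_name": sub["gene_name"].to_numpy(),
        "chrom": sub["chrom"].to_numpy(),
        "start": np.maximum(start, 1),
        "end": np.maximum(end, 1),
        "strand": sub["strand"].to_numpy(),
        "tss": tss,
    })
    return out.reset_index(drop=True)


def _trees(frame: pd.DataFrame, payload_cols: list[str]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in frame.groupby("chrom", sort=False):
        t = IntervalTree()
        for row in grp.itertuples(index=False):
            # 1-based inclusive [start, end] -> half-open [start, end+1)
            t.addi(row.start, row.end + 1,
                   tuple(getattr(row, c) for c in payload_cols))
        trees[chrom] = t
    return trees


class GenomeAnnotation:
    """Indexed promoter and gene-span intervals for fast window queries."""

    def __init__(self, promoters: pd.DataFrame, genes: pd.DataFrame | None):
        self.promoters = promoters
        self._ptrees = _trees(promoters, ["gene_id", "gene_name", "tss"])
        if genes is not None and len(genes):
            body = genes[genes["feature"] == "gene"] \
                if "feature" in genes.columns else genes
            self._gtrees = _trees(body, ["gene_id", "gene_name"])
        else:
            self._gtrees = {}

    def classify(self, chrom: str, start: int, end: int) -> tuple[str, object]:
        """Gene context of one window: (context, gene_name-or-NA)."""
        mid = (start + end) / 2.0
        ptree = self._ptrees.get(chrom)
        if ptree is not None:
            hits = ptree.overlap(start, end + 1)
            if hits:
                best = min(
                    hits,
                    key=lambda iv: (abs(iv.data[2] - mid), iv.data[0]),
                )
                return "promoter", best.data[1]
        gtree = self._gtrees.get(chrom)
        if gtree is not None:
            hits = gtree.overlap(start, end + 1)
            if hits:
                best = min(
                    hits,
                    key=lambda iv: (abs((iv.begin + iv.end - 1) / 2.0 - mid),
                                    iv.data[0]),
                )
                return "gene_body", best.data[1]
        return "intergenic", pd.NA


def classify_window(
    window: tuple[str, int, int],
    promoters: pd.DataFrame,
    genes: pd.DataFrame | None = None,
) -> tuple[str, object]:
    """Classify one window; see :class:`GenomeAnnotation` for the rules."""
    ann = GenomeAnnotation(promoters, genes)
    return ann.classify(*window)


def classify_windows(
    windows: pd.DataFrame,
    promoters: pd.DataFrame,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Vector version: adds ``gene_context`` and ``gene_name`` columns."""
    ann = GenomeAnnotation(promoters, genes)
    ctx, names = [], []
    for row in windows.itertuples(index=False):
        c, n = ann.classify(row.chrom, int(row.start), int(row.end))
        ctx.append(c)
        names.append(n)
    out = windows.copy()
    out["gene_context"] = ctx
    out["gene_name"] = names
    return out


def promoter_filter(dmrs: pd.DataFrame, promoters: pd.DataFrame) -> pd.DataFrame:
    """Keep DMR windows overlapping >= 1 promoter by >= 1 base."""
    if len(promoters) == 0 or len(dmrs) == 0:
        return dmrs.iloc[0:0]
    trees = _trees(promoters, ["gene_id"])
    keep = []
    for row in dmrs.itertuples(index=False):
        t = trees.get(row.chrom)
        keep.append(bool(t is not None and t.overlaps(row.start, row.end + 1)))
    return dmrs.loc[np.asarray(keep)]


def promoters_to_bed(promoters: pd.DataFrame, path) -> None:
    """Export promoters as BED (0-based half-open) for external cross-checks."""
    bed = pd.DataFrame({
        "chrom": promoters["chrom"],
        "start": promoters["start"] - 1,
        "end": promoters["end"],
        "name": promoters["gene_id"],
        "score": 0,
        "strand": promoters["strand"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)
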