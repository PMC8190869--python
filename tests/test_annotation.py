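import numpy as np
import pandas as pd
import pytest

from methdmr import (ValidationError, classify_window, classify_windows,
                     extract_promoters, promoter_filter)


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "chrom",
                                       "start", "end", "strand", "feature"])


class TestExtractPromoters:
    def test_plus_strand_definition(self):
        g = _genes([["g1", "A", "chr1", 10000, 20000, "+", "gene"]])
        p = extract_promoters(g).iloc[0]
        assert (p["start"], p["end"], p["tss"]) == (8500, 10500, 10000)

    def test_minus_strand_mirror(self):
        g = _genes([["g1", "A", "chr1", 5000, 10000, "-", "gene"]])
        p = extract_promoters(g).iloc[0]
        assert (p["start"], p["end"], p["tss"]) == (9500, 11500, 10000)

    def test_clipped_at_chromosome_origin(self):
        g = _genes([["g1", "A", "chr1", 100, 2000, "+", "gene"]])
        p = extract_promoters(g).iloc[0]
        assert (p["start"], p["end"]) == (1, 600)

    def test_length_is_2001_unclipped_and_strand_flip_reflects(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(10_000, 1_000_000, size=50)
        g = _genes([[f"g{i}", f"G{i}", "chr1", int(s), int(s) + 5000, "+",
                     "gene"] for i, s in enumerate(starts)])
        p = extract_promoters(g)
        assert ((p["end"] - p["start"] + 1) == 2001).all()
        flipped = g.copy()
        flipped["strand"] = "-"
        # reflect the gene span so the - strand TSS sits where + strand's was
        flipped["end"] = g["start"]
        flipped["start"] = g["start"] - 5000
        pf = extract_promoters(flipped)
        # promoters mirror about the shared TSS: [t-u, t+d] -> [t-d, t+u]
        assert pf["start"].tolist() == (2 * p["tss"] - p["end"]).tolist()
        assert pf["end"].tolist() == (2 * p["tss"] - p["start"]).tolist()

    def test_missing_strand_rejected(self):
        g = _genes([["g1", "A", "chr1", 100, 2000, ".", "gene"]])
        with pytest.raises(ValidationError):
            extract_promoters(g)


class TestClassifyWindow:
    PROMOTERS = pd.DataFrame({
        "gene_id": ["g1", "g2"], "gene_name": ["TNNI2", "OTHER"],
        "chrom": ["chr11", "chr11"], "start": [1860500, 1862950],
        "end": [1862500, 1864950], "strand": ["+", "+"],
        "tss": [1862000, 1864450],
    })
    GENES = _genes([["g3", "BODY", "chr11", 1_900_000, 1_950_000, "+",
                     "gene"]])

    def test_promoter_hit_with_nearest_tss(self):
        ctx, name = classify_window(("chr11", 1861001, 1862000),
                                    self.PROMOTERS, self.GENES)
        assert (ctx, name) == ("promoter", "TNNI2")

    def test_gene_body_when_no_promoter(self):
        ctx, name = classify_window(("chr11", 1_900_001, 1_901_000),
                                    self.PROMOTERS, self.GENES)
        assert (ctx, name) == ("gene_body", "BODY")

    def test_intergenic_on_unannotated_chromosome(self):
        ctx, name = classify_window(("chrX", 1, 1000), self.PROMOTERS,
                                    self.GENES)
        assert ctx == "intergenic" and pd.isna(name)

    def test_single_base_touch_counts_as_overlap(self):
        prom = self.PROMOTERS.iloc[[0]]
        ctx, _ = classify_window(("chr11", 1862500, 1863499), prom, None)
        assert ctx == "promoter"
        ctx2, _ = classify_window(("chr11", 1862501, 1863500), prom, None)
        assert ctx2 == "intergenic"


class TestPromoterFilter:
    def _windows(self, spans, chrom="chr1"):
        return pd.DataFrame({"chrom": chrom, "start": [s for s, _ in spans],
                             "end": [e for _, e in spans]})

    def test_exact_subset_retained(self):
        proms = pd.DataFrame({
            "gene_id": ["g1"], "gene_name": ["A"], "chrom": ["chr1"],
            "start": [5000], "end": [7000], "strand": ["+"], "tss": [6500],
        })
        wins = self._windows([(1, 1000), (4001, 5000), (6001, 7000),
                              (7001, 8000), (9001, 10000)])
        kept = promoter_filter(wins, proms)
        assert kept["start"].tolist() == [4001, 6001]   # 1-bp touch included

    def test_empty_promoter_set(self):
        assert len(promoter_filter(self._windows([(1, 1000)]),
                                   pd.DataFrame(columns=["gene_id",
                                                         "gene_name", "chrom",
                                                         "start", "end",
                                                         "strand",
                                                         "tss"]))) == 0


def test_classification_agrees_with_brute_force_scan():
    """intervaltree lookups equal an all-pairs overlap scan (both strands)."""
    rng = np.random.default_rng(3)
    n_win, n_gene = 1500, 200
    chroms = np.array(["chr1", "chr2"])[rng.integers(0, 2, n_win)]
    starts = rng.integers(0, 3000, n_win) * 1000 + 1
    wins = pd.DataFrame({"chrom": chroms, "start": starts,
                         "end": starts + 999})
    g_chrom = np.array(["chr1", "chr2"])[rng.integers(0, 2, n_gene)]
    g_start = rng.integers(1, 3_000_000, n_gene)
    strands = np.array(["+", "-"])[rng.integers(0, 2, n_gene)]
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n_gene)],
        "gene_name": [f"G{i}" for i in range(n_gene)],
        "chrom": g_chrom, "start": g_start, "end": g_start + 20_000,
        "strand": strands, "feature": "gene",
    })
    proms = extract_promoters(genes)
    out = classify_windows(wins, proms, genes)
    kept = promoter_filter(wins, proms)
    kept_idx = set(zip(kept["chrom"], kept["start"]))
    for row, got in zip(wins.itertuples(index=False),
                        out["gene_context"]):
        same = proms[proms["chrom"] == row.chrom]
        hit_prom = ((same["start"] <= row.end)
                    & (same["end"] >= row.start)).any()
        gsame = genes[genes["chrom"] == row.chrom]
        hit_gene = ((gsame["start"] <= row.end)
                    & (gsame["end"] >= row.start)).any()
        expect = ("promoter" if hit_prom
                  else "gene_body" if hit_gene else "intergenic")
        assert got == expect
        assert ((row.chrom, row.start) in kept_idx) == hit_prom
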