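"""Readers and writers for the file formats the pipeline touches.

Formats handled here:

* Bismark coverage files — 6-column TSV (chrom, start, end, %methylation,
  methylated count, unmethylated count), one cytosine per line.
* Sample sheets — TSV with one row per sequenced sample carrying tissue,
  stage, prognosis, metastasis and survival metadata.
* GTF gene annotations (GENCODE dialect), reduced to gene/transcript records.
* DMR tables — the TSV the caller emits, 1-based inclusive coordinates.

All genomic intervals are 1-based inclusive throughout the package; the only
0-based half-open conversion happens at BED export boundaries.  Plain and
gzip-compressed paths are accepted everywhere.
"""

from __future__ import annotations

import gzip
import shutil
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ParseError, ValidationError

TISSUES = frozenset({"primary", "adjacent", "metastatic"})
STAGES = frozenset({"adjacent", "I", "II", "IV"})
PROGNOSES = frozenset({"favorable", "unfavorable"})
SEXES = frozenset({"male", "female"})
SMOKER = frozenset({"yes", "no"})

#: canonical column order of a parsed coverage frame
CPG_COLUMNS = ["chrom", "pos", "meth_count", "unmeth_count"]

#: canonical column order of a DMR table
DMR_COLUMNS = [
    "chrom", "start", "end", "meth_diff", "p", "q",
    "direction", "gene_context", "gene_name",
]

_OPTIONAL_SHEET_COLUMNS = [
    "prognosis", "lim", "lum", "followup_days", "lim_event",
    "age", "sex", "smoker",
]


def read_bismark_coverage(path: str | Path) -> pd.DataFrame:
    """Read a Bismark ``.cov`` file into a per-CpG count frame.

    Returns a DataFrame with columns ``chrom, pos, meth_count, unmeth_count``
    in file order.  ``pos`` is the 1-based start coordinate; the percent
    column is ignored (methylation is always recomputed from the counts).

    Raises
    ------
    ParseError
        If a line does not have exactly 6 tab-separated fields.
    ValidationError
        If a count is negative or end is neither start nor start+1.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment=None, dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.ParserError as exc:  # ragged rows
        raise ParseError(f"{path}: malformed coverage line: {exc}") from exc
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CPG_COLUMNS)
    if df.shape[1] != 6:
        raise ParseError(
            f"{path}: expected 6 tab-separated columns, found {df.shape[1]} "
            "(line 1)"
        )
    df.columns = ["chrom", "start", "end", "percent", "meth", "unmeth"]
    try:
        start = df["start"].astype(np.int64)
        end = df["end"].astype(np.int64)
        meth = df["meth"].astype(np.int64)
        unmeth = df["unmeth"].astype(np.int64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric field: {exc}") from exc
    bad = ~((end == start) | (end == start + 1))
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 1
        raise ValidationError(
            f"{path}: line {line}: end must equal start or start+1"
        )
    neg = (meth < 0) | (unmeth < 0)
    if neg.any():
        line = int(np.flatnonzero(neg)[0]) + 1
        raise ValidationError(f"{path}: line {line}: negative count")
    return pd.DataFrame({
        "chrom": df["chrom"].to_numpy(),
        "pos": start.to_numpy(),
        "meth_count": meth.to_numpy(),
        "unmeth_count": unmeth.to_numpy(),
    })


def _parse_bool(series: pd.Series, column: str) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    out = []
    for i, v in enumerate(series):
        if pd.isna(v) or str(v).strip().upper() in {"", "NA", "NAN"}:
            out.append(pd.NA)
            continue
        key = str(v).strip().lower()
        if key not in mapping:
            raise ValidationError(
                f"column {column!r}, row {i}: cannot parse boolean {v!r}"
            )
        out.append(mapping[key])
    return pd.Series(out, dtype="boolean", index=series.index)


def _check_enum(series: pd.Series, allowed: frozenset, column: str,
                required: bool) -> pd.Series:
    vals = series.astype("string").str.strip()
    vals = vals.where(~vals.str.upper().isin(["NA", "NAN", ""]), pd.NA)
    for i, v in vals.items():
        if pd.isna(v):
            if required:
                raise ValidationError(f"column {column!r}, row {i}: missing value")
            continue
        if v not in allowed:
            raise ValidationError(
                f"column {column!r}, row {i}: unknown token {v!r} "
                f"(allowed: {sorted(allowed)})"
            )
    return vals


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort sample sheet (TSV with header).

    Required columns: ``sample_id, patient_id, tissue, stage``.  Optional
    columns (missing ones are added as NA): ``prognosis, lim, lum,
    followup_days, lim_event, age, sex, smoker``.

    Enforced invariants: unique sample_id; tissue/stage tokens from their
    controlled vocabularies; ``tissue == adjacent`` iff ``stage == adjacent``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ["sample_id", "patient_id", "tissue", "stage"]:
        if col not in df.columns:
            raise ValidationError(f"sample sheet missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r}")
    df["tissue"] = _check_enum(df["tissue"], TISSUES, "tissue", required=True)
    df["stage"] = _check_enum(df["stage"], STAGES, "stage", required=True)
    mismatch = (df["tissue"] == "adjacent") != (df["stage"] == "adjacent")
    if mismatch.any():
        row = int(np.flatnonzero(mismatch.to_numpy())[0])
        raise ValidationError(
            f"row {row} ({df['sample_id'].iloc[row]!r}): tissue=adjacent and "
            "stage=adjacent must co-occur"
        )
    for col in _OPTIONAL_SHEET_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df["prognosis"] = _check_enum(df["prognosis"], PROGNOSES, "prognosis", False)
    df["sex"] = _check_enum(df["sex"], SEXES, "sex", False)
    df["smoker"] = _check_enum(df["smoker"], SMOKER, "smoker", False)
    df["lim"] = _parse_bool(df["lim"], "lim")
    df["lum"] = _parse_bool(df["lum"], "lum")
    df["lim_event"] = _parse_bool(df["lim_event"], "lim_event")
    for col in ("followup_days", "age"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if (df["followup_days"].dropna() < 0).any():
        raise ValidationError("negative followup_days")
    return df[["sample_id", "patient_id", "tissue", "stage"]
              + _OPTIONAL_SHEET_COLUMNS]


def _maybe_gunzip(path: str | Path) -> tuple[Path, bool]:
    path = Path(path)
    if path.suffix == ".gz":
        tmp = Path(tempfile.mkstemp(suffix=".gtf")[1])
        with gzip.open(path, "rb") as src, open(tmp, "wb") as dst:
            shutil.copyfileobj(src, dst)
        return tmp, True
    return path, False


def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """Read gene and transcript records from a GTF (GENCODE dialect).

    Returns a DataFrame with columns ``gene_id, gene_name, chrom, start, end,
    strand, feature`` — coordinates 1-based inclusive, exactly as in the GTF.
    Features other than gene/transcript are skipped.
    """
    import gffutils

    real, is_tmp = _maybe_gunzip(path)
    try:
        db = gffutils.create_db(
            str(real), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        rows = []
        for feature in db.all_features():
            if feature.featuretype not in ("gene", "transcript"):
                continue
            if "gene_id" not in feature.attributes:
                raise ParseError(
                    f"{path}: {feature.featuretype} at {feature.seqid}:"
                    f"{feature.start} lacks gene_id attribute"
                )
            if feature.strand not in ("+", "-"):
                raise ValidationError(
                    f"{path}: {feature.seqid}:{feature.start}: missing strand"
                )
            name = feature.attributes.get("gene_name", [pd.NA])[0]
            rows.append((
                feature.attributes["gene_id"][0], name, feature.seqid,
                int(feature.start), int(feature.end), feature.strand,
                feature.featuretype,
            ))
    finally:
        if is_tmp:
            real.unlink(missing_ok=True)
    return pd.DataFrame(
        rows,
        columns=["gene_id", "gene_name", "chrom", "start", "end",
                 "strand", "feature"],
    )


def write_dmr_table(dmrs: pd.DataFrame, path: str | Path) -> None:
    """Write a DMR table as TSV (1-based inclusive coordinates, NA for NaN).

    Missing annotation columns (``gene_context``, ``gene_name``) are written
    as NA so the schema is stable across pipeline stages.
    """
    out = dmrs.copy()
    for col in DMR_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out[DMR_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dmr_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV produced by :func:`write_dmr_table`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in DMR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: DMR table missing columns {missing}")
    return df[DMR_COLUMNS]
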