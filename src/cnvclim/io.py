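"""Readers and writers for the flat-file formats the pipeline touches.

Coordinates are 1-based inclusive in every TSV (PennCNV convention); BED
output is converted to 0-based half-open, GFF3 stays 1-based inclusive.
"""

from __future__ import annotations

import pandas as pd

from .cnv import CN_LABELS, validate_calls

CALL_FILE_COLUMNS = ["chrom", "start", "end", "state", "cn", "sample", "numsnp"]


def write_calls_tsv(calls: pd.DataFrame, path) -> int:
    """Write calls as a PennCNV-style TSV; returns the row count."""
    validate_calls(calls)
    out = pd.DataFrame({
        "chrom": calls["chrom"],
        "start": calls["start"],
        "end": calls["end"],
        "state": calls["cn"].map(CN_LABELS),
        "cn": calls["cn"],
        "sample": calls["sample"],
        "numsnp": calls["num_snps"],
    })
    out.to_csv(path, sep="\t", index=False)
    return len(out)


def read_calls_tsv(path) -> pd.DataFrame:
    """Read a PennCNV-style call TSV into the internal call schema."""
    raw = pd.read_csv(path, sep="\t")
    missing = [c for c in CALL_FILE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"call file {path} missing columns {missing}")
    calls = pd.DataFrame({
        "sample": raw["sample"],
        "chrom": raw["chrom"].astype(str),
        "start": raw["start"].astype(int),
        "end": raw["end"].astype(int),
        "cn": raw["cn"].astype(int),
        "num_snps": raw["numsnp"].astype(int),
    })
    return validate_calls(calls)


def write_table(df: pd.DataFrame, path, index: bool = False) -> int:
    df.to_csv(path, sep="\t", index=index)
    return len(df)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_bed(intervals: pd.DataFrame, path, name_col: str | None = "name",
              extra_cols: tuple = ()) -> int:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    cols = {
        "chrom": intervals["chrom"],
        "start": intervals["start"].astype(int) - 1,
        "end": intervals["end"].astype(int),
    }
    out = pd.DataFrame(cols)
    if name_col is not None and name_col in intervals.columns:
        out["name"] = intervals[name_col]
    for col in extra_cols:
        out[col] = intervals[col]
    out.to_csv(path, sep="\t", index=False, header=False)
    return len(out)


def write_gff3(intervals: pd.DataFrame, path, feature: str = "gene",
               source: str = "cnvclim", name_col: str = "name") -> int:
    """Write 1-based inclusive intervals as a minimal GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in intervals.itertuples(index=False):
            name = getattr(row, name_col)
            fh.write(f"{row.chrom}\t{source}\t{feature}\t{row.start}\t{row.end}"
                     f"\t.\t+\t.\tID={name};Name={name}\n")
    return len(intervals)
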