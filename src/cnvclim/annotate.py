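"""Gene and QTL interval annotation of candidate CNV regions.

Intervals are 1-based inclusive internally.  A gene is reported for a
region when the overlap covers at least 10% of the region length; QTLs
are first restricted to confidence intervals below 5 Mb and reported at
50% coverage of the region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = ["read_gff3", "read_bed", "gene_overlap", "qtl_overlap"]


def read_gff3(path, feature: str | None = "gene") -> pd.DataFrame:
    """Read a GFF3 file into a 1-based inclusive interval frame."""
    df = pr.read_gff3(str(path)).df
    if feature is not None and "Feature" in df.columns:
        df = df[df["Feature"] == feature]
    name = df["Name"] if "Name" in df.columns else df.get("ID", df["Chromosome"].astype(str))
    return pd.DataFrame({
        "chrom": df["Chromosome"].astype(str),
        "start": df["Start"].astype(int) + 1,   # pyranges stores 0-based half-open
        "end": df["End"].astype(int),
        "name": name.to_numpy(),
    }).reset_index(drop=True)


def read_bed(path, score_as: str | None = None) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into 1-based inclusive intervals.

    ``score_as`` renames the BED score column (used for QTL confidence
    interval widths stored in column 5).
    """
    df = pr.read_bed(str(path)).df
    out = pd.DataFrame({
        "chrom": df["Chromosome"].astype(str),
        "start": df["Start"].astype(int) + 1,
        "end": df["End"].astype(int),
    })
    if "Name" in df.columns:
        out["name"] = df["Name"].to_numpy()
    if score_as is not None and "Score" in df.columns:
        out[score_as] = df["Score"].to_numpy()
    return out


def _overlap_pairs(regions: pd.DataFrame, features: pd.DataFrame,
                   feature_prefix: str) -> pd.DataFrame:
    """All (region, feature) pairs with >= 1 bp overlap, via an interval join."""
    ra = pr.PyRanges(pd.DataFrame({
        "Chromosome": regions["chrom"].astype(str),
        "Start": regions["start"].astype(int) - 1,
        "End": regions["end"].astype(int),
        "region_idx": np.arange(len(regions)),
    }))
    fa = pr.PyRanges(pd.DataFrame({
        "Chromosome": features["chrom"].astype(str),
        "Start": features["start"].astype(int) - 1,
        "End": features["end"].astype(int),
        "feature_idx": np.arange(len(features)),
    }))
    joined = ra.join(fa).df
    if not len(joined):
        return pd.DataFrame(columns=["chrom", "start", "end", "overlap_bp",
                                     f"{feature_prefix}_name",
                                     f"{feature_prefix}_start",
                                     f"{feature_prefix}_end",
                                     "region_idx", "feature_idx"])
    ri = joined["region_idx"].to_numpy()
    fi = joined["feature_idx"].to_numpy()
    r_start = regions["start"].to_numpy()[ri]
    r_end = regions["end"].to_numpy()[ri]
    f_start = features["start"].to_numpy()[fi]
    f_end = features["end"].to_numpy()[fi]
    overlap = np.minimum(r_end, f_end) - np.maximum(r_start, f_start) + 1
    name = (features["name"].to_numpy()[fi] if "name" in features.columns
            else fi.astype(str))
    return pd.DataFrame({
        "chrom": regions["chrom"].to_numpy()[ri],
        "start": r_start, "end": r_end,
        "overlap_bp": overlap,
        f"{feature_prefix}_name": name,
        f"{feature_prefix}_start": f_start,
        f"{feature_prefix}_end": f_end,
        "region_idx": ri, "feature_idx": fi,
    })


def gene_overlap(regions: pd.DataFrame, genes: pd.DataFrame,
                 min_frac: float = 0.10, frac_of: str = "region") -> pd.DataFrame:
    """(region, gene) pairs whose overlap covers >= ``min_frac`` of the region.

    ``frac_of="gene"`` measures the fraction against the gene length
    instead.
    """
    pairs = _overlap_pairs(regions, genes, "gene")
    if not len(pairs):
        return pairs
    if frac_of == "region":
        ref = pairs["end"] - pairs["start"] + 1
    elif frac_of == "gene":
        ref = pairs["gene_end"] - pairs["gene_start"] + 1
    else:
        raise ValueError("frac_of must be 'region' or 'gene'")
    pairs["frac"] = pairs["overlap_bp"] / ref
    out = pairs[pairs["frac"] >= min_frac].reset_index(drop=True)
    return out.sort_values(["chrom", "start", "gene_name"]).reset_index(drop=True)


def qtl_overlap(regions: pd.DataFrame, qtls: pd.DataFrame,
                max_ci_bp: float = 5e6, min_frac: float = 0.50,
                reciprocal: bool = False) -> pd.DataFrame:
    """(region, QTL) pairs under the confidence-interval and coverage rules.

    QTLs with a confidence interval of ``max_ci_bp`` or wider are
    excluded first (strict <); a pair is kept when the overlap covers at
    least ``min_frac`` of the region (and, with ``reciprocal``, also of
    the QTL).
    """
    if "ci_width_bp" not in qtls.columns:
        raise ValueError("QTL table must carry a 'ci_width_bp' column")
    narrow = qtls[qtls["ci_width_bp"] < max_ci_bp].reset_index(drop=True)
    pairs = _overlap_pairs(regions, narrow, "qtl")
    if not len(pairs):
        pairs["frac"] = pd.Series(dtype=float)
        return pairs
    region_len = pairs["end"] - pairs["start"] + 1
    pairs["frac"] = pairs["overlap_bp"] / region_len
    keep = pairs["frac"] >= min_frac
    if reciprocal:
        qtl_len = pairs["qtl_end"] - pairs["qtl_start"] + 1
        keep &= (pairs["overlap_bp"] / qtl_len) >= min_frac
    return (pairs[keep].sort_values(["chrom", "start", "qtl_name"])
            .reset_index(drop=True))
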