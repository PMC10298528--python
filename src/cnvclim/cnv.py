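"""CNV call quality control, CNVR construction and call-set summaries.

Calls are rows of a pandas DataFrame with columns ``sample``, ``chrom``,
``start``, ``end`` (1-based inclusive), ``cn`` (copy-number class in
{0, 1, 3, 4}) and ``num_snps``.  Copy numbers 0/1 are the deletion classes
(homozygous / hemizygous), 3/4 the duplication classes (duplication /
biallelic triplication).

Overlapping or book-ended calls are merged into copy number variable
regions (CNVRs) with bedtools-merge semantics: on the 1-based inclusive
scale two calls merge when ``next.start <= current.end + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "CALL_COLUMNS",
    "DELETION_CLASSES",
    "DUPLICATION_CLASSES",
    "CN_LABELS",
    "QcThresholds",
    "CnvSummary",
    "validate_calls",
    "call_lengths",
    "filter_samples",
    "filter_calls",
    "merge_to_cnvrs",
    "dedupe_unique",
    "summarize",
    "concordance",
]

CALL_COLUMNS = ("sample", "chrom", "start", "end", "cn", "num_snps")
DELETION_CLASSES = frozenset({0, 1})
DUPLICATION_CLASSES = frozenset({3, 4})
CN_LABELS = {
    0: "homozygous_deletion",
    1: "hemizygous_deletion",
    3: "duplication",
    4: "triplication",
}

QC_METRICS = ("lrr_sd", "baf_drift", "waviness", "call_count")


@dataclass(frozen=True)
class QcThresholds:
    """Per-sample array-quality gates.

    A sample passes when LRR standard deviation, BAF drift and waviness
    factor are each strictly below their threshold and its call count
    does not exceed ``max_call_count`` (only counts above the limit
    indicate poor DNA quality).
    """

    max_lrr_sd: float = 0.3
    max_baf_drift: float = 0.01
    max_waviness: float = 0.05
    max_call_count: int = 100


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Check call-table schema and invariants; returns the frame unchanged."""
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    if len(calls):
        if (calls["start"] > calls["end"]).any():
            raise ValueError("call with start > end")
        if (calls["num_snps"] < 1).any():
            raise ValueError("call with num_snps < 1")
        bad = set(calls["cn"].unique()) - set(CN_LABELS)
        if bad:
            raise ValueError(f"unknown copy-number classes: {sorted(bad)}")
    return calls


def call_lengths(calls: pd.DataFrame) -> pd.Series:
    """Call length in bp on the 1-based inclusive scale (end - start + 1)."""
    return calls["end"] - calls["start"] + 1


def filter_samples(qc: pd.DataFrame,
                   thresholds: QcThresholds = QcThresholds()) -> tuple[list, pd.DataFrame]:
    """Split samples into passing ids and a table of failures with reasons.

    ``qc`` needs columns ``sample``, ``lrr_sd``, ``baf_drift``,
    ``waviness`` and ``call_count``.  Comparisons on the noise metrics are
    strict (<); the call-count gate removes only samples with more than
    ``max_call_count`` calls.
    """
    for col in ("sample",) + QC_METRICS:
        if col not in qc.columns:
            raise ValueError(f"QC table missing column {col!r}")
        if col != "sample" and qc[col].isna().any():
            bad = qc.loc[qc[col].isna(), "sample"].iloc[0]
            raise ValueError(f"missing QC metric {col!r} for sample {bad!r}")

    t = thresholds
    reasons = {
        "lrr_sd": qc["lrr_sd"] >= t.max_lrr_sd,
        "baf_drift": qc["baf_drift"] >= t.max_baf_drift,
        "waviness": qc["waviness"] >= t.max_waviness,
        "call_count": qc["call_count"] > t.max_call_count,
    }
    fail_mask = np.logical_or.reduce(list(reasons.values()))
    fails = qc.loc[fail_mask, ["sample"]].copy()
    fails["reasons"] = [
        ",".join(name for name, mask in reasons.items() if mask.iloc[i])
        for i in np.flatnonzero(fail_mask)
    ]
    passed = qc.loc[~fail_mask, "sample"].tolist()
    return passed, fails.reset_index(drop=True)


def filter_calls(calls: pd.DataFrame,
                 min_snps_exclusive: int = 3,
                 min_len_bp: int = 1000) -> pd.DataFrame:
    """Keep calls with more than ``min_snps_exclusive`` SNPs and length >= ``min_len_bp``."""
    validate_calls(calls)
    if not len(calls):
        return calls.copy()
    keep = (calls["num_snps"] > min_snps_exclusive) & (call_lengths(calls) >= min_len_bp)
    return calls.loc[keep].reset_index(drop=True)


def _region_class(cns) -> str:
    has_del = any(c in DELETION_CLASSES for c in cns)
    has_dup = any(c in DUPLICATION_CLASSES for c in cns)
    if has_del and has_dup:
        return "mixed"
    return "loss" if has_del else "gain"


def merge_to_cnvrs(calls: pd.DataFrame, n_samples: int | None = None) -> pd.DataFrame:
    """Merge calls into CNVRs by interval union (book-ended calls merge).

    Returns one row per region with ``chrom``, ``start``, ``end``,
    ``cnvr_class`` (loss / gain / mixed from the supporting calls),
    ``n_calls``, ``n_samples`` (distinct carriers) and, when the cohort
    size ``n_samples`` is given, ``carrier_frequency``.
    """
    validate_calls(calls)
    regions = []
    for chrom, grp in calls.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        start = end = None
        cns: list[int] = []
        carriers: set = set()
        n_calls = 0
        for row in grp.itertuples(index=False):
            if start is None:
                start, end = row.start, row.end
            elif row.start <= end + 1:
                end = max(end, row.end)
            else:
                regions.append((chrom, start, end, _region_class(cns), n_calls, len(carriers)))
                start, end, cns, carriers, n_calls = row.start, row.end, [], set(), 0
            cns.append(row.cn)
            carriers.add(row.sample)
            n_calls += 1
        if start is not None:
            regions.append((chrom, start, end, _region_class(cns), n_calls, len(carriers)))
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "cnvr_class",
                                         "n_calls", "n_samples"])
    if n_samples is not None:
        out["carrier_frequency"] = out["n_samples"] / n_samples
    return out


def dedupe_unique(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse calls sharing identical coordinates into unique CNVs.

    A unique CNV is a distinct (chrom, start, end) triple; its class is
    deletion / duplication when all observed copy numbers fall on one
    side, mixed otherwise.
    """
    validate_calls(calls)
    if not len(calls):
        return pd.DataFrame(columns=["chrom", "start", "end", "unique_class", "n_calls"])

    def classify(cns) -> str:
        cls = _region_class(set(cns))
        return {"loss": "deletion", "gain": "duplication"}.get(cls, cls)

    grouped = calls.groupby(["chrom", "start", "end"], sort=True)["cn"]
    out = grouped.agg([("unique_class", classify), ("n_calls", "size")]).reset_index()
    return out


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CnvSummary:
    """Per-class call counts/lengths/frequencies plus CNVR and unique-CNV tallies."""

    call_counts: dict = field(default_factory=dict)      # class label -> count
    call_lengths_mb: dict = field(default_factory=dict)  # class label -> Mb
    call_frequencies: dict = field(default_factory=dict)  # class label -> % of calls
    total_calls: int = 0
    total_length_mb: float = 0.0
    cnvr_counts: dict = field(default_factory=dict)      # loss/gain/mixed -> count
    total_cnvrs: int = 0
    unique_counts: dict = field(default_factory=dict)    # deletion/duplication/mixed
    total_unique: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"class": label, "count": self.call_counts.get(label, 0),
             "length_mb": self.call_lengths_mb.get(label, 0.0),
             "frequency_pct": self.call_frequencies.get(label, 0.0)}
            for label in CN_LABELS.values()
        ]
        return pd.DataFrame(rows)


def summarize(calls: pd.DataFrame,
              cnvrs: pd.DataFrame | None = None,
              uniques: pd.DataFrame | None = None) -> CnvSummary:
    """Tabulate calls by copy-number class with lengths (Mb) and percentages.

    Percentages are count/total*100 rounded half-up to 2 decimals; an
    empty call set yields an all-zero summary.
    """
    validate_calls(calls)
    s = CnvSummary()
    s.total_calls = int(len(calls))
    lengths = call_lengths(calls) if len(calls) else pd.Series(dtype=float)
    for cn, label in CN_LABELS.items():
        mask = calls["cn"] == cn if len(calls) else pd.Series(dtype=bool)
        cnt = int(mask.sum())
        s.call_counts[label] = cnt
        s.call_lengths_mb[label] = float(lengths[mask].sum()) / 1e6 if cnt else 0.0
        s.call_frequencies[label] = (
            _round2(100.0 * cnt / s.total_calls) if s.total_calls else 0.0
        )
    s.total_length_mb = float(lengths.sum()) / 1e6 if len(calls) else 0.0
    if cnvrs is not None:
        s.cnvr_counts = cnvrs["cnvr_class"].value_counts().to_dict()
        s.total_cnvrs = int(len(cnvrs))
    if uniques is not None:
        s.unique_counts = uniques["unique_class"].value_counts().to_dict()
        s.total_unique = int(len(uniques))
    return s


def _direction(cn: int) -> str:
    return "del" if cn in DELETION_CLASSES else "dup"


def concordance(set_a: pd.DataFrame, set_b: pd.DataFrame) -> float:
    """Percent of calls in ``set_a`` matched in ``set_b``.

    A call matches when some call in ``set_b`` from the same sample and
    chromosome, of the same direction (deletion-class vs
    duplication-class), overlaps it by at least 1 bp.
    """
    validate_calls(set_a)
    validate_calls(set_b)
    if not len(set_a):
        raise ValueError("concordance undefined for an empty query set")
    if not len(set_b):
        return 0.0

    b = set_b.assign(direction=set_b["cn"].map(_direction))
    b_groups = {key: grp.sort_values("start")[["start", "end"]].to_numpy()
                for key, grp in b.groupby(["sample", "chrom", "direction"])}

    matched = 0
    a = set_a.assign(direction=set_a["cn"].map(_direction))
    for row in a.itertuples(index=False):
        ivals = b_groups.get((row.sample, row.chrom, row.direction))
        if ivals is None:
            continue
        # overlap iff b.start <= a.end and b.end >= a.start
        idx = np.searchsorted(ivals[:, 0], row.end, side="right")
        if idx and (ivals[:idx, 1] >= row.start).any():
            matched += 1
    return 100.0 * matched / len(set_a)
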