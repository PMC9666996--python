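"""Transcriptome A-to-I editing from per-site pileup records.

Inosine arising from adenosine deamination is read as G by sequencers, so G
reads at reference-A sites are the operational signal. Records are filtered
to reference-A sites with depth >= 10 and mean quality >= 25 before
quantification; the pooled (read-level) fraction

    100 * sum(G reads) / sum(depth)   over retained sites

is the default estimator, with a site-level variant (fraction of retained
sites carrying at least one G read) also exposed. The quality filter applies
to the per-site mean quality carried by the pileup TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import pandas as pd

from .editquant import wald_ci
from scipy.stats import norm

__all__ = [
    "RnaPileupRecord",
    "filter_pileup",
    "a_to_i_percent",
    "a_to_i_summary",
    "transcript_position_percent",
    "compare_samples",
    "read_pileup_tsv",
    "write_pileup_tsv",
]

_PILEUP_COLUMNS = ["chrom", "pos", "ref", "A", "C", "G", "T", "depth", "mean_quality"]


@dataclass(frozen=True)
class RnaPileupRecord:
    """One transcriptomic position: reference base, per-base read counts,
    and the site's mean (mapping/base) quality on the Phred scale."""

    chrom: str
    pos: int
    ref: str
    a: int
    c: int
    g: int
    t: int
    mean_quality: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", self.ref.upper())
        if self.ref not in "ACGT":
            raise ValueError(f"reference base must be ACGT, got {self.ref!r}")
        if min(self.a, self.c, self.g, self.t) < 0:
            raise ValueError("base counts must be non-negative")
        if self.mean_quality < 0:
            raise ValueError("mean_quality must be >= 0")

    @property
    def depth(self) -> int:
        return self.a + self.c + self.g + self.t

    def count(self, base: str) -> int:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}[base.upper()]


def filter_pileup(
    records: Sequence[RnaPileupRecord],
    min_depth: int = 10,
    min_quality: float = 25.0,
) -> list[RnaPileupRecord]:
    """Retain reference-A records with depth >= min_depth and mean quality
    >= min_quality, preserving input order. Idempotent."""
    return [
        r
        for r in records
        if r.ref == "A" and r.depth >= min_depth and r.mean_quality >= min_quality
    ]


def a_to_i_percent(records: Sequence[RnaPileupRecord], mode: str = "read") -> float:
    """Percent A-to-I editing over filtered reference-A records.

    ``mode='read'`` (default): 100 * total G reads / total depth — the pooled
    per-read fraction. ``mode='site'``: 100 * (records with >= 1 G read) /
    record count.
    """
    if not records:
        raise ValueError("no records after filtering; cannot quantify")
    for r in records:
        if r.ref != "A":
            raise ValueError("a_to_i_percent expects reference-A records only")
    if mode == "read":
        depth = sum(r.depth for r in records)
        if depth < 1:
            raise ValueError("total depth is zero")
        return 100.0 * sum(r.g for r in records) / depth
    if mode == "site":
        return 100.0 * sum(1 for r in records if r.g > 0) / len(records)
    raise ValueError(f"unknown mode {mode!r}")


def a_to_i_summary(records: Sequence[RnaPileupRecord]) -> dict:
    """JSON-ready summary reporting both estimator modes with their counts."""
    depth = sum(r.depth for r in records)
    g_reads = sum(r.g for r in records)
    read_pct = a_to_i_percent(records, "read")
    lo, hi = wald_ci(read_pct, depth)
    return {
        "n_sites": len(records),
        "n_reads": depth,
        "g_reads": g_reads,
        "read_level": {"percent": read_pct, "ci_low": lo, "ci_high": hi},
        "site_level": {"percent": a_to_i_percent(records, "site")},
    }


class TranscriptBaseFrequency(NamedTuple):
    percent: float
    depth: int
    ci_low: float
    ci_high: float


def transcript_position_percent(
    records: Sequence[RnaPileupRecord],
    chrom: str,
    pos: int,
    base: str,
    confidence: float = 0.95,
) -> TranscriptBaseFrequency:
    """Frequency of ``base`` among reads covering one transcript position,
    with a Wald CI. Errors if the position is absent or has zero depth."""
    for r in records:
        if r.chrom == chrom and r.pos == pos:
            if r.depth < 1:
                raise ValueError(f"zero depth at {chrom}:{pos}")
            pct = 100.0 * r.count(base) / r.depth
            lo, hi = wald_ci(pct, r.depth, confidence)
            return TranscriptBaseFrequency(pct, r.depth, lo, hi)
    raise ValueError(f"no pileup record at {chrom}:{pos}")


class SampleComparison(NamedTuple):
    difference: float
    ci_low: float
    ci_high: float


def compare_samples(
    treated: float,
    untreated: float,
    n_treated: int,
    n_untreated: int,
    confidence: float = 0.95,
) -> SampleComparison:
    """Difference of two A-to-I percentages (treated − untreated) with a
    Wald CI from the combined standard error of the two proportions."""
    if min(n_treated, n_untreated) < 1:
        raise ValueError("read counts must be >= 1")
    z = norm.ppf(0.5 * (1.0 + confidence))
    p1, p2 = treated / 100.0, untreated / 100.0
    se = math.sqrt(p1 * (1 - p1) / n_treated + p2 * (1 - p2) / n_untreated)
    diff = treated - untreated
    half = 100.0 * z * se
    return SampleComparison(diff, diff - half, diff + half)


def read_pileup_tsv(path: str | Path) -> list[RnaPileupRecord]:
    """Read pileup TSV (chrom, pos, ref, A, C, G, T, depth, mean_quality)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pileup TSV missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        rec = RnaPileupRecord(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            a=int(row.A),
            c=int(row.C),
            g=int(row.G),
            t=int(row.T),
            mean_quality=float(row.mean_quality),
        )
        if rec.depth != int(row.depth):
            raise ValueError(
                f"depth column disagrees with base counts at {rec.chrom}:{rec.pos}"
            )
        records.append(rec)
    return records


def write_pileup_tsv(records: Sequence[RnaPileupRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "A": r.a,
            "C": r.c,
            "G": r.g,
            "T": r.t,
            "depth": r.depth,
            "mean_quality": r.mean_quality,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)
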