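"""Cumulative off-target editing statistic over the editing window.

For each candidate off-target locus (supplied as per-position window counts,
protospacer-strand oriented) the statistic pools, over editing-window
positions whose reference base is A or T, the reads showing the base-editor
signature conversion — G where A is expected and C where T is expected
(A·T -> G·C on the duplex) — and divides by the informative reads at those
same positions:

    cumulative% = 100 * (G@ref-A + C@ref-T) / (informative reads at ref-A/T)

The alternative reading of the conversion direction (A reads where G is
expected, T where C is expected) is available via ``interpretation``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .ampliconio import TargetSite, WindowCounts
from .editquant import wald_ci

__all__ = [
    "OffTargetLocus",
    "cumulative_offtarget_percent",
    "offtarget_report",
    "read_loci_manifest",
]

#: reference base -> read base that counts as a conversion, per interpretation
_CONVERSIONS = {
    "at_to_gc": {"A": "G", "T": "C"},
    "gc_to_at": {"G": "A", "C": "T"},
}


@dataclass(frozen=True)
class OffTargetLocus:
    """One candidate off-target site: an id plus its window counts."""

    id: str
    window_counts: WindowCounts

    @property
    def reference_bases(self) -> str:
        return self.window_counts.reference_bases


def cumulative_offtarget_percent(
    locus: OffTargetLocus | WindowCounts,
    window: tuple[int, int] = (3, 9),
    interpretation: str = "at_to_gc",
) -> tuple[float, int]:
    """Pooled conversion percentage over editing-window A/T positions.

    Returns ``(percent, n_informative)`` where ``n_informative`` is the
    pooled A+C+G+T read count over the contributing positions (N reads are
    excluded from numerator and denominator alike).

    Raises ``ValueError`` if no window position has an A or T reference base
    (the statistic is undefined; such a locus is unreportable).
    """
    if interpretation not in _CONVERSIONS:
        raise ValueError(f"unknown interpretation {interpretation!r}")
    conv = _CONVERSIONS[interpretation]
    counts = locus.window_counts if isinstance(locus, OffTargetLocus) else locus
    lo, hi = window
    numerator = 0
    denominator = 0
    for pos in range(lo, hi + 1):
        ref = counts.reference_bases[pos - 1]
        if ref not in conv:
            continue
        numerator += counts.base_count(pos, conv[ref])
        denominator += counts.informative(pos)
    if denominator == 0:
        raise ValueError(
            f"no informative reference {'/'.join(conv)} position in window {window}"
        )
    return 100.0 * numerator / denominator, denominator


def offtarget_report(
    counts_by_condition: Mapping[str, Mapping[str, WindowCounts]],
    control_condition: str,
    window: tuple[int, int] = (3, 9),
    confidence: float = 0.95,
    interpretation: str = "at_to_gc",
) -> pd.DataFrame:
    """Per locus x condition cumulative statistic with Wald CIs.

    ``counts_by_condition`` maps condition label -> {locus id -> counts};
    every condition must supply counts for every locus. A treated locus is
    flagged when its CI does not overlap the control's CI at that locus.
    """
    if control_condition not in counts_by_condition:
        raise ValueError(f"control condition {control_condition!r} not supplied")
    locus_ids = sorted(counts_by_condition[control_condition])
    for cond, per_locus in counts_by_condition.items():
        for lid in locus_ids:
            if lid not in per_locus:
                raise ValueError(f"missing counts for locus {lid!r} in condition {cond!r}")

    stats: dict[tuple[str, str], tuple[float, int, float, float]] = {}
    for cond, per_locus in counts_by_condition.items():
        for lid in locus_ids:
            pct, n = cumulative_offtarget_percent(
                per_locus[lid], window=window, interpretation=interpretation
            )
            lo, hi = wald_ci(pct, n, confidence)
            stats[(cond, lid)] = (pct, n, lo, hi)

    rows = []
    for cond in counts_by_condition:
        for lid in locus_ids:
            pct, n, lo, hi = stats[(cond, lid)]
            c_lo, c_hi = stats[(control_condition, lid)][2:]
            flagged = cond != control_condition and (lo > c_hi or hi < c_lo)
            rows.append(
                {
                    "locus": lid,
                    "condition": cond,
                    "n": n,
                    "cumulative_pct": pct,
                    "ci_low": lo,
                    "ci_high": hi,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)


def read_loci_manifest(path: str | Path) -> pd.DataFrame:
    """Read a loci manifest TSV: columns id, chrom, strand, window_ref_23nt."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["id", "chrom", "strand", "window_ref_23nt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"loci manifest missing columns: {missing}")
    if df["id"].duplicated().any():
        raise ValueError("locus ids must be unique")
    return df
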