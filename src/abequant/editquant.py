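"""On-target, bystander, and Sanger editing statistics.

Implements the allele-counting arithmetic used to score an adenine base
editing experiment against a heterozygous control:

* raw edited-read percentage at a window position,
  ``100 * edited reads / informative reads``;
* control-baseline normalization,
  ``100 * (edited% - control%) / (100 - control%)``, which maps the
  pre-existing wild-type allele fraction (50% in a compound-heterozygous
  patient) to 0 and complete conversion to 100;
* Wald binomial confidence intervals, ``p ± z * sqrt(p(1-p)/n)``;
* Sanger-trace efficiency against a heterozygous T baseline,
  ``100 * (baseline_T - T%) / baseline_T``.

Confidence intervals are computed on the raw proportion scale and mapped
through the (affine) normalization, so the interval transforms exactly.
Negative normalized efficiencies — possible when the treated sample carries
fewer edited reads than the control — are reported as-is with a QC flag
rather than clamped, since silent clamping would hide control contamination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import norm

from .ampliconio import WINDOW_LEN, TargetSite, WindowCounts

__all__ = [
    "SangerSite",
    "EditingEstimate",
    "raw_edit_percent",
    "normalize_efficiency",
    "wald_ci",
    "sanger_efficiency",
    "quantify_condition",
    "dose_table",
    "write_report_tsv",
]


@dataclass(frozen=True)
class SangerSite:
    """Per-base proportions at one Sanger trace position.

    ``proportions`` maps base letters to percentages summing to 100 (±0.5 to
    absorb chromatogram-caller rounding). ``baseline_t`` is the expected T
    percentage in the unedited sample: 50 for a heterozygous C>T locus, 100
    for a homozygous mutant.
    """

    proportions: Mapping[str, float]
    baseline_t: float = 50.0

    def __post_init__(self) -> None:
        props = {b.upper(): float(v) for b, v in self.proportions.items()}
        object.__setattr__(self, "proportions", props)
        for b, v in props.items():
            if b not in "ACGT":
                raise ValueError(f"unexpected base {b!r} in Sanger proportions")
            if not 0.0 <= v <= 100.0:
                raise ValueError("Sanger proportions must be in [0, 100]")
        total = sum(props.values())
        if abs(total - 100.0) > 0.5:
            raise ValueError(f"Sanger proportions sum to {total}, expected 100 ± 0.5")

    @property
    def t_percent(self) -> float:
        return self.proportions.get("T", 0.0)


@dataclass(frozen=True)
class EditingEstimate:
    """Editing statistics at one window position.

    ``ci_low``/``ci_high`` bracket ``normalized_percent`` (the CI is computed
    on the raw proportion and pushed through the affine normalization).
    """

    position: int
    role: str  # 'target' or 'bystander'
    ref_base: str
    edited_base: str
    raw_percent: float
    control_percent: float
    normalized_percent: float
    ci_low: float
    ci_high: float
    n: int
    flags: tuple[str, ...] = ()


def raw_edit_percent(
    counts: WindowCounts, position: int, edited_base: str
) -> tuple[float, int]:
    """Percent of informative reads carrying ``edited_base`` at a position.

    Informative reads are A+C+G+T; N reads are excluded from the denominator.
    Returns ``(percent, n_informative)``.
    """
    if not 1 <= position <= WINDOW_LEN:
        raise ValueError("position must be in 1..23")
    n = counts.informative(position)
    if n < 1:
        raise ValueError(f"no informative reads at window position {position}")
    pct = 100.0 * counts.base_count(position, edited_base) / n
    return pct, n


def normalize_efficiency(edited_percent: float, control_percent: float) -> float:
    """Control-baseline normalization of an edited-read percentage.

    ``100 * (edited - control) / (100 - control)``: 0 when the treated sample
    matches the control, 100 at complete conversion. May be negative when
    treated < control; callers flag rather than clamp.
    """
    if not 0.0 <= control_percent < 100.0:
        raise ValueError("control_percent must be in [0, 100)")
    if not 0.0 <= edited_percent <= 100.0:
        raise ValueError("edited_percent must be in [0, 100]")
    return 100.0 * (edited_percent - control_percent) / (100.0 - control_percent)


def wald_ci(
    p_hat: float, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wald (normal-approximation) binomial CI on the percent scale.

    ``p ± z * sqrt(p(1-p)/n)`` with z the standard-normal quantile for
    ``(1+confidence)/2`` (1.959964 at 95%); bounds clamped to [0, 100]. At
    p̂ = 0 or 100 the interval degenerates to a point, a known Wald edge case.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p_hat <= 100.0:
        raise ValueError("p_hat must be in [0, 100]")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    z = norm.ppf(0.5 * (1.0 + confidence))
    p = p_hat / 100.0
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (
        max(0.0, 100.0 * (p - half)),
        min(100.0, 100.0 * (p + half)),
    )


def sanger_efficiency(site: SangerSite) -> float:
    """Editing efficiency from a Sanger trace: 100*(baseline_T - T%)/baseline_T.

    With the heterozygous baseline of 50, a fully corrected trace (T = 0)
    scores 100% and an untreated trace (T = baseline) scores 0%.
    """
    if site.baseline_t <= 0:
        raise ValueError("baseline_t must be > 0")
    return 100.0 * (site.baseline_t - site.t_percent) / site.baseline_t


def _estimate_at(
    counts: WindowCounts,
    control_counts: WindowCounts,
    position: int,
    role: str,
    edited_base: str,
    confidence: float,
) -> EditingEstimate:
    raw, n = raw_edit_percent(counts, position, edited_base)
    control, _ = raw_edit_percent(control_counts, position, edited_base)
    normalized = normalize_efficiency(raw, control)
    lo_raw, hi_raw = wald_ci(raw, n, confidence)
    ci_low = normalize_efficiency(lo_raw, control)
    ci_high = normalize_efficiency(hi_raw, control)
    flags: tuple[str, ...] = ()
    if normalized < 0.0:
        flags = ("negative_normalized",)
    return EditingEstimate(
        position=position,
        role=role,
        ref_base=counts.reference_bases[position - 1],
        edited_base=edited_base.upper(),
        raw_percent=raw,
        control_percent=control,
        normalized_percent=normalized,
        ci_low=ci_low,
        ci_high=ci_high,
        n=n,
        flags=flags,
    )


def quantify_condition(
    counts: WindowCounts,
    control_counts: WindowCounts,
    confidence: float = 0.95,
    edited_base: str = "G",
) -> tuple[EditingEstimate, list[EditingEstimate]]:
    """Target and bystander editing estimates for one treated condition.

    The control's edited-base percentage at the matched position supplies the
    normalization baseline both for the target (pre-existing wild-type allele
    reads) and for each bystander (artifact reads in the untreated control).
    """
    if counts.site != control_counts.site:
        raise ValueError("treated and control counts must share the same TargetSite")
    site = counts.site
    target = _estimate_at(
        counts, control_counts, site.target_position, "target", edited_base, confidence
    )
    bystanders = [
        _estimate_at(counts, control_counts, p, "bystander", edited_base, confidence)
        for p in site.bystander_positions
    ]
    return target, bystanders


def dose_table(
    conditions: Sequence[tuple[str, EditingEstimate, Sequence[EditingEstimate]]],
) -> pd.DataFrame:
    """Tabulate editing estimates across dose conditions.

    One row per condition x position (target first, then bystanders), in the
    declared condition order. Duplicate condition labels are rejected.
    """
    if not conditions:
        raise ValueError("at least one condition is required")
    labels = [c[0] for c in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels")
    rows = []
    for label, target, bystanders in conditions:
        for est in [target, *bystanders]:
            rows.append(
                {
                    "condition": label,
                    "window_pos": est.position,
                    "role": est.role,
                    "ref_base": est.ref_base,
                    "edited_base": est.edited_base,
                    "n": est.n,
                    "raw_pct": est.raw_percent,
                    "control_pct": est.control_percent,
                    "normalized_pct": est.normalized_percent,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "flags": ";".join(est.flags),
                }
            )
    return pd.DataFrame(rows)


def write_report_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a dose/report table with percentages rendered to 1 decimal."""
    table.to_csv(path, sep="\t", index=False, float_format="%.1f")
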