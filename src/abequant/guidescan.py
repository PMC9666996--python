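"""ABE targetability screening for point mutations.

An adenine base editor can revert a mutation only if the mutant base reads
as adenine on one strand (i.e. the genomic change is C>T or A-gaining on the
plus strand, G>A on the minus strand) and a protospacer can be placed so
that this adenine falls inside the editing window with an NGG PAM
immediately 3'. The scan therefore runs on the *mutant* (post-mutation)
sequence — the protospacer the editor needs must match the patient genome —
and enumerates placements on both strands.

Candidates are ranked to minimize bystander exposure: target position
closest to the window centre first, then fewest other in-window adenines,
then 5'-most placement on the given reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .ampliconio import (
    PROTOSPACER_LEN,
    TargetSite,
    iupac_match,
    revcomp,
)

__all__ = [
    "MutationSpec",
    "GuideCandidate",
    "NotABETargetableError",
    "find_guides",
    "classify_ptc",
    "screen_mutations",
    "read_mutations_tsv",
]


class NotABETargetableError(ValueError):
    """The mutant base is not adenine on either strand — no ABE can act."""


@dataclass(frozen=True)
class MutationSpec:
    """A point mutation in its local genomic context.

    ``ref_sequence`` is the local reference (pre-mutation) sequence on the
    plus strand; ``mutation_offset`` is 1-based within it. Optional coding
    annotation (``codon_window``, ``codon_offset``, ``coding_strand``)
    enables consequence classification: ``codon_window`` is an in-frame
    stretch of the coding sequence containing the mutated base at 1-based
    ``codon_offset``.
    """

    ref_sequence: str
    mutation_offset: int
    ref_base: str
    alt_base: str
    id: str = ""
    codon_window: Optional[str] = None
    codon_offset: Optional[int] = None
    coding_strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_sequence", self.ref_sequence.upper())
        object.__setattr__(self, "ref_base", self.ref_base.upper())
        object.__setattr__(self, "alt_base", self.alt_base.upper())
        if not 1 <= self.mutation_offset <= len(self.ref_sequence):
            raise ValueError("mutation_offset outside ref_sequence")
        if self.ref_sequence[self.mutation_offset - 1] != self.ref_base:
            raise ValueError(
                f"ref_sequence has {self.ref_sequence[self.mutation_offset - 1]!r} "
                f"at offset {self.mutation_offset}, expected {self.ref_base!r}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        if self.coding_strand not in "+-":
            raise ValueError("coding_strand must be '+' or '-'")

    @property
    def alt_sequence(self) -> str:
        """The local sequence after the mutation (the patient genome)."""
        i = self.mutation_offset - 1
        return self.ref_sequence[:i] + self.alt_base + self.ref_sequence[i + 1 :]


@dataclass(frozen=True)
class GuideCandidate:
    """One protospacer placement covering the mutant adenine.

    ``strand`` is the protospacer strand relative to ``ref_sequence``;
    ``plus_start`` is the 1-based plus-strand coordinate of the 5'-most base
    of the protospacer's footprint (used only for tie-breaking).
    """

    site: TargetSite
    strand: str
    plus_start: int
    target_position: int
    in_window_adenines: tuple[int, ...]

    @property
    def n_bystanders(self) -> int:
        return sum(1 for p in self.in_window_adenines if p != self.target_position)

    def rank_key(self, window: tuple[int, int]) -> tuple:
        centre = 0.5 * (window[0] + window[1])
        return (
            abs(self.target_position - centre),
            self.n_bystanders,
            self.plus_start,
            self.strand,
        )


def find_guides(
    mutation: MutationSpec,
    pam_pattern: str = "NGG",
    window: tuple[int, int] = (3, 9),
    length: int = PROTOSPACER_LEN,
) -> list[GuideCandidate]:
    """Enumerate protospacers placing the mutant adenine in the editing window.

    Scans the mutant (alt) sequence on both strands for every placement where
    (i) the mutant base reads A on the protospacer strand at a window
    position and (ii) the PAM pattern matches immediately 3'. Returns
    candidates sorted by rank (bystander-minimizing); empty when no PAM is
    suitably placed.

    Raises
    ------
    NotABETargetableError
        If the mutant base is neither A (plus strand) nor T (whose complement
        reads A on the minus strand).
    """
    if length != PROTOSPACER_LEN:
        raise ValueError("only 20-nt protospacers are supported")
    strands: list[str] = []
    if mutation.alt_base == "A":
        strands.append("+")
    if mutation.alt_base == "T":
        strands.append("-")
    if not strands:
        raise NotABETargetableError(
            f"mutant base {mutation.alt_base!r} does not read as adenine on either strand"
        )

    alt = mutation.alt_sequence
    n = len(alt)
    lo, hi = window
    candidates = []
    for strand in strands:
        seq = alt if strand == "+" else revcomp(alt)
        # 0-based index of the mutant base on this strand's sequence
        m = mutation.mutation_offset - 1 if strand == "+" else n - mutation.mutation_offset
        for p in range(lo, hi + 1):
            start = m - (p - 1)  # 0-based protospacer start on this strand
            end = start + length + len(pam_pattern)
            if start < 0 or end > n:
                continue
            protospacer = seq[start : start + length]
            pam = seq[start + length : end]
            if not iupac_match(pam_pattern, pam):
                continue
            if any(b not in "ACGT" for b in protospacer + pam):
                continue
            adenines = tuple(
                q for q in range(lo, hi + 1) if protospacer[q - 1] == "A"
            )
            plus_start = start + 1 if strand == "+" else n - end + 1
            site = TargetSite(
                protospacer=protospacer,
                pam=pam,
                strand=strand,
                target_position=p,
                bystander_positions=tuple(q for q in adenines if q != p),
                window=window,
                pam_pattern=pam_pattern,
            )
            candidates.append(
                GuideCandidate(
                    site=site,
                    strand=strand,
                    plus_start=plus_start,
                    target_position=p,
                    in_window_adenines=adenines,
                )
            )
    candidates.sort(key=lambda c: c.rank_key(window))
    return candidates


def classify_ptc(coding_sequence_window: str, mutation: MutationSpec) -> str:
    """Classify a mutation's coding consequence: ptc, missense, silent, other.

    ``coding_sequence_window`` is an in-frame codon string written 5'->3' on
    the coding strand, containing the mutated base at ``mutation.codon_offset``
    (1-based). The pre- and post-mutation windows are translated with the
    standard genetic code; a gained stop codon is a premature termination
    codon (ptc), an amino-acid change without stop gain is missense, and an
    unchanged protein sequence is silent. Stop-loss and other outcomes
    return 'other'.
    """
    win = coding_sequence_window.upper()
    if len(win) % 3 != 0 or not win:
        raise ValueError("coding window length must be a positive multiple of 3")
    off = mutation.codon_offset
    if off is None:
        raise ValueError("mutation lacks codon annotation (codon_offset)")
    if not 1 <= off <= len(win):
        raise ValueError("codon_offset outside coding window")
    if mutation.coding_strand == "+":
        ref_b, alt_b = mutation.ref_base, mutation.alt_base
    else:
        ref_b, alt_b = (
            str(Seq(mutation.ref_base).complement()),
            str(Seq(mutation.alt_base).complement()),
        )
    if win[off - 1] != ref_b:
        raise ValueError(
            f"coding window has {win[off - 1]!r} at offset {off}, "
            f"expected {ref_b!r} on the coding strand"
        )
    mutated = win[: off - 1] + alt_b + win[off:]
    aa_ref = str(Seq(win).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_ref == aa_alt:
        return "silent"
    if "*" in aa_alt and "*" not in aa_ref:
        return "ptc"
    if "*" in aa_ref and "*" not in aa_alt:
        return "other"
    return "missense"


def screen_mutations(
    mutations: Sequence[MutationSpec],
    pam_pattern: str = "NGG",
    window: tuple[int, int] = (3, 9),
    length: int = PROTOSPACER_LEN,
) -> tuple[pd.DataFrame, dict]:
    """Screen a mutation panel for ABE targetability.

    Returns a per-mutation table (targetable flag, best candidate geometry,
    coding consequence where annotated) and an aggregate summary with the
    targetable count and fraction.
    """
    if not mutations:
        raise ValueError("at least one mutation is required")
    rows = []
    n_targetable = 0
    for i, mut in enumerate(mutations):
        mut_id = mut.id or f"mut{i + 1}"
        try:
            candidates = find_guides(mut, pam_pattern, window, length)
        except NotABETargetableError:
            candidates = []
        targetable = bool(candidates)
        n_targetable += targetable
        consequence = ""
        if mut.codon_window is not None:
            consequence = classify_ptc(mut.codon_window, mut)
        best = candidates[0] if candidates else None
        rows.append(
            {
                "id": mut_id,
                "change": f"{mut.ref_base}>{mut.alt_base}",
                "targetable": targetable,
                "n_candidates": len(candidates),
                "best_strand": best.strand if best else "",
                "best_target_position": best.target_position if best else pd.NA,
                "best_protospacer": best.site.protospacer if best else "",
                "best_pam": best.site.pam if best else "",
                "best_n_bystanders": best.n_bystanders if best else pd.NA,
                "consequence": consequence,
            }
        )
    table = pd.DataFrame(rows)
    n = len(mutations)
    summary = {
        "n_mutations": n,
        "n_targetable": n_targetable,
        "fraction_targetable": n_targetable / n,
        "n_ptc": int((table["consequence"] == "ptc").sum()),
    }
    return table, summary


def read_mutations_tsv(path: str | Path) -> list[MutationSpec]:
    """Read mutations from TSV: id, ref_sequence, mutation_offset, ref_base,
    alt_base, and optional codon_window, codon_offset, coding_strand."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["id", "ref_sequence", "mutation_offset", "ref_base", "alt_base"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"mutations TSV missing columns: {missing}")
    muts = []
    for i, row in df.iterrows():
        try:
            kwargs = dict(
                id=row["id"],
                ref_sequence=row["ref_sequence"],
                mutation_offset=int(row["mutation_offset"]),
                ref_base=row["ref_base"],
                alt_base=row["alt_base"],
            )
            if "codon_window" in df.columns and pd.notna(row["codon_window"]):
                kwargs["codon_window"] = row["codon_window"]
                kwargs["codon_offset"] = int(row["codon_offset"])
                kwargs["coding_strand"] = row.get("coding_strand", "+") or "+"
            muts.append(MutationSpec(**kwargs))
        except (ValueError, KeyError, TypeError) as exc:
            raise ValueError(f"malformed mutation at line {i + 2}: {exc}") from exc
    return muts
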