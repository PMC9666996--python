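"""Amplicon read handling for base-editing quantification.

This module locates the 23-nt protospacer+PAM window of a target site inside
amplicon sequencing reads, tabulates per-position base counts on the
protospacer strand, and converts between protospacer, genomic, and cDNA (c.)
coordinates.

Conventions
-----------
* Protospacer positions are counted 1–20 from the 5' (PAM-distal) end; the
  PAM occupies window positions 21–23. An adenine base editor acts inside an
  editing window, by default positions 3–9.
* All I/O coordinates are 1-based inclusive (matching c.-notation and genomic
  browser coordinates); half-open intervals appear only in internal slicing.
* Counts are always reported on the protospacer strand, regardless of the
  orientation in which a read was sequenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "GenomicAnchor",
    "CdnaAnchor",
    "TargetSite",
    "WindowCounts",
    "WindowPlacement",
    "AmbiguousPlacementError",
    "NoReadsLocatedError",
    "WINDOW_LEN",
    "PROTOSPACER_LEN",
    "revcomp",
    "iupac_match",
    "locate_window",
    "count_bases",
    "protospacer_to_genomic",
    "protospacer_to_cdna",
    "read_fasta",
    "read_fastq",
    "site_from_config",
]

PROTOSPACER_LEN = 20
PAM_LEN = 3
WINDOW_LEN = PROTOSPACER_LEN + PAM_LEN  # 23-nt protospacer + PAM window

BASES = "ACGT"
_BASE_ORDER = "ACGTN"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> integer code; anything unknown maps to 4 (N)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True if ``seq`` matches ``pattern`` under IUPAC ambiguity codes."""
    if len(pattern) != len(seq):
        return False
    return all(
        s in ambiguous_dna_values.get(p.upper(), p.upper())
        for p, s in zip(pattern, seq.upper())
    )


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class AmbiguousPlacementError(ValueError):
    """Raised when a read admits two or more equally good window placements."""


class NoReadsLocatedError(ValueError):
    """Raised when no read in a set contains the protospacer+PAM window."""


@dataclass(frozen=True)
class GenomicAnchor:
    """Anchors one protospacer position to a 1-based plus-strand coordinate.

    ``sign`` is +1 when the plus-strand coordinate increases with protospacer
    position (protospacer 5'->3' runs along the genomic plus strand) and -1
    otherwise.
    """

    chrom: str
    protospacer_position: int
    coordinate: int
    sign: int = 1

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError("genomic anchor sign must be +1 or -1")
        if not 1 <= self.protospacer_position <= PROTOSPACER_LEN:
            raise ValueError("genomic anchor position must be in 1..20")


@dataclass(frozen=True)
class CdnaAnchor:
    """Anchors one protospacer position to a cDNA (c.) coordinate.

    cDNA coordinates follow ``value + orientation * (anchor_position - p)``:
    with ``orientation=+1`` the c. coordinate increases as the protospacer
    position decreases, which is the case when the gene's coding strand is
    opposite to the protospacer strand.
    """

    protospacer_position: int
    value: int
    orientation: int = 1

    def __post_init__(self) -> None:
        if self.orientation not in (1, -1):
            raise ValueError("cDNA anchor orientation must be +1 or -1")
        if not 1 <= self.protospacer_position <= PROTOSPACER_LEN:
            raise ValueError("cDNA anchor position must be in 1..20")


@dataclass(frozen=True)
class TargetSite:
    """Geometry of one protospacer: sequence, PAM, anchors, editable positions.

    Parameters
    ----------
    protospacer
        20-nt spacer-matching sequence, written 5'->3' on the protospacer
        strand. For an ABE correction site this is the *mutant* genomic
        sequence (the target adenine appears as A).
    pam
        3-nt PAM immediately 3' of the protospacer (NGG for SpCas9).
    strand
        ``'+'`` if the protospacer strand is the written reference/amplicon
        strand, ``'-'`` if it is its reverse complement.
    target_position
        Protospacer position (1–20) of the adenine the editor must correct.
    bystander_positions
        Other in-window positions whose editing is tracked.
    window
        Inclusive editing-window bounds within 1..20, default (3, 9).
    """

    protospacer: str
    pam: str
    strand: str = "+"
    target_position: int = 8
    bystander_positions: tuple[int, ...] = ()
    window: tuple[int, int] = (3, 9)
    genomic_anchor: GenomicAnchor | None = None
    cdna_anchor: CdnaAnchor | None = None
    pam_pattern: str = "NGG"

    def __post_init__(self) -> None:
        object.__setattr__(self, "protospacer", self.protospacer.upper())
        object.__setattr__(self, "pam", self.pam.upper())
        object.__setattr__(
            self, "bystander_positions", tuple(self.bystander_positions)
        )
        object.__setattr__(self, "window", tuple(self.window))
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if any(b not in BASES for b in self.protospacer):
            raise ValueError("protospacer alphabet must be ACGT")
        if len(self.pam) != PAM_LEN:
            raise ValueError("PAM must be 3 nt")
        if not iupac_match(self.pam_pattern, self.pam):
            raise ValueError(
                f"PAM {self.pam!r} does not match pattern {self.pam_pattern!r}"
            )
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        lo, hi = self.window
        if not (1 <= lo <= hi <= PROTOSPACER_LEN):
            raise ValueError("window must be within [1, 20]")
        if not lo <= self.target_position <= hi:
            raise ValueError("target_position must lie inside the window")
        for p in self.bystander_positions:
            if not 1 <= p <= PROTOSPACER_LEN:
                raise ValueError("bystander positions must be in 1..20")

    @property
    def window_reference(self) -> str:
        """23-nt protospacer+PAM reference on the protospacer strand."""
        return self.protospacer + self.pam

    @property
    def excluded_positions(self) -> frozenset[int]:
        """Window positions (1-based, 1..23) never counted as mismatches.

        Editable positions (the whole editing window) are excluded so fully
        edited reads are not lost; PAM positions matching N carry no
        information and are excluded too.
        """
        lo, hi = self.window
        excl = set(range(lo, hi + 1))
        for i, c in enumerate(self.pam_pattern.upper()):
            if c == "N":
                excl.add(PROTOSPACER_LEN + 1 + i)
        return frozenset(excl)

    def base_at(self, position: int) -> str:
        """Reference base on the protospacer strand at window position 1..23."""
        if not 1 <= position <= WINDOW_LEN:
            raise ValueError("window position must be in 1..23")
        return self.window_reference[position - 1]


class WindowPlacement(NamedTuple):
    """Placement of the 23-nt window in a read: offset is 0-based within the
    read oriented to the protospacer strand."""

    offset: int
    orientation: str  # '+' read as given, '-' reverse complement
    mismatches: int


@dataclass
class WindowCounts:
    """Per-position base counts over the 23-nt protospacer+PAM window.

    ``counts`` is a (23, 5) integer array in A, C, G, T, N order, all on the
    protospacer strand. ``reference_bases`` is the 23-nt window reference.
    """

    site: TargetSite
    counts: np.ndarray
    reads_located: int
    reads_dropped: int = 0
    reference_bases: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (WINDOW_LEN, 5):
            raise ValueError("counts must be a (23, 5) array (A,C,G,T,N)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.reference_bases:
            self.reference_bases = self.site.window_reference
        if len(self.reference_bases) != WINDOW_LEN:
            raise ValueError("reference_bases must be 23 nt")
        rowsums = self.counts.sum(axis=1)
        if not (rowsums == self.reads_located).all():
            raise ValueError(
                "per-position counts must sum to reads_located at every position"
            )

    def base_count(self, position: int, base: str) -> int:
        """Count of ``base`` at window position 1..23."""
        return int(self.counts[position - 1, _BASE_ORDER.index(base.upper())])

    def informative(self, position: int) -> int:
        """A+C+G+T reads at a position; N reads are excluded from denominators."""
        return int(self.counts[position - 1, :4].sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(_BASE_ORDER))
        df.insert(0, "ref_base", list(self.reference_bases))
        df.insert(0, "window_pos", np.arange(1, WINDOW_LEN + 1))
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        site: TargetSite,
        reads_dropped: int = 0,
    ) -> "WindowCounts":
        """Load precomputed counts (columns window_pos, ref_base, A, C, G, T, N)."""
        df = pd.read_csv(path, sep="\t")
        required = ["window_pos", "ref_base", "A", "C", "G", "T", "N"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"counts TSV missing columns: {missing}")
        df = df.sort_values("window_pos")
        if list(df["window_pos"]) != list(range(1, WINDOW_LEN + 1)):
            raise ValueError("counts TSV must cover window positions 1..23")
        counts = df[list(_BASE_ORDER)].to_numpy(dtype=np.int64)
        return cls(
            site=site,
            counts=counts,
            reads_located=int(counts[0].sum()),
            reads_dropped=reads_dropped,
            reference_bases="".join(df["ref_base"]).upper(),
        )

    @classmethod
    def from_bases(
        cls,
        site: TargetSite,
        window_bases: Iterable[str],
        reads_dropped: int = 0,
    ) -> "WindowCounts":
        """Tally a collection of 23-nt window strings (protospacer strand)."""
        counts = np.zeros((WINDOW_LEN, 5), dtype=np.int64)
        n = 0
        pos_idx = np.arange(WINDOW_LEN)
        for w in window_bases:
            codes = _encode(w)
            np.add.at(counts, (pos_idx, codes), 1)
            n += 1
        return cls(
            site=site,
            counts=counts,
            reads_located=n,
            reads_dropped=reads_dropped,
        )


# ---------------------------------------------------------------------------
# Window location and counting
# ---------------------------------------------------------------------------

def _compare_mask(site: TargetSite) -> np.ndarray:
    mask = np.ones(WINDOW_LEN, dtype=bool)
    for p in site.excluded_positions:
        mask[p - 1] = False
    return mask


def _placements(
    read_codes: np.ndarray, ref_codes: np.ndarray, mask: np.ndarray, max_mismatch: int
) -> list[tuple[int, int]]:
    """(mismatches, offset) pairs with mismatches <= max_mismatch."""
    n = read_codes.size - WINDOW_LEN
    if n < 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(read_codes, WINDOW_LEN)
    mm = ((windows != ref_codes) & mask).sum(axis=1)
    offs = np.nonzero(mm <= max_mismatch)[0]
    return [(int(mm[o]), int(o)) for o in offs]


def locate_window(
    read_sequence: str, site: TargetSite, max_mismatch: int = 2
) -> WindowPlacement | None:
    """Find the unique placement of the protospacer+PAM window in a read.

    Both the read and its reverse complement are searched; mismatches are
    counted only at non-editable, non-PAM-N window positions so that edited
    reads are located as reliably as unedited ones. Returns ``None`` when no
    placement has at most ``max_mismatch`` mismatches.

    Raises
    ------
    AmbiguousPlacementError
        If two or more placements tie at the minimal mismatch count; such
        reads are dropped by :func:`count_bases`.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    read = read_sequence.upper()
    ref_codes = _encode(site.window_reference)
    mask = _compare_mask(site)
    candidates: list[tuple[int, str, int]] = []
    for orientation, seq in (("+", read), ("-", revcomp(read))):
        for mm, off in _placements(_encode(seq), ref_codes, mask, max_mismatch):
            candidates.append((mm, orientation, off))
    if not candidates:
        return None
    candidates.sort()
    best = candidates[0]
    if len(candidates) > 1 and candidates[1][0] == best[0]:
        raise AmbiguousPlacementError(
            f"{len(candidates)} equally good window placements (mismatches={best[0]})"
        )
    return WindowPlacement(offset=best[2], orientation=best[1], mismatches=best[0])


def _read_seq(read) -> str:
    if isinstance(read, str):
        return read
    return str(read.seq)  # Bio.SeqRecord


def count_bases(
    reads: Iterable, site: TargetSite, max_mismatch: int = 2
) -> WindowCounts:
    """Tally per-position base counts over the window for a set of reads.

    Reads may be plain strings or Bio.SeqRecord objects. Each located read
    contributes one base (possibly N) at all 23 window positions, oriented to
    the protospacer strand; reads with no placement or an ambiguous placement
    are dropped and counted in ``reads_dropped``.
    """
    counts = np.zeros((WINDOW_LEN, 5), dtype=np.int64)
    pos_idx = np.arange(WINDOW_LEN)
    located = 0
    dropped = 0
    total = 0
    for read in reads:
        total += 1
        seq = _read_seq(read).upper()
        try:
            placement = locate_window(seq, site, max_mismatch)
        except AmbiguousPlacementError:
            dropped += 1
            continue
        if placement is None:
            dropped += 1
            continue
        oriented = seq if placement.orientation == "+" else revcomp(seq)
        window = oriented[placement.offset : placement.offset + WINDOW_LEN]
        np.add.at(counts, (pos_idx, _encode(window)), 1)
        located += 1
    if total == 0:
        raise ValueError("no reads supplied")
    if located == 0:
        raise NoReadsLocatedError(
            f"no read out of {total} contained the protospacer+PAM window"
        )
    return WindowCounts(
        site=site, counts=counts, reads_located=located, reads_dropped=dropped
    )


# ---------------------------------------------------------------------------
# Coordinate conversion
# ---------------------------------------------------------------------------

def protospacer_to_genomic(site: TargetSite, position: int) -> tuple[str, int]:
    """Map a protospacer position (1–20) to (chromosome, 1-based coordinate)."""
    if not 1 <= position <= PROTOSPACER_LEN:
        raise ValueError("protospacer position must be in 1..20")
    anchor = site.genomic_anchor
    if anchor is None:
        raise ValueError("site has no genomic anchor")
    coord = anchor.coordinate + anchor.sign * (position - anchor.protospacer_position)
    return anchor.chrom, coord


def protospacer_to_cdna(site: TargetSite, position: int) -> int:
    """Map a protospacer position (1–20) to a cDNA (c.) coordinate."""
    if not 1 <= position <= PROTOSPACER_LEN:
        raise ValueError("protospacer position must be in 1..20")
    anchor = site.cdna_anchor
    if anchor is None:
        raise ValueError("site has no cDNA anchor")
    return anchor.value + anchor.orientation * (
        anchor.protospacer_position - position
    )


# ---------------------------------------------------------------------------
# File I/O and configuration
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fastq(path: str | Path):
    """Iterate over FASTQ (Phred+33) records."""
    return SeqIO.parse(str(path), "fastq")


def site_from_config(source: str | Path | dict) -> TargetSite:
    """Build a TargetSite from a YAML/JSON file path or a parsed mapping.

    Keys mirror the TargetSite fields; anchors may be given as mappings, e.g.
    ``genomic_anchor: {chrom: chr3, protospacer_position: 8, coordinate:
    48580586, sign: 1}``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    if not isinstance(cfg, dict):
        raise ValueError("site config must be a mapping")
    kwargs = dict(cfg)
    if isinstance(kwargs.get("genomic_anchor"), dict):
        kwargs["genomic_anchor"] = GenomicAnchor(**kwargs["genomic_anchor"])
    if isinstance(kwargs.get("cdna_anchor"), dict):
        kwargs["cdna_anchor"] = CdnaAnchor(**kwargs["cdna_anchor"])
    if "bystander_positions" in kwargs:
        kwargs["bystander_positions"] = tuple(kwargs["bystander_positions"])
    if "window" in kwargs:
        kwargs["window"] = tuple(kwargs["window"])
    return TargetSite(**kwargs)
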