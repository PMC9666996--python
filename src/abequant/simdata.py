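"""Synthetic data with the statistical structure of a base-editing study.

Three generators back the downstream quantification stages:

* :func:`simulate_amplicon_reads` — amplicon deep-sequencing reads from a
  diploid (compound-heterozygous) locus. Each molecule is drawn from an
  allele by its fraction, edited A->G on the protospacer strand with
  per-position rates (editing precedes read-out noise, matching the
  biology: the genomic edit happens first, the sequencer then corrupts the
  read), and finally corrupted with a uniform substitution error.
* :func:`simulate_sanger_site` — per-base proportions at one Sanger trace
  position with truncated-Gaussian calling noise.
* :func:`simulate_rna_pileup` — transcriptome pileup records with a
  background A-to-I rate, including sites deliberately below the depth and
  quality filter thresholds.

All randomness flows through one ``numpy`` generator seeded explicitly, so
a fixed seed reproduces FASTQ output byte-for-byte.

The bundled demo locus mirrors the geometry of an ABE correction of a
heterozygous C>T nonsense mutation: the target adenine sits at protospacer
position 8 and a lone bystander adenine at position 3 of the editing window
(3-9), with the protospacer on the minus strand of the written amplicon.
The sequences themselves are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import truncnorm

from .ampliconio import (
    CdnaAnchor,
    GenomicAnchor,
    PROTOSPACER_LEN,
    TargetSite,
    WINDOW_LEN,
    locate_window,
    revcomp,
)
from .editquant import SangerSite
from .rnaedit import RnaPileupRecord

__all__ = [
    "AlleleSpec",
    "EditModel",
    "SeqNoise",
    "simulate_amplicon_reads",
    "simulate_sanger_site",
    "simulate_rna_pileup",
    "write_fastq",
    "example_site",
    "example_alleles",
    "example_edit_model",
]

_BASES = "ACGT"
_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i


@dataclass(frozen=True)
class AlleleSpec:
    """One allele of the locus: a full amplicon sequence and its molecular
    fraction in the bulk population (0.5/0.5 for a compound heterozygote)."""

    name: str
    sequence: str
    fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("allele fraction must be in [0, 1]")
        if any(b not in _BASES for b in self.sequence):
            raise ValueError(f"allele {self.name!r} sequence alphabet must be ACGT")


@dataclass(frozen=True)
class EditModel:
    """Per-position A->G editing rates on the protospacer strand.

    ``per_position_rate`` maps protospacer positions (1-20) to the
    probability that an adenine there is converted on an editable molecule.
    ``correlation`` couples in-window edits to the target edit: given the
    target edit occurred on a molecule, every other position's rate is
    raised to ``rate ** (1 - correlation)``; 0 (the default) makes positions
    independent Bernoulli draws, the minimal assumption when only marginal
    rates are known.
    """

    site: TargetSite
    per_position_rate: Mapping[int, float]
    editable_alleles: Optional[tuple[str, ...]] = None
    correlation: float = 0.0

    def __post_init__(self) -> None:
        rates = {int(p): float(r) for p, r in self.per_position_rate.items()}
        object.__setattr__(self, "per_position_rate", rates)
        for p, r in rates.items():
            if not 1 <= p <= PROTOSPACER_LEN:
                raise ValueError("edit positions must be in 1..20")
            if not 0.0 <= r <= 1.0:
                raise ValueError("edit rates must be in [0, 1]")
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be in [0, 1]")
        if self.editable_alleles is not None:
            object.__setattr__(
                self, "editable_alleles", tuple(self.editable_alleles)
            )


@dataclass(frozen=True)
class SeqNoise:
    """Sequencing read-out model: depth, uniform substitution error, and
    Gaussian Phred qualities (clamped to [2, 40], written Phred+33)."""

    depth: int
    sub_error: float = 0.0
    read_length: Optional[int] = None
    qual_mean: float = 35.0
    qual_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.sub_error < 0.5:
            raise ValueError("sub_error must be in [0, 0.5)")
        if self.qual_sd < 0:
            raise ValueError("qual_sd must be >= 0")


def _edit_indices(allele_seq: str, site: TargetSite) -> tuple[dict[int, int], str]:
    """Map protospacer positions to written-strand indices for one allele.

    Returns (position -> 0-based index, edited written-strand character).
    The protospacer is located with mismatches tolerated only at editable
    window positions, so both the mutant and the corrected/wild-type allele
    anchor at the same placement.
    """
    placement = locate_window(allele_seq, site, max_mismatch=0)
    if placement is None:
        raise ValueError(
            f"protospacer+PAM of the target site not found in allele sequence"
        )
    n = len(allele_seq)
    idx = {}
    for p in range(1, PROTOSPACER_LEN + 1):
        if placement.orientation == "+":
            idx[p] = placement.offset + p - 1
        else:
            idx[p] = n - 1 - (placement.offset + p - 1)
    edited_char = "G" if placement.orientation == "+" else "C"
    return idx, edited_char


def simulate_amplicon_reads(
    alleles: Sequence[AlleleSpec],
    model: EditModel,
    noise: SeqNoise,
) -> list[SeqRecord]:
    """Simulate unpaired full-amplicon reads from a bulk edited population.

    Each read is drawn from an allele by fraction, edited per ``model``
    (A->G on the protospacer strand, i.e. the complementary T->C change when
    the protospacer lies on the opposite strand of the written amplicon),
    then corrupted with uniform substitution errors; qualities are Gaussian
    on the Phred scale. Deterministic under ``noise.seed``.
    """
    if not alleles:
        raise ValueError("at least one allele is required")
    fractions = np.array([a.fraction for a in alleles], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("allele fractions must sum to 1")
    lengths = {len(a.sequence) for a in alleles}
    if len(lengths) != 1:
        raise ValueError("allele sequences must have equal length")
    (length,) = lengths
    if noise.read_length is not None and noise.read_length < length:
        raise ValueError("read_length must cover the full amplicon")

    site = model.site
    placements = {}
    for a in alleles:
        try:
            placements[a.name] = _edit_indices(a.sequence, site)
        except ValueError as exc:
            raise ValueError(f"allele {a.name!r}: {exc}") from exc

    rng = np.random.default_rng(noise.seed)
    depth = noise.depth
    allele_idx = rng.choice(len(alleles), size=depth, p=fractions)

    seq_codes = np.stack(
        [_CODE[np.frombuffer(a.sequence.encode(), np.uint8)] for a in alleles]
    )
    mat = seq_codes[allele_idx].copy()

    # per-molecule editing, target position first so the correlation knob can
    # condition the remaining in-window positions on the target outcome
    target = site.target_position
    positions = sorted(model.per_position_rate, key=lambda p: (p != target, p))
    editable = (
        set(model.editable_alleles)
        if model.editable_alleles is not None
        else {a.name for a in alleles}
    )
    edited_code = {"G": _CODE[ord("G")], "C": _CODE[ord("C")]}
    for ai, allele in enumerate(alleles):
        rows = np.nonzero(allele_idx == ai)[0]
        if allele.name not in editable or rows.size == 0:
            continue
        idx_map, edited_char = placements[allele.name]
        strand_a = "A" if edited_char == "G" else "T"  # written-strand adenine
        target_edited = np.zeros(rows.size, dtype=bool)
        for p in positions:
            rate = model.per_position_rate[p]
            if rate == 0.0 or allele.sequence[idx_map[p]] != strand_a:
                continue
            if p == target:
                mask = rng.random(rows.size) < rate
                target_edited = mask
            else:
                eff = np.where(
                    target_edited & (model.correlation > 0),
                    rate ** (1.0 - model.correlation),
                    rate,
                )
                mask = rng.random(rows.size) < eff
            mat[rows[mask], idx_map[p]] = edited_code[edited_char]

    if noise.sub_error > 0:
        err = rng.random((depth, length)) < noise.sub_error
        shifts = rng.integers(1, 4, size=(depth, length), dtype=np.uint8)
        mat = np.where(err, (mat + shifts) % 4, mat)

    quals = np.clip(
        np.rint(rng.normal(noise.qual_mean, noise.qual_sd, size=(depth, length))),
        2,
        40,
    ).astype(int)

    ascii_mat = _ASCII[mat]
    records = []
    for i in range(depth):
        rec = SeqRecord(
            Seq(ascii_mat[i].tobytes().decode("ascii")),
            id=f"read{i + 1:06d}",
            description=f"allele={alleles[allele_idx[i]].name}",
        )
        rec.letter_annotations["phred_quality"] = quals[i].tolist()
        records.append(rec)
    return records


def write_fastq(records: Sequence[SeqRecord], path: str | Path) -> int:
    """Write reads as FASTQ (Phred+33); returns the record count."""
    return SeqIO.write(records, str(path), "fastq")


def simulate_sanger_site(
    true_t_freq: float, noise_sd: float, seed: int = 0, baseline_t: float = 50.0
) -> SangerSite:
    """One Sanger trace position: T at ``true_t_freq`` percent plus Gaussian
    calling noise truncated to [0, 100]; the remainder is called C."""
    if not 0.0 <= true_t_freq <= 100.0:
        raise ValueError("true_t_freq must be in [0, 100]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        t = float(true_t_freq)
    else:
        a = (0.0 - true_t_freq) / noise_sd
        b = (100.0 - true_t_freq) / noise_sd
        t = float(
            truncnorm.rvs(
                a, b, loc=true_t_freq, scale=noise_sd,
                random_state=np.random.default_rng(seed),
            )
        )
    return SangerSite(
        proportions={"A": 0.0, "C": 100.0 - t, "G": 0.0, "T": t},
        baseline_t=baseline_t,
    )


def simulate_rna_pileup(
    n_sites: int,
    background_rate: float,
    depth_dist: Optional[Mapping] = None,
    qual_dist: Optional[Mapping] = None,
    seed: int = 0,
    non_a_fraction: float = 0.0,
    chrom: str = "chrT",
) -> list[RnaPileupRecord]:
    """Transcriptome pileup records with background A-to-I editing.

    Reference-A sites carry Binomial(depth, ``background_rate``) G reads,
    the rest A. ``depth_dist`` (``{"mean", "low_fraction"}``) draws Poisson
    depths floored at 10 except for a ``low_fraction`` of sites given depth
    1-9; ``qual_dist`` (``{"mean", "sd", "low_fraction"}``) draws Gaussian
    mean qualities floored at 25 except for a ``low_fraction`` given
    qualities in [10, 25). Sites below either floor exist specifically to
    exercise the depth >= 10 and quality >= 25 filters.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0.0 <= background_rate < 1.0:
        raise ValueError("background_rate must be in [0, 1)")
    depth_dist = {"mean": 50.0, "low_fraction": 0.0, **(depth_dist or {})}
    qual_dist = {"mean": 35.0, "sd": 2.0, "low_fraction": 0.0, **(qual_dist or {})}
    rng = np.random.default_rng(seed)

    depths = np.maximum(rng.poisson(depth_dist["mean"], size=n_sites), 10)
    n_low_d = int(round(depth_dist["low_fraction"] * n_sites))
    if n_low_d:
        low_d = rng.choice(n_sites, size=n_low_d, replace=False)
        depths[low_d] = rng.integers(1, 10, size=n_low_d)

    quals = np.maximum(
        rng.normal(qual_dist["mean"], qual_dist["sd"], size=n_sites), 25.0
    )
    n_low_q = int(round(qual_dist["low_fraction"] * n_sites))
    if n_low_q:
        low_q = rng.choice(n_sites, size=n_low_q, replace=False)
        quals[low_q] = rng.uniform(10.0, 24.9, size=n_low_q)

    refs = np.full(n_sites, "A", dtype="<U1")
    n_non_a = int(round(non_a_fraction * n_sites))
    if n_non_a:
        non_a = rng.choice(n_sites, size=n_non_a, replace=False)
        refs[non_a] = rng.choice(list("CGT"), size=n_non_a)

    records = []
    for i in range(n_sites):
        depth = int(depths[i])
        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
        if refs[i] == "A":
            g = int(rng.binomial(depth, background_rate))
            counts["G"] = g
            counts["A"] = depth - g
        else:
            counts[str(refs[i])] = depth
        records.append(
            RnaPileupRecord(
                chrom=chrom,
                pos=1000 + i,
                ref=str(refs[i]),
                a=counts["A"],
                c=counts["C"],
                g=counts["G"],
                t=counts["T"],
                mean_quality=float(quals[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Demo locus (synthetic sequences, study-like geometry)
# ---------------------------------------------------------------------------

#: synthetic mutant protospacer: adenines at positions 3 (bystander) and 8
#: (target) are the only A's inside the editing window (3-9)
DEMO_PROTOSPACER_MUT = "GTACCTGACGTCGTCGGTCT"
#: corrected/wild-type counterpart: G at position 8
DEMO_PROTOSPACER_WT = "GTACCTGGCGTCGTCGGTCT"
DEMO_PAM = "CGG"

_DEMO_LEFT = "ATGACCGTTCTGGTCAAGCTTGAGCCAGAT"
_DEMO_RIGHT = "CCTTGGAGAACCTGCATCTTGGACGTACGA"


def example_site() -> TargetSite:
    """Synthetic demo target site with study-like geometry.

    Target adenine at protospacer position 8 (anchored chr3:48,580,586,
    c.5047), bystander adenine at position 3 (chr3:48,580,581, c.5052),
    NGG PAM, protospacer on the minus strand of the written amplicon; the
    protospacer sequence itself is synthetic.
    """
    return TargetSite(
        protospacer=DEMO_PROTOSPACER_MUT,
        pam=DEMO_PAM,
        strand="-",
        target_position=8,
        bystander_positions=(3,),
        window=(3, 9),
        genomic_anchor=GenomicAnchor(
            chrom="chr3", protospacer_position=8, coordinate=48_580_586, sign=1
        ),
        cdna_anchor=CdnaAnchor(protospacer_position=8, value=5047, orientation=1),
    )


def example_alleles() -> list[AlleleSpec]:
    """Compound-heterozygous demo alleles at 50/50 molecular fractions.

    The mutant allele reads T at the target coordinate on the written
    (coding) strand — adenine on the protospacer strand — while the
    wild-type-like allele reads C (G on the protospacer strand), emulating a
    heterozygous C>T nonsense mutation with a 50% mutant-read baseline.
    """
    mut = _DEMO_LEFT + revcomp(DEMO_PROTOSPACER_MUT + DEMO_PAM) + _DEMO_RIGHT
    wt = _DEMO_LEFT + revcomp(DEMO_PROTOSPACER_WT + DEMO_PAM) + _DEMO_RIGHT
    return [
        AlleleSpec(name="mut", sequence=mut, fraction=0.5),
        AlleleSpec(name="wt", sequence=wt, fraction=0.5),
    ]


def example_edit_model(
    target_rate: float = 0.9,
    bystander_rate: float = 0.0,
    correlation: float = 0.0,
) -> EditModel:
    """Edit model on the demo site: target at position 8, bystander at 3."""
    return EditModel(
        site=example_site(),
        per_position_rate={8: target_rate, 3: bystander_rate},
        correlation=correlation,
    )
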