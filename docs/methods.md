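# Methods

## Scope and model

`abequant` quantifies adenine base-editing outcomes at one target locus and a
panel of candidate off-target loci, from three kinds of input: amplicon
deep-sequencing reads (FASTQ, Phred+33, or precomputed per-position count
tables), per-base proportions from Sanger traces, and per-site RNA pileup
records. A companion scanner screens point mutations for ABE targetability.
All statistics are binomial read-count statistics; no alignment to a genome is
performed — reads are anchored by locating the 23-nt protospacer+PAM window
directly, which is appropriate for amplicon sequencing where every read covers
the site.

### Coordinates and geometry

Protospacer positions run 1–20 from the 5' (PAM-distal) end; the 3-nt PAM
occupies window positions 21–23. The editing window defaults to positions 3–9
(configurable per site, since ABE variants differ). Genomic and cDNA
coordinates are affine functions of protospacer position, each defined by
anchoring one protospacer position to a known coordinate plus an orientation
sign; all I/O coordinates are 1-based inclusive.

### Window location

`locate_window` scans a read and its reverse complement for the 23-nt window,
counting mismatches only at positions that carry no editing information: the
editing-window positions and PAM `N` positions are excluded (15 compared
positions for the default NGG/3–9 geometry), so a fully edited read anchors
exactly like an unedited one. Excluding editable positions is load-bearing:
counting them would preferentially drop highly edited reads and bias
efficiency downward. The default budget is 2 mismatches over the compared
positions. A unique best placement wins; a tie at the minimal mismatch count
is ambiguous and the read is dropped (and counted). Reads located on the
reverse strand are re-oriented so all counts are reported on the protospacer
strand. Reads with `N` at a window position contribute to the `N` tally and to
`reads_located` but are excluded from proportion denominators.

### Editing statistics

* Raw editing at a position: `100·k/n` over informative (A+C+G+T) reads.
* Control normalization: `100·(treated% − control%)/(100 − control%)`. The
  control percentage is taken from the matched position of an untreated
  control sample: at the target it is the pre-existing wild-type allele
  fraction (~50% for a compound heterozygote), at bystander positions it is
  the artifact level. Negative normalized values (treated below control) are
  reported with a `negative_normalized` flag, never clamped — clamping would
  hide control contamination.
* Wald CI: `p̂ ± z·√(p̂(1−p̂)/n)`, z = Φ⁻¹((1+confidence)/2) (1.959964 at the
  default 95%), clamped to [0, 100] on the raw scale. The CI is computed on
  the raw proportion and mapped through the normalization; because the
  normalization is affine in the treated percentage, the interval transforms
  exactly. The interval degenerates to a point at p̂ ∈ {0, 100}, a known Wald
  edge case, and treats the control percentage as fixed.
* Sanger efficiency: `100·(baseline_T − T%)/baseline_T`. The heterozygous
  baseline 50 is a default, not a constant; a homozygous locus uses 100.

### Off-target statistic

Over editing-window positions whose protospacer-strand reference base is A or
T, the cumulative statistic pools G reads at ref-A positions and C reads at
ref-T positions (the A·T→G·C editor signature on the duplex) and divides by
the informative reads at those same positions. The opposite reading of the
conversion direction is selectable via `interpretation="gc_to_at"`. Loci with
no A/T reference base in the window are unreportable (error). The per-locus
report flags a treated condition when its Wald CI fails to overlap the
control's CI at the same locus — a deliberately conservative screen, not a
formal test.

### Transcriptome A-to-I

Pileup records are filtered to reference-A sites with depth ≥ 10 and mean
quality ≥ 25 (both inclusive). The phrase "number of adenosines converted to
inosine" is ambiguous between reads and sites, so both estimators are
implemented and labeled: read-level `100·ΣG/Σdepth` (default) and site-level
`100·(#sites with ≥1 G)/#sites`. The quality filter applies to the one quality
summary the pileup TSV carries per site; per-read quality filtering is out of
scope for this input path. Known genomic SNPs are not masked (that would
require external databases); on real data the read-level background therefore
includes homozygous/heterozygous A>G variants, which inflate the absolute
level but cancel in treated-vs-untreated comparisons
(`compare_samples`, a difference of proportions with combined Wald SE).

### Targetability scanning

`find_guides` scans the *mutant* (post-mutation) sequence — the editor must
find its protospacer in the patient genome — on both strands for every
placement where the mutant base reads A on the protospacer strand at a window
position with the PAM pattern (IUPAC, default NGG) immediately 3'. Mutations
whose alt base is neither A nor T are rejected as untargetable by
construction. Candidates are ranked by distance of the target from the window
centre, then by the number of other in-window adenines (bystander exposure),
then by 5'-most placement; the centre-first rule reflects that ABE activity
peaks mid-window and bystander minimization is the practical design concern.
Coding consequences (`classify_ptc`) translate the affected in-frame codon
window pre/post mutation with the standard genetic code; stop gain → `ptc`,
amino-acid change → `missense`, unchanged protein → `silent`, stop loss and
other outcomes → `other`.

## Synthetic data

The generator produces the three input kinds with the statistical structure
the analyses assume, and is itself first-class, tested code.

* **Amplicon reads.** A diploid locus is modelled as two alleles at fixed
  molecular fractions (default 50/50, the compound-heterozygote baseline).
  Each molecule is drawn from an allele, edited, then corrupted — editing
  precedes sequencing error, matching the biology. Editing converts A→G on
  the protospacer strand (equivalently T→C on the written strand when the
  protospacer is on the opposite strand) independently per position at the
  model's marginal rates. A `correlation` knob couples in-window edits to the
  target edit (conditional rate `rate^(1−correlation)`); the default 0
  (independence) is the minimal assumption when only marginal rates are
  known, and the realistic joint value is unknown. Substitution errors are
  uniform over the three alternative bases; qualities are Gaussian on the
  Phred scale, clamped to [2, 40], written Phred+33. Reads are full-amplicon
  and unpaired; indels, PCR jackpots, and paired-end structure are not
  modelled. A fixed seed reproduces FASTQ output byte-for-byte.
* **Sanger sites.** The T proportion is the truth plus Gaussian noise
  truncated to [0, 100]; the remainder is called C.
* **RNA pileups.** Reference-A sites carry Binomial(depth, background) G
  reads. Depths are Poisson floored at 10 and qualities Gaussian floored at
  25, except for configurable fractions of sites forced *below* each
  threshold — these exist specifically to exercise the filters, and the
  flooring makes the pass/fail partition exact by construction.

What passing tests on this generator do **not** show: robustness to indels or
misalignment, PCR amplification bias, position-dependent error profiles,
strand bias, or SNP contamination of the A-to-I background. The generator is a
model of the counting statistics, not of a sequencer.

## Default parameters and problem sizes

| Parameter | Default | Rationale |
|---|---|---|
| allele fractions | 0.5 / 0.5 | compound-heterozygous baseline |
| editing window | (3, 9) | standard ABE8e-class window |
| target / bystander position | 8 / 3 | demo-site geometry |
| max_mismatch | 2 of 15 compared positions | tolerate error without mislocation |
| substitution error | 0.002 | Illumina-scale per-base error |
| confidence | 0.95 (z = 1.959964) | convention |
| RNA filters | depth ≥ 10, quality ≥ 25 | low-coverage/low-quality exclusion |
| RNA background | 0.001 | endogenous A-to-I scale |

Statistical checks in the suite run at sizes chosen to make 3-SE bands tight
relative to the effects tested: parameter recovery at depth 20,000 and rates
{0.1, 0.5, 0.9}; Wald coverage over 1,000 replicates at p = 0.9, n = 2,000;
A-to-I recovery over ~10⁵ pooled reads; the off-target error-model check pools
five 20,000-read replicates. Oracle-equivalence checks (counting, the
cumulative statistic, guide enumeration) compare against literal brute-force
implementations on ≤100-read / ≤100-nt instances.

## Numerical and degenerate-input choices

Percentages are kept at full precision internally and rendered to one decimal
in TSV reports. Zero informative reads at a queried position, a 100% control
(degenerate normalization denominator), an empty filtered pileup, a window
with no A/T reference base, and a zero Sanger baseline are all errors, not
silent zeros. Ambiguous window placements are dropped and counted rather than
guessed. The demo locus (`example_site`, `example_alleles`) uses synthetic
sequences with the study-like geometry described above; its coordinate anchors
(position 8 ↦ chr3:48,580,586 / c.5047, orientation such that genomic
coordinate increases with protospacer position while the c. coordinate
decreases) make the affine coordinate maps concrete and testable.

## Known limitations

Indel outcomes and allele phasing are out of scope; the off-target flag is a
CI-overlap screen without multiplicity control; the Wald interval undercovers
near the boundaries (by construction — it is the field's reporting
convention, not the best available interval); the targetability scanner does
not score guide activity (no CFD/Doench or learned bystander models) and its
fraction-targetable summaries depend on the window convention chosen.
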