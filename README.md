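# abequant

Quantification of adenine base-editing (ABE) outcomes from sequencing data.

Adenine base editors convert A·T base pairs to G·C within a narrow editing
window of their 20-nt protospacer, which makes them attractive for reverting
pathogenic C>T/G>A point mutations — for example premature-termination-codon
(PTC) mutations in *COL7A1* that cause recessive dystrophic epidermolysis
bullosa. Scoring such an experiment means answering five questions from
sequencing data: how many alleles were corrected at the target adenine, how
often the other window adenines (bystanders) were converted, whether candidate
off-target loci show any A·T→G·C signal, whether the transcriptome shows excess
A-to-I editing, and — before any of that — whether a given mutation is
targetable at all (an NGG PAM must place the mutant adenine inside the window).
`abequant` implements all five analyses for amplicon deep sequencing, Sanger
traces, and RNA pileups, plus a synthetic-data module that generates inputs
with the structure these analyses assume (compound-heterozygous diploid
alleles, per-position editing rates, sequencing error), so the whole pipeline
is testable without any external data.

## The statistics

For a window position with `n` informative reads (A+C+G+T) of which `k` carry
the edited base G, the raw editing percentage is `p̂ = 100·k/n`. Because a
compound-heterozygous patient already carries ~50% wild-type reads at the
target, raw percentages are normalized against a matched untreated control:

    efficiency% = 100 · (p̂_treated − p̂_control) / (100 − p̂_control)

which maps the control baseline to 0 and complete conversion to 100. The same
normalization is applied to bystander positions (whose control percentage
reflects sequencing artifacts). Uncertainty uses the Wald binomial interval
`p̂ ± z·√(p̂(1−p̂)/n)` (z = 1.959964 at 95%), computed on the raw proportion and
mapped exactly through the affine normalization.

Sanger traces are scored from the per-base proportions at the mutation locus:
`efficiency% = 100·(T_baseline − T%)/T_baseline`, with T_baseline = 50 for a
heterozygous locus.

Off-target loci are scored by the cumulative conversion statistic over window
positions 3–9: G reads where A is expected plus C reads where T is expected,
divided by the informative reads at those same reference-A/T positions.

Transcriptome A-to-I editing keeps reference-A pileup sites with depth ≥ 10
and mean quality ≥ 25, then reports `100·ΣG/Σdepth` over retained sites
(inosine reads as G).

## Worked example

Simulate a heterozygous locus (50% mutant reads) edited at a true target rate
of 0.9 and bystander rate of 0.5, then quantify against an unedited control:

```python
import abequant as ab
from abequant.editquant import dose_table

site = ab.example_site()          # target A at position 8, bystander at 3
alleles = ab.example_alleles()    # mut/wt at 50/50

treated = ab.simulate_amplicon_reads(
    alleles, ab.example_edit_model(target_rate=0.9, bystander_rate=0.5),
    ab.SeqNoise(depth=2000, sub_error=0.002, seed=11))
control = ab.simulate_amplicon_reads(
    alleles, ab.example_edit_model(0.0, 0.0),
    ab.SeqNoise(depth=2000, sub_error=0.002, seed=12))

target, bystanders = ab.quantify_condition(
    ab.count_bases(treated, site), ab.count_bases(control, site))
print(dose_table([("high", target, bystanders)]).round(1).to_string(index=False))
```

```
condition  window_pos      role ref_base edited_base    n  raw_pct  control_pct  normalized_pct  ci_low  ci_high flags
     high           8    target        A           G 2000     94.8         50.6            89.6    87.6     91.5
     high           3 bystander        A           G 2000     50.1          0.2            50.0    47.8     52.2
```

The raw G percentage at the target (94.8%) includes the pre-existing wild-type
allele; normalizing against the control's 50.6% recovers the simulated editing
rate (89.6%, true value 90), with the 95% Wald CI covering it. The bystander
position has essentially no control signal, so its normalized value tracks the
raw 50%. The same objects feed the off-target report
(`abequant.offtarget_report`), the RNA summary (`abequant.a_to_i_summary`),
and the Sanger estimator — e.g. a trace with 18% residual T over the 50%
heterozygous baseline scores `sanger_efficiency = 64.0`%.

A command-line interface mirrors the workflow:

```bash
abequant simulate --seed 7 --out demo/
abequant quantify --treated demo/treated.fastq --control demo/control.fastq --out demo/reports
abequant rna --pileup demo/rna_pileup.tsv --out demo/reports
abequant design --mutations mutations.tsv --out demo/design
```

Every run writes a `manifest.json` (version, parameters, seed); reruns with
the same seed reproduce FASTQ outputs byte-for-byte.

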