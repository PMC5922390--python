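# Methods

## Problem and scope

A matched tumor/normal design labels every tumor variant's origin directly:
a variant present in the normal genome is inherited (germline), one absent
from it arose somatically. A tumor-only design must instead guess origin
from population databases, and the guess fails in both directions — rare
germline variants are reported as somatic (false positives), and recurrent
somatic mutations archived in the database are filtered away (false
negatives). This package audits that trade-off on a 35-gene panel. Read
alignment and raw variant calling are out of scope: the pipeline starts
from per-patient small-variant calls (VCF or a flat table) with tumor and
normal read counts, restricted to missense/nonsense SNVs inside the panel
intervals.

## Origin classification

The matched-normal caller behind the original data is proprietary, so
origin is assigned by a documented evidence-threshold classifier over read
counts. With VAF = alt reads / depth:

| parameter | default | meaning |
|---|---|---|
| `min_tumor_alt` | 4 reads | minimum tumor alt support to call anything |
| `min_tumor_vaf` | 0.05 | minimum tumor VAF |
| `germline_min_normal_alt` | 4 reads | normal alt support for a germline call |
| `germline_min_normal_vaf` | 0.20 | normal VAF for a germline call |
| `somatic_max_normal_alt` | 1 read | normal alt support tolerated in a somatic call |
| `somatic_max_normal_vaf` | 0.02 | normal VAF ceiling for a somatic call |

A variant failing the tumor minima is *unassigned*; normal evidence between
the somatic ceiling and the germline floor (normal VAF in [0.02, 0.20) with
≥ 2 alt reads) is *ambiguous*. Both are excluded from every downstream tally
and reported separately — borderline normal evidence is not forced either
way. These are conventional paired-calling heuristics at ~30× normal / ~60×
tumor depth; the audit logic downstream is threshold-agnostic, and a
fixture mode consumes a trusted origin column directly (transcribed
published tables, synthetic ground truth). The label is monotone in normal
evidence: more normal alt reads can never move a call from germline toward
somatic.

## Cohort-common variants and the rescue rule

"Allele frequency in the sample" is implemented as **carrier frequency**
(carriers / N patients), not an allelic fraction over 2N chromosomes,
because somatic variants have no diploid allele count and the generator
collapses genotypes to carrier/non-carrier anyway; the comparison is strict
(> 0.02). The AF-regime rescue rule removes variants that have no reported
population AF but are database members *and* cohort-common with at least
one germline observation — the restriction to germline-observed sites keeps
recurrent somatic hotspots (which can be database-archived without a
frequency) from being rescued out, which would create false negatives the
matched design never produces.

## Filter regimes

`database_membership` removes every database member. `af_threshold@c`
removes variants with reported AF ≥ c (inclusive, matching the stated
filter definitions) plus the rescue-rule removals. Variants that are
neither AF-annotated nor rescued are always retained: public AF estimates
bottom out around 1e-4, so absence of a frequency is informative of rarity,
not of somatic origin. Structural consequences: lowering the cutoff can
only grow the removed set, so retained(0.001) ⊆ retained(0.01) and FP(0.001)
≤ FP(0.01); when every AF-annotated variant is also a database member, the
membership filter removes a superset of any AF filter.

## Expression assessment

A variant is *not assessable* when RNA coverage at the locus is below
`min_assessable_depth` (default 10 reads) or no RNA count record exists;
otherwise it is *expressed* if alt support reaches `min_alt_reads` (3) and
alt fraction `min_alt_fraction` (0.05). Only assessable calls enter
denominators. The thresholds are conservative pileup heuristics; the
summary arithmetic is independent of them, and allele-specific expression,
RNA editing and isoform structure are deliberately not modeled.

## Synthetic cohorts

The generator emulates the *structure* of a paired panel study, not any
particular tumor biology. Per gene it plants one common SNP with AF ~
U(0.05, 0.40), carried per patient with Hardy–Weinberg carrier probability
1−(1−AF)²; rare/private germline variants arrive at 0.02 per kb of CDS per
patient (panel total ≈ 110 kb → ≈ 2.2 per patient), placed
length-proportionally with AF ~ U(1e-5, 5e-4). Somatic events are Poisson
with mean 0.9 per patient, gene chosen CDS-length-proportionally with a 4×
driver-gene enrichment, and 25% of events recur at four fixed hotspot sites
(two in KRAS, two in PIK3CA). These defaults give an expected
germline:somatic mix of ≈ 95:5 at 600 patients. Annotation is deliberately
incomplete: common sites are always database members but lack a reported AF
with probability 0.15 (exercising the rescue rule); rare sites are members
with probability 0.6; hotspots are members with probability 0.5, always
AF-absent; other somatic sites are absent from the database. Expression
dropout is Bernoulli per variant: 0.18 somatic, 0.10 germline. Read depths
default to 60× tumor / 30× normal / 50× RNA with germline VAF 0.5 and
somatic VAF 0.4.

Sequencing noise is **off by default**: evidence is a deterministic
function of depth and VAF, so classification and expression tests against
ground truth are exact. `sequencing_noise=True` switches depths to Poisson
and alt counts to Binomial (with a 0.001 error rate for somatic normal
reads), under which classification discordance stays well under 2% at the
default depths. Everything is reproducible byte-for-byte from the single
seed.

What the generator does *not* emulate: linkage disequilibrium, mutational
signatures, subclonality and purity, copy-number-distorted VAFs, and —
because the config splits germline AFs into a common (> 0.02) and a rare
(< 0.001) class with nothing in between — a continuous allele-frequency
spectrum. That last gap means the AF ≥ 0.01 and AF ≥ 0.001 regimes produce
identical partitions on synthetic cohorts (their ordering properties then
hold with equality); on real data, intermediate-frequency variants separate
them. Passing tests therefore demonstrate the correctness of the
accounting, not the real-world magnitude of the difference between the two
AF cutoffs.

## Numerical and reporting conventions

Coordinates are 1-based closed (VCF convention); multi-allelic records are
split, indels dropped with a logged count; contig names must match exactly
across files unless chr-prefix normalization is explicitly enabled. An
absent population AF is represented as missing, distinct from AF = 0. Table
percentages are integers rounded half-up and always re-derived from the
row's own counts; full-precision fractions live only in the JSON summary.
The per-patient burden mean is taken over patients with ≥ 1 retained call
(zero-variant patients are excluded from that mean but counted in the
any-FP fractions); burden histograms list patients above the display cap
(default 30 calls) as excluded outliers rather than binning them. The
gene-size correlation uses unique-site counts (not occurrence counts)
against the packaged CDS lengths, which come from canonical transcripts;
the correlation on real data therefore depends on the transcript set chosen
and is a qualitative, not exact, target.

## Problem sizes

Default analyses simulate 600 patients (≈ 10,500 variants); the test suite
uses 40–150-patient cohorts for unit-level checks and five 600-patient
seeds for parameter-recovery checks, sizes at which binomial standard
errors on the recovered fractions are a fraction of a percentage point.
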