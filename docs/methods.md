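# Methods

This note documents the models, parameter choices and numerical conventions
behind `balscan`, and what the synthetic-data tests do and do not establish
about real sequencing data.

## Genetic model

A strain carries a recessive lethal mutation homozygous on both chromosome I
homologs, kept alive by a free duplication that contributes a third,
wild-type copy of the leftmost interval (default 7.3 Mbp, configurable).
Copy dosage drives both observables the pipeline uses:

* **Allelic ratio.** At a site mutant on `m` of `t` copies, the expected
  fraction of alternate-supporting reads is `m/t`: 2/3 for a balanced
  lesion or the marker under the duplication, 1 for a homozygous site
  outside it, 1/3 for a single mutant copy. The ratio is computed as
  alt/(alt+ref); the alternative alt/ref reading would exceed 1 at balanced
  sites and cannot reproduce the 66%/100%/33% expectations, so it is not
  used.
* **Read depth.** Mean depth is proportional to copy number: 3 inside the
  duplicated interval, 2 outside. The duplication statistic
  `D = 1 − depth_out/depth_in` is therefore 1/3 with the duplication and 0
  without it. `D` is normalized by the *duplicated* interval's depth so its
  analytic value is 1/3 (a one-third excess); normalizing by the remainder
  would give 1/2 and is deliberately not used.

## Quality control

Marker states are banded on the observed ratio with boundaries midway
between the analytic expectations 0, 1/3, 2/3 and 1: `absent < 0.10 ≤
single_copy < 0.45 ≤ balanced < 0.85 ≤ homozygous`. The duplication is
called present when `D ≥ 1/6`, the midpoint between the two analytic
values; at 30X with 10 kb windows the sampling noise of `D` is far smaller
than 1/6 (hundreds of windows per side), so both error rates are
negligible — the false-positive rate on flat tracks is measured by
simulation in the test suite and is below 1%. At least 5 windows on each
side are required; fewer is an error, not a call. A strain is excluded when
any marker misses its expected band or the duplication is absent. The
EMS-spectrum summary (fraction of SNVs that are G>A/C>T, computed over
strain-private calls when the parental background is supplied) is reported
for inspection but is not an exclusion criterion.

## Filters

The three filters are pure predicates — background-key subtraction, the
inclusive allelic-ratio window [0.40, 0.90], and location (duplicated
interval; coding) — so they commute and are idempotent. The window bounds
are taken as inclusive; at depth 30 the probability mass exactly on a
boundary is negligible either way. The coding filter keeps, besides CDS
overlaps, the two intronic bases at each CDS junction, so splice-signal
candidates are not lost to the location rule. Retention of a balanced site
at depth `n` is the exact binomial tail `P(0.4 ≤ X/n ≤ 0.9)`, `X ~
Binomial(n, 2/3)` — about 98% at n=30 — and the test suite checks the
empirical retention against this tail.

## Consequence classification

SNVs in a CDS are classified by translating the reference and alternate
codon (standard genetic code, minus-strand genes on the coding strand):
stop-gain → nonsense, amino-acid change → missense, silent → synonymous.
Stop-loss and start-loss fold into missense to keep the seven-category
scheme closed. The splice signal is exactly the 2 intronic bp at each
intron end (the canonical GT..AG minimal signal). Indels change the frame
according to the number of *coding* bases inserted or deleted only (an
indel spanning a CDS/intron boundary counts just its coding part); a net
change that is not a multiple of 3 is a frameshift, otherwise
frame-preserving. An indel touching only splice-signal bases is a
splice-signal disruption; anything else is noncoding. A variant overlapping
several gene models keeps the most severe classification and is flagged
ambiguous. The classifier is validated against a brute-force oracle that
mutates the chromosome, re-extracts and re-translates the full CDS.

## Ranking

Severity is ordinal: nonsense 6, frameshift 5, splice signal 4, in-frame
indel 3, missense 2, synonymous 1, noncoding 0. The order within the
null-like pair (nonsense vs frameshift) is a convention, not a claim, and
is configurable. A variant inside the strain's genetically mapped zone
gains +0.5 — deliberately smaller than one severity step, since confirmed
lesions do occur outside their mapped zone. Ties break by allelic-ratio
proximity to 2/3, then by position, making reports deterministic.
Synonymous and noncoding variants are never candidates; a strain left with
only those yields "no candidate".

## Enrichment and expression

Per-category enrichment uses Pearson's χ² on 2×2 tables without continuity
correction (a flag enables it); a zero margin is flagged undefined rather
than raised. Raw p-values are primary; a Bonferroni column (adjusted for
the number of categories) is always attached. Sampling profiles draw
equal-size gene sets without replacement, 1000 iterations by default, and
report per-category mean ± standard error. Genes holding several category
labels count once per category.

Expression profiles span 23 embryonic 30-minute bins (0–660 min), L1–L4,
pre-gravid and gravid adult, with an optional germline-less comparator
column. Per-gene values are total normalized reads over coding bases
divided by CDS length. Clustering is agglomerative with average linkage on
Euclidean distances of row-standardized profiles (the algorithm family is
given; linkage and metric are this package's choice and configurable), cut
at k=7. The maternal-contribution rule formalizes a verbal description:
maternal iff mean expression over the 0–150 min bins and the gravid-adult
value both exceed 2× the mean larval expression (any positive signal
qualifies when larval expression is exactly zero). The 2× factor and the
150-min early window are heuristics; the germline-less column is advisory
and not part of the boolean rule.

## Synthetic strain generator

The generator reproduces the structure the analysis assumes, with defaults
set to the screen's reported conditions:

| parameter | default | meaning |
|---|---|---|
| chromosome_length | 15 Mbp | one chromosome |
| dup_end | 7.3 Mbp | duplicated interval [0, dup_end) |
| n_genes / genes_in_dup_fraction | 300 / 0.6 | non-overlapping 2–4-exon genes |
| essential_fraction | 0.25 | genes whose loss is lethal |
| n_zones | 60 | map zones tiling the duplication |
| parental_snvs / parental_indels | 571 / 167 | background load, uniform |
| strain_snvs_mean / strain_indels_mean | 44 / 7 | Poisson per-strain counts in the duplicated interval |
| ems_transition_fraction | 0.9 | G>A/C>T share of EMS SNVs |
| coverage | 30 | mean reads per site for 2 copies |
| depth_window | 10 kb | depth-track resolution |

Gene models are frame-safe (ATG start, single terminal stop, no internal
stops, canonical GT..AG introns), so planted consequences can be verified
by translation. Chromosome length, gene count and gene sizes are this
package's choices for a realistic single-chromosome substrate; the
mutagen's transition share is reported only qualitatively in the
literature, so 0.9 is a stated stand-in, not a measured value. Per-strain
variant counts are Poisson around the reported means, which are given only
as averages. The causal variant is always at 2-of-3 dosage — the genetics
of rescue by a wild-type copy forces this — and is planted as a nonsense,
splice, missense or frameshift lesion in an essential gene under the
duplication (EMS-compatible substitutions preferred). Indel lengths are
uniform on {1, 2} bp. Background sites are homozygous on every copy (3/3
under the duplication), so they sit near ratio 1 and are removed both by
key subtraction and, largely, by the ratio window. Duplication-loss strains
get homozygous markers, no causal variant and flat depth.

Read sampling: per-site depth ~ Poisson(coverage · copies/2), alternate
count ~ Binomial(depth, m/t); window depth is the mean of per-base Poisson
coverage. **Not modelled:** read-level errors, mapping artifacts,
alignment-induced indel ambiguity, GC-coverage bias, contamination, and
recombination/duplication-loss lineage dynamics. Passing recovery tests on
this generator therefore demonstrates the correctness of the dosage
arithmetic, filters and ranking logic — not robustness to alignment or
calling artifacts in real data, which enter upstream of this pipeline.

All randomness flows from a single master seed; strains use derived
sub-seeds (master + index), so cohorts are byte-reproducible and
individually regenerable.

## Problem sizes used in the tests

The test suite simulates one 50-balanced + 10-duplication-loss cohort at
full default geometry (15 Mbp chromosome, 30X) for recovery and exclusion
checks, 400 flat tracks on a 1.5 Mbp chromosome for the false-positive
estimate, ≥1200 random substitutions for the classifier/oracle comparison,
20 000 binomial draws for the ratio-window retention check, and 84 profiles
(12 per template) for clustering recovery. These sizes put simulation error
well below the tested tolerances while keeping the suite fast.

## Known limitations

* Multi-isoform genes are handled by classifying against every overlapping
  model and keeping the most severe call; the generator itself emits
  single-isoform genes.
* The severity order between nonsense and frameshift is conventional.
* The coding filter and classifier consider only CDS/splice structure; no
  promoter, UTR or regulatory annotation.
* Enrichment p-values on real annotation snapshots are not reproduced here;
  the module implements the statistics, not the historical annotation
  state.
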