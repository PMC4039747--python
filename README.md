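# balscan

Causal-mutation identification for balancer-duplication lethal screens in
*Caenorhabditis elegans*.

## The problem

Recessive lethal mutations cannot be kept as homozygous stocks. In a
balancer screen they are induced with EMS in a strain that carries a *free
duplication* — an extrachromosomal fragment holding wild-type copies of the
left arm of chromosome I (sDp2, ~7.3 Mbp). An animal homozygous for a lethal
mutation under the duplication survives because the fragment supplies a
third, wild-type allele. After whole-genome sequencing of such a strain, the
causal lesion has a characteristic signature:

* it lies **inside the duplicated interval**;
* it is present on 2 of the 3 copies of that interval, so its **allelic
  ratio** (alt reads / total reads) sits near **2/3** rather than 1;
* it disrupts a **coding sequence or splice signal** of an essential gene.

`balscan` implements the corresponding analysis for cohorts of sequenced
strains:

1. **QC** — verify the two phenotypic marker mutations at their expected
   ratios (2/3 for the marker under the duplication, 1 outside it; a ratio
   near 1/3 flags a single mutant copy), and confirm the duplication from
   windowed read depth: with 3 copies inside and 2 outside, the statistic
   `D = 1 − depth_out/depth_in` is 1/3; strains with flat depth lost the
   duplication and are excluded.
2. **Filtering** — subtract the parental strain's background variants, keep
   calls with allelic ratio in [0.40, 0.90], restrict to the duplicated
   interval and to coding sequence (CDS plus the 2 bp intronic splice
   signals).
3. **Consequence classification** — each surviving variant is categorized
   as nonsense, missense, synonymous, splice-signal disruption,
   frameshifting indel, frame-preserving indel or noncoding, with
   amino-acid change notation such as `Q > *`.
4. **Ranking** — candidates are ordered by severity; the strain's genetic
   map zone adds a small tie-breaking bonus (a guide, never a gate), and a
   strain whose surviving variants are all synonymous/noncoding yields
   "no candidate".

Two companion analyses are included: per-category χ² enrichment of a gene
set against a comparison pool with equal-size random-sampling reference
profiles (1000 iterations, mean ± SE), and stage-resolved expression
analysis (per-CDS normalization, agglomerative clustering of the
developmental time course into seven stage patterns, and a
maternal-contribution call).

Because the screen's raw sequencing data are not public, the package ships
a **synthetic strain generator** that reproduces the statistical structure
above — 571 background SNVs + 167 background indels, ~44 EMS SNVs and ~7
small indels per strain (G>A/C>T-biased), one planted causal variant per
balanced strain, 3:2 copy structure, Poisson depth and binomial allele
counts — together with ground-truth records for parameter-recovery tests.

## Worked example

```bash
balscan simulate --out demo --seed 11 --n-strains 4 --n-unbalanced 1
balscan qc --cohort demo
balscan run --cohort demo
```

The QC table shows the depth statistic at ~1/3 for balanced strains and ~0
for the planted duplication-loss strain, which is excluded with its reason:

```text
strain_id   duplication_present  depth_statistic  ems_transition_fraction  exclude  reasons
strain_001  True                 0.3333           0.891…                   False
strain_002  True                 0.3333           0.891…                   False
strain_003  True                 0.3334           0.972…                   False
strain_004  True                 0.3334           0.954…                   False
strain_005  False                -0.0             0.878…                   True     marker dpy_marker: observed state 'homozygous' (ratio 1.0), expected 'balanced'; duplication absent (depth statistic D = -0.000)
```

`balscan run` then filters, annotates and ranks each passing strain; with
truth records present it also reports recovery of the planted causal
variant:

```text
strain_id   excluded  gene_id    category  aa_change  recovered
strain_001  False     gene_0006  nonsense  L > *      True
strain_002  False     gene_0127  nonsense  E > *      True
strain_003  False     gene_0074  nonsense  Y > *      True
strain_004  False     gene_0101  nonsense  Q > *      True
strain_005  True                                      True
# strains=5 excluded=1 recovery=1.000 (of 5 with truth)
```

Each row is one strain: the nominated gene, the consequence category of the
top-ranked candidate and its amino-acid change (`L > *` is a leucine codon
turned into a stop). `recovered=True` means the top candidate is exactly
the planted causal variant (for the excluded strain it means the exclusion
was correct).

The same steps are available as library calls
(`balscan.simulate_cohort`, `balscan.run_cohort`, …); see `docs/methods.md`
for the model details and parameter defaults.

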