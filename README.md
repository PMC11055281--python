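# autozyg

Autozygosity mapping and recessive-variant discovery for livestock herds.

When a handful of related calves in a closed beef herd collapse under
exercise, the classic discovery path is: genotype the herd on a SNP array,
find the region where every affected animal is homozygous for the same
ancestral haplotype, sequence a couple of cases, filter the genome-wide
variant list down to the one allele that fits recessive inheritance, annotate
its protein consequence, and design a cheap restriction-digest (RFLP) assay
to genotype everyone else. `autozyg` implements that whole path as a tested,
reusable library — together with a forward herd simulator that generates the
exact study design (a de novo nonsense allele descending from one founder
bull through a line-bred pedigree), so every stage can be validated against
known truth without any external data.

It is aimed at quantitative/livestock geneticists and students who want a
desk-scale, fully inspectable version of a recessive-disease mapping study.

## What it computes

* **Herd simulation** (`autozyg.herdsim`) — pedigree with line breeding,
  Mendelian gene drop of a causal allele from one founder, phased marker
  haplotypes under a Haldane crossover model conditioned on the causal
  transmissions, SNP-array genotypes with error/missingness, WGS variant
  tables (case / herd / external cohorts), glycogen phenotypes, a 20-exon
  gene model carrying the causal C>T, and the reference sequence.
* **Homozygosity mapping** (`autozyg.roh_mapping`) — marker QC (MAF and
  call-rate thresholds), per-animal runs of homozygosity, the case-shared
  homozygous region, per-SNP control homozygosity for the case alleles,
  refinement to the low-homozygosity core, and a per-marker two-sided Fisher
  exact recessive association scan with Bonferroni control.
* **Carrier typing** (`autozyg.haplotype_carrier`) — the suspect haplotype
  read directly off homozygous cases; copy counting by genotype
  compatibility; detection of recombination-truncated haplotypes.
* **Variant filter cascade** (`autozyg.variant_cascade`) — biallelic sites
  homozygous-alternative in all cases → minor allele frequency < 0.15 →
  ≤ 1 other homozygote → ≤ 2 external-cohort heterozygotes → predicted
  protein impact → absent from other breeds, with per-stage counts and
  region enrichment.
* **Consequence annotation** (`autozyg.consequence_annot`) — codon-level SNV
  effects with HGVS-style c./p. labels, protein truncation fraction, and the
  nonsense-mediated-decay (NMD) 50-nt rule: a premature stop more than 50 nt
  upstream of the last exon–exon junction is an NMD candidate.
* **Assay design** (`autozyg.assay_rflp`) — exact-match in-silico PCR and
  IUPAC-aware restriction digestion (Type IIS offsets supported), plus an
  allele-discriminating enzyme search around a known SNV.
* **Statistics** (`autozyg.phenostats`) — Welch t-tests (from raw data or
  published summary statistics), one-way ANOVA with Bonferroni pairwise
  correction, fold changes, CIELAB hue angle / chroma / a\*/b\*, cook loss.
* **Orchestration** (`autozyg.pipeline`, CLI `autozyg`) — `run_all` chains
  every stage and writes a deterministic report bundle.

## Worked example

```bash
autozyg run-all --seed 7 --out out/
```

prints

```
reports written to out
cascade: input=5001 -> case_hom_biallelic=822 -> maf_lt_0.15=364 ->
  other_hom_le_1=1 -> external_het_le_2=1 -> protein_impact=1 ->
  not_in_other_breeds=1
```

Reading the bundle: 5,001 WGS variants enter the cascade (5,000 background
plus the planted causal SNV); 822 are biallelic and homozygous-alternative
in both sequenced cases; 364 also have MAF < 0.15 across all samples; the
other-homozygote rule collapses those to 1 — the planted causal variant —
which survives every remaining stage. `candidate_annotations.tsv` reports it
as a nonsense SNV, `p.Arg650*` at codon 650 of an 842-residue protein in
exon 16 of 20, truncating 22.9% of the protein, with `nmd_candidate=True`
(the stop is far upstream of the last junction, so no protein is expected).
`carrier_report.tsv` types all 250 animals for the suspect haplotype
(seed 7: 149 / 94 / 7 animals with 0 / 1 / 2 copies), and `rflp_report.tsv`
shows the designed digest: the wild-type amplicon cuts into 123 + 118 bp
while the variant allele yields one uncut 241 bp fragment, so the three
genotypes are distinguishable on a gel.

The same objects are available from Python:

```python
from autozyg import SimConfig, simulate_herd
from autozyg.pipeline import PipelineConfig, run_all

result = run_all(PipelineConfig(sim=SimConfig(seed=7), out_dir="out"))
result.cascade.stage_counts      # [5001, 822, 364, 1, 1, 1, 1]
result.carrier_tally             # {0: 149, 1: 94, 2: 7}
result.candidate_annotations     # nonsense call with NMD flag
```

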