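# Methods

This note documents the models, defaults, and numerical conventions behind
`autozyg`, and what the simulation-based tests do and do not demonstrate.

## The discovery model

The package assumes a fully penetrant autosomal recessive allele that arose
de novo in a single founder sire of a closed, line-bred herd. Affected
animals are therefore autozygous around the causal locus: both chromosomes
descend from the one founder haplotype that carries the allele. Discovery
proceeds as the field does it: array-based homozygosity mapping localizes
the shared-descent region; whole-genome sequencing of a small number of
cases plus cohort-level genotype filters isolate candidate variants;
coding-consequence annotation and cross-breed absence single out the causal
allele; and an allele-specific restriction digest turns it into a herd
genotyping assay.

## The herd simulator

`herdsim` generates the study design rather than a generic population:

* **Pedigree.** `n_founders` unrelated founders (default 40, alternating
  sex); `n_generations` (5) rounds of `n_matings_per_generation` (21)
  matings with `n_offspring_per_mating` (2) calves each, ~250 animals
  total. A fraction `line_mating_fraction` (0.8) of sires and dams are
  drawn from the founder bull's descendants; from generation 2 one mating
  per generation is forced line x line, so matings with the founder on both
  parental paths — the topology that can produce affected calves — always
  exist.
* **Gene drop and ascertainment.** The founder is heterozygous; every
  meiosis transmits either allele with probability 1/2. The drop is
  rejection-sampled until the final generation contains at least
  `min_affected_last_gen` (4) homozygotes. This conditioning is the
  simulator's analogue of ascertainment: the study design exists only
  because affected calves appeared. It biases the accepted drops toward
  more carrier transmissions, exactly as real case ascertainment does.
* **Recombination.** Haldane model: per meiosis and chromosome a Poisson
  crossover count at `recombination_rate` with breakpoints uniform in bp
  (linear bp<->cM map, no interference). Desk chromosomes are 10 Mb stand-ins
  for ~50–100 Mb cattle chromosomes, so the default rate is 10 cM/Mb,
  keeping a realistic ~1 Morgan map length per chromosome; this is what
  makes the shared-descent region sub-chromosomal after five generations.
  On the causal chromosome each gamete's strand choice is anchored at the
  causal position so marker descent is always consistent with the gene drop.
* **Markers.** 300 jittered, ~evenly spaced biallelic SNPs per chromosome;
  allele-B frequency ~ Uniform(0.05, 0.95). Inside a ±1.5 Mb window around
  the causal locus, marker allele-B frequencies are drawn from
  Uniform(0.05, 0.30) and the causal-bearing founder haplotype carries
  allele B there. This reproduces a stated property of the mapped region in
  this study design — only a few percent of control animals homozygous for
  the case alleles — which an i.i.d. founder-haplotype model cannot produce
  (the founder's allele would be the major allele about half the time,
  giving ~45% expected control homozygosity and no low-homozygosity core to
  refine toward).
* **Array noise.** Genotyping errors replace the true dosage with one of
  the other two states uniformly (rate 0.001); missingness is 0.005. The
  noise-free matrix is retained as test truth.
* **WGS table.** 5,000 background biallelic SNVs (2% multiallelic) with
  i.i.d. Hardy–Weinberg genotypes at Uniform(0.05, 0.95) allele
  frequencies, for 2 sequenced cases, 35 herd controls, and 50 external
  animals; 1% missingness. Herd WGS controls are drawn from unaffected
  animals — affected calves died, were sold, or are the sequenced cases, so
  they do not appear in control cohorts. The causal SNV is planted with
  genotypes implied by the gene drop; the external cohort carries zero
  alternative alleles there (the de novo assumption). A synthetic
  other-breed evidence table marks each background variant "seen elsewhere"
  with probability 0.9 (standing variation) and the causal variant never.
* **Gene model and reference.** A plus-strand, fully coding 20-exon
  transcript (126 bp coding per exon, 135 in the last; 2 kb introns)
  encoding an 842-residue protein, positioned so the causal C>T converts
  codon 650 (CGA→TGA) in exon 16, >50 nt upstream of the last junction.
  The rest of the reference is uniform random sequence, generated
  per-chromosome from independent seed streams.
* **Phenotypes.** Muscle glycogen ~ Normal(189.3, 7.4) mmol/kg for affected
  animals and Normal(101.0, 6.2) for others. The source summaries report
  "±" without naming SD or SEM; the simulator treats them as SD
  (conservative, and overridable in `SimConfig`).

What the simulator does **not** emulate: linkage disequilibrium among
background markers and variants (all i.i.d. given descent), realistic
site-frequency spectra, genotype likelihoods, selection, X-linked
inheritance, or structural variants. Passing recovery tests therefore shows
the pipeline's logic is correct under the assumed inheritance model — not
that its thresholds are optimal for any particular real panel.

## Mapping conventions

* **Marker QC**: drop markers with MAF < 1e-4 or call rate < 90%.
* **ROH** (`call_roh`): greedy left-to-right maximal windows with at most
  `max_het` heterozygotes (1) and `max_missing` missing calls (2), at least
  `min_snps` (15) markers and `min_length_bp` (500 kb) span; greediness
  guarantees non-overlapping segments. The study's original tool parameters
  are unpublished, so every knob is explicit.
* **Shared region**: maximal runs of markers at which every case is
  homozygous for the same allele; missing case genotypes are compatible
  (they never shatter a true autozygous segment) but cannot determine the
  allele on their own. Strict runs separated by one marker at which at most
  one case deviates are merged (`merge_shared_runs`) — the shared-region
  analogue of the heterozygote allowance every ROH caller applies, since a
  single array error in one case otherwise splits the true region; the
  conflicted marker is excluded from the merged marker set.
* **Envelope bounds**: a region's autozygosity boundary lies somewhere in
  the gap beyond its terminal markers, so each region carries outer
  "envelope" coordinates (up to the adjacent non-qualifying markers) used
  for containment tests and as the cascade's region of interest. Printed
  `start_bp`/`end_bp` remain the terminal marker positions.
* **Region selection**: the pipeline scans first (per-marker two-sided
  Fisher exact test of homozygous-for-minor by case/control) and picks the
  shared region containing the most of the 20 best-associated markers, ties
  broken by length — the scan-then-homozygosity order of the original
  design, and robust to p-value ties when cases are few.
* **Refinement**: the maximal sub-region whose every SNP has a control
  homozygote count strictly below the threshold; equal-length ties go to
  the smaller summed control fraction. The pipeline default threshold is
  `ceil(0.45 x n_controls)`: in this deliberately inbred desk herd the
  causal-window homozygosity ceiling is ~0.30 of controls (rare tag alleles
  plus descent), while flanking founder-major markers regularly exceed
  0.45, so refinement trims flanks without ever disqualifying the core.
  A fraction-of-controls default travels across herd sizes; absolute counts
  from any particular study do not.
* **Association scan**: Bonferroni-adjusted significance at alpha 0.01
  (matching the P < 0.01 framing of the motivating analysis); all-missing
  markers are skipped and logged.

Measured over 50 default-design replicates, the refined region contains the
planted causal locus in 98% of runs, the causal variant survives the full
cascade in 100% and is the unique final candidate in 100%
(`scripts/acceptance.py` recomputes these).

## Carrier typing

Inside the mapped region the suspect haplotype is read directly from the
homozygous cases, so carrier typing is genotype compatibility, not
statistical phasing: an animal has 2 copies if homozygous for the block
allele at every marker, 1 copy if every marker genotype can contain the
block allele, else 0. A missing genotype is compatible (counts toward 1)
but blocks a 2-copy call; per-call missing counts are reported.
Compatibility over-calls carriage, so the false-carrier rate (typed ≥1,
truly 0 copies) is measured against simulation truth and reported rather
than assumed zero — mirroring the imperfect predictiveness of haplotype
tests observed in practice. Truncated carriage is the maximal compatible
stretch containing the anchor marker (the most associated marker in the
region); `truncated_by_bp` is the summed distance from the stretch
boundaries to the block's terminal markers — one of several defensible
operationalizations, fixed and documented here.

## Cascade conventions

"Homozygous" in the other-homozygote stage means homozygous for the
alternative (case-shared) allele — forced by the preceding stage that
requires cases homozygous-alternative. MAF is computed over all non-missing
called genotypes across all cohorts; missing genotypes leave the
denominator. Sites with a missing case genotype are dropped (and logged) at
the first stage. Multiallelic records survive parsing and die only at the
biallelic filter, so stage counts are meaningful. The protein-impact
hand-off annotates surviving SNVs against overlapping transcripts and keeps
missense, nonsense, stop/start-loss, and splice-region calls. The three
genotype-pattern filters are independent per-site predicates: permuting
them changes intermediate counts but never the surviving set (tested).

## Annotation conventions

Consequences come from direct codon comparison on the assembled CDS
(validated: starts ATG, ends with a stop, no internal stop). Splice-region
is defined as 1–2 bp into the intron plus a 3 bp exonic junction flank;
exonic SNVs take their coding classification, and the exonic flank yields
`splice_region` only when the coding change is synonymous. HGVS output is
simplified (`c.<pos><ref>><alt>`, `p.<Ref3><codon><Alt3|*>`; no reference
prefixes, SNVs only). The truncation fraction for a premature stop at codon
p of an L-residue protein is (L − p + 1)/L. The NMD rule is strict: a
nonsense call is an NMD candidate iff the transcript coordinate of the
junction between the last two exons exceeds the coordinate of the stop
codon's first base by more than 50 nt; single-exon transcripts never
qualify. Published descriptions of the motivating variant contain an
internal inconsistency between its printed coding position, codon number,
and truncation percentage; this annotator applies standard arithmetic
throughout and makes no attempt to reproduce inconsistent printed values.

## Assay conventions

Primer matching is exact — the module is a design checker, not a
thermodynamic simulator. Enzymes are data: an IUPAC recognition string and
signed cut offsets from the recognition 3' end, so Type IIS
downstream-cutting enzymes are expressible. Each site yields one top-strand
cut: plus-strand (and palindromic) sites cut at `3'-end + cut_offset_top`,
minus-only sites at `5'-boundary − cut_offset_bottom`; cuts falling outside
the sequence are skipped with a warning. Digesting the reverse complement
reverses the fragment list exactly for centrally-blunt specs; sticky-end
offsets give strand-specific lengths by construction. Fragment lengths
always sum to the input length.

## Statistics conventions

All tests are two-sided. Welch's t with Welch–Satterthwaite degrees of
freedom is used for two-sample comparisons, including the pairwise
comparisons inside the ANOVA report (the source analyses name neither
pooled nor Welch; unequal variances are the safer default at these group
sizes). Bonferroni-adjusted p-values are capped at 1. An all-identical
dataset returns F = 0, p = 1 rather than NaN. Hue angle is reported in
degrees (the only unit consistent with published meat-color values);
`a*/b*` is flagged undefined at b\* = 0.

## Determinism and problem sizes

Every stochastic component draws from `numpy.random.default_rng` seeded via
`SeedSequence` children of one user seed; `run_all` with a fixed seed
produces a byte-identical report bundle (timestamps are confined to console
logging). The shipped defaults — 3 chromosomes x 300 markers, ~250 animals,
5 generations, 5,000 background WGS variants, 87 sequenced samples, and
50-replicate recovery studies — are desk-scale choices that keep a full
simulation-to-report cycle under a few seconds and the complete validation
suite around a minute, while preserving every structural feature of the
full-scale design (95k markers, 721 genotyped animals, 147 sequenced).

## Known limitations

Compatibility-based carrier typing is an upper bound on carriage and cannot
distinguish one true copy from a chance-compatible genotype; the reported
false-carrier rate quantifies this. The association scan is an exact test
for localization on simulated herds, not a mixed-model GWA — it does not
correct for relatedness and is not meant for real cohorts with structure.
Per-SNP refinement inherits the noise of single-marker counts; one extreme
marker can still split a qualifying run (rate measured at ~2% of
replicates). The annotator handles SNVs only (no indels/MNVs), and the GFF3
reader covers the mRNA/exon/CDS subset it documents.
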