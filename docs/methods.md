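# Methods

## Scope and model

The package models the downstream half of a targeted amplicon-sequencing
study of FFPE lymphoma tissue: it starts from per-position candidate
variant calls (counts + quality) and ends at cohort statistics and
survival. Read alignment and primary variant calling are out of scope; the
caller's output is consumed through a documented TSV dialect (or VCF),
since the original caller's native schema is not public.

All genomic coordinates are 1-based inclusive (VCF/GRCh37 convention); BED
panel input is converted on read. VAF is always recomputed as
`reads_variant / reads_total` and never taken from a file, so a single
definition holds everywhere.

## Filter cascade

Thresholds and their boundary semantics (defaults in
`resources/default_config.yaml`):

| parameter | default | boundary |
|---|---|---|
| `min_phred` | 30 | exclusive — quality must exceed 30 |
| `min_coverage` | 100 | inclusive — 100 reads pass ("below 100" fails) |
| `vaf_reject_below` | 0.05 | inclusive — 5% enters the review band |
| `vaf_auto_accept_at` | 0.20 | inclusive — 20% is auto-accepted |
| `primer_proximity_bp` | 5 | insert-edge distance strictly below 5 bp is proximal |
| `min_overlap_coverage` | 20 | reads needed in the second amplicon to judge concordance |
| `min_overlap_support_reads` | 1 | variant reads defining "support" in an amplicon |

Design choices that were genuinely open:

- **Primer proximity window.** The exclusion of calls "near the primer" has
  no published distance; 5 bp inside the insert edge is a conventional
  choice and configurable. A variant is excluded only if it is
  edge-proximal in *every* covering amplicon — interior support in one
  overlapping amplicon rescues it.
- **Review band.** Manual inspection of 5–20% VAF calls is codified: such a
  call passes exactly when every automatic check passes, and keeps a
  distinct `review_accept` verdict so downstream consumers can flag it.
  All checks apply to all VAF bands.
- **Overlap concordance** is only evaluable with at least two covering
  amplicons at ≥ 20 reads each; otherwise it abstains rather than reject
  for lack of data.
- **Mapping ambiguity** is a panel-level flag supplied at panel build time;
  inspecting mismatch-rich alignments is upstream of this package.
- Reason codes accumulate; `reject` holds iff at least one code fired, so
  tightening `min_coverage` or the VAF floor can only shrink the accepted
  set (tested as a property).

The shipped blacklist contains one entry: the recurrent NOTCH1 1-bp
deletion at chr9:139390945 (GRCh37), an artifact that repeatedly fails
independent resequencing.

## Annotation

Variant typing is pure length arithmetic on the allele pair (anchor-base
convention for indels); an exhaustive oracle over all allele pairs up to
length 4 backs it. Protein consequences come from compact in-frame coding
windows shipped as an editable TSV (`cds_windows_synthetic.tsv`). These
windows are **synthetic**: schematic coding stretches for the 24 panel
genes, mutually consistent with the packaged panel, the simulator and the
annotation anchors (MYD88 codon 265 is CTG with the T at chr3:38182641, so
T>C yields Leu265Pro; the NOTCH1 window around the blacklist hotspot lies
in the PEST domain). They are not a transcript annotation of the real
genome, and positions outside them annotate as `other` with a warning.

The damaging consensus requires at least three of the five tool verdicts
to agree; ties (e.g. 2 damaging / 2 tolerated / 1 missing) and unreachable
quorums are `undetermined`, which conservatively does not count as
damaging. Nonsense and frameshift mutations are deleterious independent of
the vote; the deleterious fraction is computed per mutation (not per
case). Synonymous variants are classified but excluded from all downstream
statistics.

Domain tables for NOTCH1, NOTCH2, KMT2D and TNFAIP3 use approximate
standard protein-annotation intervals restricted to the conventional
domain vocabulary (EGF, LNR, HD-N/HD-C, TM, RAM, ANK, NLS, TAD, PEST, PHD,
HMG, FYRN, FYRC, SET, ZNF); they are editable resources, validated to be
non-overlapping per gene so domain lookup is a partition query.

## Cohort statistics

- Patients are counted once per gene regardless of mutation multiplicity;
  zero-mutation patients stay in the matrix as all-false rows.
- The NF-κB gene set is exactly the 19 panel genes whose pathway
  assignment involves NF-κB signalling; KMT2D, NOTCH1/2, TP53 and FAS are
  excluded.
- Clonality: VAF < 20% subclonal (boundary clonal), VAF > 50% clonal with
  possible LOH/UPD (boundary clonal). The expected clonal heterozygous VAF
  is purity/2; with loss of the second allele it is purity/(2 − purity).
- The Fisher exact test enumerates the hypergeometric support with
  log-factorial accumulation; the two-sided p sums point probabilities not
  exceeding the observed one within relative tolerance 1e-7 (the
  minimum-likelihood convention dominant in statistical software). Any
  zero margin gives p = 1. Exactness is verified against an
  integer-arithmetic enumeration on every 2×2 table with N ≤ 40 and
  against `scipy.stats.fisher_exact`.
- The co-occurrence screen admits genes mutated in ≥ 12 patients (the
  convention for a 63-patient cohort), reports direction relative to the
  independence expectation, and applies no multiple-testing correction by
  default (an optional Benjamini–Hochberg flag exists).

## Survival

Disease-free survival is follow-up months from diagnosis to relapse or
death (the DFS origin is the diagnosis-date proxy carried by the clinical
table; a relapse-only event mode is available since the DFS definition is
a documented assumption). Ties between events and censorings at one time
are resolved events-first. The log-rank statistic uses the hypergeometric
variance at each event time; p comes from the 1-df chi-square. Both the
product-limit curve and the test are verified against lifelines, and the
test's calibration (type-I error in [0.03, 0.07] at n=100/arm over 1000
null simulations) and power (> 0.95 at hazard ratio 3, n=200/arm) are
checked by Monte-Carlo.

## Synthetic cohort generator

The generator emulates the study conditions, not raw reads (counts only):

- **Landscape.** Default 63 patients; per-gene probabilities of carrying a
  non-synonymous mutation mirror the observed cohort (TNFAIP3 0.27, KMT2D
  0.22, MYD88 0.19, NOTCH1/NOTCH2/TP53 0.08, BCL10 0.06, NFKBIA/TNIP1
  0.03, seven genes 0.02, eight genes 0). TNIP1's frequency is not printed
  in the source landscape; 3% was chosen once as "rare". KMT2D/TNFAIP3
  carriers gain a second mutation with probability 0.15; 67% of MYD88
  mutations sit at the Leu265Pro hotspot.
- **Exclusivity.** For TNFAIP3–MYD88 a conditional model suppresses
  co-occurrence by a factor (1 − exclusivity), default 0.8, while
  preserving both marginals; the true mechanism is unknown, so this is a
  declared free parameter.
- **VAF model.** Purity U(0.70, 0.95) (the ≥ 70% tumor-content inclusion
  rule). Clonal heterozygous mutations have expected VAF purity/2;
  subclonal mutations draw a cancer-cell fraction U(0.10, 0.45); TNFAIP3
  clonal mutations lose the second allele with probability 0.25, giving
  the VAF > 50% mode that produces a TNFAIP3 mean VAF near 48%. Per-gene
  subclonal fractions default to 0.25 with overrides for the
  mostly-subclonal genes (TNIP1/MAP3K7 0.8, BCL10/NFKBIA 0.7, NOTCH1 0.4,
  TNFAIP3 0.05).
- **Coverage.** Negative-binomial (mean 160, size 100 → SD ≈ 20) clamped
  to [20, 204]. The size parameter is a free choice (only the mean and
  range of the emulated assay are known); with it, coverage below the
  100-read gate is rare (≈ 0.1%), and the clamp shifts the mean by ≈ 0.1
  reads. Position coverage is split multinomially across covering
  amplicons and variant reads are Binomial(amplicon depth, VAF).
- **Artifacts.** FFPE-style noise at a configurable per-amplicon rate;
  80% C:G>T:A (the deamination convention; the emulated assay does not
  quantify its spectrum); VAF from a Beta concentrated below 5%, and the
  emitted read count is capped strictly below 5% of coverage, so the
  reporting floor removes every artifact at evaluable coverage *by
  construction* (binomial sampling alone would let a few fluctuate over
  the gate). Artifact support is confined to a single amplicon, as
  PCR-introduced errors are.
- **Germline SNPs.** A small set of population SNPs (default 8) with
  allele frequencies U(0.1, 0.5) is planted in patients and listed in the
  known-SNP table, so the SNP filter does real work. Planting *somatic*
  truth keys into the SNP list (`snp_overlap_fraction`) is off by default
  — it is a stress scenario for measuring the SNP filter's cost, not a
  study condition — and is exercised in tests.
- **Survival.** Exponential relapse times, baseline hazard 0.008/month
  (≈ 40% events by 5 years in the wild-type group), hazard ratio 3 for
  MYD88-mutated patients, censoring U(19, 194) months matching the
  follow-up range; death occurs in 20% of relapses.

Seeded runs are bit-reproducible, and every emitted variant row is
attributable to exactly one of truth / artifact / planted SNP.

### What the generator does and does not emulate

It reproduces the count-level statistics the pipeline consumes (VAFs,
coverage, artifact floor, landscape frequencies, hazards). It does not
model read-level errors, strand bias, alignment artifacts, per-amplicon
coverage heterogeneity beyond the multinomial split, copy-number changes
other than the single LOH mode, or inter-lab batch effects. Passing tests
therefore demonstrate correctness of the pipeline's rules and statistics
under the declared generative model, not performance on any real cohort.

### Frequency-recovery experiment

The recovery check (200 replicate 63-patient cohorts; mean recovered
per-gene frequency within 3 binomial SE of the configured value) is run
with clonal-only truth. The configured probabilities describe an
*observed* mutation landscape; subclonal mutations whose expected VAF
falls below the 5% reporting floor are undetectable by design, so
including them would bias the comparison by construction rather than
measure pipeline fidelity. Subclonal sensitivity is characterised
separately by `recovery_report` under the default (subclonal) settings,
where it is expectedly lower near the 5–20% band.

## Problem sizes

Default analyses and tests use: 63-patient cohorts (200 replicates for
recovery), 1000/500 Monte-Carlo draws for log-rank calibration/power at
100–200 subjects per arm, and the exhaustive Fisher sweep over all 135,751
tables with N ≤ 40. These sizes keep every check well-powered while the
full suite runs in well under a minute of simulation time.

## Known limitations

- The coding windows are schematic; real-transcript annotation (and hence
  real HGVS nomenclature, splice effects, isoforms) is out of scope.
- No copy-number inference: VAF > 50% raises a flag, nothing more.
- The exact 2×2 cell counts behind the emulated study's exclusivity
  result are not recoverable from printed marginal frequencies alone, so
  the exclusivity analysis is validated on synthetic cohorts with known
  injected exclusivity rather than against a fixed published table.
- Single-cohort quantities at n = 63 (gene percentages, Fisher p,
  log-rank p) are strongly seed-dependent; the acceptance script reports
  honest draws, not averages.
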