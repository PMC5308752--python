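# oamlseq

Targeted-amplicon mutation analysis for ocular adnexal marginal zone
lymphoma of MALT type (OAML), built as a reusable, tested pipeline:
post-call variant filtering, consequence annotation, cohort
mutation-landscape statistics, mutual-exclusivity testing, and
mutation-stratified disease-free survival — together with a synthetic
FFPE-amplicon cohort generator so every stage is testable with known ground
truth.

## Who this is for

Groups analysing deep targeted amplicon sequencing of FFPE lymphoma panels
(here: 24 genes centred on NF-κB signalling plus NOTCH1/2, KMT2D, TP53,
FAS), where the raw caller output must be reduced to reliable somatic
mutations before any cohort-level statistics are meaningful.

## The method

**Filter cascade.** A candidate call at a position survives only if

- variant quality (phred) is strictly above 30 and coverage is at least
  100 reads;
- its VAF (variant reads / total reads) is at least 5%; calls between 5%
  and 20% are retained with a distinct `review_accept` verdict (a codified
  version of the manual review applied to that band), calls at or above 20%
  are auto-accepted;
- it is not adjacent to an amplicon primer (within 5 bp of the insert edge
  in *every* covering amplicon), not supported by only one of two
  overlapping amplicons, and not on an amplicon flagged as
  mapping-ambiguous;
- it is not a known polymorphism (db137-style list) and not on the shipped
  blacklist (which contains the recurrent NOTCH1 1-bp deletion at
  chr9:139390945, GRCh37, a known unvalidated artifact).

Rejections carry machine-readable reason codes; decisions are deterministic
and order-independent.

**Annotation.** Variant type (substitution/deletion/insertion/complex),
protein effect (missense, nonsense, frameshift, in-frame indel,
synonymous), a damaging consensus requiring agreement of ≥3 of 5 prediction
tools (SIFT, PolyPhen2 HDIV/HVAR, LRT, MutationTaster), and protein-domain
mapping (PEST, SET, ANK, ZNF, …) for lollipop summaries. A mutation is
*deleterious* if nonsense or frameshift, or missense with a damaging vote.

**Cohort statistics.** Patients × genes indicator matrix, per-gene and
NF-κB pathway (19-gene union) frequencies, variant-type breakdown, and
clonality from VAF: below 20% subclonal, above 50% clonal with possible
second-allele loss or uniparental disomy; the expected clonal heterozygous
VAF in a tumor of purity *p* is *p*/2. Gene-pair exclusivity is tested with
a two-sided Fisher exact test implemented from first principles
(hypergeometric enumeration with fixed margins, minimum-likelihood
two-sided rule, log-factorial accumulation).

**Survival.** Kaplan–Meier product-limit estimator
S(t) = ∏<sub>t<sub>i</sub>≤t</sub> (1 − d<sub>i</sub>/n<sub>i</sub>) with
Greenwood standard errors, and the two-group log-rank test (1 df) for
disease-free survival by mutation status.

**Synthetic cohorts.** 63 patients by default; per-gene mutation
probabilities mirror the observed landscape (TNFAIP3 27%, KMT2D 22%, MYD88
19%, …); purity U(0.70, 0.95); clonal heterozygous VAF = purity/2 with
binomial read sampling at negative-binomial coverage (mean 160, clamped to
[20, 204]); sub-5% C:G>T:A-biased artifact noise; TNFAIP3–MYD88
exclusivity; exponential relapse hazard tripled in the MYD88-mutated group.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_filter_variants.py
python analysis/03_annotate_mutations.py
python analysis/04_cohort_landscape.py
python analysis/05_survival_analysis.py
```

The filter step reduces 246 candidate calls to 72 accepted mutations
(53 `accept` + 19 `review_accept`), the bulk of the rejections being the
168 germline SNP calls:

```
246 candidate variants:
  accept          53
  review_accept   19
  reject          174
rejection reasons (a variant may carry several):
  KNOWN_SNP            168
  VAF_BELOW_MIN        6
  SINGLE_AMPLICON_ONLY 3
```

and the landscape step summarises the cohort (seed 1; all quantities are
stochastic at n = 63):

```
63 patients, 72 non-synonymous mutations in 14 genes
  TNFAIP3  13/63 (21%)
  KMT2D    12/63 (19%)
  MYD88     8/63 (13%)
  ...
NF-kB pathway (>=1 of 19 genes): 38/63 (60%)
mean mutated genes/patient 1.08 (range 0-3)
type mix: substitution 74%, deletion 17%, insertion 10%, complex 0%
deleterious fraction 64%
TNFAIP3-MYD88 co-occurrence table [[0,13],[8,42]]: two-sided Fisher p = 0.1882
```

Here the indicator matrix, frequencies and clonality tables land under
`results/landscape/`, and the survival step writes the KM curves and
log-rank comparison (log-rank p = 0.0457; MYD88-mutated median DFS 45.1
vs 79.8 months wild type on this draw) under `results/survival/`.

The same pipeline is scriptable via the `oamlseq` CLI
(`simulate`, `filter`, `annotate`, `cohort`, `survival`, `report`), every
stage exchanging plain TSV/CSV/BED files and emitting a `manifest.json`
with config snapshot, input checksums and record counts.

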