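#!/usr/bin/env python
"""Cohort mutation landscape: matrix, frequencies, clonality, exclusivity.

Builds the patients x genes indicator matrix over all 63 patients, reports
per-gene and NF-kB pathway mutation frequencies, the mean number of mutated
genes per patient, VAF-based clonality calls, and the TNFAIP3-MYD88
exclusivity Fisher test.  Tables go under results/landscape/.
"""

from pathlib import Path

from oamlseq.annotation import read_annotated_table
from oamlseq.cohort_stats import (
    annotate_clonality,
    build_matrix,
    cooccurrence_screen,
    fisher_exact_two_sided,
    gene_frequencies,
    nfkb_gene_set,
    pathway_frequency,
    summary_statistics,
    vaf_by_gene,
    write_clonality_table,
    write_frequency_table,
    write_matrix,
)
from oamlseq.io_formats import read_clinical_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    mutations = read_annotated_table(ROOT / "annotation" / "annotated.tsv")
    clinical = read_clinical_table(ROOT / "cohort" / "clinical.csv")
    patients = [p.patient_id for p in clinical]
    matrix = build_matrix(mutations, patients)
    out = ROOT / "landscape"
    out.mkdir(parents=True, exist_ok=True)

    write_matrix(matrix, out / "matrix.tsv")
    write_frequency_table(matrix, out / "gene_frequencies.tsv")
    purity = {p.patient_id: p.tumor_content_fraction for p in clinical}
    calls = annotate_clonality(matrix.detail, purity)
    write_clonality_table(calls, out / "clonality.tsv")
    vaf_by_gene(matrix).to_csv(out / "vaf_by_gene.tsv", sep="\t", index=False,
                               float_format="%.6g")
    screen = cooccurrence_screen(matrix, min_cases=12)
    screen.to_csv(out / "cooccurrence.tsv", sep="\t", index=False,
                  float_format="%.6g")

    freqs = gene_frequencies(matrix).set_index("gene")
    stats = summary_statistics(matrix)
    n_nfkb, f_nfkb = pathway_frequency(matrix, nfkb_gene_set())
    print(f"{len(patients)} patients, {stats['n_mutations']} non-synonymous "
          f"mutations in {int((freqs['n_mutated'] > 0).sum())} genes")
    top = freqs.sort_values('n_mutated', ascending=False).head(6)
    for gene, row in top.iterrows():
        print(f"  {gene:8s} {int(row['n_mutated']):2d}/{len(patients)} "
              f"({100 * row['fraction']:.0f}%)")
    print(f"NF-kB pathway (>=1 of 19 genes): {n_nfkb}/{len(patients)} "
          f"({100 * f_nfkb:.0f}%)")
    print(f"mean mutated genes/patient {stats['mean_mutated_genes']:.2f} "
          f"(range {stats['min_mutated_genes']}-{stats['max_mutated_genes']})")
    bd = stats["type_breakdown"]
    print("type mix: " + ", ".join(f"{k} {100 * v:.0f}%" for k, v in bd.items()))
    print(f"deleterious fraction {100 * stats['deleterious_fraction']:.0f}%")
    n_sub = sum(c.label == "subclonal" for c in calls)
    print(f"clonality: {n_sub}/{len(calls)} subclonal (<20% VAF)")

    ind = matrix.indicator
    a = int((ind["TNFAIP3"] & ind["MYD88"]).sum())
    b = int((ind["TNFAIP3"] & ~ind["MYD88"]).sum())
    c = int((~ind["TNFAIP3"] & ind["MYD88"]).sum())
    d = len(patients) - a - b - c
    p = fisher_exact_two_sided(a, b, c, d)
    print(f"TNFAIP3-MYD88 co-occurrence table [[{a},{b}],[{c},{d}]]: "
          f"two-sided Fisher p = {p:.4f}")
    if not screen.empty:
        print("co-occurrence screen (genes mutated in >= 12 cases):")
        print(screen.to_string(index=False))


if __name__ == "__main__":
    main()
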