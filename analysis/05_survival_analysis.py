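#!/usr/bin/env python
"""Disease-free survival stratified by MYD88 mutation status.

Kaplan-Meier product-limit curves for MYD88-mutated versus wild-type
patients with the two-group log-rank test, on the full cohort and on the
stage-I subgroup.  Curves go to results/survival/.
"""

from pathlib import Path

from oamlseq.cohort_stats import read_matrix
from oamlseq.io_formats import read_clinical_table
from oamlseq.survival import dfs_by_mutation, write_km_table

ROOT = Path(__file__).resolve().parents[1] / "results"
GENE = "MYD88"


def main() -> None:
    matrix = read_matrix(ROOT / "landscape" / "matrix.tsv")
    clinical = read_clinical_table(ROOT / "cohort" / "clinical.csv")
    out = ROOT / "survival"
    out.mkdir(parents=True, exist_ok=True)

    res = dfs_by_mutation(matrix, clinical, GENE)
    curves = [res[k] for k in ("km_mutated", "km_wildtype") if k in res]
    write_km_table(curves, out / "km_curves.tsv")
    print(f"DFS by {GENE} status: {res['n_mutated']} mutated vs "
          f"{res['n_wildtype']} wild type")
    if "logrank_p" in res:
        print(f"  log-rank chi2 = {res['logrank_chi2']:.3f}, "
              f"p = {res['logrank_p']:.4f}")
    for key in ("km_mutated", "km_wildtype"):
        if key in res:
            print(f"  {res[key].group}: median DFS "
                  f"{res[key].median:.1f} months")

    stage1 = [p for p in clinical if p.ann_arbor_stage == "I"]
    res1 = dfs_by_mutation(matrix, stage1, GENE)
    print(f"stage-I subgroup ({len(stage1)} patients): ", end="")
    if "logrank_p" in res1:
        print(f"log-rank p = {res1['logrank_p']:.4f}")
    else:
        print("no two-group comparison possible")


if __name__ == "__main__":
    main()
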