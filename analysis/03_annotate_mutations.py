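#!/usr/bin/env python
"""Annotate accepted variants: consequence class, damaging vote, domains.

Writes results/annotation/annotated.tsv and a lollipop-style per-position
count table for external plotting.
"""

from collections import Counter
from pathlib import Path

from oamlseq.annotation import (
    annotate_mutations,
    deleterious_flag,
    write_annotated_table,
    write_lollipop_table,
)
from oamlseq.filter_engine import read_decisions
from oamlseq.io_formats import read_predictor_table, read_variant_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    variants = read_variant_table(ROOT / "cohort" / "variants.tsv")
    decisions = read_decisions(ROOT / "filter" / "decisions.tsv", variants)
    predictors = read_predictor_table(ROOT / "cohort" / "predictors.tsv")
    mutations = annotate_mutations(decisions, predictors)
    out = ROOT / "annotation"
    out.mkdir(parents=True, exist_ok=True)
    write_annotated_table(mutations, out / "annotated.tsv")
    write_lollipop_table(mutations, out / "lollipop.tsv")

    nonsyn = [m for m in mutations if m.non_synonymous]
    types = Counter(m.consequence.variant_type for m in nonsyn)
    effects = Counter(m.consequence.protein_effect for m in nonsyn)
    n_del = sum(deleterious_flag(m) for m in nonsyn)
    print(f"{len(nonsyn)} non-synonymous mutations accepted")
    print("variant types:", dict(types))
    print("protein effects:", dict(effects))
    print(f"deleterious (nonsense/frameshift or 3-of-5 damaging vote): "
          f"{n_del}/{len(nonsyn)} = {100 * n_del / len(nonsyn):.0f}%")
    in_domain = [m for m in nonsyn if m.domain]
    print(f"{len(in_domain)} mutations map into annotated protein domains, e.g.")
    for m in in_domain[:5]:
        print(f"  {m.variant.gene} {m.consequence.protein_change} -> {m.domain}")


if __name__ == "__main__":
    main()
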