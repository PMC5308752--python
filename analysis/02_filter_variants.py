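#!/usr/bin/env python
"""Run the variant-filter cascade on the simulated cohort.

Applies, in order: phred > 30 quality gate, coverage >= 100 gate, the 5% VAF
reporting floor with a 5-20% review band, mapping-ambiguity and
primer-proximity panel checks, overlap concordance between adjacent
amplicons, and known-SNP/blacklist exclusion.  Writes one decision per
variant to results/filter/decisions.tsv.
"""

from collections import Counter
from pathlib import Path

from oamlseq.filter_engine import FilterConfig, run_filter_cascade, write_decisions
from oamlseq.io_formats import (
    read_amplicon_panel,
    read_snp_table,
    read_variant_table,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    variants = read_variant_table(ROOT / "cohort" / "variants.tsv")
    panel = read_amplicon_panel(ROOT / "cohort" / "panel.bed")
    snp_db = read_snp_table(ROOT / "cohort" / "snps.tsv")
    decisions = run_filter_cascade(variants, panel, snp_db, FilterConfig())
    out = ROOT / "filter"
    out.mkdir(parents=True, exist_ok=True)
    write_decisions(decisions, out / "decisions.tsv")

    verdicts = Counter(d.verdict for d in decisions)
    reasons = Counter(r for d in decisions for r in d.reasons)
    print(f"{len(decisions)} candidate variants:")
    for v in ("accept", "review_accept", "reject"):
        print(f"  {v:15s} {verdicts.get(v, 0)}")
    print("rejection reasons (a variant may carry several):")
    for code, n in reasons.most_common():
        print(f"  {code:20s} {n}")


if __name__ == "__main__":
    main()
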