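#!/usr/bin/env python
"""Generate the synthetic 63-patient amplicon cohort used by the analyses.

Emits the full input bundle (variant calls, amplicon panel, known-SNP list,
predictor verdicts, clinical table, ground truth) under results/cohort/.
"""

from pathlib import Path

from oamlseq.synthetic_cohort import SimConfig, simulate_cohort, write_bundle

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    cfg = SimConfig(seed=SEED)
    bundle = simulate_cohort(cfg)
    paths = write_bundle(bundle, OUT)
    n_truth = len(bundle.truth.records)
    n_art = sum(1 for o in bundle.origins.values() if o == "artifact")
    n_snp = sum(1 for o in bundle.origins.values() if o == "snp")
    print(f"cohort of {cfg.n_patients} patients (seed {SEED})")
    print(f"  {len(bundle.variants)} candidate variant calls "
          f"({n_truth} truth mutations emitted or missed, "
          f"{n_snp} germline SNP calls, {n_art} FFPE-style artifacts)")
    print(f"  panel: {len(bundle.panel)} amplicons over 24 genes")
    print(f"  outputs: {', '.join(str(p) for p in paths.values())}")


if __name__ == "__main__":
    main()
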