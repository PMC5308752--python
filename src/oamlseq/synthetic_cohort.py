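"""Synthetic FFPE-amplicon cohort generator with known ground truth.

Emulates the data shapes of a 63-patient targeted-amplicon study of ocular
adnexal MALT lymphoma: per-gene clonal mutation probabilities mirroring the
observed mutation landscape, purity-scaled VAFs (a clonal heterozygous
mutation in a tumor of purity p is expected at VAF p/2), negative-binomial
position coverage with mean 160 clamped to [20, 204], sub-5% FFPE-style
artifact noise biased toward C:G>T:A deamination changes, germline SNPs,
per-tool damaging verdicts, and relapse times with a mutation-linked hazard.

Every emitted variant row is attributable to exactly one of {truth,
artifact, planted SNP} via the bundle's ``origins`` map, and seeded runs are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import CdsWindow, _build_codon_table, load_cds_windows
from .filter_engine import FilterDecision
from .io_formats import (
    Amplicon,
    PatientRecord,
    PredictorVerdicts,
    SnpRecord,
    VariantCall,
    PREDICTOR_TOOLS,
    write_amplicon_panel,
    write_clinical_table,
    write_predictor_table,
    write_snp_table,
    write_variant_table,
)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "TruthSet",
    "SimBundle",
    "build_panel",
    "simulate_cohort",
    "toy_bundle",
    "write_bundle",
    "recovery_report",
]

# Default per-gene probabilities of carrying >= 1 non-synonymous mutation,
# mirroring the observed cohort landscape (most frequent: TNFAIP3 27%,
# KMT2D 22%, MYD88 19%; NOTCH1/NOTCH2/TP53 8%; eight genes unmutated).
DEFAULT_GENE_PROBS = {
    "TNFAIP3": 0.27,
    "KMT2D": 0.22,
    "MYD88": 0.19,
    "NOTCH1": 0.08,
    "NOTCH2": 0.08,
    "TP53": 0.08,
    "BCL10": 0.06,
    "NFKBIA": 0.03,
    "TNIP1": 0.03,
    "MAP3K7": 0.02,
    "MAP3K14": 0.02,
    "CYLD": 0.02,
    "CD79B": 0.02,
    "TRAF6": 0.02,
    "CARD11": 0.02,
    "BIRC3": 0.02,
    "CD79A": 0.0,
    "FAS": 0.0,
    "IKBKG": 0.0,
    "MALT1": 0.0,
    "RIPK1": 0.0,
    "RIPK2": 0.0,
    "TNIP2": 0.0,
    "TRAF3": 0.0,
}

# Genes whose mutations are mostly subclonal in the observed landscape.
DEFAULT_SUBCLONAL_OVERRIDES = {
    "TNFAIP3": 0.05,
    "NOTCH1": 0.40,
    "TNIP1": 0.80,
    "MAP3K7": 0.80,
    "BCL10": 0.70,
    "NFKBIA": 0.70,
}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_patients: int = 63
    gene_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_PROBS)
    )
    subclonal_fraction: float = 0.25
    subclonal_overrides: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBCLONAL_OVERRIDES)
    )
    subclonal_ccf_range: tuple[float, float] = (0.10, 0.45)
    purity_range: tuple[float, float] = (0.70, 0.95)
    coverage_mean: float = 160.0
    coverage_dispersion: float = 100.0  # negative-binomial size parameter
    coverage_bounds: tuple[int, int] = (20, 204)
    truth_phred_range: tuple[float, float] = (33.0, 45.0)
    artifact_rate_per_amplicon: float = 0.0005  # per amplicon and patient
    artifact_vaf_beta: tuple[float, float] = (1.5, 50.0)
    artifact_ct_bias: float = 0.8
    artifact_phred_range: tuple[float, float] = (25.0, 40.0)
    exclusive_pair: tuple[str, str] = ("TNFAIP3", "MYD88")
    exclusivity: float = 0.8
    loh_prob: dict[str, float] = field(default_factory=lambda: {"TNFAIP3": 0.25})
    second_mutation_prob: float = 0.15  # for KMT2D / TNFAIP3 carriers
    myd88_hotspot_prob: float = 0.67  # fraction of MYD88 mutations at Leu265Pro
    snp_overlap_fraction: float = 0.0  # truth keys also planted in the SNP list
    n_population_snps: int = 8
    synonymous_rate: float = 0.0  # expected planted synonymous calls/patient
    survival_gene: str = "MYD88"
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.008  # events per month, wild-type group
    censor_range: tuple[float, float] = (19.0, 194.0)
    death_given_relapse: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for g, p in self.gene_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"gene probability out of [0,1] for {g}")
        for name in ("subclonal_fraction", "exclusivity", "artifact_ct_bias",
                     "snp_overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]")
        if self.coverage_bounds[0] > self.coverage_bounds[1]:
            raise ValueError("bad coverage bounds")


@dataclass
class TruthRecord:
    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    clonality: str  # clonal | subclonal
    ccf: float
    expected_vaf: float
    zygosity: str = "het"  # het | loh

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.patient_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TruthSet:
    records: list[TruthRecord]
    purity: dict[str, float]
    mutated_group: set[str]  # patients whose truth includes the survival gene
    survival_gene: str
    hazard_ratio: float
    baseline_hazard: float


@dataclass
class SimBundle:
    """The full input bundle one cohort simulation produces."""

    variants: list[VariantCall]
    panel: list[Amplicon]
    snp_db: dict[tuple[str, int, str, str], SnpRecord]
    predictors: dict[tuple[str, int, str, str], PredictorVerdicts]
    clinical: list[PatientRecord]
    truth: TruthSet | None
    origins: dict[tuple[str, str, int, str, str], str]  # variant -> origin class
    cfg: SimConfig | None = None


# ---------------------------------------------------------------------------
# panel construction

def build_panel(
    windows: dict[str, list[CdsWindow]] | None = None,
    insert_len: int = 100,
    step: int = 60,
    primer_5p: int = 22,
    primer_3p: int = 20,
) -> list[Amplicon]:
    """Tile every coding window with overlapping amplicons.

    Adjacent amplicons share ``insert_len - step`` bp of insert, so most
    positions are covered twice and overlap concordance is assessable.
    """
    windows = windows if windows is not None else load_cds_windows()
    panel: list[Amplicon] = []
    for gene in sorted(windows):
        for wi, w in enumerate(windows[gene]):
            length = len(w.seq)
            start = 0
            j = 0
            while start < length:
                end = min(start + insert_len - 1, length - 1)
                panel.append(
                    Amplicon(
                        amplicon_id=f"{gene}_w{wi}_a{j}",
                        chrom=w.chrom,
                        insert_start=w.start + start,
                        insert_end=w.start + end,
                        primer_len_5p=primer_5p,
                        primer_len_3p=primer_3p,
                        gene=gene,
                    )
                )
                if end == length - 1:
                    break
                start += step
                j += 1
    panel.sort(key=lambda a: (a.chrom, a.insert_start))
    return panel


def _covering_amplicons(panel: list[Amplicon], chrom: str, pos: int) -> list[Amplicon]:
    return [a for a in panel if a.covers(chrom, pos)]


# ---------------------------------------------------------------------------
# allele construction helpers

def _window_base(w: CdsWindow, pos: int) -> str:
    return w.seq[pos - w.start]


def _aa_of(codon: str) -> str:
    return _build_codon_table()[codon]


def _substitution_effect(w: CdsWindow, idx: int, alt: str) -> str:
    codon_i, off = divmod(idx, 3)
    ref_codon = w.seq[codon_i * 3 : codon_i * 3 + 3]
    alt_codon = ref_codon[:off] + alt + ref_codon[off + 1 :]
    aa_ref, aa_alt = _aa_of(ref_codon), _aa_of(alt_codon)
    if aa_alt == "*":
        return "nonsense"
    return "synonymous" if aa_alt == aa_ref else "missense"


def _draw_truth_allele(
    rng: np.random.Generator, w: CdsWindow, want_synonymous: bool = False
) -> tuple[int, str, str]:
    """Sample (pos, ref, alt) inside the window, away from insert edges.

    Substitutions are resampled until non-synonymous (or synonymous when
    ``want_synonymous``); indel lengths mix 1/2/3 bp so roughly 70% of
    indels shift the frame.
    """
    length = len(w.seq)
    lo, hi = 5, length - 6
    u = rng.random()
    if want_synonymous or u < 0.70:  # substitution
        for _ in range(200):
            idx = int(rng.integers(lo, hi + 1))
            ref = w.seq[idx]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            effect = _substitution_effect(w, idx, alt)
            if want_synonymous and effect == "synonymous":
                return w.start + idx, ref, alt
            if not want_synonymous and effect in ("missense", "nonsense"):
                return w.start + idx, ref, alt
        raise RuntimeError("failed to sample substitution allele")
    if u < 0.90:  # deletion, anchor-base representation
        dlen = int(rng.choice([1, 2, 3], p=[0.5, 0.2, 0.3]))
        idx = int(rng.integers(lo, min(hi, length - 2 - dlen) + 1))
        ref = w.seq[idx : idx + 1 + dlen]
        return w.start + idx, ref, ref[0]
    if u < 0.99:  # insertion
        ilen = int(rng.choice([1, 2, 3], p=[0.55, 0.15, 0.3]))
        idx = int(rng.integers(lo, hi + 1))
        ref = w.seq[idx]
        ins = "".join(rng.choice(list("ACGT"), size=ilen))
        return w.start + idx, ref, ref + ins
    # complex: two-base exchange
    idx = int(rng.integers(lo, hi))
    ref = w.seq[idx : idx + 2]
    alt = "".join(str(rng.choice([b for b in "ACGT" if b != r])) for r in ref)
    return w.start + idx, ref, alt


# ---------------------------------------------------------------------------
# read-count emission

def _draw_coverage(rng: np.random.Generator, cfg: SimConfig) -> int:
    k = cfg.coverage_dispersion
    p = k / (k + cfg.coverage_mean)
    cov = int(rng.negative_binomial(k, p))
    return int(np.clip(cov, *cfg.coverage_bounds))


def _emit_counts(
    rng: np.random.Generator,
    panel: list[Amplicon],
    chrom: str,
    pos: int,
    vaf: float,
    cfg: SimConfig,
    single_amplicon: bool = False,
) -> tuple[int, int, list[str], dict[str, tuple[int, int]]]:
    """Draw per-amplicon totals (multinomial split of the position coverage)
    and binomial variant reads; artifacts confine support to one amplicon."""
    covering = _covering_amplicons(panel, chrom, pos)
    cov = _draw_coverage(rng, cfg)
    n_amp = max(len(covering), 1)
    totals = rng.multinomial(cov, [1.0 / n_amp] * n_amp)
    amp_counts: dict[str, tuple[int, int]] = {}
    total_var = 0
    for i, a in enumerate(covering):
        if single_amplicon:
            var = 0
        else:
            var = int(rng.binomial(totals[i], vaf))
        amp_counts[a.amplicon_id] = (int(totals[i]), var)
        total_var += var
    if single_amplicon and covering:
        # all variant support in the highest-coverage amplicon
        target = max(amp_counts, key=lambda k: amp_counts[k][0])
        t = amp_counts[target][0]
        var = int(rng.binomial(t, min(2 * vaf, 1.0)))
        amp_counts[target] = (t, var)
        total_var = var
    return cov, total_var, [a.amplicon_id for a in covering], amp_counts


# ---------------------------------------------------------------------------
# cohort simulation

def simulate_cohort(cfg: SimConfig | None = None) -> SimBundle:
    """Generate one cohort: variant calls, panel, SNP list, predictor
    verdicts, clinical table and ground truth, all from ``cfg.seed``."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    windows = load_cds_windows()
    panel = build_panel(windows)
    patients = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    purity = {
        pid: float(rng.uniform(*cfg.purity_range)) for pid in patients
    }

    # germline SNPs shared across the cohort
    snp_db: dict[tuple[str, int, str, str], SnpRecord] = {}
    pop_snps: list[tuple[tuple[str, int, str, str], float]] = []
    window_list = [w for g in sorted(windows) for w in windows[g]]
    lengths = np.array([len(w.seq) for w in window_list], dtype=float)
    wprobs = lengths / lengths.sum()
    for _ in range(cfg.n_population_snps):
        w = window_list[int(rng.choice(len(window_list), p=wprobs))]
        idx = int(rng.integers(0, len(w.seq)))
        ref = w.seq[idx]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        key = (w.chrom, w.start + idx, ref, alt)
        if key in snp_db:
            continue
        snp_db[key] = SnpRecord(*key)
        pop_snps.append((key, float(rng.uniform(0.1, 0.5))))

    variants: list[VariantCall] = []
    truth_records: list[TruthRecord] = []
    origins: dict[tuple[str, str, int, str, str], str] = {}
    predictors: dict[tuple[str, int, str, str], PredictorVerdicts] = {}
    mutated_group: set[str] = set()

    g1, g2 = cfg.exclusive_pair
    genes = list(cfg.gene_probs)

    def gene_window(gene: str) -> CdsWindow:
        ws = windows[gene]
        wl = np.array([len(w.seq) for w in ws], dtype=float)
        return ws[int(rng.choice(len(ws), p=wl / wl.sum()))]

    def add_predictors(key: tuple[str, int, str, str], damaging_latent: bool) -> None:
        if key in predictors:
            return
        verdicts = {}
        for tool in PREDICTOR_TOOLS:
            u = rng.random()
            if u < 0.08:
                verdicts[tool] = "missing"
            else:
                p_dam = 0.85 if damaging_latent else 0.12
                verdicts[tool] = "damaging" if rng.random() < p_dam else "tolerated"
        predictors[key] = PredictorVerdicts(*key, verdicts=verdicts)

    for pid in patients:
        taken: set[tuple[str, int]] = set()  # (chrom, pos) used in this patient
        p_purity = purity[pid]

        # --- which genes are mutated (latent-exclusivity model for one pair)
        mutated_genes: list[str] = []
        has_g1 = rng.random() < cfg.gene_probs.get(g1, 0.0)
        p2 = cfg.gene_probs.get(g2, 0.0)
        p1 = cfg.gene_probs.get(g1, 0.0)
        if p1 < 1.0:
            # marginal of g2 preserved while co-occurrence is suppressed
            p2_given_g1 = p2 * (1 - cfg.exclusivity)
            p2_given_not = (p2 - p1 * p2_given_g1 / 1.0) / (1 - p1) if p1 else p2
        else:
            p2_given_g1 = p2_given_not = p2
        has_g2 = rng.random() < (p2_given_g1 if has_g1 else p2_given_not)
        if has_g1:
            mutated_genes.append(g1)
        if has_g2:
            mutated_genes.append(g2)
        for gene in genes:
            if gene in (g1, g2):
                continue
            if rng.random() < cfg.gene_probs[gene]:
                mutated_genes.append(gene)

        if cfg.survival_gene in mutated_genes:
            mutated_group.add(pid)

        # --- truth mutations
        for gene in mutated_genes:
            n_mut = 1
            if gene in ("KMT2D", "TNFAIP3") and rng.random() < cfg.second_mutation_prob:
                n_mut = 2
            for _ in range(n_mut):
                w = gene_window(gene)
                if gene == "MYD88" and rng.random() < cfg.myd88_hotspot_prob:
                    # recurrent Leu265Pro hotspot
                    pos, ref, alt = 38182641, "T", "C"
                    w = next(x for x in windows["MYD88"] if x.contains("chr3", pos))
                else:
                    for _ in range(50):
                        pos, ref, alt = _draw_truth_allele(rng, w)
                        if (w.chrom, pos) not in taken:
                            break
                if (w.chrom, pos) in taken:
                    continue
                taken.add((w.chrom, pos))
                sub_p = cfg.subclonal_overrides.get(gene, cfg.subclonal_fraction)
                if rng.random() < sub_p:
                    clonality = "subclonal"
                    ccf = float(rng.uniform(*cfg.subclonal_ccf_range))
                    expected_vaf = p_purity * ccf / 2
                    zygosity = "het"
                else:
                    clonality = "clonal"
                    ccf = 1.0
                    if rng.random() < cfg.loh_prob.get(gene, 0.0):
                        zygosity = "loh"
                        expected_vaf = p_purity / (2 - p_purity)
                    else:
                        zygosity = "het"
                        expected_vaf = p_purity / 2
                truth_records.append(
                    TruthRecord(pid, gene, w.chrom, pos, ref, alt, clonality,
                                ccf, expected_vaf, zygosity)
                )
                cov, var, amp_ids, amp_counts = _emit_counts(
                    rng, panel, w.chrom, pos, expected_vaf, cfg
                )
                if var == 0:
                    continue  # below the caller's detection floor: no row emitted
                vc = VariantCall(
                    patient_id=pid, chrom=w.chrom, pos=pos, ref=ref, alt=alt,
                    gene=gene, reads_total=cov, reads_variant=var,
                    phred=float(rng.uniform(*cfg.truth_phred_range)),
                    amplicon_ids=amp_ids, per_amplicon_counts=amp_counts,
                )
                variants.append(vc)
                origins[(pid, *vc.key)] = "truth"
                if len(ref) == 1 and len(alt) == 1:
                    add_predictors(vc.key, damaging_latent=rng.random() < 0.6)
                if rng.random() < cfg.snp_overlap_fraction:
                    snp_db.setdefault(vc.key, SnpRecord(*vc.key))

        # --- planted synonymous passenger calls (off by default)
        n_syn = int(rng.poisson(cfg.synonymous_rate))
        for _ in range(n_syn):
            w = window_list[int(rng.choice(len(window_list), p=wprobs))]
            try:
                pos, ref, alt = _draw_truth_allele(rng, w, want_synonymous=True)
            except RuntimeError:
                continue
            if (w.chrom, pos) in taken:
                continue
            taken.add((w.chrom, pos))
            cov, var, amp_ids, amp_counts = _emit_counts(
                rng, panel, w.chrom, pos, p_purity / 2, cfg
            )
            if var == 0:
                continue
            vc = VariantCall(
                patient_id=pid, chrom=w.chrom, pos=pos, ref=ref, alt=alt,
                gene=w.gene, reads_total=cov, reads_variant=var,
                phred=float(rng.uniform(*cfg.truth_phred_range)),
                amplicon_ids=amp_ids, per_amplicon_counts=amp_counts,
            )
            variants.append(vc)
            origins[(pid, *vc.key)] = "truth_synonymous"

        # --- germline SNP calls
        for key, af in pop_snps:
            if rng.random() < af:
                chrom, pos, ref, alt = key
                if (chrom, pos) in taken:
                    continue
                taken.add((chrom, pos))
                cov, var, amp_ids, amp_counts = _emit_counts(
                    rng, panel, chrom, pos, 0.5, cfg
                )
                if var == 0:
                    continue
                vc = VariantCall(
                    patient_id=pid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    gene=next((a.gene for a in panel if a.covers(chrom, pos)), ""),
                    reads_total=cov, reads_variant=var,
                    phred=float(rng.uniform(*cfg.truth_phred_range)),
                    amplicon_ids=amp_ids, per_amplicon_counts=amp_counts,
                )
                variants.append(vc)
                origins[(pid, *vc.key)] = "snp"
                add_predictors(vc.key, damaging_latent=False)

        # --- FFPE-style artifacts, strictly below the 5% reporting floor
        n_art = int(rng.poisson(cfg.artifact_rate_per_amplicon * len(panel)))
        for _ in range(n_art):
            a = panel[int(rng.integers(0, len(panel)))]
            pos = int(rng.integers(a.insert_start, a.insert_end + 1))
            if (a.chrom, pos) in taken:
                continue
            w = next(
                (w for g in windows.values() for w in g
                 if w.contains(a.chrom, pos)), None
            )
            if w is None:
                continue
            taken.add((a.chrom, pos))
            ref = _window_base(w, pos)
            if rng.random() < cfg.artifact_ct_bias and ref in "CG":
                alt = "T" if ref == "C" else "A"
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            vaf = float(rng.beta(*cfg.artifact_vaf_beta))
            vaf = min(vaf, 0.049)
            cov, _, amp_ids, amp_counts = _emit_counts(
                rng, panel, a.chrom, pos, vaf, cfg, single_amplicon=True
            )
            cap = math.ceil(0.05 * cov) - 1
            if cap < 1:
                continue
            target = max(amp_counts, key=lambda k: amp_counts[k][0])
            t, v = amp_counts[target]
            v = min(max(v, 1), cap, t)
            amp_counts[target] = (t, v)
            vc = VariantCall(
                patient_id=pid, chrom=a.chrom, pos=pos, ref=ref, alt=alt,
                gene=w.gene, reads_total=cov, reads_variant=v,
                phred=float(rng.uniform(*cfg.artifact_phred_range)),
                amplicon_ids=amp_ids, per_amplicon_counts=amp_counts,
            )
            variants.append(vc)
            origins[(pid, *vc.key)] = "artifact"
            add_predictors(vc.key, damaging_latent=False)

    # --- clinical table with mutation-linked relapse hazard
    clinical: list[PatientRecord] = []
    for pid in patients:
        rate = cfg.baseline_hazard * (
            cfg.hazard_ratio if pid in mutated_group else 1.0
        )
        event_time = float(rng.exponential(1.0 / rate))
        censor_time = float(rng.uniform(*cfg.censor_range))
        relapse = event_time <= censor_time
        followup = max(min(event_time, censor_time), 1.0)
        death = bool(relapse and rng.random() < cfg.death_given_relapse)
        stage = str(rng.choice(["I", "II", "III", "IV"], p=[0.80, 0.10, 0.05, 0.05]))
        clinical.append(
            PatientRecord(
                patient_id=pid,
                age_years=float(np.clip(rng.normal(67, 12), 29, 87)),
                sex=str(rng.choice(["M", "F"], p=[0.63, 0.37])),
                ann_arbor_stage=stage,
                localization=str(
                    rng.choice(
                        ["orbita", "conjunctiva", "lacrimal gland"],
                        p=[0.43, 0.46, 0.11],
                    )
                ),
                treatment=str(
                    rng.choice(
                        ["radiotherapy", "immunochemotherapy", "anti-CD20", "none"],
                        p=[0.80, 0.13, 0.03, 0.04],
                    )
                ),
                relapse=relapse,
                death=death,
                followup_months=followup,
                tumor_content_fraction=purity[pid],
            )
        )

    truth = TruthSet(
        records=truth_records,
        purity=purity,
        mutated_group=mutated_group,
        survival_gene=cfg.survival_gene,
        hazard_ratio=cfg.hazard_ratio,
        baseline_hazard=cfg.baseline_hazard,
    )
    return SimBundle(
        variants=variants, panel=panel, snp_db=snp_db, predictors=predictors,
        clinical=clinical, truth=truth, origins=origins, cfg=cfg,
    )


# ---------------------------------------------------------------------------
# recovery metrics

def recovery_report(bundle: SimBundle, decisions: list[FilterDecision]) -> dict:
    """Sensitivity/specificity against the truth set.

    Sensitivity is reported per clonality class (subclonal recall is expected
    to be lower near the 5-20% VAF band); false discoveries are accepted
    variants attributable to artifact or SNP origins; per-gene frequency
    deviation compares the recovered patient fraction with the configured
    probability, with a binomial standard error.
    """
    if bundle.truth is None:
        raise ValueError("bundle has no truth set")
    accepted = {
        (d.variant.patient_id, *d.variant.key) for d in decisions if d.accepted
    }
    by_class: dict[str, list[bool]] = {"clonal": [], "subclonal": []}
    for t in bundle.truth.records:
        by_class[t.clonality].append(t.key in accepted)
    out: dict = {}
    for cls, hits in by_class.items():
        out[f"{cls}_sensitivity"] = (
            sum(hits) / len(hits) if hits else float("nan")
        )
        out[f"n_{cls}_truth"] = len(hits)
    false_pos = [
        k for k in accepted
        if bundle.origins.get(k, "truth") in ("artifact", "snp")
    ]
    out["false_discoveries"] = len(false_pos)

    n = len({p.patient_id for p in bundle.clinical}) or len(
        bundle.truth.purity
    )
    gene_rec: dict[str, set[str]] = {}
    for pid, chrom, pos, ref, alt in accepted:
        if bundle.origins.get((pid, chrom, pos, ref, alt)) == "truth":
            gene = next(
                (t.gene for t in bundle.truth.records
                 if t.key == (pid, chrom, pos, ref, alt)), None
            )
            if gene:
                gene_rec.setdefault(gene, set()).add(pid)
    gene_probs = (bundle.cfg or SimConfig()).gene_probs
    out["per_gene"] = {
        gene: {
            "configured": p,
            "recovered_fraction": len(gene_rec.get(gene, set())) / n,
            "binomial_se": math.sqrt(p * (1 - p) / n) if 0 < p < 1 else 0.0,
        }
        for gene, p in gene_probs.items()
    }
    return out


# ---------------------------------------------------------------------------
# the shipped toy fixture

def toy_bundle() -> SimBundle:
    """A 10-patient fixture in which exactly four variants survive the filter
    cascade; the six rejects each exercise one exclusion rule (low coverage,
    sub-5% VAF, known SNP, single-amplicon support, blacklist, primer
    proximity).  Deterministic by construction."""
    windows = load_cds_windows()
    panel = build_panel(windows)
    table = _build_codon_table()

    def find_sub(gene: str, effect: str, min_edge: int = 6) -> tuple[CdsWindow, int, str, str]:
        for w in windows[gene]:
            for idx in range(min_edge, len(w.seq) - min_edge):
                ref = w.seq[idx]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    if _substitution_effect(w, idx, alt) == effect:
                        return w, idx, ref, alt
        raise RuntimeError(f"no {effect} substitution found for {gene}")

    def amps_for(chrom: str, pos: int) -> list[Amplicon]:
        return _covering_amplicons(panel, chrom, pos)

    def split_counts(chrom: str, pos: int, cov: int, var: int) -> dict:
        covering = amps_for(chrom, pos)
        n = len(covering)
        counts = {}
        base_t, base_v = cov // n, var // n
        for i, a in enumerate(covering):
            t = base_t + (cov % n if i == 0 else 0)
            v = base_v + (var % n if i == 0 else 0)
            counts[a.amplicon_id] = (t, v)
        return counts

    variants: list[VariantCall] = []

    def add(pid, gene, chrom, pos, ref, alt, cov, var, phred, counts=None):
        covering = amps_for(chrom, pos)
        variants.append(
            VariantCall(
                patient_id=pid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene=gene, reads_total=cov, reads_variant=var, phred=phred,
                amplicon_ids=[a.amplicon_id for a in covering],
                per_amplicon_counts=(
                    counts if counts is not None
                    else split_counts(chrom, pos, cov, var)
                ),
            )
        )

    # accepted quartet
    add("P01", "MYD88", "chr3", 38182641, "T", "C", 150, 60, 35.0)  # Leu265Pro
    w, idx, ref, alt = find_sub("KMT2D", "nonsense")
    add("P02", "KMT2D", w.chrom, w.start + idx, ref, alt, 160, 64, 38.0)
    w, idx, ref, alt = find_sub("TNFAIP3", "missense")
    add("P03", "TNFAIP3", w.chrom, w.start + idx, ref, alt, 150, 72, 40.0)
    pest = next(x for x in windows["NOTCH1"] if x.contains("chr9", 139390945))
    del_idx = 30  # interior, away from the blacklist hotspot
    dref = pest.seq[del_idx : del_idx + 2]
    add("P04", "NOTCH1", "chr9", pest.start + del_idx, dref, dref[0], 140, 42, 36.0)

    # six designed rejects
    w, idx, ref, alt = find_sub("TP53", "missense")
    add("P05", "TP53", w.chrom, w.start + idx, ref, alt, 99, 40, 35.0)  # LOW_COVERAGE
    w, idx, ref, alt = find_sub("CARD11", "missense")
    add("P06", "CARD11", w.chrom, w.start + idx, ref, alt, 200, 6, 35.0)  # VAF 3%
    w, idx, ref, alt = find_sub("CYLD", "missense")
    snp_key = (w.chrom, w.start + idx, ref, alt)
    add("P07", "CYLD", *snp_key, 150, 70, 37.0)  # KNOWN_SNP
    w, idx, ref, alt = find_sub("NFKBIA", "missense", min_edge=65)
    covering = amps_for(w.chrom, w.start + idx)
    assert len(covering) >= 2, "single-amplicon scenario needs an overlap"
    counts = {covering[0].amplicon_id: (80, 12), covering[1].amplicon_id: (50, 0)}
    add("P08", "NFKBIA", w.chrom, w.start + idx, ref, alt, 130, 12, 36.0,
        counts=counts)  # SINGLE_AMPLICON_ONLY
    bl = pest.seq[139390945 - pest.start : 139390945 - pest.start + 2]
    add("P09", "NOTCH1", "chr9", 139390945, bl, bl[0], 160, 40, 37.0)  # BLACKLISTED
    w2 = windows["BCL10"][0]
    add("P10", "BCL10", w2.chrom, w2.start + 2, w2.seq[2],
        "A" if w2.seq[2] != "A" else "G", 150, 45, 36.0)  # PRIMER_PROXIMAL

    snp_db = {snp_key: SnpRecord(*snp_key)}
    predictors = {}
    for v in variants:
        if len(v.ref) == 1 and len(v.alt) == 1:
            dam = v.patient_id in ("P01", "P03")
            verdicts = {
                t: ("damaging" if dam else "tolerated") for t in PREDICTOR_TOOLS
            }
            predictors[v.key] = PredictorVerdicts(*v.key, verdicts=verdicts)

    clinical = []
    rng = np.random.default_rng(7)
    for i, v in enumerate(variants):
        pid = v.patient_id
        clinical.append(
            PatientRecord(
                patient_id=pid,
                age_years=float(55 + 2 * i),
                sex="M" if i % 3 else "F",
                ann_arbor_stage="I" if i < 8 else "II",
                localization=["orbita", "conjunctiva", "lacrimal gland"][i % 3],
                treatment="radiotherapy",
                relapse=bool(i in (0, 4)),
                death=False,
                followup_months=float(24 + 12 * i),
                tumor_content_fraction=float(0.70 + 0.02 * i),
            )
        )
    del rng
    return SimBundle(
        variants=variants, panel=panel, snp_db=snp_db, predictors=predictors,
        clinical=clinical, truth=None,
        origins={(v.patient_id, *v.key): "truth" for v in variants},
    )


# ---------------------------------------------------------------------------
# serialization

def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the full input bundle in the pipeline's file dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": outdir / "variants.tsv",
        "panel": outdir / "panel.bed",
        "snps": outdir / "snps.tsv",
        "predictors": outdir / "predictors.tsv",
        "clinical": outdir / "clinical.csv",
    }
    write_variant_table(bundle.variants, paths["variants"])
    write_amplicon_panel(bundle.panel, paths["panel"])
    write_snp_table(bundle.snp_db, paths["snps"])
    write_predictor_table(bundle.predictors, paths["predictors"])
    write_clinical_table(bundle.clinical, paths["clinical"])
    if bundle.truth is not None:
        paths["truth"] = outdir / "truth.tsv"
        with open(paths["truth"], "w") as fh:
            fh.write(
                "patient_id\tgene\tchrom\tpos\tref\talt\tclonality\tccf\t"
                "expected_vaf\tzygosity\tpurity\n"
            )
            for t in bundle.truth.records:
                fh.write(
                    f"{t.patient_id}\t{t.gene}\t{t.chrom}\t{t.pos}\t{t.ref}\t"
                    f"{t.alt}\t{t.clonality}\t{t.ccf:.6g}\t{t.expected_vaf:.6g}\t"
                    f"{t.zygosity}\t{bundle.truth.purity[t.patient_id]:.6g}\n"
                )
    return paths
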