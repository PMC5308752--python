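"""The variant-filter cascade for FFPE amplicon panels.

Raw candidate calls are reduced to accepted calls by composing, in order:
a quality/coverage gate (phred strictly above 30, coverage of at least 100
reads), a VAF band (below 5% rejected; 5-20% kept only as ``review_accept``;
20% and above auto-accepted), a mapping-ambiguity check driven by the panel,
a primer-proximity check at amplicon insert edges, an overlap-concordance
check between adjacent amplicons, and known-SNP / blacklist exclusion.

The manual review step used for 5-20% VAF calls in the original assay is
codified: a review-band variant passes only if every automatic check passes,
and it keeps the distinct ``review_accept`` verdict so downstream reports can
flag it.  Decisions are deterministic given inputs and config, and invariant
under permutation of the input list.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable

import yaml

from .io_formats import Amplicon, SnpRecord, VariantCall

__all__ = [
    "REASON_CODES",
    "FilterConfig",
    "FilterDecision",
    "default_blacklist",
    "quality_coverage_gate",
    "vaf_band",
    "primer_proximity_check",
    "overlap_concordance_check",
    "snp_and_blacklist_check",
    "run_filter_cascade",
    "write_decisions",
    "read_decisions",
]

REASON_CODES = (
    "LOW_PHRED",
    "LOW_COVERAGE",
    "VAF_BELOW_MIN",
    "PRIMER_PROXIMAL",
    "SINGLE_AMPLICON_ONLY",
    "AMBIGUOUS_MAPPING",
    "KNOWN_SNP",
    "BLACKLISTED",
)


def default_blacklist() -> set[tuple[str, int, str, str]]:
    """The packaged position blacklist (recurrent unvalidated artifacts)."""
    out: set[tuple[str, int, str, str]] = set()
    res = importlib_resources.files("oamlseq.resources").joinpath("blacklist.tsv")
    with res.open() as fh:
        next(fh)  # header
        for line in fh:
            chrom, pos, ref, alt = line.rstrip("\n").split("\t")[:4]
            out.add((chrom, int(pos), ref, alt))
    return out


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade.

    ``min_phred`` is exclusive (quality must exceed it); ``min_coverage`` is
    inclusive; the VAF bounds are inclusive at 5% and 20%.
    """

    min_phred: float = 30.0
    min_coverage: int = 100
    vaf_reject_below: float = 0.05
    vaf_auto_accept_at: float = 0.20
    primer_proximity_bp: int = 5
    min_overlap_support_reads: int = 1
    min_overlap_coverage: int = 20
    blacklist: set[tuple[str, int, str, str]] = field(default_factory=default_blacklist)

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf_reject_below <= self.vaf_auto_accept_at <= 1.0):
            raise ValueError("require 0 <= vaf_reject_below <= vaf_auto_accept_at <= 1")
        if self.min_coverage <= 0 or self.min_overlap_coverage <= 0:
            raise ValueError("coverage thresholds must be positive")
        if self.primer_proximity_bp < 0 or self.min_overlap_support_reads < 0:
            raise ValueError("negative threshold")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        section = doc.get("filter", doc)
        kwargs = {
            k: section[k]
            for k in (
                "min_phred",
                "min_coverage",
                "vaf_reject_below",
                "vaf_auto_accept_at",
                "primer_proximity_bp",
                "min_overlap_support_reads",
                "min_overlap_coverage",
            )
            if k in section
        }
        bl = section.get("blacklist", "default")
        if bl is None:
            kwargs["blacklist"] = set()
        elif bl != "default":
            kwargs["blacklist"] = _read_blacklist_file(bl)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "min_phred": self.min_phred,
            "min_coverage": self.min_coverage,
            "vaf_reject_below": self.vaf_reject_below,
            "vaf_auto_accept_at": self.vaf_auto_accept_at,
            "primer_proximity_bp": self.primer_proximity_bp,
            "min_overlap_support_reads": self.min_overlap_support_reads,
            "min_overlap_coverage": self.min_overlap_coverage,
            "blacklist_size": len(self.blacklist),
        }


def _read_blacklist_file(path: str | Path) -> set[tuple[str, int, str, str]]:
    out: set[tuple[str, int, str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "chrom\t")):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            out.add((chrom, int(pos), ref, alt))
    return out


@dataclass
class FilterDecision:
    """Accept/review/reject verdict plus machine-readable reason codes."""

    variant: VariantCall
    verdict: str  # accept | review_accept | reject
    reasons: list[str] = field(default_factory=list)
    vaf: float = float("nan")

    def __post_init__(self) -> None:
        bad = [r for r in self.reasons if r not in REASON_CODES]
        if bad:
            raise ValueError(f"unknown reason codes {bad}")
        if (self.verdict == "reject") != bool(self.reasons):
            raise ValueError("verdict 'reject' iff reasons non-empty")

    @property
    def accepted(self) -> bool:
        return self.verdict in ("accept", "review_accept")


# ---------------------------------------------------------------------------
# individual rules

def quality_coverage_gate(v: VariantCall, cfg: FilterConfig) -> list[str]:
    """LOW_PHRED iff phred <= min_phred; LOW_COVERAGE iff coverage < min_coverage."""
    codes = []
    if v.phred <= cfg.min_phred:
        codes.append("LOW_PHRED")
    if v.reads_total < cfg.min_coverage:
        codes.append("LOW_COVERAGE")
    return codes


def vaf_band(v: VariantCall, cfg: FilterConfig) -> str:
    """Band the VAF: < 5% -> "reject"; [5%, 20%) -> "review"; >= 20% -> "accept"."""
    if v.reads_total == 0:
        raise ValueError(f"VAF undefined at {v.chrom}:{v.pos}: zero coverage")
    vaf = v.vaf
    if vaf < cfg.vaf_reject_below:
        return "reject"
    if vaf < cfg.vaf_auto_accept_at:
        return "review"
    return "accept"


def _covering(v: VariantCall, panel: list[Amplicon]) -> list[Amplicon]:
    return [a for a in panel if a.covers(v.chrom, v.pos)]


def primer_proximity_check(
    v: VariantCall, panel: list[Amplicon], cfg: FilterConfig
) -> str | None:
    """PRIMER_PROXIMAL iff the position sits within ``primer_proximity_bp`` of
    the nearer insert edge in *every* covering amplicon; a variant interior to
    at least one covering amplicon passes.  Positions outside all amplicons
    take the AMBIGUOUS_MAPPING path (cannot be assessed)."""
    covering = _covering(v, panel)
    if not covering:
        return "AMBIGUOUS_MAPPING"
    if all(a.edge_distance(v.pos) < cfg.primer_proximity_bp for a in covering):
        return "PRIMER_PROXIMAL"
    return None


def overlap_concordance_check(
    v: VariantCall, panel: list[Amplicon], cfg: FilterConfig
) -> str | None:
    """SINGLE_AMPLICON_ONLY iff, among covering amplicons with per-amplicon
    counts and total reads >= ``min_overlap_coverage``, one amplicon lacks
    variant support while another has it.  With fewer than two sufficiently
    covered amplicons the rule is not evaluable and no code is returned."""
    evaluable = {
        amp: (tot, var)
        for amp, (tot, var) in v.per_amplicon_counts.items()
        if tot >= cfg.min_overlap_coverage
    }
    if len(evaluable) < 2:
        return None
    supports = [var >= cfg.min_overlap_support_reads for _, var in evaluable.values()]
    if any(supports) and not all(supports):
        return "SINGLE_AMPLICON_ONLY"
    return None


def snp_and_blacklist_check(
    v: VariantCall,
    snp_db: dict[tuple[str, int, str, str], SnpRecord],
    cfg: FilterConfig,
) -> list[str]:
    codes = []
    if v.key in snp_db:
        codes.append("KNOWN_SNP")
    if v.key in cfg.blacklist:
        codes.append("BLACKLISTED")
    return codes


# ---------------------------------------------------------------------------
# cascade

def run_filter_cascade(
    variants: Iterable[VariantCall],
    panel: list[Amplicon],
    snp_db: dict[tuple[str, int, str, str], SnpRecord],
    cfg: FilterConfig | None = None,
) -> list[FilterDecision]:
    """Apply all rules to every variant and return one decision per variant.

    Reasons accumulate: a variant failing several rules carries every code.
    Review-band variants (VAF in [5%, 20%)) are accepted as ``review_accept``
    only if no reason code fired.
    """
    cfg = cfg or FilterConfig()
    decisions = []
    for v in variants:
        reasons: list[str] = []
        reasons += quality_coverage_gate(v, cfg)
        band = "reject"
        if v.reads_total > 0:
            band = vaf_band(v, cfg)
            if band == "reject":
                reasons.append("VAF_BELOW_MIN")
        covering = _covering(v, panel)
        if any(a.mapping_ambiguous for a in covering):
            reasons.append("AMBIGUOUS_MAPPING")
        prox = primer_proximity_check(v, panel, cfg)
        if prox and prox not in reasons:
            reasons.append(prox)
        conc = overlap_concordance_check(v, panel, cfg)
        if conc:
            reasons.append(conc)
        reasons += snp_and_blacklist_check(v, snp_db, cfg)
        if reasons:
            verdict = "reject"
        elif band == "accept":
            verdict = "accept"
        else:
            verdict = "review_accept"
        vaf = v.vaf if v.reads_total > 0 else float("nan")
        decisions.append(FilterDecision(variant=v, verdict=verdict,
                                        reasons=reasons, vaf=vaf))
    return decisions


def write_decisions(decisions: Iterable[FilterDecision], path: str | Path) -> None:
    """One TSV row per variant: identity, verdict, semicolon-joined reasons."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["patient_id", "chrom", "pos", "ref", "alt", "gene",
             "vaf", "verdict", "reasons"]
        )
        for d in decisions:
            v = d.variant
            vaf = "" if math.isnan(d.vaf) else f"{d.vaf:.6g}"
            writer.writerow(
                [v.patient_id, v.chrom, v.pos, v.ref, v.alt, v.gene,
                 vaf, d.verdict, ";".join(d.reasons)]
            )


def read_decisions(
    path: str | Path, variants: Iterable[VariantCall]
) -> list[FilterDecision]:
    """Rehydrate decisions from a TSV, joining verdicts back onto the full
    variant records by (patient, chrom, pos, ref, alt)."""
    by_key = {(v.patient_id, *v.key): v for v in variants}
    out: list[FilterDecision] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = (row["patient_id"], row["chrom"], int(row["pos"]),
                   row["ref"], row["alt"])
            v = by_key.get(key)
            if v is None:
                raise ValueError(f"{path}: decision for unknown variant {key}")
            out.append(
                FilterDecision(
                    variant=v,
                    verdict=row["verdict"],
                    reasons=row["reasons"].split(";") if row["reasons"] else [],
                    vaf=float(row["vaf"]) if row["vaf"] else float("nan"),
                )
            )
    return out
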