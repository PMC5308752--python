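"""Mutation-type and protein-consequence annotation.

Accepted variants are classified by variant type (substitution / deletion /
insertion / complex) and protein effect (missense, nonsense, frameshift,
in-frame indel, synonymous), scored by the five-tool damaging consensus
(at least three of SIFT, PolyPhen2 HDIV/HVAR, LRT and MutationTaster must
agree), and mapped onto protein domains for lollipop-style summaries.

Coding context comes from compact single-transcript coding windows shipped
as an editable TSV resource (``cds_windows_synthetic.tsv``).  The windows
are synthetic: schematic in-frame coding stretches for the 24 panel genes,
consistent with the packaged panel and simulator rather than with any real
transcript annotation.  Domain intervals for NOTCH1, NOTCH2, KMT2D and
TNFAIP3 are approximate standard protein-annotation coordinates.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable

from .filter_engine import FilterDecision
from .io_formats import PredictorVerdicts, VariantCall

__all__ = [
    "VARIANT_TYPES",
    "PROTEIN_EFFECTS",
    "CdsWindow",
    "ConsequenceClass",
    "AnnotatedMutation",
    "load_cds_windows",
    "load_domain_map",
    "classify_variant_type",
    "classify_protein_effect",
    "damaging_consensus",
    "map_to_domain",
    "deleterious_flag",
    "annotate_mutations",
    "write_annotated_table",
    "read_annotated_table",
    "write_lollipop_table",
]

VARIANT_TYPES = ("substitution", "deletion", "insertion", "complex")
PROTEIN_EFFECTS = (
    "missense", "nonsense", "frameshift", "inframe_indel", "synonymous", "other",
)

_CODON_TABLE = {}


def _build_codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        bases = "TCAG"
        aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        codons = [a + b + c for a in bases for b in bases for c in bases]
        _CODON_TABLE.update(zip(codons, aas))
    return _CODON_TABLE


_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


@dataclass
class CdsWindow:
    """An in-frame coding window: ``seq[0:3]`` is the codon for ``aa_start``."""

    gene: str
    chrom: str
    start: int  # 1-based genomic position of seq[0]
    aa_start: int
    seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class ConsequenceClass:
    variant_type: str
    protein_effect: str
    protein_change: str = ""
    protein_pos: int | None = None


@dataclass
class AnnotatedMutation:
    """A filtered variant together with its functional annotation."""

    variant: VariantCall
    verdict: str
    consequence: ConsequenceClass
    damaging: str = "undetermined"  # yes | no | undetermined
    domain: str | None = None
    clonality: str | None = None  # filled by cohort_stats.classify_clonality

    @property
    def vaf(self) -> float:
        return self.variant.vaf

    @property
    def non_synonymous(self) -> bool:
        return self.consequence.protein_effect != "synonymous"


def load_cds_windows(path: str | Path | None = None) -> dict[str, list[CdsWindow]]:
    """Load coding windows keyed by gene, from a TSV or the packaged resource."""
    if path is None:
        res = importlib_resources.files("oamlseq.resources")
        fh = res.joinpath("cds_windows_synthetic.tsv").open()
    else:
        fh = open(path)
    windows: dict[str, list[CdsWindow]] = {}
    with fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            w = CdsWindow(
                gene=row["gene"],
                chrom=row["chrom"],
                start=int(row["start"]),
                aa_start=int(row["aa_start"]),
                seq=row["seq"].upper(),
            )
            if len(w.seq) % 3:
                raise ValueError(f"window {w.gene}:{w.start}: length not in frame")
            windows.setdefault(w.gene, []).append(w)
    return windows


def load_domain_map(
    path: str | Path | None = None,
) -> dict[str, list[tuple[str, int, int]]]:
    """Domain intervals (name, aa_start, aa_end) per gene, 1-based inclusive.

    Intervals are validated to be non-overlapping within a gene so domain
    lookup is a partition query.
    """
    if path is None:
        res = importlib_resources.files("oamlseq.resources")
        fh = res.joinpath("domains.tsv").open()
    else:
        fh = open(path)
    domains: dict[str, list[tuple[str, int, int]]] = {}
    with fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            domains.setdefault(row["gene"], []).append(
                (row["domain"], int(row["aa_start"]), int(row["aa_end"]))
            )
    for gene, intervals in domains.items():
        intervals.sort(key=lambda d: d[1])
        for (n1, s1, e1), (n2, s2, e2) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                raise ValueError(f"{gene}: overlapping domains {n1} and {n2}")
    return domains


# ---------------------------------------------------------------------------
# classification

def classify_variant_type(ref: str, alt: str) -> str:
    """Classify an allele pair by length arithmetic.

    Single-base equal-length exchange -> substitution; alt a proper prefix of
    ref -> deletion; ref a proper prefix of alt -> insertion; everything else
    (multi-base exchanges, combined events) -> complex.
    """
    if not ref or not alt:
        raise ValueError("empty allele")
    if ref == alt:
        raise ValueError("ref == alt")
    if len(ref) == 1 and len(alt) == 1:
        return "substitution"
    if len(alt) < len(ref) and ref.startswith(alt):
        return "deletion"
    if len(ref) < len(alt) and alt.startswith(ref):
        return "insertion"
    return "complex"


def classify_protein_effect(
    v: VariantCall, windows: dict[str, list[CdsWindow]]
) -> ConsequenceClass:
    """Protein-level consequence from the coding window covering the variant.

    Indels whose length change is not a multiple of 3 are frameshifts;
    substitutions introducing a stop codon are nonsense; positions outside
    every supplied window get effect "other" with a warning.
    """
    vt = classify_variant_type(v.ref, v.alt)
    window = next(
        (w for w in windows.get(v.gene, []) if w.contains(v.chrom, v.pos)), None
    )
    if window is None:
        warnings.warn(
            f"{v.gene} {v.chrom}:{v.pos}: outside supplied coding windows",
            stacklevel=2,
        )
        return ConsequenceClass(variant_type=vt, protein_effect="other")

    table = _build_codon_table()
    idx = v.pos - window.start

    if vt == "substitution":
        codon_i, off = divmod(idx, 3)
        ref_codon = window.seq[codon_i * 3 : codon_i * 3 + 3]
        if ref_codon[off] != v.ref:
            warnings.warn(
                f"{v.gene} {v.chrom}:{v.pos}: ref allele {v.ref!r} does not match "
                f"coding window base {ref_codon[off]!r}",
                stacklevel=2,
            )
        alt_codon = ref_codon[:off] + v.alt + ref_codon[off + 1 :]
        aa_ref, aa_alt = table[ref_codon], table[alt_codon]
        aa_pos = window.aa_start + codon_i
        if aa_alt == "*":
            return ConsequenceClass(vt, "nonsense", f"{_AA3[aa_ref]}{aa_pos}Ter", aa_pos)
        if aa_alt == aa_ref:
            return ConsequenceClass(vt, "synonymous", f"{_AA3[aa_ref]}{aa_pos}=", aa_pos)
        return ConsequenceClass(
            vt, "missense", f"{_AA3[aa_ref]}{aa_pos}{_AA3[aa_alt]}", aa_pos
        )

    if vt in ("deletion", "insertion"):
        change = abs(len(v.ref) - len(v.alt))
        # first affected base: after the shared prefix (anchor convention)
        anchor = len(v.alt) if vt == "deletion" else len(v.ref)
        codon_i = min((idx + anchor) // 3, len(window.seq) // 3 - 1)
        aa_pos = window.aa_start + codon_i
        aa_ref = table[window.seq[codon_i * 3 : codon_i * 3 + 3]]
        if change % 3:
            return ConsequenceClass(vt, "frameshift", f"{_AA3[aa_ref]}{aa_pos}fs", aa_pos)
        suffix = "del" if vt == "deletion" else "ins"
        return ConsequenceClass(
            vt, "inframe_indel", f"{_AA3[aa_ref]}{aa_pos}{suffix}", aa_pos
        )

    # complex events: no single-residue call is attempted
    return ConsequenceClass(vt, "other")


def damaging_consensus(verdicts: PredictorVerdicts) -> str:
    """"yes" iff >= 3 tools vote damaging, "no" iff >= 3 vote tolerated,
    otherwise "undetermined" (ties and unreachable quorums included)."""
    counts = Counter(verdicts.verdicts.values())
    if counts["damaging"] >= 3:
        return "yes"
    if counts["tolerated"] >= 3:
        return "no"
    return "undetermined"


def map_to_domain(
    gene: str,
    protein_pos: int | None,
    domain_map: dict[str, list[tuple[str, int, int]]],
) -> str | None:
    """The unique domain containing ``protein_pos``, or None (inter-domain,
    unknown gene, or no protein position)."""
    if protein_pos is None:
        return None
    if gene not in domain_map:
        return None
    for name, start, end in domain_map[gene]:
        if start <= protein_pos <= end:
            return name
    return None


def deleterious_flag(m: AnnotatedMutation) -> bool:
    """True for nonsense and frameshift mutations, and for missense mutations
    with a damaging consensus vote."""
    return m.consequence.protein_effect in ("nonsense", "frameshift") or (
        m.damaging == "yes"
    )


# ---------------------------------------------------------------------------
# driver

def annotate_mutations(
    decisions: Iterable[FilterDecision],
    predictors: dict[tuple[str, int, str, str], PredictorVerdicts] | None = None,
    windows: dict[str, list[CdsWindow]] | None = None,
    domain_map: dict[str, list[tuple[str, int, int]]] | None = None,
) -> list[AnnotatedMutation]:
    """Annotate every accepted (``accept``/``review_accept``) variant.

    The damaging vote is applied only to missense variants with at least
    three non-missing verdicts; nonsense and frameshift mutations are
    deleterious independent of the vote.
    """
    predictors = predictors or {}
    windows = windows if windows is not None else load_cds_windows()
    domain_map = domain_map if domain_map is not None else load_domain_map()
    out: list[AnnotatedMutation] = []
    for d in decisions:
        if not d.accepted:
            continue
        v = d.variant
        cons = classify_protein_effect(v, windows)
        damaging = "undetermined"
        if cons.protein_effect == "missense" and v.key in predictors:
            damaging = damaging_consensus(predictors[v.key])
        out.append(
            AnnotatedMutation(
                variant=v,
                verdict=d.verdict,
                consequence=cons,
                damaging=damaging,
                domain=map_to_domain(v.gene, cons.protein_pos, domain_map),
            )
        )
    return out


_ANNOTATED_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt", "gene",
    "reads_total", "reads_variant", "vaf", "verdict",
    "variant_type", "protein_effect", "protein_change", "protein_pos",
    "damaging", "deleterious", "domain", "clonality",
]


def write_annotated_table(
    mutations: Iterable[AnnotatedMutation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATED_COLUMNS)
        for m in mutations:
            v = m.variant
            writer.writerow(
                [v.patient_id, v.chrom, v.pos, v.ref, v.alt, v.gene,
                 v.reads_total, v.reads_variant, f"{v.vaf:.6g}", m.verdict,
                 m.consequence.variant_type, m.consequence.protein_effect,
                 m.consequence.protein_change,
                 m.consequence.protein_pos if m.consequence.protein_pos else "",
                 m.damaging, "yes" if deleterious_flag(m) else "no",
                 m.domain or "", m.clonality or ""]
            )


def read_annotated_table(path: str | Path) -> list[AnnotatedMutation]:
    """Read back an annotated-mutation TSV (inverse of the writer; amplicon
    context is not retained across the file boundary)."""
    out: list[AnnotatedMutation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            v = VariantCall(
                patient_id=row["patient_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=row["gene"],
                reads_total=int(row["reads_total"]),
                reads_variant=int(row["reads_variant"]),
                phred=float("nan"),
            )
            out.append(
                AnnotatedMutation(
                    variant=v,
                    verdict=row["verdict"],
                    consequence=ConsequenceClass(
                        variant_type=row["variant_type"],
                        protein_effect=row["protein_effect"],
                        protein_change=row["protein_change"],
                        protein_pos=(
                            int(row["protein_pos"]) if row["protein_pos"] else None
                        ),
                    ),
                    damaging=row["damaging"],
                    domain=row["domain"] or None,
                    clonality=row["clonality"] or None,
                )
            )
    return out


def write_lollipop_table(
    mutations: Iterable[AnnotatedMutation], path: str | Path
) -> None:
    """Per-gene protein-position counts for external lollipop plotting."""
    counts: Counter[tuple[str, int, str]] = Counter()
    for m in mutations:
        if m.consequence.protein_pos is not None and m.non_synonymous:
            counts[(m.variant.gene, m.consequence.protein_pos,
                    m.consequence.protein_effect)] += 1
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "protein_pos", "effect", "count"])
        for (gene, pos, effect), n in sorted(counts.items()):
            writer.writerow([gene, pos, effect, n])
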