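"""Cohort-level mutation landscape statistics.

Builds the patients x genes indicator matrix, per-gene and pathway mutation
frequencies, clonality calls from VAF relative to tumor purity, the
variant-type / deleterious summary, and the gene-pair co-occurrence screen
with a two-sided Fisher exact test.

The Fisher test is implemented from first principles (log-factorial
accumulation over the hypergeometric support, minimum-likelihood two-sided
rule): the two-sided p is the sum of point probabilities of all tables with
the observed margins whose probability does not exceed the observed table's,
within a relative tie tolerance of 1e-7.  This is the dominant convention in
statistical software and is numerically stable for N up to ~10^4.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from math import exp, lgamma, log
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotatedMutation, deleterious_flag

__all__ = [
    "panel_genes",
    "gene_pathways",
    "nfkb_gene_set",
    "CohortMatrix",
    "ClonalityCall",
    "build_matrix",
    "gene_frequencies",
    "pathway_frequency",
    "summary_statistics",
    "classify_clonality",
    "annotate_clonality",
    "vaf_by_gene",
    "fisher_exact_two_sided",
    "cooccurrence_screen",
    "write_matrix",
    "read_matrix",
]


def gene_pathways() -> dict[str, str]:
    """The 24-gene panel with each gene's signalling-pathway assignment."""
    res = importlib_resources.files("oamlseq.resources").joinpath("panel_genes.tsv")
    out: dict[str, str] = {}
    with res.open() as fh:
        next(fh)
        for line in fh:
            gene, pathway = line.rstrip("\n").split("\t")
            out[gene] = pathway
    return out


def panel_genes() -> list[str]:
    return list(gene_pathways())


def nfkb_gene_set() -> list[str]:
    """The 19 panel genes whose pathway assignment involves NF-kB signalling
    (canonical and/or non-canonical)."""
    return [g for g, p in gene_pathways().items() if "NF-kB" in p]


@dataclass
class CohortMatrix:
    """Patients x genes mutation indicator plus per-variant detail.

    ``indicator.loc[p, g]`` is True iff patient p carries >= 1 accepted
    non-synonymous mutation in gene g; a patient may contribute several
    detail rows to one gene.
    """

    patients: list[str]
    genes: list[str]
    indicator: pd.DataFrame
    detail: list[AnnotatedMutation] = field(default_factory=list)


@dataclass
class ClonalityCall:
    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    vaf: float
    label: str  # subclonal | clonal | clonal_possible_LOH_or_UPD
    expected_clonal_vaf: float | None = None


def build_matrix(
    mutations: Iterable[AnnotatedMutation],
    patients: Sequence[str],
    genes: Sequence[str] | None = None,
) -> CohortMatrix:
    """Build the indicator matrix over the full patient list.

    Synonymous mutations are excluded; patients with no mutations are
    retained as all-False rows.  A mutation for a patient absent from the
    list is an error.
    """
    genes = list(genes) if genes is not None else panel_genes()
    patients = list(patients)
    pset = set(patients)
    indicator = pd.DataFrame(False, index=patients, columns=genes)
    detail: list[AnnotatedMutation] = []
    for m in mutations:
        if not m.non_synonymous:
            continue
        pid, gene = m.variant.patient_id, m.variant.gene
        if pid not in pset:
            raise ValueError(f"mutation for unknown patient {pid!r}")
        if gene not in indicator.columns:
            raise ValueError(f"gene {gene!r} not in panel")
        indicator.loc[pid, gene] = True
        detail.append(m)
    return CohortMatrix(patients=patients, genes=genes,
                        indicator=indicator, detail=detail)


def gene_frequencies(m: CohortMatrix) -> pd.DataFrame:
    """Per-gene fraction of patients mutated, with counts alongside.

    Patients are counted once per gene regardless of mutation multiplicity.
    """
    if not m.patients:
        raise ValueError("empty cohort")
    counts = m.indicator.sum(axis=0)
    return pd.DataFrame(
        {
            "gene": m.genes,
            "n_mutated": counts.values.astype(int),
            "n_patients": len(m.patients),
            "fraction": counts.values / len(m.patients),
        }
    )


def pathway_frequency(m: CohortMatrix, gene_set: Sequence[str]) -> tuple[int, float]:
    """(count, fraction) of patients with >= 1 mutated gene-set member (union)."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = set(gene_set) - set(m.genes)
    if missing:
        raise ValueError(f"gene-set members not in matrix: {sorted(missing)}")
    hit = m.indicator[gene_set].any(axis=1)
    return int(hit.sum()), float(hit.mean())


def summary_statistics(m: CohortMatrix) -> dict:
    """Mean/range of mutated genes per patient, mutation-type breakdown and
    deleterious fraction (over non-synonymous mutations, not patients)."""
    per_patient = m.indicator.sum(axis=1)
    types = [d.consequence.variant_type for d in m.detail]
    n_mut = len(types)
    breakdown = {
        t: (types.count(t) / n_mut if n_mut else 0.0)
        for t in ("substitution", "deletion", "insertion", "complex")
    }
    n_del = sum(deleterious_flag(d) for d in m.detail)
    return {
        "n_patients": len(m.patients),
        "n_mutations": n_mut,
        "mean_mutated_genes": float(per_patient.mean()),
        "min_mutated_genes": int(per_patient.min()),
        "max_mutated_genes": int(per_patient.max()),
        "type_breakdown": breakdown,
        "deleterious_fraction": (n_del / n_mut) if n_mut else 0.0,
    }


# ---------------------------------------------------------------------------
# clonality

def classify_clonality(
    m: AnnotatedMutation, tumor_content_fraction: float | None = None
) -> ClonalityCall:
    """Label a mutation by VAF: below 20% subclonal; above 50% clonal with a
    possible second-allele loss or uniparental disomy; otherwise clonal.

    Both boundaries stay clonal (the subclonal rule is strict "<20%", the
    LOH/UPD flag strict ">50%").  The expected clonal heterozygous VAF is
    purity/2 when the tumor content is known.  The label is also written back
    onto the mutation.
    """
    vaf = m.vaf
    if vaf < 0.20:
        label = "subclonal"
    elif vaf > 0.50:
        label = "clonal_possible_LOH_or_UPD"
    else:
        label = "clonal"
    m.clonality = label
    v = m.variant
    return ClonalityCall(
        patient_id=v.patient_id,
        chrom=v.chrom,
        pos=v.pos,
        ref=v.ref,
        alt=v.alt,
        gene=v.gene,
        vaf=vaf,
        label=label,
        expected_clonal_vaf=(
            tumor_content_fraction / 2 if tumor_content_fraction is not None else None
        ),
    )


def annotate_clonality(
    mutations: Iterable[AnnotatedMutation],
    purity_by_patient: dict[str, float] | None = None,
) -> list[ClonalityCall]:
    purity_by_patient = purity_by_patient or {}
    return [
        classify_clonality(m, purity_by_patient.get(m.variant.patient_id))
        for m in mutations
    ]


def vaf_by_gene(m: CohortMatrix) -> pd.DataFrame:
    """Mean and SD of VAF per gene over non-synonymous mutations."""
    rows = [(d.variant.gene, d.vaf) for d in m.detail]
    df = pd.DataFrame(rows, columns=["gene", "vaf"])
    if df.empty:
        return pd.DataFrame(columns=["gene", "n", "mean_vaf", "sd_vaf"])
    g = df.groupby("gene")["vaf"]
    out = pd.DataFrame(
        {"n": g.size(), "mean_vaf": g.mean(), "sd_vaf": g.std(ddof=1)}
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# Fisher exact test and co-occurrence screen

def _lbinom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Full hypergeometric enumeration with fixed margins; tables whose point
    probability is within relative tolerance 1e-7 of the observed one count
    as ties and are included.  Any zero margin gives p = 1.
    """
    for x in (a, b, c, d):
        if not isinstance(x, (int, np.integer)) or x < 0:
            raise ValueError("cells must be non-negative integers")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    denom = _lbinom(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    lobs = _lbinom(r1, a) + _lbinom(r2, c1 - a) - denom
    cutoff = lobs + log(1 + 1e-7)
    total = 0.0
    for k in range(lo, hi + 1):
        lp = _lbinom(r1, k) + _lbinom(r2, c1 - k) - denom
        if lp <= cutoff:
            total += exp(lp)
    return min(total, 1.0)


def cooccurrence_screen(
    m: CohortMatrix, min_cases: int = 12, bh_correction: bool = False
) -> pd.DataFrame:
    """Pairwise co-occurrence / exclusivity screen over frequently mutated genes.

    Only genes mutated in at least ``min_cases`` patients enter.  Direction is
    "-" when the observed co-mutated count falls below the expectation under
    independence, "+" otherwise.  No multiple-testing correction by default;
    ``bh_correction`` adds Benjamini-Hochberg adjusted values.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    counts = m.indicator.sum(axis=0)
    eligible = [g for g in m.genes if counts[g] >= min_cases]
    rows = []
    n = len(m.patients)
    for i, ga in enumerate(eligible):
        for gb in eligible[i + 1 :]:
            va, vb = m.indicator[ga].values, m.indicator[gb].values
            n11 = int(np.sum(va & vb))
            n10 = int(np.sum(va & ~vb))
            n01 = int(np.sum(~va & vb))
            n00 = n - n11 - n10 - n01
            expected = counts[ga] * counts[gb] / n
            rows.append(
                {
                    "gene_a": ga,
                    "gene_b": gb,
                    "n_both": n11,
                    "n_a_only": n10,
                    "n_b_only": n01,
                    "n_neither": n00,
                    "expected_both": expected,
                    "direction": "-" if n11 < expected else "+",
                    "p_value": fisher_exact_two_sided(n11, n10, n01, n00),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "n_both", "n_a_only", "n_b_only",
                 "n_neither", "expected_both", "direction", "p_value"],
    )
    if bh_correction and not df.empty:
        from scipy.stats import false_discovery_control

        df["q_value"] = false_discovery_control(df["p_value"].values, method="bh")
    return df


# ---------------------------------------------------------------------------
# writers

def write_matrix(m: CohortMatrix, path: str | Path) -> None:
    """Oncoprint-style 0/1 matrix, patients as rows."""
    out = m.indicator.astype(int)
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> CohortMatrix:
    """Read an oncoprint 0/1 matrix back (detail rows are not retained)."""
    df = pd.read_csv(path, sep="\t", index_col="patient_id")
    df.index = df.index.astype(str)
    return CohortMatrix(
        patients=list(df.index),
        genes=list(df.columns),
        indicator=df.astype(bool),
    )


def write_frequency_table(m: CohortMatrix, path: str | Path) -> None:
    gene_frequencies(m).to_csv(path, sep="\t", index=False)


def write_clonality_table(calls: Iterable[ClonalityCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["patient_id", "chrom", "pos", "ref", "alt", "gene",
                         "vaf", "label", "expected_clonal_vaf"])
        for c in calls:
            writer.writerow(
                [c.patient_id, c.chrom, c.pos, c.ref, c.alt, c.gene,
                 f"{c.vaf:.6g}", c.label,
                 "" if c.expected_clonal_vaf is None
                 else f"{c.expected_clonal_vaf:.6g}"]
            )
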