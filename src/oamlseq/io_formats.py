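"""Readers and writers for the pipeline's external tables.

Five inputs feed the pipeline: per-position variant call tables (TSV dialect
or VCF), the amplicon panel (extended BED), a known-SNP list, precomputed
damaging-predictor verdicts, and the clinical table.  All coordinates are
held 1-based inclusive internally (VCF/GRCh37 convention); BED input is
converted on read.  VAF is always recomputed from read counts, never read
from a file.

The TSV variant dialect is a documented stand-in for a caller's native
export, whose schema is typically vendor-specific.  Columns::

    patient_id chrom pos ref alt gene reads_total reads_variant phred
    amplicon_ids per_amplicon_counts

``amplicon_ids`` is comma-joined; ``per_amplicon_counts`` is comma-joined
``amplicon:total:variant`` triples and may be empty (concordance checks then
degrade to "not evaluable").
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pysam

__all__ = [
    "VariantCall",
    "Amplicon",
    "SnpRecord",
    "PredictorVerdicts",
    "PatientRecord",
    "FormatError",
    "PREDICTOR_TOOLS",
    "read_variant_table",
    "write_variant_table",
    "read_amplicon_panel",
    "write_amplicon_panel",
    "read_snp_table",
    "write_snp_table",
    "read_predictor_table",
    "write_predictor_table",
    "read_clinical_table",
    "write_clinical_table",
]

PREDICTOR_TOOLS = ("SIFT", "PolyPhen2_HDIV", "PolyPhen2_HVAR", "LRT", "MutationTaster")

STAGES = ("I", "II", "III", "IV", "unknown")
LOCALIZATIONS = ("orbita", "conjunctiva", "lacrimal gland", "unknown")
TREATMENTS = ("radiotherapy", "immunochemotherapy", "anti-CD20", "none", "unknown")


class FormatError(ValueError):
    """Malformed input table; message carries file and row context."""


@dataclass
class VariantCall:
    """One candidate variant at one position in one patient sample."""

    patient_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    reads_total: int
    reads_variant: int
    phred: float
    amplicon_ids: list[str] = field(default_factory=list)
    per_amplicon_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("empty allele string")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.reads_total < 0 or self.reads_variant < 0:
            raise ValueError("negative read count")
        if self.reads_variant > self.reads_total:
            raise ValueError(
                f"reads_variant {self.reads_variant} > reads_total "
                f"{self.reads_total} at {self.chrom}:{self.pos}"
            )
        if self.per_amplicon_counts:
            tot = sum(t for t, _ in self.per_amplicon_counts.values())
            if tot != self.reads_total:
                raise ValueError(
                    f"per-amplicon totals ({tot}) != reads_total "
                    f"({self.reads_total}) at {self.chrom}:{self.pos}"
                )

    @property
    def vaf(self) -> float:
        """Variant allele frequency; NaN when coverage is zero."""
        if self.reads_total == 0:
            return float("nan")
        return self.reads_variant / self.reads_total

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class Amplicon:
    """One panel amplicon; insert coordinates exclude primers, 1-based inclusive."""

    amplicon_id: str
    chrom: str
    insert_start: int
    insert_end: int
    primer_len_5p: int = 0
    primer_len_3p: int = 0
    gene: str = ""
    mapping_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.insert_start > self.insert_end:
            raise ValueError(
                f"amplicon {self.amplicon_id}: insert_start > insert_end"
            )
        if self.primer_len_5p < 0 or self.primer_len_3p < 0:
            raise ValueError(f"amplicon {self.amplicon_id}: negative primer length")

    def covers(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.insert_start <= pos <= self.insert_end

    def edge_distance(self, pos: int) -> int:
        """Distance (bp) from pos to the nearer insert edge; 0 at the edge."""
        return min(pos - self.insert_start, self.insert_end - pos)


@dataclass(frozen=True)
class SnpRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    source: str = "db137"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PredictorVerdicts:
    """Damaging/tolerated/missing verdicts from the five prediction tools."""

    chrom: str
    pos: int
    ref: str
    alt: str
    verdicts: dict[str, str] = field(default_factory=dict)

    VALID = ("damaging", "tolerated", "missing")

    def __post_init__(self) -> None:
        for tool in PREDICTOR_TOOLS:
            self.verdicts.setdefault(tool, "missing")
        extra = set(self.verdicts) - set(PREDICTOR_TOOLS)
        if extra:
            raise ValueError(f"unknown predictor tools: {sorted(extra)}")
        for tool, v in self.verdicts.items():
            if v not in self.VALID:
                raise ValueError(f"invalid verdict {v!r} for {tool}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PatientRecord:
    patient_id: str
    age_years: float
    sex: str
    ann_arbor_stage: str
    localization: str
    treatment: str
    relapse: bool
    death: bool
    followup_months: float
    tumor_content_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.followup_months <= 0:
            raise ValueError(
                f"patient {self.patient_id}: followup_months must be > 0"
            )
        if self.ann_arbor_stage not in STAGES:
            raise ValueError(
                f"patient {self.patient_id}: bad stage {self.ann_arbor_stage!r}"
            )
        if self.localization not in LOCALIZATIONS:
            raise ValueError(
                f"patient {self.patient_id}: bad localization {self.localization!r}"
            )
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"patient {self.patient_id}: bad treatment {self.treatment!r}"
            )
        if self.tumor_content_fraction is not None:
            if not 0.0 <= self.tumor_content_fraction <= 1.0:
                raise ValueError(
                    f"patient {self.patient_id}: tumor content outside [0,1]"
                )
            if self.tumor_content_fraction < 0.70:
                warnings.warn(
                    f"patient {self.patient_id}: tumor content "
                    f"{self.tumor_content_fraction:.2f} below the 70% inclusion rule",
                    stacklevel=2,
                )


# ---------------------------------------------------------------------------
# variant tables

_VARIANT_COLUMNS = [
    "patient_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "reads_total",
    "reads_variant",
    "phred",
    "amplicon_ids",
    "per_amplicon_counts",
]


def _parse_amp_counts(text: str) -> dict[str, tuple[int, int]]:
    out: dict[str, tuple[int, int]] = {}
    if not text:
        return out
    for triple in text.split(","):
        amp, tot, var = triple.split(":")
        out[amp] = (int(tot), int(var))
    return out


def _fmt_amp_counts(counts: dict[str, tuple[int, int]]) -> str:
    return ",".join(f"{a}:{t}:{v}" for a, (t, v) in sorted(counts.items()))


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[VariantCall]:
    """Read variant calls from the TSV dialect or a VCF file.

    Invalid rows raise :class:`FormatError` with the offending row number.
    """
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variant_tsv(path: str | Path) -> list[VariantCall]:
    records: list[VariantCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_VARIANT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing required columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    VariantCall(
                        patient_id=row["patient_id"],
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        ref=row["ref"],
                        alt=row["alt"],
                        gene=row["gene"],
                        reads_total=int(row["reads_total"]),
                        reads_variant=int(row["reads_variant"]),
                        phred=float(row["phred"]),
                        amplicon_ids=(
                            row["amplicon_ids"].split(",")
                            if row["amplicon_ids"]
                            else []
                        ),
                        per_amplicon_counts=_parse_amp_counts(
                            row["per_amplicon_counts"]
                        ),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}: row {i}: {exc}") from exc
    return records


def write_variant_table(records: Iterable[VariantCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_VARIANT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.chrom,
                    r.pos,
                    r.ref,
                    r.alt,
                    r.gene,
                    r.reads_total,
                    r.reads_variant,
                    repr(r.phred),
                    ",".join(r.amplicon_ids),
                    _fmt_amp_counts(r.per_amplicon_counts),
                ]
            )


def _read_variant_vcf(path: str | Path) -> list[VariantCall]:
    """VCF 4.x dialect: DP/AD from FORMAT, gene/amplicons from INFO.

    INFO keys: ``GENE``, ``PATIENT``, ``AMPLICONS`` (comma list),
    ``AMPCOUNTS`` (``amp|total|variant`` comma list).  The record QUAL column
    carries the variant quality score.
    """
    records: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for i, rec in enumerate(vf.fetch() if vf.index else vf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(f"{path}: record {i}: expected one ALT allele")
            patient = rec.info.get("PATIENT")
            if patient is None and samples:
                patient = samples[0]
            if patient is None:
                raise FormatError(f"{path}: record {i}: no PATIENT info or sample")
            dp = ad = None
            if samples:
                fmt = rec.samples[samples[0]]
                dp = fmt.get("DP")
                ad = fmt.get("AD")
            if dp is None or ad is None:
                raise FormatError(
                    f"{path}: record {i}: missing coverage (DP/AD required)"
                )
            amp_ids = list(rec.info.get("AMPLICONS", ()) or ())
            amp_counts: dict[str, tuple[int, int]] = {}
            for triple in rec.info.get("AMPCOUNTS", ()) or ():
                amp, tot, var = triple.split("|")
                amp_counts[amp] = (int(tot), int(var))
            try:
                records.append(
                    VariantCall(
                        patient_id=str(patient),
                        chrom=rec.chrom,
                        pos=rec.pos,  # pysam exposes 1-based pos
                        ref=rec.ref,
                        alt=rec.alts[0],
                        gene=str(rec.info.get("GENE", "")),
                        reads_total=int(dp),
                        reads_variant=int(ad[1]),
                        phred=float(rec.qual if rec.qual is not None else 0.0),
                        amplicon_ids=[str(a) for a in amp_ids],
                        per_amplicon_counts=amp_counts,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: record {i}: {exc}") from exc
    return records


def write_variant_vcf(records: list[VariantCall], path: str | Path) -> None:
    """Write calls as a single-sample plain-text VCF (see ``_read_variant_vcf``)."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="HUGO symbol">')
    header.add_line('##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient id">')
    header.add_line(
        '##INFO=<ID=AMPLICONS,Number=.,Type=String,Description="Covering amplicons">'
    )
    header.add_line(
        '##INFO=<ID=AMPCOUNTS,Number=.,Type=String,'
        'Description="Per-amplicon amp|total|variant read counts">'
    )
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    for chrom in dict.fromkeys(r.chrom for r in records):
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_sample("SAMPLE")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in records:
            rec = vf.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                alleles=(r.ref, r.alt),
                qual=r.phred,
            )
            rec.info["GENE"] = r.gene
            rec.info["PATIENT"] = r.patient_id
            if r.amplicon_ids:
                rec.info["AMPLICONS"] = tuple(r.amplicon_ids)
            if r.per_amplicon_counts:
                rec.info["AMPCOUNTS"] = tuple(
                    f"{a}|{t}|{v}" for a, (t, v) in sorted(r.per_amplicon_counts.items())
                )
            rec.samples["SAMPLE"]["DP"] = r.reads_total
            rec.samples["SAMPLE"]["AD"] = (
                r.reads_total - r.reads_variant,
                r.reads_variant,
            )
            vf.write(rec)


# ---------------------------------------------------------------------------
# amplicon panel

def read_amplicon_panel(path: str | Path) -> list[Amplicon]:
    """Read the panel from extended BED.

    Columns: chrom, start (0-based), end (half-open), amplicon_id, score,
    strand, primer_len_5p, primer_len_3p, then optional gene and
    mapping_ambiguous (0/1).  Insert coordinates are the amplicon with both
    primers trimmed, converted to 1-based inclusive.  Strand is parsed but
    ignored by all computations.
    """
    amplicons: list[Amplicon] = []
    seen: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}: line {i}: expected >= 8 BED columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise FormatError(f"{path}: line {i}: start >= end")
            if name in seen:
                raise FormatError(f"{path}: line {i}: duplicate amplicon_id {name!r}")
            seen.add(name)
            p5, p3 = int(parts[6]), int(parts[7])
            gene = parts[8] if len(parts) > 8 else ""
            ambiguous = bool(int(parts[9])) if len(parts) > 9 else False
            try:
                amplicons.append(
                    Amplicon(
                        amplicon_id=name,
                        chrom=chrom,
                        insert_start=start + 1 + p5,  # BED->1-based, trim 5' primer
                        insert_end=end - p3,
                        primer_len_5p=p5,
                        primer_len_3p=p3,
                        gene=gene,
                        mapping_ambiguous=ambiguous,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: {exc}") from exc
    if not amplicons:
        warnings.warn(f"{path}: empty amplicon panel", stacklevel=2)
    amplicons.sort(key=lambda a: (a.chrom, a.insert_start))
    return amplicons


def write_amplicon_panel(amplicons: Iterable[Amplicon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in sorted(amplicons, key=lambda a: (a.chrom, a.insert_start)):
            bed_start = a.insert_start - 1 - a.primer_len_5p
            bed_end = a.insert_end + a.primer_len_3p
            fh.write(
                "\t".join(
                    [
                        a.chrom,
                        str(bed_start),
                        str(bed_end),
                        a.amplicon_id,
                        "0",
                        "+",
                        str(a.primer_len_5p),
                        str(a.primer_len_3p),
                        a.gene,
                        str(int(a.mapping_ambiguous)),
                    ]
                )
                + "\n"
            )


def overlapping_pairs(amplicons: list[Amplicon]) -> list[tuple[str, str]]:
    """Amplicon-id pairs sharing >= 1 bp of insert on the same chromosome."""
    pairs = []
    by_chrom: dict[str, list[Amplicon]] = {}
    for a in amplicons:
        by_chrom.setdefault(a.chrom, []).append(a)
    for group in by_chrom.values():
        group = sorted(group, key=lambda a: a.insert_start)
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if b.insert_start > a.insert_end:
                    break
                pairs.append((a.amplicon_id, b.amplicon_id))
    return pairs


# ---------------------------------------------------------------------------
# SNP list

def read_snp_table(path: str | Path) -> dict[tuple[str, int, str, str], SnpRecord]:
    """Read the known-SNP list (4-column TSV + optional source), keyed by allele."""
    db: dict[tuple[str, int, str, str], SnpRecord] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {i}: expected >= 4 columns")
            rec = SnpRecord(
                chrom=parts[0],
                pos=int(parts[1]),
                ref=parts[2],
                alt=parts[3],
                source=parts[4] if len(parts) > 4 else "db137",
            )
            db[rec.key] = rec
    return db


def write_snp_table(
    db: dict[tuple[str, int, str, str], SnpRecord] | Iterable[SnpRecord],
    path: str | Path,
) -> None:
    records = db.values() if isinstance(db, dict) else db
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsource\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.source}\n")


# ---------------------------------------------------------------------------
# predictor verdicts

def read_predictor_table(
    path: str | Path,
) -> dict[tuple[str, int, str, str], PredictorVerdicts]:
    db: dict[tuple[str, int, str, str], PredictorVerdicts] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom", "pos", "ref", "alt", *PREDICTOR_TOOLS}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                rec = PredictorVerdicts(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    verdicts={t: row[t] for t in PREDICTOR_TOOLS},
                )
            except ValueError as exc:
                raise FormatError(f"{path}: row {i}: {exc}") from exc
            db[rec.key] = rec
    return db


def write_predictor_table(
    db: dict[tuple[str, int, str, str], PredictorVerdicts] | Iterable[PredictorVerdicts],
    path: str | Path,
) -> None:
    records = db.values() if isinstance(db, dict) else db
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "alt", *PREDICTOR_TOOLS])
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            writer.writerow(
                [r.chrom, r.pos, r.ref, r.alt]
                + [r.verdicts[t] for t in PREDICTOR_TOOLS]
            )


# ---------------------------------------------------------------------------
# clinical table

_CLINICAL_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "ann_arbor_stage",
    "localization",
    "treatment",
    "relapse",
    "death",
    "followup_months",
    "tumor_content_fraction",
]

_STAGE_MAP = {"1": "I", "2": "II", "3": "III", "4": "IV"}


def normalize_stage(raw: str) -> str:
    """Normalize an Ann Arbor stage string to I/II/III/IV/unknown.

    Suffix letters (E for extranodal, A/B symptom annotation) are stripped,
    so e.g. "IEA" normalizes to "I".
    """
    s = raw.strip().upper()
    if not s or s in ("NA", "UNKNOWN", "?"):
        return "unknown"
    s = _STAGE_MAP.get(s, s)
    for stage in ("IV", "III", "II", "I"):
        if s.startswith(stage):
            rest = s[len(stage):]
            if all(c in "EAB SX" for c in rest):
                return stage
    raise ValueError(f"unparseable Ann Arbor stage {raw!r}")


def _normalize_enum(raw: str, allowed: tuple[str, ...], aliases: dict[str, str]) -> str:
    s = raw.strip().lower()
    if not s or s in ("na", "unknown", "?"):
        return "unknown"
    s = aliases.get(s, s)
    if s in allowed:
        return s
    raise ValueError(f"unrecognized value {raw!r} (allowed: {allowed})")


_LOC_ALIASES = {"orbit": "orbita", "lacrimal": "lacrimal gland"}
_TREAT_ALIASES = {
    "rt": "radiotherapy",
    "anti-cd20 antibody": "anti-CD20",
    "anti-cd20": "anti-CD20",
    "rituximab": "anti-CD20",
    "no therapy": "none",
}


def _parse_bool(raw: str) -> bool:
    s = raw.strip().lower()
    if s in ("yes", "y", "true", "1"):
        return True
    if s in ("no", "n", "false", "0"):
        return False
    raise ValueError(f"unparseable boolean {raw!r}")


def read_clinical_table(path: str | Path) -> list[PatientRecord]:
    """Read the clinical table (CSV); categorical fields are normalized,
    unknowns preserved as "unknown" rather than dropped."""
    records: list[PatientRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = set(_CLINICAL_COLUMNS) - {"tumor_content_fraction"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                tcf = row.get("tumor_content_fraction", "")
                records.append(
                    PatientRecord(
                        patient_id=row["patient_id"],
                        age_years=float(row["age_years"]),
                        sex=row["sex"].strip().upper() or "unknown",
                        ann_arbor_stage=normalize_stage(row["ann_arbor_stage"]),
                        localization=_normalize_enum(
                            row["localization"], LOCALIZATIONS, _LOC_ALIASES
                        ),
                        treatment=_normalize_enum(
                            row["treatment"], TREATMENTS, _TREAT_ALIASES
                        ),
                        relapse=_parse_bool(row["relapse"]),
                        death=_parse_bool(row["death"]),
                        followup_months=float(row["followup_months"]),
                        tumor_content_fraction=float(tcf) if tcf else None,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: row {i}: {exc}") from exc
    return records


def write_clinical_table(records: Iterable[PatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_CLINICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    repr(r.age_years),
                    r.sex,
                    r.ann_arbor_stage,
                    r.localization,
                    r.treatment,
                    "yes" if r.relapse else "no",
                    "yes" if r.death else "no",
                    repr(r.followup_months),
                    "" if r.tumor_content_fraction is None
                    else repr(r.tumor_content_fraction),
                ]
            )
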