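"""Variant typing, protein consequences, damaging consensus, domain mapping."""

from itertools import product

import pytest

from oamlseq.annotation import (
    annotate_mutations,
    classify_protein_effect,
    classify_variant_type,
    damaging_consensus,
    deleterious_flag,
    load_cds_windows,
    load_domain_map,
    map_to_domain,
    read_annotated_table,
    write_annotated_table,
    AnnotatedMutation,
    ConsequenceClass,
)
from oamlseq.io_formats import PredictorVerdicts, VariantCall, PREDICTOR_TOOLS


@pytest.fixture(scope="module")
def windows():
    return load_cds_windows()


@pytest.fixture(scope="module")
def domains():
    return load_domain_map()


# ---------------------------------------------------------------------------
# variant type

def _type_oracle(ref: str, alt: str) -> str:
    """Alignment-free length-table oracle for allele-pair classification."""
    if len(ref) == len(alt):
        return "substitution" if len(ref) == 1 else "complex"
    shorter, longer = sorted((ref, alt), key=len)
    if longer.startswith(shorter):
        return "deletion" if len(ref) > len(alt) else "insertion"
    return "complex"


def test_variant_type_matches_oracle_exhaustively():
    """Agreement with the brute-force table on every allele pair up to length 4."""
    alleles = [
        "".join(p)
        for n in range(1, 5)
        for p in product("ACGT", repeat=n)
    ]
    for ref in alleles:
        for alt in alleles:
            if ref == alt:
                continue
            assert classify_variant_type(ref, alt) == _type_oracle(ref, alt), \
                (ref, alt)


@pytest.mark.parametrize(
    "ref, alt, expected",
    [("T", "C", "substitution"), ("CAG", "C", "deletion"),
     ("C", "CAG", "insertion"), ("AT", "GC", "complex"),
     ("ATG", "CG", "complex")],
)
def test_variant_type_examples(ref, alt, expected):
    assert classify_variant_type(ref, alt) == expected


def test_variant_type_rejects_empty_allele():
    with pytest.raises(ValueError, match="empty allele"):
        classify_variant_type("", "A")


# ---------------------------------------------------------------------------
# protein effect

def _vc(gene, chrom, pos, ref, alt):
    return VariantCall("P01", chrom, pos, ref, alt, gene, 150, 60, 35.0)


def test_myd88_hotspot_is_leu265pro(windows):
    cons = classify_protein_effect(_vc("MYD88", "chr3", 38182641, "T", "C"),
                                   windows)
    assert cons.protein_effect == "missense"
    assert cons.protein_change == "Leu265Pro"
    assert cons.protein_pos == 265


def test_notch1_pest_deletion_is_frameshift(windows, domains):
    w = next(x for x in windows["NOTCH1"] if x.contains("chr9", 139390945))
    pos = w.start + 33
    ref = w.seq[33:35]
    cons = classify_protein_effect(
        _vc("NOTCH1", "chr9", pos, ref, ref[0]), windows
    )
    assert cons.protein_effect == "frameshift"
    assert map_to_domain("NOTCH1", cons.protein_pos, domains) == "PEST"


def test_inframe_deletion(windows):
    w = windows["MYD88"][0]
    ref = w.seq[9:13]  # anchor + 3 deleted bases
    cons = classify_protein_effect(
        _vc("MYD88", w.chrom, w.start + 9, ref, ref[0]), windows
    )
    assert cons.protein_effect == "inframe_indel"


def test_nonsense_substitution(windows):
    # find a stop-creating change in the KMT2D SET window
    from oamlseq.synthetic_cohort import _substitution_effect

    w = windows["KMT2D"][0]
    for idx in range(6, len(w.seq) - 6):
        for alt in "ACGT":
            if alt != w.seq[idx] and \
                    _substitution_effect(w, idx, alt) == "nonsense":
                cons = classify_protein_effect(
                    _vc("KMT2D", w.chrom, w.start + idx, w.seq[idx], alt),
                    windows,
                )
                assert cons.protein_effect == "nonsense"
                assert cons.protein_change.endswith("Ter")
                return
    pytest.fail("no stop-creating substitution found")


def test_synonymous_classified_not_nonsynonymous(windows):
    from oamlseq.synthetic_cohort import _substitution_effect

    for gene, ws in windows.items():
        for w in ws:
            for idx in range(6, len(w.seq) - 6):
                for alt in "ACGT":
                    if alt != w.seq[idx] and \
                            _substitution_effect(w, idx, alt) == "synonymous":
                        cons = classify_protein_effect(
                            _vc(gene, w.chrom, w.start + idx, w.seq[idx], alt),
                            windows,
                        )
                        assert cons.protein_effect == "synonymous"
                        return
    pytest.fail("no synonymous substitution found")


def test_position_outside_windows_is_other_with_warning(windows):
    with pytest.warns(UserWarning, match="outside supplied coding windows"):
        cons = classify_protein_effect(_vc("MYD88", "chr3", 1000, "A", "G"),
                                       windows)
    assert cons.protein_effect == "other"


# ---------------------------------------------------------------------------
# damaging consensus

def _verdicts(*slots):
    mapping = {"D": "damaging", "T": "tolerated", "M": "missing"}
    return PredictorVerdicts(
        "chr1", 1, "A", "G",
        verdicts={t: mapping[s] for t, s in zip(PREDICTOR_TOOLS, slots)},
    )


@pytest.mark.parametrize(
    "slots, expected",
    [
        (("D", "D", "D", "T", "T"), "yes"),
        (("D", "D", "T", "T", "T"), "no"),
        (("D", "D", "M", "M", "M"), "undetermined"),  # quorum unreachable
        (("D", "D", "T", "T", "M"), "undetermined"),  # 2-2 tie
        (("D", "D", "D", "D", "D"), "yes"),
        (("M", "M", "M", "M", "M"), "undetermined"),
    ],
)
def test_damaging_consensus_three_of_five(slots, expected):
    assert damaging_consensus(_verdicts(*slots)) == expected


# ---------------------------------------------------------------------------
# domains

def test_set_domain_mapping(domains):
    assert map_to_domain("KMT2D", 5450, domains) == "SET"


def test_notch2_pest_mapping(domains):
    assert map_to_domain("NOTCH2", 2430, domains) == "PEST"


def test_position_before_first_domain_maps_to_none(domains):
    assert map_to_domain("NOTCH1", 1, domains) is None


def test_unknown_gene_maps_to_none(domains):
    assert map_to_domain("NOSUCH", 100, domains) is None


def test_domains_partition_protein_positions(domains):
    """Each protein position lies in at most one domain interval."""
    for gene, intervals in domains.items():
        for pos in range(1, max(e for _, _, e in intervals) + 2):
            hits = [n for n, s, e in intervals if s <= pos <= e]
            assert len(hits) <= 1, (gene, pos, hits)


# ---------------------------------------------------------------------------
# deleterious flag and driver

def _annotated(effect, damaging="undetermined"):
    return AnnotatedMutation(
        variant=_vc("GENE", "chr1", 10, "A", "G"),
        verdict="accept",
        consequence=ConsequenceClass("substitution", effect),
        damaging=damaging,
    )


@pytest.mark.parametrize(
    "effect, damaging, expected",
    [
        ("frameshift", "undetermined", True),
        ("nonsense", "undetermined", True),
        ("missense", "yes", True),
        ("missense", "no", False),
        ("missense", "undetermined", False),
        ("inframe_indel", "undetermined", False),
    ],
)
def test_deleterious_flag(effect, damaging, expected):
    assert deleterious_flag(_annotated(effect, damaging)) is expected


def test_annotate_covers_accepted_only(toy, toy_decisions):
    muts = annotate_mutations(toy_decisions, toy.predictors)
    assert {m.variant.patient_id for m in muts} == {"P01", "P02", "P03", "P04"}
    for m in muts:
        assert m.consequence.variant_type in \
            ("substitution", "deletion", "insertion", "complex")
        assert m.consequence.protein_effect != "other"
    by_patient = {m.variant.patient_id: m for m in muts}
    assert by_patient["P01"].consequence.protein_change == "Leu265Pro"
    assert by_patient["P01"].damaging == "yes"
    assert by_patient["P02"].consequence.protein_effect == "nonsense"
    assert by_patient["P04"].consequence.protein_effect == "frameshift"
    assert by_patient["P04"].domain == "PEST"


def test_annotated_table_round_trip(tmp_path, toy, toy_decisions):
    muts = annotate_mutations(toy_decisions, toy.predictors)
    path = tmp_path / "ann.tsv"
    write_annotated_table(muts, path)
    back = read_annotated_table(path)
    assert len(back) == len(muts)
    for a, b in zip(muts, back):
        assert a.consequence == b.consequence
        assert a.damaging == b.damaging
        assert a.domain == b.domain
        assert a.variant.key == b.variant.key
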