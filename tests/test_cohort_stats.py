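"""Cohort matrix, frequencies, clonality, Fisher exact test, co-occurrence."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oamlseq.annotation import AnnotatedMutation, ConsequenceClass
from oamlseq.cohort_stats import (
    CohortMatrix,
    build_matrix,
    classify_clonality,
    cooccurrence_screen,
    fisher_exact_two_sided,
    gene_frequencies,
    nfkb_gene_set,
    panel_genes,
    pathway_frequency,
    read_matrix,
    summary_statistics,
    vaf_by_gene,
    write_matrix,
)
from oamlseq.io_formats import VariantCall


def _mut(pid, gene, vaf=0.4, effect="missense", vtype="substitution",
         damaging="undetermined", pos=100):
    total = 200
    return AnnotatedMutation(
        variant=VariantCall(pid, "chr1", pos, "A", "G", gene, total,
                            int(round(vaf * total)), 35.0),
        verdict="accept",
        consequence=ConsequenceClass(vtype, effect),
        damaging=damaging,
    )


def test_panel_has_24_genes_and_19_nfkb_members():
    assert len(panel_genes()) == 24
    nfkb = nfkb_gene_set()
    assert len(nfkb) == 19
    for excluded in ("KMT2D", "NOTCH1", "NOTCH2", "TP53", "FAS"):
        assert excluded not in nfkb


class TestBuildMatrix:
    def test_indicator_rows(self):
        muts = [_mut("P1", "MYD88"), _mut("P1", "KMT2D"), _mut("P3", "MYD88")]
        m = build_matrix(muts, ["P1", "P2", "P3"])
        assert m.indicator.loc["P1", "MYD88"]
        assert m.indicator.loc["P1", "KMT2D"]
        assert not m.indicator.loc["P2"].any()
        assert m.indicator.loc["P3", "MYD88"]

    def test_double_mutation_one_cell_two_detail_rows(self):
        muts = [_mut("P1", "TNFAIP3", pos=100), _mut("P1", "TNFAIP3", pos=200)]
        m = build_matrix(muts, ["P1"])
        assert int(m.indicator.values.sum()) == 1
        assert len(m.detail) == 2

    def test_empty_mutations_all_false(self):
        m = build_matrix([], ["P1", "P2"])
        assert not m.indicator.values.any()

    def test_unknown_patient_is_error(self):
        with pytest.raises(ValueError, match="unknown patient"):
            build_matrix([_mut("P9", "MYD88")], ["P1"])

    def test_synonymous_excluded(self):
        m = build_matrix([_mut("P1", "MYD88", effect="synonymous")], ["P1"])
        assert not m.indicator.values.any()
        assert m.detail == []


class TestFrequencies:
    def test_fraction_with_counts(self):
        muts = [_mut(f"P{i}", "MYD88") for i in range(12)]
        m = build_matrix(muts, [f"P{i}" for i in range(63)])
        freq = gene_frequencies(m).set_index("gene")
        assert freq.loc["MYD88", "n_mutated"] == 12
        assert freq.loc["MYD88", "fraction"] == pytest.approx(12 / 63)
        assert freq.loc["CD79A", "fraction"] == 0.0

    def test_all_patients_mutated(self):
        muts = [_mut(f"P{i}", "TNFAIP3") for i in range(3)]
        m = build_matrix(muts, [f"P{i}" for i in range(3)])
        freq = gene_frequencies(m).set_index("gene")
        assert freq.loc["TNFAIP3", "fraction"] == 1.0

    def test_column_sums_equal_counts(self):
        muts = [_mut("P1", "MYD88"), _mut("P2", "MYD88"), _mut("P2", "KMT2D")]
        m = build_matrix(muts, ["P1", "P2", "P3"])
        freq = gene_frequencies(m).set_index("gene")
        assert (freq["n_mutated"] == m.indicator.sum(axis=0)).all()

    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError, match="empty cohort"):
            gene_frequencies(build_matrix([], []))


class TestPathwayFrequency:
    def test_non_member_not_counted(self):
        m = build_matrix([_mut("P1", "KMT2D")], ["P1"])
        assert pathway_frequency(m, nfkb_gene_set()) == (0, 0.0)

    def test_union_counts_once(self):
        m = build_matrix([_mut("P1", "TNFAIP3"), _mut("P1", "MYD88")], ["P1"])
        assert pathway_frequency(m, nfkb_gene_set()) == (1, 1.0)

    def test_empty_gene_set_is_error(self):
        m = build_matrix([], ["P1"])
        with pytest.raises(ValueError, match="empty gene set"):
            pathway_frequency(m, [])

    def test_union_frequency_matches_independence_oracle(self):
        """Monte-Carlo: with independent per-gene Bernoulli mutation calls the
        union frequency approaches 1 - prod(1 - p_g)."""
        rng = np.random.default_rng(11)
        genes = ["TNFAIP3", "MYD88", "BCL10", "NFKBIA"]
        probs = np.array([0.27, 0.19, 0.06, 0.03])
        n, reps = 63, 100
        expected = 1 - np.prod(1 - probs)
        fractions = []
        for _ in range(reps):
            draws = rng.random((n, len(genes))) < probs
            muts = [
                _mut(f"P{i}", genes[j])
                for i in range(n)
                for j in range(len(genes))
                if draws[i, j]
            ]
            m = build_matrix(muts, [f"P{i}" for i in range(n)])
            fractions.append(pathway_frequency(m, genes)[1])
        se = np.sqrt(expected * (1 - expected) / (n * reps))
        assert abs(np.mean(fractions) - expected) < 3 * se


class TestSummaryStatistics:
    def test_mean_and_range(self):
        muts = ([_mut("P2", "MYD88")] +
                [_mut("P3", "MYD88"), _mut("P3", "KMT2D")] +
                [_mut("P4", "TNFAIP3"), _mut("P4", "BCL10")])
        m = build_matrix(muts, ["P1", "P2", "P3", "P4"])
        st_ = summary_statistics(m)
        assert st_["mean_mutated_genes"] == pytest.approx(1.25)
        assert (st_["min_mutated_genes"], st_["max_mutated_genes"]) == (0, 2)

    def test_type_breakdown_over_mutations(self):
        muts = ([_mut(f"P{i}", "KMT2D", vtype="substitution") for i in range(7)]
                + [_mut("P7", "KMT2D", vtype="deletion"),
                   _mut("P8", "KMT2D", vtype="deletion"),
                   _mut("P9", "KMT2D", vtype="insertion")])
        m = build_matrix(muts, [f"P{i}" for i in range(10)])
        bd = summary_statistics(m)["type_breakdown"]
        assert bd == {"substitution": 0.7, "deletion": 0.2,
                      "insertion": 0.1, "complex": 0.0}

    def test_deleterious_fraction(self):
        muts = [_mut("P1", "KMT2D", effect="nonsense"),
                _mut("P2", "KMT2D", effect="missense", damaging="yes"),
                _mut("P3", "KMT2D", effect="missense", damaging="no"),
                _mut("P4", "KMT2D", effect="missense")]
        m = build_matrix(muts, ["P1", "P2", "P3", "P4"])
        assert summary_statistics(m)["deleterious_fraction"] == pytest.approx(0.5)


class TestClonality:
    @pytest.mark.parametrize(
        "vaf, label",
        [
            (0.19, "subclonal"),
            (0.20, "clonal"),                      # boundary stays clonal
            (0.48, "clonal"),
            (0.50, "clonal"),                      # LOH flag is strict > 50%
            (0.55, "clonal_possible_LOH_or_UPD"),
        ],
    )
    def test_vaf_thresholds(self, vaf, label):
        call = classify_clonality(_mut("P1", "TNFAIP3", vaf=vaf))
        assert call.label == label

    def test_expected_clonal_vaf_is_half_purity(self):
        call = classify_clonality(_mut("P1", "TNFAIP3", vaf=0.4), 0.8)
        assert call.expected_clonal_vaf == pytest.approx(0.40)

    def test_labels_partition_and_cutoff_monotonicity(self):
        vafs = np.linspace(0.01, 0.99, 50)
        calls = [classify_clonality(_mut("P1", "KMT2D", vaf=v)) for v in vafs]
        labels = {c.label for c in calls}
        assert labels == {"subclonal", "clonal", "clonal_possible_LOH_or_UPD"}
        n_sub = sum(c.label == "subclonal" for c in calls)
        assert n_sub == sum(v < 0.20 for v in vafs)

    def test_vaf_by_gene_summary(self):
        muts = [_mut("P1", "TNFAIP3", vaf=0.4), _mut("P2", "TNFAIP3", vaf=0.5)]
        m = build_matrix(muts, ["P1", "P2"])
        row = vaf_by_gene(m).set_index("gene").loc["TNFAIP3"]
        assert row["mean_vaf"] == pytest.approx(0.45)
        assert row["n"] == 2


class TestFisher:
    def test_modal_table_is_one(self):
        assert fisher_exact_two_sided(5, 5, 5, 5) == pytest.approx(1.0)

    def test_fully_concentrated_table(self):
        # only the two extreme tables are as improbable as the observed one
        assert fisher_exact_two_sided(10, 0, 0, 10) == \
            pytest.approx(2 / comb(20, 10))

    def test_zero_margin_gives_one(self):
        assert fisher_exact_two_sided(0, 0, 3, 7) == 1.0
        assert fisher_exact_two_sided(0, 5, 0, 7) == 1.0

    def test_example_table_against_direct_enumeration(self):
        # brute force over a in 0..12 with margins fixed
        a, b, c, d = 0, 12, 17, 34
        r1, r2, c1 = a + b, c + d, a + c
        n = r1 + r2
        denom = comb(n, c1)
        num_obs = comb(r1, a) * comb(r2, c1 - a)
        p_oracle = sum(
            comb(r1, k) * comb(r2, c1 - k)
            for k in range(max(0, c1 - r2), min(r1, c1) + 1)
            if comb(r1, k) * comb(r2, c1 - k) <= num_obs
        ) / denom
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(p_oracle)

    def test_against_reference_statistics_routine(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 30, size=4)
            ours = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
            ref = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 25), st.integers(0, 25),
           st.integers(0, 25), st.integers(0, 25))
    def test_symmetry_under_row_and_column_swaps(self, a, b, c, d):
        p = fisher_exact_two_sided(a, b, c, d)
        assert fisher_exact_two_sided(c, d, a, b) == pytest.approx(p)
        assert fisher_exact_two_sided(b, a, d, c) == pytest.approx(p)

    def test_rejects_negative_or_non_integer(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            fisher_exact_two_sided(0.5, 2, 3, 4)  # type: ignore[arg-type]


class TestCooccurrence:
    def _matrix(self, sets, n=63):
        muts = [
            _mut(f"P{i}", gene)
            for gene, idx in sets.items()
            for i in idx
        ]
        return build_matrix(muts, [f"P{i}" for i in range(n)])

    def test_eligibility_threshold(self):
        m = self._matrix({
            "TNFAIP3": range(17), "MYD88": range(20, 32),
            "KMT2D": range(35, 49), "BCL10": range(5),
        })
        table = cooccurrence_screen(m, min_cases=12)
        assert len(table) == 3  # three genes at >= 12 cases -> three pairs
        assert set(table["gene_a"]) | set(table["gene_b"]) == \
            {"TNFAIP3", "MYD88", "KMT2D"}

    def test_disjoint_sets_negative_direction(self):
        m = self._matrix({"TNFAIP3": range(25), "MYD88": range(30, 55)})
        row = cooccurrence_screen(m, min_cases=12).iloc[0]
        assert row["direction"] == "-"
        assert row["p_value"] < 0.01

    def test_identical_sets_positive_direction(self):
        m = self._matrix({"TNFAIP3": range(20), "MYD88": range(20)})
        row = cooccurrence_screen(m, min_cases=12).iloc[0]
        assert row["direction"] == "+"
        assert row["p_value"] < 1e-6

    def test_fewer_than_two_eligible_genes(self):
        m = self._matrix({"TNFAIP3": range(13)})
        assert cooccurrence_screen(m, min_cases=12).empty

    def test_bh_flag_adds_q_values(self):
        m = self._matrix({
            "TNFAIP3": range(17), "MYD88": range(12),
            "KMT2D": range(30, 44),
        })
        table = cooccurrence_screen(m, min_cases=12, bh_correction=True)
        assert "q_value" in table.columns
        assert (table["q_value"] >= table["p_value"] - 1e-12).all()


def test_matrix_round_trip(tmp_path):
    muts = [_mut("P1", "MYD88"), _mut("P2", "KMT2D")]
    m = build_matrix(muts, ["P1", "P2", "P3"])
    path = tmp_path / "m.tsv"
    write_matrix(m, path)
    back = read_matrix(path)
    assert back.patients == m.patients
    assert back.genes == m.genes
    assert (back.indicator == m.indicator).all().all()
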