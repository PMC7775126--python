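"""Genomic class assignment, recurrence discovery, class-distribution test."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from cjmel.classify import (
    CLASS_LABELS,
    DriverCatalog,
    assign_class,
    class_distribution_test,
    classify_cohort,
    recurrent_candidates,
)
from cjmel.io import MutationRecord


def _rec(sample, gene, vc="Missense_Mutation", pchange=None, vtype="SNP"):
    ref, alt = ("ACT", "-") if vtype == "DEL" else ("C", "T")
    return MutationRecord(
        sample_id=sample, gene=gene, chrom="chr1", pos=100, ref=ref, alt=alt,
        variant_type=vtype, variant_classification=vc, protein_change=pchange,
    )


class TestAssignClass:
    def test_braf_v600e_is_braf_class(self):
        gc = assign_class("S", [_rec("S", "BRAF", pchange="p.V600E")])
        assert gc.class_label == "BRAF" and len(gc.evidence) == 1

    def test_nras_q61l_without_braf_is_ras_class(self):
        gc = assign_class("S", [_rec("S", "NRAS", pchange="p.Q61L")])
        assert gc.class_label == "RAS"

    def test_nf1_lof_is_nf1_class(self):
        gc = assign_class("S", [_rec("S", "NF1", vc="Nonsense_Mutation",
                                     pchange="p.R1306*")])
        assert gc.class_label == "NF1"

    def test_no_catalog_hits_is_triple_wt(self):
        gc = assign_class("S", [_rec("S", "TTN", pchange="p.A100V")])
        assert gc.class_label == "TripleWT" and gc.evidence == []

    def test_precedence_braf_over_ras_over_nf1(self):
        recs = [
            _rec("S", "NF1", vc="Frame_Shift_Del", vtype="DEL", pchange="p.Q5fs"),
            _rec("S", "HRAS", pchange="p.G13D"),
        ]
        assert assign_class("S", recs).class_label == "RAS"
        recs.append(_rec("S", "BRAF", pchange="p.V600E"))
        assert assign_class("S", recs).class_label == "BRAF"

    def test_adding_braf_hotspot_never_leaves_braf(self):
        rng = np.random.default_rng(0)
        genes = ["TTN", "NRAS", "NF1", "USH2A"]
        for _ in range(25):
            recs = [
                _rec("S", str(rng.choice(genes)),
                     pchange=f"p.Q{int(rng.integers(1, 99))}R")
                for _ in range(rng.integers(0, 5))
            ]
            with_braf = recs + [_rec("S", "BRAF", pchange="p.V600E")]
            assert assign_class("S", with_braf).class_label == "BRAF"

    def test_ras_hotspot_requires_catalog_codon(self):
        assert assign_class("S", [_rec("S", "KRAS", pchange="p.A146T")]).class_label == "TripleWT"
        assert assign_class("S", [_rec("S", "KRAS", pchange="p.G12D")]).class_label == "RAS"


class TestClassifyCohort:
    def test_counts_partition_cohort(self, cohort):
        table, counts = classify_cohort(cohort.mutations, cohort.samples)
        assert counts.sum() == len(cohort.samples)
        assert list(counts.index) == list(CLASS_LABELS)

    def test_matches_planted_truth(self, cohort):
        table, _ = classify_cohort(cohort.mutations, cohort.samples)
        got = table.set_index("sample_id")["class_label"].to_dict()
        want = {s: cohort.truth["per_sample"][s]["class"] for s in cohort.samples}
        assert got == want

    def test_empty_cohort(self):
        _, counts = classify_cohort([], [])
        assert list(counts) == [0, 0, 0, 0]

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError):
            classify_cohort([_rec("ghost", "BRAF", pchange="p.V600E")], ["S1"])


class TestRecurrentCandidates:
    def _mini_cohort(self):
        recs = []
        for s in ("A", "B", "C"):
            recs.append(_rec(s, "ACSS3", pchange="p.P532S"))
            recs.append(_rec(s, "USH2A", pchange=f"p.T{100 + ord(s)}M"))
            recs.append(_rec(s, "BRAF", pchange="p.V600E"))
        recs.append(_rec("A", "KIT", pchange="p.L576P"))
        recs.append(_rec("B", "KIT", pchange="p.L576P"))
        return recs

    def test_planted_three_carrier_variant_reported(self):
        out = recurrent_candidates(self._mini_cohort())
        hit = out[(out.gene == "ACSS3") & (out.protein_change == "p.P532S")]
        assert len(hit) == 1 and hit.n_carriers.iloc[0] == 3

    def test_two_carriers_below_threshold(self):
        out = recurrent_candidates(self._mini_cohort())
        assert "KIT" not in set(out.gene)

    def test_gene_level_mode_reports_gene_set(self):
        out = recurrent_candidates(self._mini_cohort(), level="gene")
        assert set(out.gene) == {"USH2A", "ACSS3", "BRAF"}

    def test_blacklist_and_driver_flagged_not_dropped(self):
        out = recurrent_candidates(self._mini_cohort(), blacklist=["USH2A"],
                                   level="gene")
        flags = out.set_index("gene")["flag"]
        assert flags["USH2A"] == "blacklist"
        assert flags["BRAF"] == "known_driver"
        assert flags["ACSS3"] == ""

    def test_order_and_duplicate_invariance(self):
        recs = self._mini_cohort()
        a = recurrent_candidates(recs)
        b = recurrent_candidates(list(reversed(recs)) + recs)  # dup rows
        assert a.equals(b)

    def test_min_carriers_below_two_rejected(self):
        with pytest.raises(ValueError):
            recurrent_candidates([], min_carriers=1)


class TestClassDistribution:
    def test_published_2x4_table(self):
        res = class_distribution_test([31, 23, 19, 17], [28, 166, 93, 46])
        assert res.df == 3
        assert res.p_value == pytest.approx(4.99e-10, rel=0.02)

    def test_identical_vectors_give_zero_statistic(self):
        res = class_distribution_test([5, 5, 5, 5], [5, 5, 5, 5])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_2x2_agrees_with_exact_conditional_null(self):
        """Chi-squared upper-tail p vs the exact permutation (fixed-margin
        hypergeometric) null at a moderate table size."""
        table = np.array([[40, 30], [25, 50]])
        res = class_distribution_test(table[0], table[1])
        n1, n2 = table.sum(axis=1)
        k = table[:, 0].sum()
        n = table.sum()
        p_exact = 0.0
        for a in range(max(0, k - n2), min(n1, k) + 1):
            t = np.array([[a, n1 - a], [k - a, n2 - (k - a)]], dtype=float)
            exp = np.outer(t.sum(1), t.sum(0)) / n
            stat = ((t - exp) ** 2 / exp).sum()
            if stat >= res.statistic - 1e-9:
                p_exact += hypergeom.pmf(a, n, n1, k)
        assert res.p_value == pytest.approx(p_exact, abs=0.01)
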