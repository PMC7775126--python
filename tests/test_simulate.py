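"""Synthetic-cohort generator: determinism, planted truth, recoverability."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from cjmel.catalogs import synthetic_catalog
from cjmel.simulate import CohortConfig, generate_cohort, truth_report
from cjmel.spectrum import context_matrix, fit_cohort_exposures, spectrum_pca
from cjmel.stats import t_test

from conftest import fast_config


class TestConfigValidation:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=0)

    def test_carrier_count_exceeding_cohort_rejected(self):
        with pytest.raises(ValueError, match="carrier count"):
            CohortConfig(n_patients=2, recurrent_variant_spec=("ACSS3", "p.P532S", 3))

    def test_class_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CohortConfig(class_probs={"BRAF": 0.5, "RAS": 0.2, "NF1": 0.2,
                                      "TripleWT": 0.2})


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = fast_config(seed=7)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(cfg).write(d1)
        generate_cohort(cfg).write(d2)
        for name in ("clinical.tsv", "mutations.tsv", "cnv_segments.tsv",
                     "expression.tsv", "fusions.tsv", "truth.json"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_different_seeds_differ(self):
        a = generate_cohort(fast_config(seed=1))
        b = generate_cohort(fast_config(seed=2))
        assert a.mutations != b.mutations


class TestDegenerateMixtures:
    def test_all_braf_cohort(self):
        cfg = fast_config(
            seed=3,
            class_probs={"BRAF": 1.0, "RAS": 0.0, "NF1": 0.0, "TripleWT": 0.0},
        )
        cohort = generate_cohort(cfg)
        assert all(v["class"] == "BRAF"
                   for v in cohort.truth["per_sample"].values())
        # every sample carries a BRAF hotspot missense (mostly V600E)
        for s in cohort.samples:
            assert any(
                r.gene == "BRAF" and r.protein_change in ("p.V600E", "p.G466E")
                for r in cohort.mutations if r.sample_id == s
            )


class TestTruthReport:
    def test_recurrent_carriers_listed(self, fast_cohort):
        report = truth_report(fast_cohort)
        acss3 = report[(report.gene == "ACSS3") & (report.kind == "recurrent_candidate")]
        assert len(acss3) == 3

    def test_every_truth_variant_exists_in_mutation_table(self, fast_cohort):
        report = truth_report(fast_cohort)
        keys = {(r.sample_id, r.gene, r.protein_change or "")
                for r in fast_cohort.mutations}
        for row in report.itertuples(index=False):
            assert (row.sample_id, row.gene, row.protein_change) in keys
            assert row.pos >= 1

    def test_only_class_drivers_without_extras(self):
        cfg = fast_config(
            seed=9,
            recurrent_variant_spec=("ACSS3", "p.P532S", 0),
            artifact_gene_spec=("USH2A", "p.T2205M", 0),
            extra_nf1_carriers=0,
        )
        report = truth_report(generate_cohort(cfg))
        assert set(report.kind) <= {"class_driver", "rtk_ras_nonclassifying"}


class TestStatisticalStructure:
    def test_context_counts_consistent_with_loads(self, fast_cohort):
        m = context_matrix(fast_cohort.mutations, fast_cohort.samples)
        for s in fast_cohort.samples:
            n_ctx_snv = sum(1 for r in fast_cohort.mutations
                            if r.sample_id == s and r.variant_type == "SNP"
                            and r.context3)
            assert m.loc[s].sum() == n_ctx_snv

    def test_exposure_mixture_recovered_by_refitting(self):
        """Bulbar-only cohort at a 0.8/0.2 sig7/sig1 mixture: mean fitted
        sig7 exposure within +/-0.05 of the template."""
        cfg = CohortConfig(
            n_patients=50, seed=13, localization_mix=0.0,
            nonneutral_means={"tarsal": 340.0, "bulbar": 340.0},
            exposure_templates={
                "tarsal": {"Signature_1": 0.2, "Signature_7": 0.8, "Signature_30": 0.0},
                "bulbar": {"Signature_1": 0.2, "Signature_7": 0.8, "Signature_30": 0.0},
            },
            exposure_alpha=1e6,  # pin per-sample weights to the template
        )
        cohort = generate_cohort(cfg)
        contexts = context_matrix(cohort.mutations, cohort.samples)
        fitted = fit_cohort_exposures(contexts, synthetic_catalog())
        assert abs(fitted["Signature_7"].mean() - 0.8) <= 0.05
        assert abs(fitted["Signature_1"].mean() - 0.2) <= 0.05

    def test_equal_templates_show_no_artifactual_pca_separation(self):
        """With identical exposure templates for both localizations the
        tarsal/bulbar PC1 separation is null-distributed (rejections at
        alpha=.05 stay near chance over 20 seeds)."""
        template = {"Signature_1": 0.3, "Signature_7": 0.4, "Signature_30": 0.3}
        rejections = 0
        for seed in range(20):
            cfg = fast_config(
                seed=seed, n_patients=12, localization_mix=0.5,
                tarsal_bulbar_like=0,
                exposure_templates={"tarsal": template, "bulbar": template},
            )
            cohort = generate_cohort(cfg)
            m = context_matrix(cohort.mutations, cohort.samples)
            by_class = pd.DataFrame(
                m.values.reshape(len(m), 6, 16).sum(axis=2),
                index=m.index,
            )
            by_class = by_class.div(by_class.sum(axis=1), axis=0)
            coords, _ = spectrum_pca(by_class)
            loc = {s: cohort.truth["per_sample"][s]["localization"]
                   for s in cohort.samples}
            tarsal = coords.loc[[s for s in cohort.samples if loc[s] == "tarsal"], "PC1"]
            bulbar = coords.loc[[s for s in cohort.samples if loc[s] == "bulbar"], "PC1"]
            if t_test(tarsal.values, bulbar.values).p_value < 0.05:
                rejections += 1
        # binomial(20, .05): >=5 rejections has probability < 3e-3
        assert rejections <= 4

    def test_dosage_effect_increases_concordance_detection(self):
        """Planted gene-dosage effects are detected more often as the
        effect grows (checked over 20 seeds at three effect sizes)."""
        from cjmel.cnv import gene_calls
        from cjmel.expression import concordance_table, log_transform
        from cjmel.genome import default_gene_map

        gm = default_gene_map()
        rates = []
        for effect in (0.0, 0.15, 0.5):
            hits = trials = 0
            for seed in range(20):
                cohort = generate_cohort(fast_config(seed=seed,
                                                     dosage_effect=effect))
                calls = gene_calls(cohort.cnv, gm)
                table = concordance_table(calls, log_transform(cohort.expression))
                verdicts = table.set_index("gene")["direction"]
                for g, info in cohort.truth["dosage_genes"].items():
                    trials += 1
                    hits += verdicts.get(g) == info["direction"]
            rates.append(hits / trials)
        assert rates[0] <= rates[1] + 0.05 <= rates[2] + 0.10
        assert rates[2] >= 0.9
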