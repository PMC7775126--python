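"""Spectra, context collapse, NNLS exposure refitting and spectrum PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cjmel.catalogs import synthetic_catalog
from cjmel.io import MutationRecord
from cjmel.spectrum import (
    CONTEXT_LABELS,
    SUBSTITUTION_CLASSES,
    collapse_substitution,
    context_matrix,
    cosine_similarity,
    fit_exposures,
    read_catalog,
    spectrum,
    spectrum_pca,
    write_catalog,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _snv(ref, alt, ctx=None, sample="S1"):
    return MutationRecord(
        sample_id=sample, gene="G", chrom="chr1", pos=10, ref=ref, alt=alt,
        variant_type="SNP", variant_classification="Missense_Mutation",
        context3=ctx,
    )


class TestCollapse:
    @pytest.mark.parametrize(
        "ref,alt,ctx,expected",
        [
            ("G", "A", "TGC", ("C>T", "GCA")),  # purine ref: reverse-complement
            ("C", "T", "ACA", ("C>T", "ACA")),  # pyrimidine ref: identity
            ("A", "C", None, ("T>G", None)),
            ("G", "C", "AGT", ("C>G", "ACT")),
        ],
    )
    def test_pyrimidine_strand_convention(self, ref, alt, ctx, expected):
        assert collapse_substitution(ref, alt, ctx) == expected

    def test_non_acgt_base_rejected(self):
        with pytest.raises(ValueError):
            collapse_substitution("N", "A")
        with pytest.raises(ValueError, match="centre"):
            collapse_substitution("C", "T", "AAA")

    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"),
           st.sampled_from("ACGT"), st.sampled_from("ACGT"))
    def test_strand_symmetry(self, ref, alt, five, three):
        if ref == alt:
            return
        ctx = five + ref + three
        flipped_ctx = "".join(COMP[b] for b in reversed(ctx))
        assert collapse_substitution(ref, alt, ctx) == collapse_substitution(
            COMP[ref], COMP[alt], flipped_ctx
        )


class TestSpectrum:
    def test_single_ct_record(self):
        v = spectrum([_snv("C", "T")])
        assert v.proportions["C>T"] == 1.0 and v.n_snv == 1

    def test_sixty_forty_fixture(self):
        recs = [_snv("C", "T")] * 60 + [_snv("T", "C")] * 40
        v = spectrum(recs)
        assert list(v.proportions) == [0, 0, 0.6, 0, 0.4, 0]

    def test_empty_sample_flagged(self):
        v = spectrum([])
        assert v.empty and v.proportions.sum() == 0

    def test_indels_ignored_but_counted(self):
        indel = MutationRecord(
            sample_id="S1", gene="G", chrom="chr1", pos=5, ref="AC", alt="-",
            variant_type="DEL", variant_classification="Frame_Shift_Del",
        )
        v = spectrum([_snv("C", "T"), indel])
        assert v.n_snv == 1 and v.n_indel_ignored == 1

    def test_spectrum_unchanged_by_complementing_every_record(self):
        rng = np.random.default_rng(0)
        recs = []
        for _ in range(50):
            ref = rng.choice(list("ACGT"))
            alt = rng.choice([b for b in "ACGT" if b != ref])
            recs.append(_snv(ref, alt))
        flipped = [_snv(COMP[r.ref], COMP[r.alt]) for r in recs]
        assert spectrum(recs).proportions.equals(spectrum(flipped).proportions)


class TestContextMatrix:
    def test_row_sums_equal_context_carrying_snvs(self, cohort):
        m = context_matrix(cohort.mutations, cohort.samples)
        expected = {
            s: sum(1 for r in cohort.mutations
                   if r.sample_id == s and r.variant_type == "SNP" and r.context3)
            for s in cohort.samples
        }
        assert m.sum(axis=1).to_dict() == expected


class TestCosine:
    def test_anchor_values(self):
        assert cosine_similarity([1, 2], [1, 2]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == 0.0
        # manual arithmetic: (1*2+2*1) / (sqrt5 * sqrt5) = 4/5
        assert cosine_similarity([1, 2], [2, 1]) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 1])


class TestFitExposures:
    def test_exact_catalog_column_is_fully_attributed(self):
        cat = synthetic_catalog()
        counts = cat.profiles["Signature_7"].values * 10000
        prof = fit_exposures(counts, cat)
        assert prof.weights["Signature_7"] == pytest.approx(1.0, abs=1e-6)
        assert prof.cosine == pytest.approx(1.0, abs=1e-9)

    def test_pure_signature_sampling_recovery(self):
        cat = synthetic_catalog()
        p = cat.profiles["Signature_7"].values
        for seed in range(20):
            counts = np.random.default_rng(seed).multinomial(1000, p)
            prof = fit_exposures(counts, cat)
            assert prof.weights["Signature_7"] >= 0.9

    def test_scaling_invariance(self):
        cat = synthetic_catalog()
        counts = np.random.default_rng(3).multinomial(
            500, cat.profiles.values @ [0.5, 0.3, 0.2]
        )
        w1 = fit_exposures(counts, cat).weights
        w2 = fit_exposures(counts * 7, cat).weights
        assert np.allclose(w1.values, w2.values)

    def test_nnls_beats_every_single_signature_fit(self):
        cat = synthetic_catalog()
        A = cat.profiles.values
        rng = np.random.default_rng(42)
        for _ in range(10):
            counts = rng.multinomial(800, A @ rng.dirichlet([1, 1, 1]))
            target = counts / counts.sum()
            prof = fit_exposures(counts, cat)
            # reconstruct the unnormalized NNLS solution's residual
            from scipy.optimize import nnls as scipy_nnls
            w, res = scipy_nnls(A, target)
            for k in range(A.shape[1]):
                a = A[:, k]
                beta = max(0.0, float(a @ target / (a @ a)))
                single_res = np.linalg.norm(target - beta * a)
                assert res <= single_res + 1e-12

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_exposures(np.zeros(96), synthetic_catalog())


class TestCatalogIO:
    def test_round_trip_cosmic_v2_layout(self, tmp_path):
        cat = synthetic_catalog()
        p = tmp_path / "cat.tsv"
        write_catalog(cat, p)
        back = read_catalog(p)
        assert np.allclose(back.profiles.values, cat.profiles.values)
        assert back.names == cat.names

    def test_shuffled_rows_and_columns_tolerated(self, tmp_path):
        cat = synthetic_catalog()
        p = tmp_path / "cat.tsv"
        write_catalog(cat, p)
        df = pd.read_csv(p, sep="\t").sample(frac=1, random_state=1)
        df = df[list(df.columns[::-1])]
        p2 = tmp_path / "cat2.tsv"
        df.to_csv(p2, sep="\t", index=False)
        back = read_catalog(p2)
        assert np.allclose(
            back.profiles[cat.names].values, cat.profiles.values
        )


class TestSpectrumPca:
    def test_identical_spectra_identical_coordinates(self):
        base = np.array([0.1, 0.1, 0.5, 0.1, 0.1, 0.1])
        rng = np.random.default_rng(0)
        rows = [base, base] + [rng.dirichlet(np.ones(6)) for _ in range(4)]
        spectra = pd.DataFrame(rows, columns=list(SUBSTITUTION_CLASSES))
        coords, evr = spectrum_pca(spectra)
        assert np.allclose(coords.iloc[0].values, coords.iloc[1].values)
        assert evr.sum() <= 1.0 + 1e-12

    def test_uv_heavy_vs_mixed_cohorts_separate_on_pc1(self):
        cat = synthetic_catalog()
        A = cat.profiles.values
        rng = np.random.default_rng(7)

        def group(weights, n):
            out = []
            for _ in range(n):
                counts = rng.multinomial(500, A @ weights)
                by_class = counts.reshape(6, 16).sum(axis=1)
                out.append(by_class / by_class.sum())
            return out

        bulbar = group(np.array([0.15, 0.80, 0.05]), 10)
        tarsal = group(np.array([0.20, 0.35, 0.45]), 6)
        spectra = pd.DataFrame(bulbar + tarsal, columns=list(SUBSTITUTION_CLASSES))
        coords, _ = spectrum_pca(spectra)
        pc1 = coords["PC1"].values
        centroid_gap = abs(pc1[:10].mean() - pc1[10:].mean())
        within = max(pc1[:10].std(), pc1[10:].std())
        assert centroid_gap > 2 * within

    def test_too_few_samples_rejected(self):
        spectra = pd.DataFrame([[1, 0, 0, 0, 0, 0]],
                               columns=list(SUBSTITUTION_CLASSES))
        with pytest.raises(ValueError):
            spectrum_pca(spectra)
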