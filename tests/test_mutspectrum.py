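from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xspec.errors import DomainError, ParseError
from xspec.sequtils import COMPLEMENT, CONTEXTS_96, PYR_CLASSES
from xspec import mutspectrum as ms
from xspec import synthdata as sd


class TestExtrapolate:
    def test_paper_worked_example(self):
        assert ms.extrapolate(13811, 0.23) == 3176

    def test_full_rate(self):
        assert ms.extrapolate(100, 1.0) == 100

    def test_direct_multiplication(self):
        assert ms.extrapolate(1000, 0.38) == 380

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            ms.extrapolate(-1, 0.5)
        with pytest.raises(DomainError):
            ms.extrapolate(10, 1.5)

    @given(st.integers(0, 10_000), st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_doubling_linearity(self, n, r):
        doubled = ms.extrapolate(2 * n, r)
        single = ms.extrapolate(n, r)
        assert doubled in (2 * single, 2 * single + 1)


class TestRatePerMb:
    def test_paper_display(self):
        assert ms.format_rate_per_mb(ms.rate_per_mb(3176, 1_412_464_843)) == "2.24"

    def test_exact_value(self):
        assert ms.format_rate_per_mb(ms.rate_per_mb(10, 1_000_000)) == "10.00"

    def test_truncation_not_rounding(self):
        assert ms.format_rate_per_mb(2.2485) == "2.24"
        assert ms.format_rate_per_mb(2.2499) == "2.24"

    def test_zero_genome_rejected(self):
        with pytest.raises(DomainError):
            ms.rate_per_mb(10, 0)

    def test_estimate_bundles_fields(self):
        est = ms.estimate_mutation_rate(13811, 0.23)
        assert est.expected_true == 3176
        assert est.display_rate == "2.24"
        assert est.genome_size_bp == 1_412_464_843


class TestSpectrum:
    def test_single_pyrimidine_variant(self):
        ref = {"chr1": "AACGTT"}
        spec = ms.spectrum([("chr1", 3, "C", "T")], ref)
        assert spec.class_counts["C>T"] == 1
        assert spec.context_counts["A[C>T]G"] == 1
        assert spec.n_total == 1

    def test_purine_variant_strand_normalized(self):
        # G>A with 5' C and 3' T reads A[C>T]G on the pyrimidine strand
        ref = {"chr1": "ACGTA"}
        spec = ms.spectrum([("chr1", 3, "G", "A")], ref)
        assert spec.class_counts["C>T"] == 1
        assert spec.context_counts["A[C>T]G"] == 1

    def test_reference_mismatch_lists_locus(self):
        ref = {"chr1": "AAAA"}
        with pytest.raises(DomainError, match=r"1:2 \(expected A, got C\)"):
            ms.spectrum([("chr1", 2, "C", "T")], ref)

    def test_end_variants_excluded_from_contexts(self):
        ref = {"chr1": "CAAAC"}
        spec = ms.spectrum([("chr1", 1, "C", "T"), ("chr1", 5, "C", "A")], ref)
        assert spec.n_total == 2
        assert spec.n_context_excluded == 2
        assert sum(spec.context_counts.values()) == 0

    def test_planted_classes_recovered_exactly(self, reference_100kb, truth_2000):
        spec = ms.spectrum([v.key for v in truth_2000.somatic], reference_100kb)
        planted = Counter(v.pyr_class for v in truth_2000.somatic)
        assert spec.class_counts == {c: planted.get(c, 0) for c in PYR_CLASSES}
        assert spec.n_total == 2000

    def test_context_rollup_invariant(self, reference_100kb, truth_2000):
        spec = ms.spectrum([v.key for v in truth_2000.somatic], reference_100kb)
        for cls in PYR_CLASSES:
            rolled = sum(v for k, v in spec.context_counts.items() if f"[{cls}]" in k)
            end_excluded = sum(
                1 for v in truth_2000.somatic
                if v.pyr_class == cls and v.context is None)
            assert spec.class_counts[cls] == rolled + end_excluded

    def test_strand_involution(self, reference_100kb, truth_2000):
        spec = ms.spectrum([v.key for v in truth_2000.somatic], reference_100kb)
        flipped_ref = {c: "".join(COMPLEMENT[b] for b in s)
                       for c, s in reference_100kb.items()}
        flipped = [(v.chrom, v.pos, COMPLEMENT[v.ref], COMPLEMENT[v.alt])
                   for v in truth_2000.somatic]
        spec2 = ms.spectrum(flipped, flipped_ref)
        assert spec.class_counts == spec2.class_counts

    def test_fasta_path_input(self, fasta_100kb, truth_2000):
        spec = ms.spectrum([v.key for v in truth_2000.somatic], fasta_100kb)
        assert spec.n_total == 2000


class TestDipyrimidineReport:
    def test_all_tca(self):
        ref = {"chr1": "ATCAA"}
        spec = ms.spectrum([("chr1", 3, "C", "T")], ref)
        rep = ms.dipyrimidine_report(spec)
        assert rep["TCA_of_all"] == 1.0
        assert rep["TCA_of_ct"] == 1.0
        assert rep["dipyrimidine_of_ct"] == 1.0

    def test_no_ct_mutations(self):
        ref = {"chr1": "ATCAA"}
        spec = ms.spectrum([("chr1", 3, "C", "A")], ref)
        rep = ms.dipyrimidine_report(spec)
        assert rep["TCA_of_all"] == 0.0
        assert rep["TCG_of_all"] == 0.0
        assert rep["TCC_of_all"] == 0.0

    def test_planted_fractions_recovered(self, reference_100kb):
        fracs = {"TCA": 0.17, "TCG": 0.10, "TCC": 0.05}
        truth = sd.plant_variants(reference_100kb, n_somatic=2000,
                                  context_fractions=fracs, seed=21)
        spec = ms.spectrum([v.key for v in truth.somatic], reference_100kb)
        rep = ms.dipyrimidine_report(spec)
        for ctx, frac in fracs.items():
            assert rep[f"{ctx}_of_all"] == pytest.approx(frac, abs=0.02)


class TestRegionBreakdown:
    def test_bed_convention_exact(self, tmp_path):
        bed = tmp_path / "model.bed"
        bed.write_text("chr1\t99\t100\tg1.exon1\t0\t+\n")
        out = ms.region_breakdown([("chr1", 100, "C", "T")], bed)
        assert out.counts["exonic"] == 1
        out2 = ms.region_breakdown([("chr1", 99, "C", "T"),
                                    ("chr1", 101, "C", "T")], bed)
        assert out2.counts["intergenic"] == 2

    def test_intron_between_exons(self, tmp_path):
        bed = tmp_path / "model.bed"
        bed.write_text("chr1\t0\t100\tg1\t0\t+\n"
                       "chr1\t0\t10\tg1.exon1\t0\t+\n")
        out = ms.region_breakdown([("chr1", 5, "C", "T"), ("chr1", 50, "C", "T"),
                                   ("chr1", 200, "C", "T")], bed)
        assert out.counts == {"exonic": 1, "intronic": 1, "intergenic": 1}

    def test_planted_regions_exact_agreement(self, gene_bed, truth_2000):
        out = ms.region_breakdown([v.key for v in truth_2000.somatic], gene_bed)
        for v in truth_2000.somatic:
            assert out.labels[v.key] == v.region
        assert sum(out.fractions.values()) == pytest.approx(1.0)

    def test_unsorted_bed_accepted(self, tmp_path):
        bed = tmp_path / "model.bed"
        bed.write_text("chr1\t500\t600\tg2\t0\t+\nchr1\t0\t100\tg1\t0\t+\n")
        out = ms.region_breakdown([("chr1", 550, "C", "T")], bed)
        assert out.counts["intronic"] == 1

    def test_malformed_bed_rejected(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\txx\t100\n")
        with pytest.raises(ParseError):
            ms.region_breakdown([("chr1", 5, "C", "T")], bed)


class TestSignatureSimilarity:
    def _spec_from_vector(self, vec):
        counts = {c: int(v) for c, v in zip(CONTEXTS_96, vec)}
        classes = {cls: 0 for cls in PYR_CLASSES}
        for ctx, n in counts.items():
            classes[ctx[2:5]] += n
        return ms.SubstitutionSpectrum(class_counts=classes,
                                       context_counts=counts,
                                       n_total=int(sum(vec)))

    def test_identical_signature_ranks_first(self):
        sigs = sd.toy_signature_matrix(3, seed=1)
        vec = (sigs["Signature_2"].to_numpy() * 10_000).round()
        out = ms.signature_similarity(self._spec_from_vector(vec), sigs)
        assert out.loc[0, "signature"] == "Signature_2"
        assert out.loc[0, "cosine_similarity"] == pytest.approx(1.0, abs=1e-3)

    def test_orthogonal_single_context_signature(self):
        mat = pd.DataFrame(0.0, index=list(CONTEXTS_96), columns=["only_first"])
        mat.iloc[0, 0] = 1.0
        vec = np.zeros(96)
        vec[1] = 100
        out = ms.signature_similarity(self._spec_from_vector(vec), mat)
        assert out.loc[0, "cosine_similarity"] == pytest.approx(0.0)

    def test_mixture_ranks_dominant_component(self):
        sigs = sd.toy_signature_matrix(2, seed=2)
        mix = 0.9 * sigs["Signature_1"] + 0.1 * sigs["Signature_2"]
        vec = (mix.to_numpy() * 100_000).round()
        out = ms.signature_similarity(self._spec_from_vector(vec), sigs)
        assert out.loc[0, "signature"] == "Signature_1"

    def test_invalid_matrix_rejected(self):
        bad = pd.DataFrame(np.ones((96, 2)), index=list(CONTEXTS_96))
        vec = np.ones(96)
        with pytest.raises(DomainError):
            ms.signature_similarity(self._spec_from_vector(vec), bad)

    def test_zero_spectrum_rejected(self):
        sigs = sd.toy_signature_matrix(2, seed=3)
        with pytest.raises(DomainError):
            ms.signature_similarity(self._spec_from_vector(np.zeros(96)), sigs)
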