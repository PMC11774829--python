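"""Catalogue construction: VCF intake, consensus, filters, 96-class labels, TMB."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adenosig import (
    Catalogue96,
    ConfigurationError,
    ReferenceMismatchError,
    build_catalogue,
    compute_tmb,
    filter_records,
    intersect_callers,
    read_somatic_vcf,
    trinucleotide_class,
)
from adenosig.catalogue import CLASSES_96, revcomp

from .conftest import make_record, write_vcf


class TestReadSomaticVcf:
    def test_ad_arithmetic(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf", [
            (100, "C", "A", 30, 20, 50),
            (200, "G", "T", 30, 20, 50),
            (300, "T", "C", 30, 20, 50),
        ])
        recs = read_somatic_vcf(path, "s1", "callerA")
        assert len(recs) == 3
        assert all(r.vaf == pytest.approx(0.4) for r in recs)
        assert all(r.depth == 50 for r in recs)
        assert all(r.var_type == "SNV" for r in recs)

    def test_allele_length_rule(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf", [(100, "AT", "A", 30, 20, 50)])
        recs = read_somatic_vcf(path, "s1", "callerA")
        assert len(recs) == 1
        assert recs[0].var_type == "DEL"

    def test_empty_body(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf", [])
        assert read_somatic_vcf(path, "s1", "callerA") == []

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_somatic_vcf(tmp_path / "nope.vcf", "s1", "callerA")

    def test_non_pass_rows_skipped(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf", [
            "chr1\t100\t.\tC\tA\t.\tLowQual\t.\tAD:DP\t30,20:50",
            (200, "C", "A", 30, 20, 50),
        ])
        recs = read_somatic_vcf(path, "s1", "callerA")
        assert [r.pos for r in recs] == [200]

    def test_dp_af_fallback(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf", [
            "chr1\t100\t.\tC\tA\t.\tPASS\t.\tDP:AF\t80:0.25",
        ])
        recs = read_somatic_vcf(path, "s1", "callerA")
        assert recs[0].depth == 80 and recs[0].vaf == pytest.approx(0.25)

    def test_underivable_row_flagged_not_silent(self, tmp_path, caplog):
        path = write_vcf(tmp_path / "a.vcf", [
            "chr1\t100\t.\tC\tA\t.\tPASS\t.\tDP\t80",
            (200, "C", "A", 30, 20, 50),
        ])
        import logging

        with caplog.at_level(logging.WARNING, logger="adenosig.catalogue"):
            recs = read_somatic_vcf(path, "s1", "callerA")
        assert [r.pos for r in recs] == [200]
        assert any("depth/VAF" in m for m in caplog.messages)

    def test_multiallelic_split(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf", [
            "chr1\t100\t.\tC\tA,T\t.\tPASS\t.\tAD:DP\t50,30,20:100",
        ])
        recs = read_somatic_vcf(path, "s1", "callerA")
        assert [(r.alt, r.vaf) for r in recs] == [("A", 0.3), ("T", 0.2)]


class TestIntersect:
    def test_shared_and_private(self):
        a = [make_record(pos=1), make_record(pos=2)]
        b = [make_record(pos=2, callers=("callerB",)), make_record(pos=3, callers=("callerB",))]
        out = intersect_callers(a, b)
        assert len(out) == 1
        assert out[0].pos == 2
        assert out[0].callers == frozenset({"callerA", "callerB"})

    def test_disjoint(self):
        assert intersect_callers([make_record(pos=1)], [make_record(pos=2)]) == []

    def test_empty(self):
        assert intersect_callers([], []) == []

    def test_numeric_fields_from_first_caller(self):
        a = [make_record(pos=5, depth=60, vaf=0.5)]
        b = [make_record(pos=5, depth=99, vaf=0.9, callers=("callerB",))]
        out = intersect_callers(a, b)
        assert out[0].depth == 60 and out[0].vaf == 0.5

    @given(
        keys_a=st.sets(st.integers(1, 30), max_size=15),
        keys_b=st.sets(st.integers(1, 30), max_size=15),
    )
    @settings(max_examples=50, deadline=None)
    def test_commutative_key_set_and_subset(self, keys_a, keys_b):
        a = [make_record(pos=p) for p in sorted(keys_a)]
        b = [make_record(pos=p, callers=("callerB",)) for p in sorted(keys_b)]
        ab = {r.key for r in intersect_callers(a, b)}
        ba = {r.key for r in intersect_callers(b, a)}
        assert ab == ba
        assert ab <= {r.key for r in a} and ab <= {r.key for r in b}


class TestFilter:
    @pytest.mark.parametrize(
        "depth,vaf,kept",
        [(50, 0.10, True), (49, 0.50, False), (100, 0.099, False), (51, 0.11, True)],
    )
    def test_inclusive_boundaries(self, depth, vaf, kept):
        recs = filter_records([make_record(depth=depth, vaf=vaf)])
        assert bool(recs) is kept

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_records([], min_depth=-1)

    @given(
        depths=st.lists(st.integers(0, 200), min_size=1, max_size=40),
        d1=st.integers(0, 100), d2=st.integers(0, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_filter_monotone_in_depth(self, depths, d1, d2):
        recs = [make_record(pos=i + 1, depth=d, vaf=0.5) for i, d in enumerate(depths)]
        lo, hi = sorted([d1, d2])
        assert len(filter_records(recs, min_depth=hi)) <= len(filter_records(recs, min_depth=lo))


class TestTrinucleotideClass:
    @pytest.mark.parametrize(
        "ctx,ref,alt,expected",
        [
            ("ACA", "C", "T", "A[C>T]A"),   # pyrimidine-centred already
            ("AGA", "G", "T", "T[C>A]T"),   # purine: revcomp both flanks
            ("CGG", "G", "A", "C[C>T]G"),   # hand oracle: revcomp(CGG)=CCG
        ],
    )
    def test_labels(self, ctx, ref, alt, expected):
        reference = {"chr1": "NN" + ctx + "NN"}  # variant at pos 4 (1-based)
        rec = make_record(pos=4, ref=ref, alt=alt)
        assert trinucleotide_class(rec, reference) == expected

    def test_reference_mismatch_error_names_site(self):
        reference = {"chr1": "AAAAA"}
        with pytest.raises(ReferenceMismatchError, match="chr1:3"):
            trinucleotide_class(make_record(pos=3, ref="C", alt="T"), reference)

    def test_contig_edge(self):
        from adenosig import ContextUnavailableError

        reference = {"chr1": "ACGT"}
        with pytest.raises(ContextUnavailableError):
            trinucleotide_class(make_record(pos=1, ref="A", alt="T"), reference)
        with pytest.raises(ContextUnavailableError):
            trinucleotide_class(make_record(pos=4, ref="T", alt="A"), reference)

    @given(
        five=st.sampled_from("ACGT"), central=st.sampled_from("ACGT"),
        three=st.sampled_from("ACGT"), alt_ix=st.integers(0, 2),
    )
    @settings(max_examples=100, deadline=None)
    def test_strand_symmetry(self, five, central, three, alt_ix):
        """Describing the same event on either strand yields one class."""
        alt = [b for b in "ACGT" if b != central][alt_ix]
        ctx = five + central + three
        fwd = {"chr1": "NN" + ctx + "NN"}
        rev = {"chr1": "NN" + revcomp(ctx) + "NN"}
        comp = dict(zip("ACGT", "TGCA"))
        c_fwd = trinucleotide_class(make_record(pos=4, ref=central, alt=alt), fwd)
        c_rev = trinucleotide_class(make_record(pos=4, ref=comp[central], alt=comp[alt]), rev)
        assert c_fwd == c_rev


class TestBuildCatalogue:
    def test_empty(self):
        c = build_catalogue([], {}, sample_id="s")
        assert c.snv_total == 0 and c.indel_total == 0
        assert all(v == 0 for v in c.counts.values())

    def test_conservation_with_indels(self, reference):
        chrom = list(reference.keys())[0]
        recs = [
            make_record(chrom=chrom, pos=p, ref=str(reference[chrom][p - 1]).upper(),
                        alt=("A" if str(reference[chrom][p - 1]).upper() != "A" else "C"))
            for p in range(500, 505)
        ]
        recs += [make_record(pos=900, ref="AT", alt="A"), make_record(pos=905, ref="A", alt="AT")]
        c = build_catalogue(recs, reference)
        assert sum(c.counts.values()) == 5
        assert c.indel_total == 2

    def test_mnv_excluded(self, caplog):
        recs = [make_record(pos=10, ref="AC", alt="GG")]
        c = build_catalogue(recs, {}, sample_id="s")
        assert c.snv_total == 0 and c.indel_total == 0

    def test_multinomial_convergence(self, rng):
        """Empirical class frequencies from a known multinomial converge."""
        probs = rng.dirichlet(np.ones(96))
        counts = rng.multinomial(10_000, probs)
        cat = Catalogue96("s", dict(zip(CLASSES_96, (int(x) for x in counts))))
        expected = probs * 10_000
        keep = expected >= 5  # chi-square validity
        chi2 = (((counts - expected) ** 2 / expected)[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.001
        assert cat.snv_total == 10_000


class TestTmb:
    def test_zero(self):
        c = build_catalogue([], {}, sample_id="s")
        r = compute_tmb(c)
        assert r.tmb == 0.0 and not r.hypermutated

    def test_hypermutation_boundary(self):
        counts = {cls: 0 for cls in CLASSES_96}
        counts[CLASSES_96[0]] = 600
        c = Catalogue96("s", counts, indel_total=70)
        r = compute_tmb(c, capture_mb=67)
        assert r.tmb == pytest.approx(10.0)
        assert r.hypermutated

    def test_capture_must_be_positive(self):
        c = build_catalogue([], {}, sample_id="s")
        with pytest.raises(ConfigurationError):
            compute_tmb(c, capture_mb=0)
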