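import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xspec.errors import CapacityError, ParseError, UsageError
from xspec import callsets as cs

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
"""


def write_vcf(tmp_path, body, name="calls.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


def make_call(pos, ref="C", alt="T", caller="m", quality=30.0, chrom="chr1"):
    return cs.VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt,
                          caller=caller, quality=quality)


class TestLoadCalls:
    def test_snvs_kept_indel_dropped(self, tmp_path, caplog):
        body = ("chr1\t100\t.\tC\tT\t30\tPASS\t.\tAD\t10,5\t15,0\n"
                "chr1\t200\t.\tG\tA\t40\tPASS\t.\tAD\t10,5\t15,0\n"
                "chr1\t300\t.\tA\tAT\t20\tPASS\t.\tAD\t10,5\t15,0\n"
                "chr1\t400\t.\tT\tG\t25\tPASS\t.\tAD\t10,5\t15,0\n")
        calls = cs.load_calls(write_vcf(tmp_path, body), "m")
        assert len(calls) == 3
        assert all(c.caller == "m" for c in calls)
        assert calls[0].tumor_depths == (10, 5)

    def test_empty_body(self, tmp_path):
        assert cs.load_calls(write_vcf(tmp_path, ""), "m") == []

    def test_multiallelic_split(self, tmp_path):
        body = "chr1\t100\t.\tA\tC,T\t30\tPASS\t.\tAD\t10,3,2\t15,0,0\n"
        calls = cs.load_calls(write_vcf(tmp_path, body), "m")
        assert [(c.pos, c.ref, c.alt) for c in calls] == [(100, "A", "C"), (100, "A", "T")]
        assert calls[0].tumor_depths == (10, 3)
        assert calls[1].tumor_depths == (10, 2)

    def test_symbolic_allele_dropped(self, tmp_path):
        body = ("chr1\t100\t.\tC\t<DEL>\t30\tPASS\t.\tAD\t10,5\t15,0\n"
                "chr1\t200\t.\tG\tA\t40\tPASS\t.\tAD\t10,5\t15,0\n")
        calls = cs.load_calls(write_vcf(tmp_path, body), "m")
        assert len(calls) == 1

    def test_malformed_vcf_raises(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("not a vcf at all\n")
        with pytest.raises(ParseError):
            cs.load_calls(path, "m")


class TestVariantCall:
    def test_chr_prefix_normalized_in_key(self):
        a = make_call(10, chrom="chr1")
        b = make_call(10, chrom="1")
        assert a.key == b.key

    @pytest.mark.parametrize("kwargs", [
        {"ref": "C", "alt": "C"},
        {"ref": "N", "alt": "T"},
        {"pos": 0},
        {"quality": float("nan")},
    ])
    def test_invalid_call_rejected(self, kwargs):
        base = dict(chrom="chr1", pos=5, ref="C", alt="T", caller="m", quality=1.0)
        base.update(kwargs)
        with pytest.raises(UsageError):
            cs.VariantCall(**base)


class TestConsensus:
    def test_identical_callsets(self):
        calls = [make_call(p) for p in range(1, 11)]
        rep = cs.consensus({"a": calls, "b": list(calls)})
        assert rep.intersection_count == 10
        assert rep.union_count == 10

    def test_disjoint_callsets(self):
        a = [make_call(p) for p in range(1, 11)]
        b = [make_call(p) for p in range(100, 105)]
        rep = cs.consensus({"a": a, "b": b})
        assert rep.intersection_count == 0
        assert rep.union_count == 15

    def test_partial_overlap_by_hand(self):
        # {k1,k2,k3} vs {k2,k3,k4} -> intersection 2, union 4
        a = [make_call(1), make_call(2), make_call(3)]
        b = [make_call(2), make_call(3), make_call(4)]
        rep = cs.consensus({"a": a, "b": b})
        assert rep.intersection_count == 2
        assert rep.union_count == 4
        assert rep.intersection_keys == {("1", 2, "C", "T"), ("1", 3, "C", "T")}

    def test_single_caller_rejected(self):
        with pytest.raises(UsageError):
            cs.consensus({"a": [make_call(1)]})

    @given(st.sets(st.integers(1, 60), max_size=30),
           st.sets(st.integers(1, 60), max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_set_algebra_invariants(self, pa, pb):
        a = [make_call(p) for p in pa]
        b = [make_call(p) for p in pb]
        rep = cs.consensus({"a": a, "b": b})
        assert rep.intersection_count == len(pa & pb)
        assert rep.union_count == len(pa) + len(pb) - rep.intersection_count
        assert rep.intersection_count <= min(len(pa) or 0, len(pb) or 0)


class TestQuartileStratify:
    def test_eight_distinct_scores(self):
        calls = [make_call(p, quality=float(p)) for p in range(1, 9)]
        bins = cs.quartile_stratify(calls)
        assert [len(bins[q]) for q in (1, 2, 3, 4)] == [2, 2, 2, 2]

    def test_all_scores_equal_single_bin(self, caplog):
        calls = [make_call(p, quality=5.0) for p in range(1, 9)]
        with caplog.at_level("WARNING"):
            bins = cs.quartile_stratify(calls)
        assert len(bins[1]) == 8
        assert any("degenerate" in rec.message for rec in caplog.records)

    def test_boundaries_against_brute_force(self):
        # oracle: sort scores, check bin membership against the percentile cuts
        calls = [make_call(p, quality=float(p)) for p in range(1, 101)]
        bins = cs.quartile_stratify(calls)
        scores = sorted(c.quality for c in calls)
        q25 = np.percentile(scores, 25)
        assert {c.quality for c in bins[1]} == {s for s in scores if s <= q25}
        assert len(bins[1]) == 25

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        calls = [make_call(p, quality=float(q))
                 for p, q in enumerate(rng.normal(size=137), start=1)]
        bins = cs.quartile_stratify(calls)
        pooled = [c for q in (1, 2, 3, 4) for c in bins[q]]
        assert sorted(c.pos for c in pooled) == sorted(c.pos for c in calls)
        sizes = [len(bins[q]) for q in (1, 2, 3, 4)]
        assert max(sizes) - min(sizes) <= 2  # ties at boundaries only

    def test_too_few_calls(self):
        with pytest.raises(UsageError):
            cs.quartile_stratify([make_call(1), make_call(2)])


@pytest.fixture
def two_caller_setup():
    rng = np.random.default_rng(11)
    shared = [make_call(p, quality=float(rng.uniform(0, 100)), caller="a")
              for p in range(1, 701)]
    a_only = [make_call(p, quality=float(rng.uniform(0, 100)), caller="a")
              for p in range(1000, 1700)]
    b_only = [make_call(p, quality=float(rng.uniform(0, 100)), caller="b")
              for p in range(2000, 2700)]
    a = shared + a_only
    b = [make_call(c.pos, quality=float(rng.uniform(0, 100)), caller="b")
         for c in shared] + b_only
    rep = cs.consensus({"a": a, "b": b})
    strat = {"a": cs.quartile_stratify(a), "b": cs.quartile_stratify(b)}
    return rep, strat


class TestBuildPanel:
    def test_default_design_gives_384(self, two_caller_setup):
        rep, strat = two_caller_setup
        panel = cs.build_panel(rep, strat, cs.PanelDesign(128, 128, 48), seed=1)
        assert len(panel) == 384

    def test_empty_design(self, two_caller_setup):
        rep, strat = two_caller_setup
        panel = cs.build_panel(rep, strat, cs.PanelDesign(0, 0, 0), seed=1)
        assert len(panel) == 0

    def test_determinism(self, two_caller_setup):
        rep, strat = two_caller_setup
        p1 = cs.build_panel(rep, strat, cs.PanelDesign(64, 64), seed=5)
        p2 = cs.build_panel(rep, strat, cs.PanelDesign(64, 64), seed=5)
        assert p1.entries == p2.entries

    def test_source_membership(self, two_caller_setup):
        rep, strat = two_caller_setup
        panel = cs.build_panel(rep, strat, cs.PanelDesign(100, 100), seed=2)
        a_keys = {c.key for bins in [strat["a"]] for q in bins for c in bins[q]}
        for e in panel.entries:
            if e.source == "overlap":
                assert e.key in rep.intersection_keys
            else:
                assert e.key not in rep.intersection_keys
                if e.source == "a-unique":
                    assert e.key in a_keys

    def test_entries_unique(self, two_caller_setup):
        rep, strat = two_caller_setup
        panel = cs.build_panel(rep, strat, cs.PanelDesign(128, 128), seed=3)
        keys = [e.key for e in panel.entries]
        assert len(keys) == len(set(keys))

    def test_stratum_too_small_names_stratum(self, two_caller_setup):
        rep, strat = two_caller_setup
        with pytest.raises(CapacityError, match="quartile"):
            cs.build_panel(rep, strat, cs.PanelDesign(10, 10_000), seed=4)

    def test_overlap_too_small(self, two_caller_setup):
        rep, strat = two_caller_setup
        with pytest.raises(CapacityError, match="overlap"):
            cs.build_panel(rep, strat, cs.PanelDesign(10_000, 0), seed=4)

    def test_per_quartile_cap(self):
        with pytest.raises(UsageError):
            cs.PanelDesign(0, 128, 10).per_quartile_draws()
        assert cs.PanelDesign(0, 130).per_quartile_draws() == (33, 33, 32, 32)
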