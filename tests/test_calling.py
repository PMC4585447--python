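"""Pileup and the variant filter cascade (strand / fraction / depth rules)."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cftrscreen.calling import (FilterThresholds, SiteCounts, call_site,
                                pileup, screen_sample)
from cftrscreen.coverage import compute_coverage, low_coverage_runs
from cftrscreen.simulate import (AlignedRead, SimulationConfig,
                                 normalize_variant, sample_cohort,
                                 simulate_reads)

T = FilterThresholds()
REF = "ACGTACGTACGTACGTACGT" * 5     # 100 bp toy reference


def _read(start, seq, cigar=None, strand="+", name="r"):
    cigar = cigar or (("M", len(seq)),)
    return AlignedRead(name=name, sample_id="s", start=start, strand=strand,
                       cigar=cigar, seq=seq)


def _site(pos, ref, **alleles):
    """alleles: allele -> (fwd, rev)"""
    return SiteCounts(pos=pos, ref=ref, allele_counts=dict(alleles))


class TestPileup:
    def test_error_free_ref_reads(self):
        reads = [_read(0, REF[0:50], name=f"r{i}",
                       strand="+" if i % 2 else "-") for i in range(100)]
        sites = pileup(reads, REF)
        assert len(sites) == 50
        for p, sc in sites.items():
            assert sc.depth == 100
            assert set(sc.allele_counts) == {REF[p]}

    def test_stranded_mixed_allele_tally(self):
        """60 ref + 40 alt reads (20 fwd / 20 rev alt) tally exactly."""
        pos = 10
        alt = "T" if REF[pos] != "T" else "C"
        reads = []
        for i in range(60):
            reads.append(_read(0, REF[:30], name=f"ref{i}",
                               strand="+" if i < 30 else "-"))
        mut = REF[:pos] + alt + REF[pos + 1:30]
        for i in range(40):
            reads.append(_read(0, mut, name=f"alt{i}",
                               strand="+" if i < 20 else "-"))
        sc = pileup(reads, REF)[pos]
        assert sc.allele_counts[alt] == (20, 20)
        assert sc.depth == 100

    def test_deletion_keyed_at_first_deleted_base(self):
        seq = REF[0:20] + REF[23:40]
        r = _read(0, seq, cigar=(("M", 20), ("D", 3), ("M", 17)))
        sites = pileup([r], REF)
        assert "D:3" in sites[20].allele_counts
        assert 21 not in sites or "D:3" not in sites[21].allele_counts
        # deleted interior bases contribute no depth
        assert 21 not in sites and 22 not in sites

    def test_insertion_keyed_to_anchor_base(self):
        seq = REF[0:20] + "GGG" + REF[20:40]
        r = _read(0, seq, cigar=(("M", 20), ("I", 3), ("M", 20)))
        sc = pileup([r], REF)[19]
        assert sc.allele_counts == {"I:GGG": (1, 0)}
        assert sc.depth == 1

    def test_inconsistent_cigar_errors(self):
        r = _read(0, "ACGT", cigar=(("M", 10),))
        with pytest.raises(ValueError):
            pileup([r], REF)


class TestCallSite:
    @pytest.mark.parametrize("alleles,depth_status_geno", [
        # depth 100, alt 30 split both strands -> PASS het
        (dict(A=(35, 35), C=(15, 15)), ("PASS", "het")),
        # depth 100, alt 19 -> low_fraction
        (dict(A=(41, 40), C=(10, 9)), ("low_fraction", None)),
        # depth 100, alt 30 all forward -> single_strand
        (dict(A=(20, 50), C=(30, 0)), ("single_strand", None)),
        # depth 100, alt 100 -> PASS hom
        (dict(C=(50, 50)), ("PASS", "hom")),
    ])
    def test_cascade_examples(self, alleles, depth_status_geno):
        sc = _site(0, "A", **alleles)
        status, geno = depth_status_geno
        calls = call_site(sc, T, REF, report_floor=0.0)
        alt_calls = [c for c in calls if c.alt != "A"]
        assert alt_calls, "expected a record for the alt allele"
        assert alt_calls[0].filter_status == status
        assert alt_calls[0].genotype == geno

    def test_below_site_minimum_is_no_call(self):
        sc = _site(0, "A", C=(20, 20))      # depth 40, all alt
        calls = call_site(sc, T, REF, report_floor=0.0)
        assert calls[0].filter_status == "no_call_region"

    def test_intermediate_depth_flagged_low_depth(self):
        sc = _site(0, "A", A=(20, 20), C=(15, 15))      # depth 70 in [50, 80)
        calls = call_site(sc, T, REF, report_floor=0.0)
        assert calls[0].filter_status == "low_depth"

    def test_hom_boundary_at_08(self):
        sc = _site(0, "A", A=(10, 10), C=(40, 40))      # af 0.80
        calls = call_site(sc, T, REF)
        assert calls[0].genotype == "hom"
        sc = _site(0, "A", A=(10, 11), C=(40, 39))      # af 0.79
        calls = call_site(sc, T, REF)
        assert calls[0].genotype == "het"

    def test_multiallelic_keeps_two(self):
        sc = _site(4, "A", C=(20, 20), G=(20, 20), T=(20, 21))
        calls = call_site(sc, T, REF)
        statuses = sorted(c.filter_status for c in calls)
        assert statuses.count("PASS") == 2
        assert "excess_alleles" in statuses


def brute_force_status(depth, alt_f, alt_r, t=T):
    """Direct boolean evaluation of the three filter conditions, written
    independently of the cascade implementation."""
    n_alt = alt_f + alt_r
    if depth < t.min_site_depth:
        return "no_call_region"
    if depth < t.min_call_depth:
        return "low_depth"
    if n_alt / depth < t.min_alt_fraction:
        return "low_fraction"
    if alt_f < 1 or alt_r < 1:
        return "single_strand"
    return "PASS"


class TestCascadeOracle:
    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(ref_f=st.integers(0, 300), ref_r=st.integers(0, 300),
           alt_f=st.integers(1, 300), alt_r=st.integers(0, 300))
    def test_matches_brute_force(self, ref_f, ref_r, alt_f, alt_r):
        sc = _site(0, "A", A=(ref_f, ref_r), C=(alt_f, alt_r))
        calls = call_site(sc, T, REF, report_floor=0.0)
        alt_calls = [c for c in calls if "C" in c.alt]
        expect = brute_force_status(sc.depth, alt_f, alt_r)
        assert alt_calls[0].filter_status == expect

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(ref_n=st.integers(0, 120), alt_f=st.integers(1, 120),
           alt_r=st.integers(1, 120), extra=st.integers(0, 80))
    def test_monotone_in_alt_reads(self, ref_n, alt_f, alt_r, extra):
        """Replacing ref reads by alt reads (depth fixed, both strands kept)
        never flips PASS to filtered."""
        depth = ref_n + alt_f + alt_r + extra
        sc1 = _site(0, "A", A=(ref_n + extra, 0), C=(alt_f, alt_r))
        sc2 = _site(0, "A", A=(ref_n, 0), C=(alt_f + extra, alt_r))
        s1 = call_site(sc1, T, REF, report_floor=0.0)[-1].filter_status \
            if ref_n + extra else "PASS"
        c1 = [c for c in call_site(sc1, T, REF, report_floor=0.0) if "C" in c.alt]
        c2 = [c for c in call_site(sc2, T, REF, report_floor=0.0) if "C" in c.alt]
        assert sc1.depth == sc2.depth == depth
        if c1[0].filter_status == "PASS":
            assert c2[0].filter_status == "PASS"


class TestNormalize:
    def test_left_align_shift(self):
        ref = "GGGCACACACATTT"
        # deleting the rightmost CA of the repeat left-aligns to the G anchor
        assert normalize_variant(8, "ACA", "A", ref) == (2, "GCA", "G")
        # applying either representation yields the same haplotype
        assert ref[:9] + ref[11:] == ref[:3] + ref[5:]

    def test_trim_and_anchor(self):
        ref = "ACGTACGT"
        assert normalize_variant(2, "GTA", "GCA", ref) == (3, "T", "C")

    def test_snv_unchanged(self):
        assert normalize_variant(5, "C", "G", REF) == (5, "C", "G")


@pytest.fixture(scope="module")
def screened(model, seq, panel, catalog):
    cfg = SimulationConfig(seed=21, n_samples=6)
    cohort = sample_cohort(catalog, cfg)
    out = []
    for truth in cohort[:3]:
        reads = simulate_reads(truth, panel, cfg, model, seq, catalog)
        out.append((truth, reads,
                    screen_sample(reads, panel, T, seq,
                                  sample_id=truth.sample_id)))
    return out


class TestScreenSample:
    def test_error_free_recovery_exact_zygosity(self, screened, catalog):
        """At error rate 0, full depth: exactly the planted small variants,
        each PASS with the planted zygosity."""
        by_id = {v.id: v for v in catalog}
        for truth, _reads, screen in screened:
            want = {(by_id[vid].pos, by_id[vid].ref_allele, by_id[vid].alt_allele): g
                    for vid, g in truth.genotypes.items()
                    if by_id[vid].vtype != "large_deletion"}
            got = {c.key: c.genotype for c in screen.calls
                   if c.filter_status == "PASS"}
            assert got == want

    def test_empty_reads_whole_target_no_call(self, panel, seq):
        screen = screen_sample([], panel, T, seq)
        assert screen.calls == []
        assert screen.no_call_regions == list(panel.target_regions)
        assert screen.n_sites_genotyped == 0

    def test_no_call_bed_equals_coverage_gaps(self, screened, panel, model):
        for _truth, reads, screen in screened:
            prof = compute_coverage(reads, panel, model.sequence_length)
            gaps = [g.interval for g in
                    low_coverage_runs(prof.depth, panel.target_regions,
                                      threshold=T.min_site_depth)]
            assert screen.no_call_regions == gaps
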