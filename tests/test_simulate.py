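"""Synthetic cohort generator: geometry, determinism, depth law, truth draws."""

import numpy as np
import pytest

from cftrscreen.simulate import (DROPOUT_CARRIERS, DROPOUT_VARIANTS, GeneModel,
                                 SampleTruth, SimulationConfig, SizingError,
                                 amplicon_efficiencies, build_reference,
                                 design_panel, normalize_variant,
                                 panel_redundancy, sample_cohort,
                                 simulate_amplicon_counts, simulate_reads)


class TestReference:
    def test_exons_sorted_nonoverlapping(self, model):
        assert model.n_exons == 27
        for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
            assert s1 < e1 <= s2 < e2
        assert model.exons[-1][1] <= model.sequence_length

    def test_same_seed_byte_identical(self, default_config, seq):
        _, seq2 = build_reference(default_config)
        assert seq2 == seq

    def test_different_seed_differs(self, seq):
        _, other = build_reference(SimulationConfig(seed=2))
        assert other != seq

    def test_tract_readback_from_sequence(self, model, seq):
        """The embedded tract read back from the FASTA-writable sequence is
        exactly (TG)^11 (T)^7 between its anchors."""
        tr = model.tgt_tract
        assert seq[tr.repeat_start:tr.repeat_end] == "TG" * 11 + "T" * 7
        left = seq[tr.repeat_start - len(tr.anchor_left):tr.repeat_start]
        right = seq[tr.repeat_end:tr.repeat_end + len(tr.anchor_right)]
        assert (left, right) == (tr.anchor_left, tr.anchor_right)

    def test_anchors_unique_in_reference(self, model, seq):
        tr = model.tgt_tract
        assert seq.count(tr.anchor_left) == 1
        assert seq.count(tr.anchor_right) == 1

    def test_sizing_error(self, default_config):
        with pytest.raises(SizingError):
            build_reference(default_config, max_length=5000)


class TestPanel:
    def test_102_amplicons_two_pools(self, panel):
        assert panel.n_amplicons == 102
        assert {a.pool for a in panel.amplicons} == {1, 2}

    def test_every_target_base_covered(self, panel):
        """Exhaustive per-base membership scan finds no uncovered target base."""
        for s, e in panel.target_regions:
            for p in range(s, e):
                assert any(a.insert[0] <= p < a.insert[1] for a in panel.amplicons), p

    def test_overlapping_amplicons_never_share_pool(self, panel):
        amps = panel.amplicons
        for i, a in enumerate(amps):
            for b in amps[i + 1:]:
                if a.insert[0] < b.insert[1] and b.insert[0] < a.insert[1]:
                    assert a.pool != b.pool

    def test_adjacent_amplicons_overlap_within_exon(self, panel, model):
        for s, e in model.exons:
            inside = sorted(a.insert for a in panel.amplicons
                            if a.insert[0] < e and s < a.insert[1])
            for (s1, e1), (s2, e2) in zip(inside, inside[1:]):
                assert s2 < e1, "adjacent amplicons must overlap"

    def test_mean_insert_length_near_150(self, panel):
        mean = np.mean([a.insert_length for a in panel.amplicons])
        assert 0.8 * 150 <= mean <= 1.2 * 150

    def test_single_exon_toy_model(self):
        toy = GeneModel(name="toy", sequence_length=400, exons=((180, 230),))
        p = design_panel(toy, n_amplicons=1)
        assert p.n_amplicons == 1
        lo, hi = p.amplicons[0].insert
        assert lo <= 180 - 15 and 230 + 15 <= hi


class TestCatalog:
    def test_ref_alleles_match_reference(self, catalog, seq):
        for v in catalog:
            if v.vtype != "large_deletion":
                assert seq[v.pos:v.pos + len(v.ref_allele)] == v.ref_allele, v.id

    def test_large_deletion_spans_whole_exons(self, catalog, model):
        ld = next(v for v in catalog if v.vtype == "large_deletion")
        lo, hi = ld.exon_span
        assert hi - lo + 1 >= 2
        assert ld.locus == (model.exons[lo - 1][0], model.exons[hi - 1][1])

    def test_alleles_are_normalized(self, catalog, seq):
        for v in catalog:
            if v.vtype == "large_deletion":
                continue
            assert normalize_variant(v.pos, v.ref_allele, v.alt_allele, seq) \
                == (v.pos, v.ref_allele, v.alt_allele), v.id


class TestCohort:
    def test_forced_hom_frequency(self, catalog):
        one = [v for v in catalog if v.id == "CFv01"]
        one[0] = one[0].__class__(**{**one[0].__dict__, "hom_freq": 1.0, "het_freq": 0.0})
        cohort = sample_cohort(one, SimulationConfig(seed=3, n_samples=8))
        assert all(s.genotypes == {"CFv01": "hom"} for s in cohort)

    def test_zygosity_tallies_match_recount(self, catalog):
        """Cohort-level hom/het tallies equal a brute-force recount over the
        emitted truth records, and track the configured Table-style rates."""
        cfg = SimulationConfig(seed=9, n_samples=177)
        cohort = sample_cohort(catalog, cfg)
        tallies = {}
        for s in cohort:
            for vid, g in s.genotypes.items():
                tallies.setdefault(vid, {"hom": 0, "het": 0})[g] += 1
        recount = {}
        for s in cohort:
            for vid, g in s.genotypes.items():
                recount.setdefault(vid, {"hom": 0, "het": 0})[g] += 1
        assert tallies == recount
        f508 = tallies["CFv01"]
        # expected 13 hom / 10 het of 177; allow ~4 sd of binomial noise
        assert abs(f508["hom"] - 13) <= 14
        assert abs(f508["het"] - 10) <= 12

    def test_deletion_carrier_count_exact(self, catalog):
        cfg = SimulationConfig(seed=5, n_samples=12, n_deletion_carriers=2)
        cohort = sample_cohort(catalog, cfg)
        carriers = [s for s in cohort if s.cnv is not None]
        assert len(carriers) == 2
        assert all(s.cnv["exon_span"] == (4, 11) and s.cnv["copies"] == 0
                   for s in carriers)

    def test_dropout_carriers_forced(self, catalog):
        cfg = SimulationConfig(seed=5, n_samples=40, dropout=True)
        cohort = sample_cohort(catalog, cfg)
        by_vid = {vid: 0 for vid in DROPOUT_VARIANTS}
        for s in cohort:
            for lo, hi in s.dropout_regions:
                for vid in DROPOUT_VARIANTS:
                    v = next(v for v in catalog if v.id == vid)
                    if v.locus == (lo, hi):
                        by_vid[vid] += 1
                        assert s.genotypes.get(vid) is not None
        for vid in DROPOUT_VARIANTS:
            assert by_vid[vid] == min(DROPOUT_CARRIERS[vid], 40)

    def test_deterministic(self, catalog, default_config):
        a = sample_cohort(catalog, default_config)
        b = sample_cohort(catalog, default_config)
        assert [(s.sample_id, s.genotypes, s.phases, s.tgt_diplotype)
                for s in a] == \
               [(s.sample_id, s.genotypes, s.phases, s.tgt_diplotype)
                for s in b]


class TestReads:
    def test_ref_fidelity_no_variants_no_error(self, panel, model, seq, catalog):
        """At error rate 0 with no variants every read base matches the
        reference (exhaustive check)."""
        cfg = SimulationConfig(seed=4, n_samples=1, mean_depth=60)
        truth = SampleTruth(sample_id="S001")
        reads = simulate_reads(truth, panel, cfg, model, seq, catalog)
        assert reads
        for r in reads:
            assert r.cigar == (("M", len(r.seq)),)
            assert seq[r.start:r.start + len(r.seq)] == r.seq

    def test_depth_law(self, panel, model, seq, catalog):
        """Per-amplicon mean count, corrected for the shared efficiency
        factor, is within 3 SE of the configured mean over >= 30 amplicons."""
        cfg = SimulationConfig(seed=6, n_samples=1)
        truth = SampleTruth(sample_id="S001",
                            tgt_diplotype=((11, 7), (11, 7)))
        counts = simulate_amplicon_counts(truth, panel, cfg, model)
        eff = amplicon_efficiencies(panel, cfg)
        expected = cfg.mean_depth / panel_redundancy(panel)
        corrected = counts / eff
        n = len(corrected)
        assert n >= 30
        se = corrected.std(ddof=1) / np.sqrt(n)
        assert abs(corrected.mean() - expected) <= 3 * se

    def test_het_alt_fraction_near_half(self, panel, model, seq, catalog):
        cfg = SimulationConfig(seed=1, n_samples=1, mean_depth=1000)
        v = next(v for v in catalog if v.id == "CFv14")     # exonic SNV
        truth = SampleTruth(sample_id="S001", genotypes={v.id: "het"},
                            phases={v.id: 0})
        reads = simulate_reads(truth, panel, cfg, model, seq, catalog)
        alt = tot = 0
        for r in reads:
            if r.start <= v.pos < r.start + len(r.seq) and r.cigar == (("M", len(r.seq)),):
                tot += 1
                alt += r.seq[v.pos - r.start] == v.alt_allele
        assert tot >= 500
        assert 0.45 <= alt / tot <= 0.55

    def test_hom_snv_all_alt(self, panel, model, seq, catalog):
        v = next(v for v in catalog if v.id == "CFv14")
        cfg = SimulationConfig(seed=1, n_samples=1, mean_depth=100)
        truth = SampleTruth(sample_id="S001", genotypes={v.id: "hom"},
                            phases={v.id: 2})
        reads = simulate_reads(truth, panel, cfg, model, seq, catalog)
        covering = [r for r in reads if r.start <= v.pos < r.end]
        assert covering
        assert all(r.seq[v.pos - r.start] == v.alt_allele for r in covering)

    def test_dropout_region_zero_reads(self, panel, model, seq, catalog):
        amp = panel.amplicons[10]
        cfg = SimulationConfig(seed=2, n_samples=1)
        truth = SampleTruth(sample_id="S001",
                            dropout_regions=[(amp.insert[0] + 10, amp.insert[0] + 20)])
        reads = simulate_reads(truth, panel, cfg, model, seq, catalog)
        lo, hi = amp.insert[0] + 10, amp.insert[0] + 20
        assert not any(r.start < hi and lo < r.end for r in reads)

    def test_counts_path_matches_read_path(self, panel, model, seq, catalog):
        """The amplicon-count fast path draws the same counts that the read
        simulator materializes."""
        cfg = SimulationConfig(seed=8, n_samples=1)
        truth = SampleTruth(sample_id="S001")
        counts = simulate_amplicon_counts(truth, panel, cfg, model)
        reads = simulate_reads(truth, panel, cfg, model, seq, catalog)
        per_amp = {}
        for r in reads:
            aid = r.name.split(":")[1]
            per_amp[aid] = per_amp.get(aid, 0) + 1
        for a, c in zip(panel.amplicons, counts):
            assert per_amp.get(a.id, 0) == c

    def test_read_length_shorter_than_insert_errors(self, panel, model, seq, catalog):
        cfg = SimulationConfig(seed=1, read_length=100)
        with pytest.raises(SizingError):
            simulate_reads(SampleTruth(sample_id="S1"), panel, cfg, model, seq, catalog)
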