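"""Generator contracts: planted structure, determinism, error model,
copy-number truth and short-read coverage."""

import numpy as np
import pytest
import edlib

from retroscope.simkit import (CATEGORIES, SimConfig, simulate_accessions,
                               simulate_genome, simulate_reads,
                               simulate_short_reads, truth_transcript)


def small_config(**kw):
    defaults = dict(seed=1, genome_length=120_000,
                    n_per_category={"tr_gag": 3, "nonltr_gene": 2})
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateGenome:
    def test_zero_elements_gives_background_only(self):
        cfg = SimConfig(seed=2, genome_length=50_000,
                        n_per_category={c: 0 for c in CATEGORIES})
        genome, truth = simulate_genome(cfg)
        assert truth == [] and len(genome) == 50_000

    def test_category_counts_and_structure(self):
        cfg = small_config()
        _genome, truth = simulate_genome(cfg)
        tr = [t for t in truth if t.category == "tr_gag"]
        assert len(tr) == 3
        for t in tr:
            assert t.ltr5_span is not None and t.ltr3_span is not None
            assert t.domain_layout == ["GAG"]
        genes = [t for t in truth if t.category == "nonltr_gene"]
        assert len(genes) == 2
        for t in genes:
            assert t.ltr5_span is None and 4 <= len(t.exon_spans) <= 10

    def test_seed_determinism(self):
        g1, t1 = simulate_genome(small_config())
        g2, t2 = simulate_genome(small_config())
        assert g1 == g2
        assert [x.span for x in t1] == [x.span for x in t2]

    def test_capacity_error(self):
        cfg = SimConfig(seed=1, genome_length=5_000,
                        n_per_category={"autonomous_full": 5})
        with pytest.raises(ValueError, match="budget"):
            simulate_genome(cfg)

    def test_ltr_pairs_meet_configured_identity(self):
        cfg = small_config(ltr_identity=0.95)
        genome, truth = simulate_genome(cfg)
        for t in truth:
            if t.ltr5_span is None:
                continue
            l5 = genome[t.ltr5_span[0]:t.ltr5_span[1]]
            l3 = genome[t.ltr3_span[0]:t.ltr3_span[1]]
            dist = edlib.align(l5, l3, mode="NW")["editDistance"]
            assert 1 - dist / len(l5) >= 0.95 - 0.01

    def test_tsd_flanks_element(self):
        genome, truth = simulate_genome(small_config())
        for t in truth:
            if not t.tsd:
                continue
            L = len(t.tsd)
            assert genome[t.span[0] - L:t.span[0]] == t.tsd
            assert genome[t.span[1]:t.span[1] + L] == t.tsd

    def test_sorted_by_coordinate(self):
        _g, truth = simulate_genome(small_config())
        spans = [t.span for t in truth]
        assert spans == sorted(spans)


class TestSimulateReads:
    def test_zero_abundance_gives_empty_sample(self):
        cfg = small_config(samples=("control", "treat"))
        genome, truth = simulate_genome(cfg)
        ab = {(t.element_id, s): (0.0 if s == "control" else 5.0)
              for t in truth for s in cfg.samples}
        cfg.abundance = ab
        reads = simulate_reads(genome, truth, cfg)
        assert reads["control"] == []
        assert len(reads["treat"]) > 0

    def test_noiseless_reads_are_exact_transcript_substrings(self):
        cfg = small_config(error_rates=(0.0, 0.0, 0.0), truncation_rate=0.0,
                           samples=("s",))
        genome, truth = simulate_genome(cfg)
        cfg.abundance = {(truth[0].element_id, "s"): 10.0}
        reads = simulate_reads(genome, truth, cfg)["s"]
        tx = truth_transcript(genome, truth[0])
        assert reads
        for _rid, seq, _q in reads:
            assert seq in tx

    def test_realized_edit_rate_near_configured(self):
        cfg = small_config(error_rates=(0.03, 0.02, 0.02), truncation_rate=0.0,
                           samples=("s",))
        genome, truth = simulate_genome(cfg)
        cfg.abundance = {(t.element_id, "s"): 10.0 for t in truth}
        reads = simulate_reads(genome, truth, cfg)["s"]
        tx = {t.element_id: truth_transcript(genome, t) for t in truth}
        edits = bases = 0
        for rid, seq, _q in reads:
            ref = tx[rid.split("|")[0]]
            edits += edlib.align(seq, ref, mode="NW")["editDistance"]
            bases += len(ref)
        assert bases > 10_000
        assert 0.07 * 0.8 <= edits / bases <= 0.07 * 1.2

    def test_unknown_locus_in_abundance_rejected(self):
        cfg = small_config()
        genome, truth = simulate_genome(cfg)
        cfg.abundance = {("no_such_locus", cfg.samples[0]): 1.0}
        with pytest.raises(ValueError, match="unknown locus"):
            simulate_reads(genome, truth, cfg)

    def test_read_names_encode_truth_locus(self):
        cfg = small_config()
        genome, truth = simulate_genome(cfg)
        reads = simulate_reads(genome, truth, cfg)
        ids = {t.element_id for t in truth}
        for sample, rs in reads.items():
            for rid, _s, _q in rs:
                eid, smp, _n = rid.split("|")
                assert eid in ids and smp == sample


def brute_force_copy_scan(element: str, assembly: str, min_identity=0.95,
                          step=200) -> int:
    """Sliding-window identity scan: count maximal runs of window starts
    whose best edit-distance match reaches the identity threshold."""
    L = len(element)
    hits = []
    for start in range(0, len(assembly) - L + 1, step):
        window = assembly[start:start + int(1.1 * L)]
        for q in (element,):
            res = edlib.align(q, window, mode="HW")
            ident = 1 - res["editDistance"] / L
            if ident >= min_identity:
                hits.append(start)
                break
    # merge starts within one element length into single loci
    loci = 0
    prev = None
    for h in hits:
        if prev is None or h - prev > 1.2 * L:
            loci += 1
        prev = h
    return loci


class TestSimulateAccessions:
    def test_all_single_copy(self):
        genome, truth = simulate_genome(small_config())
        cnv = {(t.element_id, "A1"): 1 for t in truth}
        accs, table = simulate_accessions(genome, truth, cnv, seed=3)
        assert accs["A1"] == genome
        assert (table["A1"] == 1).all()

    def test_empty_spec_returns_nothing(self):
        genome, truth = simulate_genome(small_config())
        accs, table = simulate_accessions(genome, truth, {}, seed=3)
        assert accs == {} and table.empty

    def test_negative_count_rejected(self):
        genome, truth = simulate_genome(small_config())
        with pytest.raises(ValueError, match="negative"):
            simulate_accessions(genome, truth, {(truth[0].element_id, "A1"): -1}, seed=3)

    def test_copy_counts_verified_by_sliding_window_oracle(self):
        genome, truth = simulate_genome(small_config())
        eid = truth[0].element_id
        cnv = {(eid, "A1"): 1, (eid, "A2"): 5}
        accs, _ = simulate_accessions(genome, truth, cnv, seed=3)
        element = genome[truth[0].span[0]:truth[0].span[1]]
        assert brute_force_copy_scan(element, accs["A1"]) == 1
        assert brute_force_copy_scan(element, accs["A2"]) == 5

    def test_zero_count_deletes_planted_copy(self):
        genome, truth = simulate_genome(small_config())
        eid = truth[0].element_id
        accs, _ = simulate_accessions(genome, truth, {(eid, "A1"): 0}, seed=3)
        element = genome[truth[0].span[0]:truth[0].span[1]]
        assert brute_force_copy_scan(element, accs["A1"]) == 0


class TestSimulateShortReads:
    def test_closed_form_read_count(self):
        genome, _ = simulate_genome(SimConfig(
            seed=4, genome_length=100_000, n_per_category={}))
        reads = simulate_short_reads(genome, depth=10, read_length=100, seed=5)
        assert len(reads) == 10_000

    def test_mean_coverage_near_depth(self):
        genome, _ = simulate_genome(SimConfig(
            seed=4, genome_length=50_000, n_per_category={}))
        reads = simulate_short_reads(genome, depth=20, read_length=100, seed=5)
        cov = np.zeros(len(genome))
        for rid, _seq, _q in reads:
            _n, start, _strand = rid.split("|")
            cov[int(start):int(start) + 100] += 1
        assert abs(cov.mean() - 20) / 20 < 0.1

    def test_seed_repeatability(self):
        genome, _ = simulate_genome(SimConfig(
            seed=4, genome_length=20_000, n_per_category={}))
        r1 = simulate_short_reads(genome, 5, 100, seed=6)
        r2 = simulate_short_reads(genome, 5, 100, seed=6)
        assert r1 == r2

    def test_preconditions(self):
        genome = "ACGT" * 1000
        with pytest.raises(ValueError):
            simulate_short_reads(genome, 0, 100, seed=1)
        with pytest.raises(ValueError):
            simulate_short_reads(genome, 5, 5000, seed=1)
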