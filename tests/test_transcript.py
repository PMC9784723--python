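"""Read clustering, consensus, spliced mapping and RPM quantification."""

import edlib
import numpy as np
import pytest

from retroscope.simkit import (SimConfig, simulate_genome, simulate_reads,
                               truth_transcript)
from retroscope.transcript import (ReadCluster, SplicedMapper, build_consensus,
                                   build_models, cluster_reads,
                                   model_from_sequence, quantify_rpm)


def make_reads(seq, n, prefix="r"):
    return [(f"{prefix}{i}", seq) for i in range(n)]


class TestClusterReads:
    def test_identical_copies_one_cluster(self):
        reads = make_reads("ACGT" * 100, 10)
        clusters = cluster_reads(reads)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_read_ids) == sorted(r[0] for r in reads)

    def test_two_dissimilar_loci_two_clusters(self, rng):
        a = "".join(rng.choice(list("ACGT"), 600))
        b = "".join(rng.choice(list("ACGT"), 600))
        clusters = cluster_reads(make_reads(a, 5, "a") + make_reads(b, 5, "b"))
        assert len(clusters) == 2
        for cl in clusters:
            assert len({rid[0] for rid in cl.member_read_ids}) == 1

    def test_singleton_dropped(self):
        assert cluster_reads([("r0", "ACGT" * 100)]) == []

    def test_short_reads_filtered(self):
        assert cluster_reads(make_reads("ACGT" * 10, 5)) == []  # < 200 nt

    def test_noisy_same_locus_reads_cocluster(self, read_scenario):
        clusters = cluster_reads(read_scenario["all"])
        impure = sum(
            1 for c in clusters
            if len({m.split("|")[0] for m in c.member_read_ids}) > 1
        )
        assert impure / len(clusters) <= 0.1
        # partition property: no read in two clusters
        seen = [m for c in clusters for m in c.member_read_ids]
        assert len(seen) == len(set(seen))


class TestBuildConsensus:
    def test_noiseless_cluster_reproduces_source(self):
        seq = "ACGTTGCA" * 80
        cl = ReadCluster("c0", [f"r{i}" for i in range(5)], seq)
        cons = build_consensus(cl, {f"r{i}": seq for i in range(5)})
        assert cons == seq

    def test_noisy_cluster_high_identity(self, rng):
        truth = "".join(rng.choice(list("ACGT"), 1500))
        reads = {}
        for i in range(20):
            seq = []
            for ch in truth:
                if rng.random() < 0.02:        # deletion
                    continue
                seq.append("ACGT"[int(rng.integers(4))] if rng.random() < 0.03 else ch)
                if rng.random() < 0.02:        # insertion
                    seq.append("ACGT"[int(rng.integers(4))])
            reads[f"r{i}"] = "".join(seq)
        rep = max(reads.values(), key=len)
        cl = ReadCluster("c0", list(reads), rep)
        cons = build_consensus(cl, reads)
        dist = edlib.align(cons, truth, mode="NW")["editDistance"]
        assert 1 - dist / len(truth) >= 0.99

    def test_two_member_tie_goes_to_longest(self):
        longer = "AAAATTTTCCCCGGGG" * 20
        shorter = longer[:-16].replace("AAAATTTT", "AAAACTTT", 1)
        cl = ReadCluster("c0", ["long", "short"], longer)
        cons = build_consensus(cl, {"long": longer, "short": shorter})
        assert cons == longer  # ties resolve toward the representative

    def test_consensus_length_bounded(self, read_scenario):
        clusters = cluster_reads(read_scenario["all"])[:5]
        for cl in clusters:
            cons = build_consensus(cl, read_scenario["sequences"])
            assert 0.8 * len(cl.representative) <= len(cons) <= 1.2 * len(cl.representative)


class TestSplicedMapper:
    def test_unique_substring_single_exon_mq60(self, scenario):
        g = scenario["genome"]
        tx = g[40_000:41_500]
        m = scenario["mapper"].map(tx)
        assert m.exons == [(40_000, 41_500)]
        assert m.mq == 60 and m.strand == "+"

    def test_spliced_transcript_exon_boundaries(self, scenario):
        genes = [t for t in scenario["truth"] if t.category == "nonltr_gene"]
        for te in genes[:3]:
            tx = truth_transcript(scenario["genome"], te)
            m = scenario["mapper"].map(tx)
            assert m.strand == te.strand
            assert len(m.exons) == len(te.exon_spans)
            for got, want in zip(m.exons, te.exon_spans):
                assert abs(got[0] - want[0]) <= 10 and abs(got[1] - want[1]) <= 10

    def test_two_identical_copies_map_with_mq0(self, rng):
        unit = "".join(rng.choice(list("ACGT"), 2000))
        spacer = "".join(rng.choice(list("ACGT"), 3000))
        genome = spacer + unit + spacer + unit + spacer
        mapper = SplicedMapper(genome)
        m = mapper.map(unit[200:1800])
        assert m is not None and m.mq == 0

    def test_unmappable_returns_none(self, scenario, rng):
        alien = "".join(rng.choice(list("ACGT"), 500))
        assert scenario["mapper"].map(alien) is None

    def test_short_transcript_rejected(self, scenario):
        with pytest.raises(ValueError):
            scenario["mapper"].map("ACGT" * 10)

    def test_build_models_filters_low_mq(self, rng):
        unit = "".join(rng.choice(list("ACGT"), 2000))
        spacer = "".join(rng.choice(list("ACGT"), 3000))
        genome = spacer + unit + spacer + unit + spacer
        mapper = SplicedMapper(genome)
        reads = make_reads(unit[100:1900], 4)
        clusters = cluster_reads(reads)
        models, dropped = build_models(clusters, dict(reads), mapper)
        assert models == []
        assert dropped and dropped[0][1].startswith("mq=")


class TestQuantifyRpm:
    def _one_model(self, rng):
        genome = "".join(rng.choice(list("ACGT"), 8000))
        mapper = SplicedMapper(genome)
        tx = genome[2000:3500]
        return model_from_sequence("cluster_0", tx, mapper), tx

    def test_closed_form_rpm(self, rng):
        model, tx = self._one_model(rng)
        em = quantify_rpm({"s": make_reads(tx, 10)}, [model],
                          total_mapped={"s": 1_000_000})
        assert em.rpm.loc["cluster_0", "s"] == pytest.approx(10.0)

    def test_detection_strictly_above_two(self, rng):
        model, tx = self._one_model(rng)
        em = quantify_rpm({"s": make_reads(tx, 2)}, [model],
                          total_mapped={"s": 1_000_000})
        assert em.rpm.loc["cluster_0", "s"] == pytest.approx(2.0)
        assert not em.detected.loc["cluster_0", "s"]
        em2 = quantify_rpm({"s": make_reads(tx, 201)}, [model],
                           total_mapped={"s": 100_000_000})
        assert em2.rpm.loc["cluster_0", "s"] == pytest.approx(2.01)
        assert em2.detected.loc["cluster_0", "s"]

    def test_zero_mapped_sample_is_an_error(self, rng):
        model, _tx = self._one_model(rng)
        with pytest.raises(ValueError, match="zero mapped"):
            quantify_rpm({"s": []}, [model])

    def test_treatment_only_detection_pattern(self, rng):
        """A locus silent in the control and active under treatment gives
        the treatment-only detection class."""
        cfg = SimConfig(seed=11, genome_length=80_000,
                        n_per_category={"tr_gag": 2}, samples=("control", "treat"))
        genome, truth = simulate_genome(cfg)
        eid0, eid1 = truth[0].element_id, truth[1].element_id
        cfg.abundance = {
            (eid0, "control"): 30.0, (eid0, "treat"): 30.0,
            (eid1, "control"): 0.0, (eid1, "treat"): 30.0,
        }
        reads = simulate_reads(genome, truth, cfg)
        per_sample = {s: [(r[0], r[1]) for r in rs] for s, rs in reads.items()}
        mapper = SplicedMapper(genome)
        models = [model_from_sequence(te.element_id, truth_transcript(genome, te), mapper)
                  for te in truth]
        em = quantify_rpm(per_sample, models)
        assert em.detected.loc[eid1, "treat"] and not em.detected.loc[eid1, "control"]
        assert em.detected.loc[eid0].all()

    def test_counts_bounded_by_total_reads(self, read_scenario, scenario, library):
        models = [model_from_sequence(te.element_id,
                                      truth_transcript(scenario["genome"], te),
                                      scenario["mapper"], library)
                  for te in scenario["truth"][:10]]
        em = quantify_rpm(read_scenario["per_sample"], models)
        for s, reads in read_scenario["per_sample"].items():
            assert em.raw_counts[s].sum() <= len(reads)
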