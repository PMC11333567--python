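import io

import numpy as np
import pytest

from squigmap.chaining import Anchor, Chain, mapping_quality
from squigmap.mapping import (
    ChunkParams,
    DecisionParams,
    MappingRecord,
    map_read,
    query_frequency_filter,
    read_paf,
    weighted_decision,
    write_paf,
)
from squigmap.signal_io import RawRead
from squigmap.simulator import SimParams, random_genome, simulate_reads


def make_chain(score, mapq=None, m=10):
    anchors = tuple(Anchor(10 + 6 * i, 10 + 6 * i, 6) for i in range(m))
    c = Chain(anchors=anchors, score=score)
    if mapq is not None:
        c.mapq = mapq
    return c


class TestQueryFrequencyFilter:
    def test_off(self):
        seeds = [(0, 7), (1, 7), (2, 7)]
        assert query_frequency_filter(seeds, 0) == seeds

    def test_multiplicity_filtered(self):
        seeds = [(0, 7), (1, 7), (2, 7), (3, 9)]
        assert query_frequency_filter(seeds, 2) == [(3, 9)]

    def test_all_distinct_unchanged(self):
        seeds = [(i, i + 100) for i in range(10)]
        assert query_frequency_filter(seeds, 1) == seeds


class TestWeightedDecision:
    def test_saturated_single_chain(self):
        chains = [make_chain(100.0, mapq=30)]
        decision, w_sum = weighted_decision(
            chains, DecisionParams(weights=(1, 1, 1), tau=0.9))
        assert decision == "map"
        assert w_sum == pytest.approx(1.0)

    def test_no_chains(self):
        assert weighted_decision([], DecisionParams()) == ("continue", 0.0)

    @pytest.mark.parametrize("tau,expected", [(0.6, "continue"),
                                              (0.4, "map")])
    def test_half_quality_all_weight_on_r1(self, tau, expected):
        chains = [make_chain(100.0, mapq=15)]
        dp = DecisionParams(weights=(1, 0, 0), tau=tau)
        decision, w_sum = weighted_decision(chains, dp)
        assert w_sum == pytest.approx(0.5)
        assert decision == expected

    def test_hand_computed_multi_chain(self):
        # best mapq 30, runner-up 0: mean mapq 15, mean score 75
        chains = [make_chain(100.0, mapq=30), make_chain(50.0, mapq=0)]
        dp = DecisionParams(weights=(0.4, 0.3, 0.3), tau=0.0,
                            cap_2=5.0, cap_3=5.0)
        _, w_sum = weighted_decision(chains, dp)
        r2 = min(5.0, 30 / 15) / 5.0
        r3 = min(5.0, 100 / 75) / 5.0
        assert w_sum == pytest.approx(0.4 * 1.0 + 0.3 * r2 + 0.3 * r3)

    def test_monotone_in_tau(self):
        chains = mapping_quality([make_chain(80.0), make_chain(30.0)])
        decisions = [weighted_decision(chains, DecisionParams(tau=t))[0]
                     for t in np.linspace(0, 1, 21)]
        # once a tau is too high to map, every higher tau also continues
        first_continue = decisions.index("continue") \
            if "continue" in decisions else len(decisions)
        assert all(d == "continue" for d in decisions[first_continue:])

    def test_weights_normalized(self):
        dp = DecisionParams(weights=(2, 1, 1))
        assert sum(dp.weights) == pytest.approx(1.0)
        assert dp.weights[0] == pytest.approx(0.5)


class TestMapRead:
    def test_simulated_read_maps_to_origin(self, index_100k, genome_100k,
                                           model6):
        reads, truth = simulate_reads([genome_100k], model6,
                                      SimParams(n_reads=5, rng_seed=42))
        for read, tr in zip(reads, truth):
            rec = map_read(read, index_100k)
            assert rec.is_mapped
            assert rec.tname == tr.tname and rec.strand == tr.strand
            assert rec.tstart < tr.tend and tr.tstart < rec.tend  # overlap
            assert rec.tags["dc"] == "mapped"
            assert 0 <= rec.qstart < rec.qend <= rec.qlen

    def test_foreign_read_stays_unmapped(self, index_100k, model6):
        foreign = random_genome(20_000, seed=4242, name="foreign")
        reads, _ = simulate_reads([foreign], model6,
                                  SimParams(n_reads=3, rng_seed=4))
        for read in reads:
            rec = map_read(read, index_100k)
            assert not rec.is_mapped
            assert rec.tags["dc"] == "unmapped_max_chunks"
            assert rec.tname == "*" and rec.mapq == 0

    def test_bases_before_decision_identity(self, e2e_scenario):
        cp = ChunkParams()
        spb = cp.samples_per_base(4000.0)
        for rec in e2e_scenario["records"]:
            expected = rec.tags["ch"] * cp.chunk_samples / spb
            assert rec.tags["bb"] == pytest.approx(expected, abs=0.01)

    def test_unusable_read_reported_unmapped(self, index_100k):
        # too short to segment at all: zero events -> warned, unmapped
        read = RawRead("stub", np.full(8, 80.0))
        with pytest.warns(UserWarning):
            rec = map_read(read, index_100k)
        assert not rec.is_mapped
        # constant but segmentable: one flat event, still unmapped
        flat = map_read(RawRead("flat", np.full(2000, 80.0)), index_100k)
        assert not flat.is_mapped and flat.tags["dc"] == "unmapped_max_chunks"


class TestPafIO:
    def records(self):
        return [
            MappingRecord("r1", 1000, 10, 900, "+", "chr1", 5000, 100, 990,
                          50, 890, 60, {"ch": 2, "ws": 0.93, "dc": "mapped"}),
            MappingRecord("r2", 800, 0, 0, "*", "*", 0, 0, 0, 0, 0, 0,
                          {"ch": 30, "dc": "unmapped_max_chunks"}),
            MappingRecord("r3", 500, 5, 450, "-", "chr2", 9000, 800, 1250,
                          30, 450, 17, {}),
        ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "x.paf"
        write_paf(self.records(), path)
        back = read_paf(path)
        assert back == self.records()

    def test_unmapped_serialization(self, tmp_path):
        path = tmp_path / "u.paf"
        write_paf([self.records()[1]], path)
        fields = path.read_text().split("\t")
        assert fields[5] == "*" and fields[11] == "0"

    def test_typed_tags(self):
        buf = io.StringIO()
        write_paf(self.records()[:1], buf)
        line = buf.getvalue()
        assert "ch:i:2" in line and "ws:f:0.93" in line and "dc:Z:mapped" in line
        (rec,) = read_paf(io.StringIO(line))
        assert rec.tags["ch"] == 2 and isinstance(rec.tags["ch"], int)
        assert rec.tags["ws"] == pytest.approx(0.93)

    def test_malformed_line_skipped(self, tmp_path, caplog):
        path = tmp_path / "bad.paf"
        write_paf(self.records()[:1], path)
        with open(path, "a") as fh:
            fh.write("only\tthree\tcolumns\n")
        with caplog.at_level("WARNING"):
            back = read_paf(path)
        assert len(back) == 1
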