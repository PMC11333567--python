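import itertools
import math

import numpy as np
import pytest

from squigmap.chaining import (
    Anchor,
    Chain,
    ChainParams,
    chain_anchors,
    gap_penalty,
    mapping_quality,
)

NO_PRUNE = ChainParams(max_gap=10**9, max_skip=10**9, max_iter=10**9,
                       min_score=1e-9, min_anchors=1)


def brute_force_best(anchors, max_gap=None):
    """Exhaustively score every increasing anchor subsequence."""
    n = len(anchors)
    best = 0.0
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            seq = [anchors[i] for i in combo]
            ok = all(
                a.x < b.x and a.y < b.y
                and (max_gap is None
                     or (b.x - a.x <= max_gap and b.y - a.y <= max_gap))
                for a, b in zip(seq, seq[1:]))
            if not ok:
                continue
            score = seq[0].w
            for a, b in zip(seq, seq[1:]):
                alpha = min(b.y - a.y, b.x - a.x, b.w)
                beta = gap_penalty((b.y - a.y) - (b.x - a.x), b.w)
                score += alpha - beta
            best = max(best, score)
    return best


def random_anchors(rng, n, span=50):
    pts = sorted({(int(rng.integers(6, span)), int(rng.integers(6, span)))
                  for _ in range(n)})
    return [Anchor(x=x, y=y, w=6) for x, y in pts]


class TestGapPenalty:
    @pytest.mark.parametrize("l,w,expected", [
        (0, 6, 0.0),
        (0, 100, 0.0),
        (1, 6, 0.06),           # log2(1) = 0
        (4, 6, 1.24),           # 0.24 + 1.0
        (-4, 6, 1.24),          # symmetric in |l|
    ])
    def test_values(self, l, w, expected):
        assert gap_penalty(l, w) == pytest.approx(expected)


class TestChainAnchors:
    def test_single_anchor(self):
        chains = chain_anchors([Anchor(10, 10, 6)], NO_PRUNE)
        assert len(chains) == 1
        assert chains[0].score == 6

    def test_two_anchor_hand_score(self):
        # alpha = min(6, 6, 6) = 6, l = 0 so no penalty: 6 + 6 = 12
        chains = chain_anchors([Anchor(10, 10, 6), Anchor(16, 16, 6)],
                               NO_PRUNE)
        assert chains[0].score == pytest.approx(12.0)
        assert chains[0].n_anchors == 2

    def test_gapped_pair_penalized(self):
        # dx=6, dy=10 -> alpha=6, l=4 -> beta=1.24
        chains = chain_anchors([Anchor(10, 10, 6), Anchor(16, 20, 6)],
                               NO_PRUNE)
        assert chains[0].score == pytest.approx(6 + 6 - 1.24)

    @pytest.mark.parametrize("trial", range(100))
    def test_dp_equals_brute_force(self, trial):
        rng = np.random.default_rng(5000 + trial)
        anchors = random_anchors(rng, int(rng.integers(1, 11)))
        got = chain_anchors(anchors, NO_PRUNE)
        assert got, "at least one chain must be reported"
        assert got[0].score == pytest.approx(brute_force_best(anchors))

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            chain_anchors([Anchor(16, 16, 6), Anchor(10, 10, 6)], NO_PRUNE)

    def test_mixed_strands_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            chain_anchors([Anchor(10, 10, 6, "+"), Anchor(16, 16, 6, "-")],
                          NO_PRUNE)

    def test_chains_respect_thresholds_and_monotonicity(self, rng):
        cp = ChainParams(max_gap=100, min_score=12.0, min_anchors=2)
        anchors = random_anchors(rng, 40, span=300)
        for chain in chain_anchors(anchors, cp):
            assert chain.score >= cp.min_score
            assert chain.n_anchors >= cp.min_anchors
            xs = [a.x for a in chain.anchors]
            ys = [a.y for a in chain.anchors]
            assert all(b > a for a, b in zip(xs, xs[1:]))
            assert all(b > a for a, b in zip(ys, ys[1:]))

    def test_anchors_assigned_to_one_chain(self, rng):
        anchors = random_anchors(rng, 60, span=400)
        chains = chain_anchors(anchors, ChainParams(
            max_gap=10**9, max_skip=10**9, max_iter=10**9,
            min_score=1e-9, min_anchors=1))
        seen = set()
        for c in chains:
            for a in c.anchors:
                assert (a.x, a.y) not in seen
                seen.add((a.x, a.y))

    def test_zero_gap_extension_never_decreases_score(self):
        base = [Anchor(10, 10, 6), Anchor(16, 16, 6)]
        extended = base + [Anchor(22, 22, 6)]
        s0 = chain_anchors(base, NO_PRUNE)[0].score
        s1 = chain_anchors(extended, NO_PRUNE)[0].score
        assert s1 >= s0

    def test_max_gap_bounds_admissibility(self):
        # second anchor is 1000 away on both axes: inadmissible at max_gap=500
        anchors = [Anchor(10, 10, 6), Anchor(1010, 1010, 6)]
        cp = ChainParams(max_gap=500, max_skip=10**9, max_iter=10**9,
                         min_score=1e-9, min_anchors=1)
        chains = chain_anchors(anchors, cp)
        assert max(c.score for c in chains) == pytest.approx(6.0)


class TestMappingQuality:
    def make(self, score, m=10):
        anchors = tuple(Anchor(10 + 6 * i, 10 + 6 * i, 6) for i in range(m))
        return Chain(anchors=anchors, score=score)

    def test_equal_top_two_gives_zero(self):
        chains = mapping_quality([self.make(50.0), self.make(50.0)])
        assert chains[0].mapq == 0

    def test_single_chain_at_score_e(self):
        # f2=0, m>=10, ln(e)=1 -> mapq 40
        chains = mapping_quality([self.make(math.e)])
        assert chains[0].mapq == 40

    def test_monotone_in_f2(self):
        qs = [mapping_quality([self.make(100.0), self.make(f2)])[0].mapq
              for f2 in (10.0, 40.0, 70.0, 99.0)]
        assert qs == sorted(qs, reverse=True)

    def test_secondary_chains_get_zero(self):
        chains = mapping_quality([self.make(80.0), self.make(30.0)])
        assert chains[0].is_primary and chains[0].mapq > 0
        assert not chains[1].is_primary and chains[1].mapq == 0

    def test_cap_at_60(self):
        chains = mapping_quality([self.make(10**9)])
        assert chains[0].mapq == 60

    def test_empty(self):
        assert mapping_quality([]) == []
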