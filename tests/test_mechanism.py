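import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleodup.homology import CandidatePair, HomologyHit
from paleodup.mechanism import (
    Anchor,
    ChainParams,
    GeneCoordinate,
    TANDEM,
    UNDEFINED,
    WGD,
    build_anchors,
    chain_anchors,
    classify_mechanism,
)


def _anchor(ia, ib, score=10.0, ca="c1", cb="c2", name=None):
    name = name or f"{ia}.{ib}"
    return Anchor(f"a{name}", f"b{name}", ca, cb, ia, ib, score)


def _pair(ga, gb, ev=1e-40):
    hit = HomologyHit(ga, gb, 90.0, 200, 5, 0, ev, 400.0)
    return CandidatePair(*sorted((ga, gb)), "fam", hit)


def brute_force_best(anchors, params):
    """Exhaustive maximum chain score over all anchor subsets, independent
    of the DP.  Assumes distinct idx_a values, so a subset admits exactly
    one candidate order (sorted by idx_a) per orientation."""
    idx = sorted(range(len(anchors)), key=lambda i: anchors[i].idx_a)
    ia = [anchors[i].idx_a for i in idx]
    ib = [anchors[i].idx_b for i in idx]
    sc = [anchors[i].score for i in idx]
    n = len(idx)
    best = -math.inf
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            for sign in (1, -1):
                ok = True
                score = sc[combo[0]]
                for u, v in zip(combo, combo[1:]):
                    da = ia[v] - ia[u]
                    db = sign * (ib[v] - ib[u])
                    if da <= 0 or db <= 0 or da > params.max_gap or db > params.max_gap:
                        ok = False
                        break
                    score += sc[v] - params.gap_penalty * (da + db - 2)
                if ok:
                    best = max(best, score)
    return best


class TestChainAnchors:
    def test_perfect_forward_diagonal(self):
        anchors = [_anchor(i, i) for i in range(1, 7)]
        chains = chain_anchors(anchors, ChainParams(min_anchors=5))
        assert len(chains) == 1
        assert chains[0].orientation == "forward"
        assert len(chains[0].anchors) == 6
        assert chains[0].total_score == pytest.approx(60.0)

    def test_perfect_reverse_diagonal(self):
        anchors = [_anchor(i, 7 - i) for i in range(1, 7)]
        chains = chain_anchors(anchors, ChainParams(min_anchors=5))
        assert len(chains) == 1
        assert chains[0].orientation == "reverse"
        assert len(chains[0].anchors) == 6

    def test_short_chain_discarded(self):
        anchors = [_anchor(i, i) for i in range(1, 5)]
        assert chain_anchors(anchors, ChainParams(min_anchors=5)) == []

    def test_gap_limit_breaks_chain(self):
        anchors = [_anchor(i, i) for i in (1, 2, 3, 4, 5, 50, 51, 52, 53, 54)]
        chains = chain_anchors(anchors, ChainParams(min_anchors=5, max_gap=20))
        assert len(chains) == 2
        assert all(len(c.anchors) == 5 for c in chains)

    def test_self_comparison_excludes_diagonal(self):
        # near-diagonal anchors on the same chromosome are tandem noise
        anchors = [_anchor(i, i + 3, ca="c1", cb="c1") for i in range(1, 10)]
        assert chain_anchors(anchors, ChainParams(min_anchors=5)) == []
        far = [_anchor(i, i + 40, ca="c1", cb="c1") for i in range(1, 10)]
        assert len(chain_anchors(far, ChainParams(min_anchors=5))) == 1

    def test_mixed_chromosome_pairs_rejected(self):
        anchors = [_anchor(1, 1, ca="c1"), _anchor(2, 2, ca="c2")]
        with pytest.raises(ValueError, match="one chromosome pair"):
            chain_anchors(anchors)

    def test_monotone_in_min_anchors(self, rng):
        anchors = [
            _anchor(int(i), int(j), name=f"{k}")
            for k, (i, j) in enumerate(
                zip(rng.integers(1, 60, 40), rng.integers(1, 60, 40))
            )
        ]
        counts = []
        for m in (3, 5, 8, 12):
            chains = chain_anchors(anchors, ChainParams(min_anchors=m))
            counts.append(sum(len(c.anchors) for c in chains))
        assert counts == sorted(counts, reverse=True)

    def test_dp_matches_brute_force_random(self):
        rng = np.random.default_rng(0)
        params = ChainParams(min_anchors=1, max_gap=5, gap_penalty=1.0)
        for trial in range(40):
            n = int(rng.integers(2, 9))
            anchors = [
                _anchor(
                    int(rng.integers(1, 12)),
                    int(rng.integers(1, 12)),
                    score=float(rng.integers(1, 20)),
                    name=f"t{trial}n{k}",
                )
                for k in range(n)
            ]
            # distinct positions per axis so genes are unambiguous
            seen_a, seen_b, uniq = set(), set(), []
            for a in anchors:
                if a.idx_a in seen_a or a.idx_b in seen_b:
                    continue
                seen_a.add(a.idx_a)
                seen_b.add(a.idx_b)
                uniq.append(a)
            if not uniq:
                continue
            expected = brute_force_best(uniq, params)
            got = chain_anchors(uniq, params)[0].total_score
            assert got == pytest.approx(expected), uniq


class TestClassifyMechanism:
    COORDS = {
        "a": GeneCoordinate("a", "c1", 5),
        "b": GeneCoordinate("b", "c1", 16),
        "c": GeneCoordinate("c", "c1", 17),
        "d": GeneCoordinate("d", "c2", 3),
    }

    def test_ten_intervening_is_tandem(self):
        labels = classify_mechanism([_pair("a", "b")], [], self.COORDS)
        assert labels[0].label == TANDEM

    def test_eleven_intervening_is_undefined(self):
        labels = classify_mechanism([_pair("a", "c")], [], self.COORDS)
        assert labels[0].label == UNDEFINED

    def test_different_chromosomes_undefined(self):
        labels = classify_mechanism([_pair("a", "d")], [], self.COORDS)
        assert labels[0].label == UNDEFINED

    def test_chain_membership_wins_over_tandem(self):
        pair = _pair("a", "b")
        chain_anchor = Anchor("a", "b", "c1", "c1", 5, 16, 10.0)
        from paleodup.mechanism import SyntenyChain

        chain = SyntenyChain((chain_anchor,), "forward", 10.0)
        labels = classify_mechanism([pair], [chain], self.COORDS)
        assert labels[0].label == WGD
        assert labels[0].chain_id == 0

    def test_missing_coordinates_undefined(self):
        labels = classify_mechanism([_pair("a", "zz")], [], self.COORDS)
        assert labels[0].label == UNDEFINED

    def test_labels_partition(self):
        pairs = [_pair("a", "b"), _pair("a", "c"), _pair("a", "d")]
        labels = classify_mechanism(pairs, [], self.COORDS)
        assert len(labels) == len(pairs)
        assert {(m.gene_a, m.gene_b) for m in labels} == {
            (p.gene_a, p.gene_b) for p in pairs
        }


class TestBuildAnchors:
    def test_canonical_order_and_score(self):
        coords = {
            "x": GeneCoordinate("x", "c2", 7),
            "y": GeneCoordinate("y", "c1", 3),
        }
        anchors, missing = build_anchors([_pair("x", "y", ev=1e-8)], coords)
        assert missing == []
        a = anchors[0]
        assert (a.chrom_a, a.chrom_b) == ("c1", "c2")
        assert (a.idx_a, a.idx_b) == (3, 7)
        assert a.score == pytest.approx(8.0)

    def test_score_floor_and_cap(self):
        coords = {
            "x": GeneCoordinate("x", "c1", 1),
            "y": GeneCoordinate("y", "c2", 1),
        }
        a1, _ = build_anchors([_pair("x", "y", ev=0.5)], coords)
        assert a1[0].score == 1.0
        a2, _ = build_anchors([_pair("x", "y", ev=1e-300)], coords)
        assert a2[0].score == 50.0
        a3, _ = build_anchors([_pair("x", "y", ev=0.0)], coords)
        assert a3[0].score == 50.0

    def test_missing_coordinates_reported(self):
        anchors, missing = build_anchors([_pair("x", "y")], {})
        assert anchors == []
        assert len(missing) == 1


@given(
    st.lists(
        st.tuples(st.integers(1, 15), st.integers(1, 15), st.integers(1, 9)),
        min_size=1,
        max_size=7,
        unique_by=(lambda t: t[0], lambda t: t[1]),
    )
)
@settings(max_examples=40, deadline=None)
def test_dp_brute_force_property(triples):
    params = ChainParams(min_anchors=1, max_gap=6, gap_penalty=1.0)
    anchors = [
        _anchor(ia, ib, score=float(s), name=f"h{k}")
        for k, (ia, ib, s) in enumerate(triples)
    ]
    got = chain_anchors(anchors, params)
    assert got
    assert got[0].total_score == pytest.approx(brute_force_best(anchors, params))
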