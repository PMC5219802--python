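import io as _io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleodup.homology import (
    FilterThresholds,
    HomologyHit,
    align_all_vs_all,
    build_candidate_pairs,
    filter_hits,
    parse_hits,
)

LINE = "{q}\t{s}\t{pid}\t{ln}\t{mm}\t{go}\t1\t400\t1\t400\t{ev}\t{bs}\n"


def _hit(q="a", s="b", pid=90.0, ln=200, mm=10, go=1, ev=1e-50, bs=500.0):
    return HomologyHit(q, s, pid, ln, mm, go, ev, bs)


class TestParseHits:
    def test_parses_identity(self):
        stream = _io.StringIO(LINE.format(q="g1", s="g2", pid="98.50", ln=400, mm=5, go=0, ev="1e-100", bs="700"))
        hits = parse_hits(stream)
        assert len(hits) == 1
        assert hits[0].percent_identity == 98.5
        assert hits[0].alignment_length == 400

    def test_empty_stream(self):
        assert parse_hits(_io.StringIO("")) == []

    def test_wrong_column_count_names_line(self):
        good = LINE.format(q="g1", s="g2", pid=90, ln=400, mm=5, go=0, ev=1e-30, bs=100)
        bad = "a\tb\tc\n"
        with pytest.raises(ValueError, match="line 2"):
            parse_hits(_io.StringIO(good + bad))

    def test_bad_number_names_line(self):
        bad = LINE.format(q="g1", s="g2", pid="xx", ln=400, mm=5, go=0, ev=1e-30, bs=100)
        with pytest.raises(ValueError, match="line 1"):
            parse_hits(_io.StringIO(bad))


class TestFilterHits:
    def test_identity_below_50_removed(self):
        assert filter_hits([_hit(pid=49.9)]) == []
        assert len(filter_hits([_hit(pid=50.0)])) == 1

    def test_alignment_exactly_300bp_removed(self):
        # 100 aa columns = 300 bp; the threshold is strict >
        assert filter_hits([_hit(ln=100)]) == []
        assert len(filter_hits([_hit(ln=101)])) == 1

    def test_self_hit_removed(self):
        assert filter_hits([_hit(q="a", s="a")]) == []

    def test_evalue_boundary_inclusive(self):
        assert len(filter_hits([_hit(ev=1e-20)])) == 1
        assert filter_hits([_hit(ev=1.1e-20)]) == []

    def test_mismatch_boundary(self):
        assert filter_hits([_hit(mm=550)]) == []
        assert len(filter_hits([_hit(mm=549)])) == 1

    def test_gap_open_boundary(self):
        assert filter_hits([_hit(go=30)]) == []
        assert len(filter_hits([_hit(go=29)])) == 1

    def test_nt_units(self):
        t = FilterThresholds(aln_units="nt")
        assert filter_hits([_hit(ln=300)], t) == []
        assert len(filter_hits([_hit(ln=301)], t)) == 1

    def test_idempotent_and_order_independent(self):
        hits = [
            _hit("a", "b", ev=1e-30),
            _hit("c", "d", pid=40),
            _hit("e", "f", ln=90),
            _hit("g", "h"),
        ]
        once = filter_hits(hits)
        assert filter_hits(once) == once
        assert sorted(filter_hits(hits[::-1]), key=str) == sorted(once, key=str)


class TestBuildCandidatePairs:
    FAMS = {"a": "f1", "b": "f1", "c": "f2"}

    def test_cross_family_dropped(self):
        assert build_candidate_pairs([_hit("a", "c")], self.FAMS) == []

    def test_reciprocal_hits_keep_better(self):
        h1 = _hit("a", "b", ev=1e-30)
        h2 = _hit("b", "a", ev=1e-50)
        pairs = build_candidate_pairs([h1, h2], self.FAMS)
        assert len(pairs) == 1
        assert pairs[0].source_hit is h2
        assert (pairs[0].gene_a, pairs[0].gene_b) == ("a", "b")

    def test_all_vs_all_pair_count(self):
        # n genes in one family, all ordered hits -> n(n-1)/2 pairs
        n = 6
        genes = [f"g{i}" for i in range(n)]
        fams = {g: "fam" for g in genes}
        hits = [_hit(q, s) for q, s in itertools.permutations(genes, 2)]
        pairs = build_candidate_pairs(hits, fams)
        assert len(pairs) == n * (n - 1) // 2

    def test_missing_family_dropped(self):
        assert build_candidate_pairs([_hit("a", "zzz")], self.FAMS) == []

    def test_order_invariance(self):
        hits = [
            _hit("a", "b", ev=1e-30, bs=100),
            _hit("b", "a", ev=1e-30, bs=200),
            _hit("a", "b", ev=1e-40, bs=50),
        ]
        for perm in itertools.permutations(hits):
            pairs = build_candidate_pairs(list(perm), self.FAMS)
            assert len(pairs) == 1
            assert pairs[0].source_hit.evalue == 1e-40


class TestAlignAllVsAll:
    def test_identical_sequences(self, rng):
        from paleodup._codon import random_cds, translate_indices, cds_to_codon_indices

        seq = translate_indices(cds_to_codon_indices(random_cds(400, rng)))
        hits = align_all_vs_all({"a": seq, "b": seq}, include_self=False)
        assert len(hits) == 2  # both orderings
        h = hits[0]
        assert h.percent_identity == 100.0
        assert h.mismatches == 0
        assert h.alignment_length == 400
        assert h.evalue < 1e-20

    def test_unrelated_sequences_fail_filters(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(list(aas), 400))
        b = "".join(rng.choice(list(aas), 400))
        hits = align_all_vs_all({"a": a, "b": b}, include_self=False)
        assert filter_hits(hits) == []

    def test_empty_input(self):
        assert align_all_vs_all({}) == []

    def test_family_restriction_subset(self, rng):
        from paleodup._codon import random_cds, translate_indices, cds_to_codon_indices

        seqs = {
            f"g{i}": translate_indices(cds_to_codon_indices(random_cds(150, rng)))
            for i in range(4)
        }
        fams = {"g0": "A", "g1": "A", "g2": "B", "g3": "B"}
        full = align_all_vs_all(seqs, include_self=False)
        restricted = align_all_vs_all(seqs, families=fams, include_self=False)
        full_keys = {(h.query, h.subject) for h in full}
        res_keys = {(h.query, h.subject) for h in restricted}
        assert res_keys <= full_keys
        assert res_keys == {("g0", "g1"), ("g1", "g0"), ("g2", "g3"), ("g3", "g2")}

    def test_matches_reference_quadratic_aligner(self, rng):
        """Summaries equal those of an independent O(nm) affine-gap DP."""
        from paleodup.homology import _summarize_alignment

        aas = "ACDEFGHIKLMNPQRSTVWY"
        base = "".join(rng.choice(list(aas), 60))
        # related pair: point changes + a deletion
        other = base[:20] + base[25:50] + "W" + base[51:]
        score = _gotoh_score(base, other)
        h = _summarize_alignment("a", "b", base, other, db_residues=120)
        assert h.bitscore == pytest.approx(
            (0.267 * score - np.log(0.041)) / np.log(2), abs=0.11
        )


def _gotoh_score(a: str, b: str, open_=-11.0, ext=-1.0) -> float:
    """Independent affine-gap global alignment score (Gotoh recursion)."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + ext * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = open_ + ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + ext, Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + ext, X[i, j - 1] + open_)
    return max(M[n, m], X[n, m], Y[n, m])


def test_recall_on_pure_wgd_bundle():
    """Every truth pair whose alignment keeps >= 50% identity (and passes
    the other filters) must appear among candidate pairs."""
    from paleodup.homology import _summarize_alignment
    from paleodup.simulate import SimConfig, WgdEvent, simulate_genome

    cfg = SimConfig(
        n_chromosomes=2,
        n_ancestral_genes=150,
        wgd_events=(WgdEvent(1.0, 0.3, 0.3),),
        tandem_rate=0.0,
        seed=21,
    )
    bundle, truth = simulate_genome(cfg)
    hits = align_all_vs_all(bundle.proteins, families=bundle.families, include_self=False)
    pairs = build_candidate_pairs(filter_hits(hits), bundle.families)
    cand = {(p.gene_a, p.gene_b) for p in pairs}
    db = sum(len(s) for s in bundle.proteins.values())
    missed = []
    for t in truth:
        h = _summarize_alignment(
            t.gene_a, t.gene_b, bundle.proteins[t.gene_a], bundle.proteins[t.gene_b], db
        )
        if filter_hits([h]) and (t.gene_a, t.gene_b) not in cand:
            missed.append(t)
    assert missed == []
    # at Ks ~1 with omega 0.2 nearly all pairs survive the filters
    assert len(cand) >= 0.9 * len(truth)


@given(st.lists(st.tuples(st.floats(0, 100), st.integers(0, 600), st.integers(0, 700), st.integers(0, 50)), max_size=30))
@settings(max_examples=30, deadline=None)
def test_filter_idempotence_property(params):
    hits = [
        _hit("a", "b", pid=p, ln=ln, mm=mm, go=go)
        for p, ln, mm, go in params
    ]
    once = filter_hits(hits)
    assert filter_hits(once) == once
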