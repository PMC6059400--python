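"""UMI grouping and consensus calling."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cfsieve as cf
from cfsieve.consensus import (AlignedRead, ReadFamily, call_consensus,
                               family_size_spectrum, group_families,
                               umi_similarity, unclipped_start)


def mk_read(name="r", start=1000, strand="+", cigar="8M", seq="ACGTACGT",
            qual=30, umi="AACCGGTT", tlen=160, mapq=60, mapped=True):
    return AlignedRead(name, "chr1", start, strand, cigar, seq, qual, umi,
                       tlen, mapq, mapped)


class TestUnclippedStart:
    @pytest.mark.parametrize("cigar,strand,expected", [
        ("125M", "+", 1000),        # POS 1001 1-based, no clipping
        ("5S120M", "+", 995),       # leading clip pushes the key left
        ("120M5S", "-", 1125),      # reverse: unclipped end + trailing clip
        ("3H2S120M", "+", 995),     # hard+soft clips both count
        ("125M", "-", 1125),
    ])
    def test_cigar_walk(self, cigar, strand, expected):
        r = mk_read(start=1000, strand=strand, cigar=cigar, seq="A" * 125)
        assert unclipped_start(r) == expected

    def test_unmapped_read_raises(self):
        with pytest.raises(ValueError):
            unclipped_start(mk_read(mapped=False))


class TestUmiSimilarity:
    def test_identical_tags_are_similarity_one(self):
        assert umi_similarity("AACCGGTT", "AACCGGTT") == 1

    def test_seven_of_eight_is_exactly_the_threshold(self):
        s = umi_similarity("AACCGGTT", "AACCGGTA")
        assert s == Fraction(7, 8)
        assert not s > Fraction("0.875")  # strict '>' keeps them apart

    def test_disjoint_tags_have_zero_similarity(self):
        assert umi_similarity("AACCGGTT", "TTGGCCAA") == 0

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            umi_similarity("AAAA", "AAA")


def brute_force_partition(umis, threshold=Fraction("0.875")):
    """Independent oracle: exhaustive seeded clustering over all pairs.

    Seeds are taken in descending abundance (ties lexicographic); every
    unassigned tag similar to the seed joins its cluster.
    """
    from collections import Counter

    counts = Counter(umis)
    order = sorted(counts, key=lambda u: (-counts[u], u))
    assigned = {}
    clusters = []
    for seed in order:
        if seed in assigned:
            continue
        members = [seed]
        assigned[seed] = len(clusters)
        for u in order:
            if u in assigned:
                continue
            if umi_similarity(u, seed) > threshold:
                assigned[u] = len(clusters)
                members.append(u)
        clusters.append(members)
    return assigned


class TestGroupFamilies:
    def test_identical_umis_form_one_family(self):
        reads = [mk_read(name="a"), mk_read(name="b")]
        fams, _ = group_families(reads)
        assert len(fams) == 1 and fams[0].family_size == 2

    def test_single_read_is_a_family_of_one(self):
        fams, _ = group_families([mk_read()])
        assert len(fams) == 1 and fams[0].family_size == 1

    def test_single_mismatch_umis_stay_apart_on_8bp_tags(self):
        reads = [mk_read(name="a", umi="AACCGGTT"),
                 mk_read(name="b", umi="AACCGGTA")]
        fams, _ = group_families(reads)
        assert len(fams) == 2

    def test_reads_without_umi_or_unmapped_are_counted_out(self):
        reads = [mk_read(), mk_read(name="x", umi=None),
                 mk_read(name="y", mapped=False)]
        fams, excluded = group_families(reads)
        assert sum(f.family_size for f in fams) == 1
        assert excluded["missing_umi"] == 1 and excluded["unmapped"] == 1

    def test_greedy_grouping_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            # small tag alphabet to provoke near-threshold similarities
            pool = ["".join(rng.choice(list("AC"), 8)) for _ in range(6)]
            umis = [pool[i] for i in rng.integers(0, len(pool), n)]
            reads = [mk_read(name=f"r{i}", umi=u) for i, u in enumerate(umis)]
            fams, _ = group_families(reads, similarity_threshold=Fraction(5, 8))
            got = {}
            for fi, fam in enumerate(fams):
                for r in fam.reads:
                    got[r.name] = fi
            expected = brute_force_partition(umis, Fraction(5, 8))
            exp_by_read = {f"r{i}": expected[u] for i, u in enumerate(umis)}
            # same partition up to label renaming
            pairs_got = {(a, b) for a in got for b in got
                         if a < b and got[a] == got[b]}
            pairs_exp = {(a, b) for a in exp_by_read for b in exp_by_read
                         if a < b and exp_by_read[a] == exp_by_read[b]}
            assert pairs_got == pairs_exp

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["AAAAAAAA", "AAAAAAAT", "CCCCCCCC"]),
                              st.integers(0, 3)), min_size=1, max_size=30))
    def test_families_partition_the_reads(self, tagged):
        reads = [mk_read(name=f"r{i}", umi=u, start=1000 + 10 * k)
                 for i, (u, k) in enumerate(tagged)]
        fams, excluded = group_families(reads)
        assert sum(f.family_size for f in fams) + sum(excluded.values()) == len(reads)
        names = [r.name for f in fams for r in f.reads]
        assert len(names) == len(set(names))


def column_family(bases, quals=None, umi="AACCGGTT"):
    quals = quals or [30] * len(bases)
    reads = [mk_read(name=f"r{i}", seq=b, cigar="1M", qual=q)
             for i, (b, q) in enumerate(zip(bases, quals))]
    return ReadFamily(0, "chr1", "+", 1000, umi, reads)


class TestCallConsensus:
    @pytest.mark.parametrize("bases,expected", [
        (list("AAAC"), "A"),   # 3/4 = 0.75 > 0.66
        (list("AAC"), "A"),    # 2/3 > 0.66 by exact rational comparison
        (list("AC"), "N"),     # tie
        (list("AACC"), "N"),   # tie at even depth
        (list("AACCC"), "N"),  # 3/5 = 0.6 not > 0.66
    ])
    def test_concordance_rule(self, bases, expected):
        cons = call_consensus(column_family(bases))
        assert cons.sequence == expected

    def test_singleton_consensus_equals_the_read(self):
        fam = ReadFamily(0, "chr1", "+", 1000, "AACCGGTT",
                         [mk_read(seq="ACGTACGT", cigar="8M")])
        cons = call_consensus(fam)
        assert cons.sequence == "ACGTACGT"
        assert np.allclose(cons.concordance, 1.0)
        assert cons.family_size == 1

    def test_low_quality_bases_do_not_vote(self):
        cons = call_consensus(column_family(list("AAC"), quals=[10, 10, 30]))
        assert cons.sequence == "C"  # only the Q30 base counts

    def test_all_bases_below_quality_yield_n(self):
        cons = call_consensus(column_family(list("AAA"), quals=[10, 10, 10]))
        assert cons.sequence == "N"

    def test_indel_members_are_excluded_but_counted(self):
        reads = [mk_read(name="a", seq="A", cigar="1M"),
                 mk_read(name="b", seq="AG", cigar="1M1I")]
        fam = ReadFamily(0, "chr1", "+", 1000, "AACCGGTT", reads)
        cons = call_consensus(fam)
        assert cons.n_excluded_indel == 1
        assert cons.sequence == "A"

    def test_threshold_decisions_are_exact_on_integer_grids(self):
        # fuzz every (votes, depth) pair up to depth 64 against integer
        # arithmetic: votes/depth > 66/100 iff 100*votes > 66*depth
        for depth in range(1, 65):
            for votes in range(0, depth + 1):
                bases = ["A"] * votes + ["C"] * (depth - votes)
                cons = call_consensus(column_family(bases))
                distinct = votes != depth - votes
                should_call_a = 100 * votes > 66 * depth and distinct
                should_call_c = 100 * (depth - votes) > 66 * depth and distinct
                expected = "A" if should_call_a else ("C" if should_call_c
                                                      else "N")
                assert cons.sequence == expected, (votes, depth)


class TestZeroNoiseClosure:
    def test_every_consensus_reconstructs_its_template(self, noise_free_library):
        frags = {f.umi: f for f in noise_free_library["fragments"]}
        consensuses = noise_free_library["consensuses"]
        assert consensuses
        for c in consensuses:
            f = frags[c.umi]
            off = c.start - f.start
            assert c.sequence == f.template_sequence[off:off + len(c)]
            assert np.allclose(c.concordance, 1.0)


class TestFamilySizeSpectrum:
    def test_counting_by_hand(self):
        spec = family_size_spectrum([1, 1, 5, 20], max_k=20)
        assert spec[0] == 4 and spec[4] == 2 and spec[19] == 1

    def test_empty_input_gives_zeros(self):
        assert family_size_spectrum([], max_k=5).tolist() == [0] * 5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 40), max_size=50))
    def test_spectrum_is_monotone_and_anchored(self, sizes):
        spec = family_size_spectrum(sizes, max_k=40)
        assert (np.diff(spec) <= 0).all()
        assert spec[0] == len(sizes)
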