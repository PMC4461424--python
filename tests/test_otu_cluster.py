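"""Alignment, divergence conventions, greedy clustering and the bimera screen."""

import numpy as np
import pytest

import oracle
from mockotu.demux_filter import FilteredRead, UniqueSequence
from mockotu.otu_cluster import (
    AlignmentResult,
    DivergenceConvention,
    divergence,
    global_align,
    greedy_cluster,
    is_bimera,
    map_reads_to_otus,
    pair_divergence,
    threshold_scan,
    validate_clustering,
)

ALL = DivergenceConvention.ALL_GAPS_COUNTED
INT = DivergenceConvention.INTERNAL_GAPS_ONLY


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate_exact(rng, seq, n_subs):
    """Exactly n_subs substitutions at distinct positions."""
    s = list(seq)
    for p in rng.choice(len(s), size=n_subs, replace=False):
        s[p] = rng.choice([c for c in "ACGT" if c != s[p]])
    return "".join(s)


def _mutate(rng, seq, n_subs=0, indels=()):
    s = list(seq)
    for _ in range(n_subs):
        p = int(rng.integers(0, len(s)))
        s[p] = rng.choice([c for c in "ACGT" if c != s[p]])
    s = "".join(s)
    for L in indels:
        p = int(rng.integers(0, len(s)))
        if rng.random() < 0.5:
            s = s[:p] + _rand_seq(rng, L) + s[p:]
        else:
            s = s[:p] + s[p + L :]
    return s


class TestGlobalAlign:
    def test_identity(self):
        s = "ACGTACGTAC" * 12
        aln = global_align(s, s)
        assert aln == AlignmentResult(120, 120, 0, 0, 0)

    def test_single_substitution(self):
        a = "ACGT" * 100
        b = a[:200] + "T" + a[201:]
        assert a[200] != "T"
        aln = global_align(a, b)
        assert aln.mismatch_columns == 1
        assert aln.total_columns == 400
        assert aln.internal_gap_columns == aln.terminal_gap_columns == 0

    def test_trimmed_internal_deletion_makes_terminal_gap(self, fixtures):
        # a 36-nt internal deletion in a 460-nt template, both trimmed to
        # 400 nt: the alignment carries the indel internally plus a 36-nt
        # terminal overhang, confirmed against the independent DP oracle
        a, b = fixtures["indel36_pair"]
        aln = global_align(a, b)
        assert aln.internal_gap_columns == 36
        assert aln.terminal_gap_columns == 36
        assert aln.mismatch_columns == 0
        assert aln.total_columns == 436
        assert oracle.align_counts(a, b) == (436, 364, 0, 36, 36)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_dp_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        for _ in range(12):
            a = _rand_seq(rng, int(rng.integers(30, 140)))
            b = _mutate(
                rng, a,
                n_subs=int(rng.integers(0, 8)),
                indels=[int(rng.integers(1, 12))
                        for _ in range(int(rng.integers(0, 3)))],
            )
            if not b:
                continue
            aln = global_align(a, b)
            assert oracle.align_counts(a, b) == (
                aln.total_columns, aln.match_columns, aln.mismatch_columns,
                aln.internal_gap_columns, aln.terminal_gap_columns,
            )


class TestDivergence:
    def test_identical_zero_under_both_conventions(self):
        aln = global_align("ACGT" * 50, "ACGT" * 50)
        assert divergence(aln, ALL) == 0.0
        assert divergence(aln, INT) == 0.0

    def test_substitution_fraction(self):
        aln = AlignmentResult(400, 399, 1, 0, 0)
        assert divergence(aln, ALL) == pytest.approx(0.0025)

    def test_terminal_gap_conventions_differ(self, fixtures):
        a, b = fixtures["indel36_pair"]
        aln = global_align(a, b)
        assert divergence(aln, ALL) == pytest.approx(72 / 436)
        assert divergence(aln, INT) == pytest.approx(0.09)

    def test_zero_denominator_rejected(self):
        aln = AlignmentResult(10, 0, 0, 0, 10)
        with pytest.raises(ValueError):
            divergence(aln, INT)


def _uniques(*pairs):
    return [UniqueSequence(s, a) for s, a in pairs]


class TestGreedyCluster:
    def test_identical_sequences_form_one_otu(self):
        s = "ACGT" * 100
        res = greedy_cluster(_uniques((s, 5), (s, 3), (s, 1)), 3)
        # identical uniques collapse trivially; total abundance conserved
        assert res.n_otus == 1
        assert res.otus[0].total_abundance == 9

    def test_threshold_radius_splits_then_merges(self):
        rng = np.random.default_rng(7)
        a = _rand_seq(rng, 400)
        b = _mutate_exact(rng, a, 20)  # 20/400 = 5.0%
        assert pair_divergence(a, b, ALL) == pytest.approx(0.05)
        two = greedy_cluster(_uniques((a, 5), (b, 3)), 3)
        one = greedy_cluster(_uniques((a, 5), (b, 3)), 5)
        assert two.n_otus == 2
        assert one.n_otus == 1  # boundary divergence merges

    def test_empty_input_gives_empty_result(self):
        res = greedy_cluster([], 3)
        assert res.n_otus == 0 and res.input_abundance == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_naive_reference(self, seed):
        rng = np.random.default_rng(500 + seed)
        ancestors = [_rand_seq(rng, 80) for _ in range(3)]
        uniques = []
        for k in range(int(rng.integers(4, 16))):
            anc = ancestors[int(rng.integers(0, 3))]
            seq = _mutate(rng, anc, n_subs=int(rng.integers(0, 6)),
                          indels=[3] if rng.random() < 0.3 else [])
            uniques.append((seq, int(rng.integers(1, 30))))
        t = int(rng.integers(1, 11))
        conv = ALL if seed % 2 else INT
        res = greedy_cluster(_uniques(*uniques), t, convention=conv)
        ref = oracle.naive_cluster(
            uniques, t, "all" if conv is ALL else "internal"
        )
        got = [(o.centroid, [u.sequence for u, _d in o.members])
               for o in res.otus]
        assert got == ref
        validate_clustering(res)

    def test_membership_and_separation_postconditions(self):
        rng = np.random.default_rng(9)
        anc = _rand_seq(rng, 200)
        uniques = [(anc, 50)] + [
            (_mutate(rng, anc, n_subs=int(rng.integers(1, 30))),
             int(rng.integers(1, 20)))
            for _ in range(12)
        ]
        for t in (1, 3, 10):
            validate_clustering(greedy_cluster(_uniques(*uniques), t))


class TestThresholdScan:
    def test_single_unique_one_otu_everywhere(self):
        scan = threshold_scan({"include": _uniques(("ACGT" * 100, 4))})
        assert all(res.n_otus == 1 for res in scan.values())

    def test_nine_percent_pair_splits_until_nine(self, fixtures):
        a, b = fixtures["indel36_pair"]  # 9.0% under INTERNAL_GAPS_ONLY
        scan = threshold_scan({"include": _uniques((a, 5), (b, 3))},
                              convention=INT)
        for t in range(1, 9):
            assert scan[(t, "include")].n_otus == 2
        for t in (9, 10):
            assert scan[(t, "include")].n_otus == 1

    def test_empty_set_zero_otus(self):
        scan = threshold_scan({"include": []})
        assert all(res.n_otus == 0 for res in scan.values())


class TestBimera:
    def _parents(self):
        rng = np.random.default_rng(21)
        p1 = _rand_seq(rng, 400)
        p2 = _mutate_exact(rng, p1, 40)  # 10% mutual divergence
        return p1, p2

    def test_prefix_suffix_join_is_flagged(self):
        p1, p2 = self._parents()
        candidate = p1[:200] + p2[200:]
        flag, parents = is_bimera(candidate, [p1, p2], threshold=3)
        assert flag and parents == (0, 1)

    def test_centroid_copy_not_flagged(self):
        p1, p2 = self._parents()
        flag, _ = is_bimera(p1, [p1, p2], threshold=3)
        assert not flag  # divergence-to-parent condition fails

    def test_requires_two_centroids(self):
        p1, p2 = self._parents()
        assert is_bimera(p1[:200] + p2[200:], [p1], threshold=3) == (False, None)

    def test_greedy_cluster_sets_chimera_aside(self):
        p1, p2 = self._parents()
        candidate = p1[:200] + p2[200:]
        res = greedy_cluster(
            _uniques((p1, 50), (p2, 40), (candidate, 2)), 3,
            chimera_check=True,
        )
        assert res.n_otus == 2
        assert [u.sequence for u in res.chimeras] == [candidate]


class TestMapReads:
    def test_partition_of_reads(self):
        rng = np.random.default_rng(31)
        a = _rand_seq(rng, 400)
        far = _rand_seq(rng, 400)
        near = _mutate(rng, a, n_subs=8)  # 2% from centroid
        uniques = _uniques((a, 4))
        res = greedy_cluster(uniques, 3)
        reads = (
            [FilteredRead(f"r{i}", "s", a, 0.1) for i in range(4)]
            + [FilteredRead("r4", "s", near, 0.1)]  # singleton-excluded
            + [FilteredRead("r5", "s", far, 0.1)]
        )
        counts, unassigned, chimeric = map_reads_to_otus(reads, res)
        assert counts[res.otus[0].otu_id] == 5
        assert unassigned == 1 and chimeric == 0
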