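"""Pairwise identity, greedy clustering, cutoff selection and table stats."""

import numpy as np
import pandas as pd
import pytest

from lignoamp.chimera import UniqueSequence
from lignoamp.cluster import (
    AbundanceTable,
    ClusterCountCurve,
    abundance_concentration,
    build_abundance_table,
    cluster_count_curve,
    cluster_greedy,
    pairwise_identity,
    remove_singletons,
    select_cutoff,
    shared_cluster_stats,
)

from conftest import mutate


def _random_seq(rng, n=100):
    return "".join(rng.choice(list("ACGT"), n))


class TestPairwiseIdentity:
    def test_identical(self):
        rng = np.random.default_rng(0)
        s = _random_seq(rng)
        assert pairwise_identity(s, s) == 1.0

    def test_five_substitutions_in_hundred(self):
        rng = np.random.default_rng(1)
        s = _random_seq(rng)
        assert pairwise_identity(s, mutate(s, [5, 25, 45, 65, 85])) == pytest.approx(0.95)

    def test_terminal_gaps_excluded(self):
        rng = np.random.default_rng(2)
        s = _random_seq(rng)
        assert pairwise_identity(s, s[:90]) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = _random_seq(rng), _random_seq(rng)
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


def _variants(rng, n, diverge_step, length=200):
    base = _random_seq(rng, length)
    out = [base]
    for i in range(1, n):
        positions = list(range(i, length, length // diverge_step))[:diverge_step]
        out.append(mutate(base, positions))
    return out


class TestGreedyClustering:
    def test_identical_sequences_one_cluster(self):
        uniques = [UniqueSequence("ACGT" * 30, 5, "a"), UniqueSequence("ACGT" * 30, 3, "b")]
        assert len(cluster_greedy(uniques, 0.95)) == 1

    def test_cutoff_straddles_divergence(self):
        """Three variants ~10% apart: separate at 95%, merged at 85%."""
        rng = np.random.default_rng(4)
        base = _random_seq(rng, 200)
        positions = list(range(0, 200, 10))
        v1 = mutate(base, positions)  # 20 diffs from base
        v2 = mutate(mutate(base, positions), positions)  # rotated twice: 20 diffs from both
        uniques = [
            UniqueSequence(base, 10, "s"),
            UniqueSequence(v1, 5, "s"),
            UniqueSequence(v2, 2, "s"),
        ]
        # brute-force all-pairs oracle
        seqs = [base, v1, v2]
        identities = [
            pairwise_identity(seqs[i], seqs[j])
            for i in range(3) for j in range(i + 1, 3)
        ]
        assert all(i == pytest.approx(0.90) for i in identities)
        assert len(cluster_greedy(uniques, 0.95)) == 3
        assert len(cluster_greedy(uniques, 0.85)) == 1

    def test_representative_is_most_abundant(self):
        rng = np.random.default_rng(5)
        base = _random_seq(rng, 150)
        near = mutate(base, [7])
        clusters = cluster_greedy(
            [UniqueSequence(base, 9, "s"), UniqueSequence(near, 14, "s")], 0.95
        )
        assert len(clusters) == 1
        assert clusters[0].representative == near

    def test_abundance_conservation_across_cutoffs(self):
        rng = np.random.default_rng(6)
        uniques = [
            UniqueSequence(_random_seq(rng, 120), int(a), "s")
            for a in rng.integers(1, 30, size=15)
        ]
        total = sum(u.abundance for u in uniques)
        for cutoff in (1.0, 0.95, 0.9, 0.8):
            clusters = cluster_greedy(uniques, cutoff)
            assert sum(c.total_abundance for c in clusters) == total

    def test_exact_cutoff_equals_duplicate_groups(self):
        rng = np.random.default_rng(7)
        seqs = [_random_seq(rng, 60) for _ in range(6)]
        uniques = [UniqueSequence(s, 1, "s") for s in seqs] + [
            UniqueSequence(seqs[0], 1, "t")
        ]
        clusters = cluster_greedy(uniques, 1.0)
        assert len(clusters) == len(set(seqs))


class TestCurveAndCutoff:
    def test_all_identical_curve_is_one(self):
        uniques = [UniqueSequence("ACGT" * 40, 3, "s")]
        curve = cluster_count_curve(uniques)
        assert set(curve.counts) == {1}

    def test_flat_region_before_divergence(self):
        rng = np.random.default_rng(8)
        base = _random_seq(rng, 200)
        uniques = [
            UniqueSequence(mutate(base, list(range(i, 200, 10))), 10 - i, "s")
            for i in range(5)
        ]  # pairwise >= 8% divergent
        curve = cluster_count_curve(uniques, d_grid=range(0, 9))
        assert curve.counts[0] == 5
        assert all(c == 5 for c in curve.counts[:7])

    def test_curve_non_increasing(self, gh11_family):
        uniques = [UniqueSequence(v.amplicon, i + 1, "s") for i, v in enumerate(gh11_family.variants)]
        curve = cluster_count_curve(uniques)
        assert all(a >= b for a, b in zip(curve.counts, curve.counts[1:]))

    def test_published_style_curve_selects_three_percent(self):
        curve = ClusterCountCurve(tuple(range(6)), (100, 60, 40, 38, 37, 36))
        selected = select_cutoff(curve, plateau_frac=0.06)
        assert selected.dissimilarity_pct == 3
        assert selected.identity == pytest.approx(0.97)
        assert selected.plateau_found

    def test_constant_curve_selects_first_step(self):
        curve = ClusterCountCurve(tuple(range(4)), (10, 10, 10, 10))
        assert select_cutoff(curve).dissimilarity_pct == 1

    def test_steep_curve_flagged_fallback(self):
        curve = ClusterCountCurve(tuple(range(4)), (100, 80, 60, 40))
        selected = select_cutoff(curve, plateau_frac=0.06)
        assert not selected.plateau_found
        assert selected.dissimilarity_pct == 3

    def test_agrees_with_bruteforce_scan_on_random_curves(self):
        """1000 random monotone curves: selection equals a linear scan of
        the delta sequence."""
        rng = np.random.default_rng(9)
        for _ in range(1000):
            n0 = int(rng.integers(20, 300))
            drops = rng.integers(0, 30, size=15)
            counts = [n0]
            for d in drops:
                counts.append(max(1, counts[-1] - int(d)))
            curve = ClusterCountCurve(tuple(range(16)), tuple(counts))
            selected = select_cutoff(curve, 0.06)
            oracle = next(
                (
                    i for i in range(1, 16)
                    if abs(counts[i] - counts[i - 1]) < 0.06 * counts[0]
                ),
                None,
            )
            if oracle is None:
                assert not selected.plateau_found
            else:
                assert selected.plateau_found
                assert selected.dissimilarity_pct == oracle

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            select_cutoff(ClusterCountCurve((0,), (5,)))


def _table(data, samples=("A", "B")):
    return AbundanceTable(
        pd.DataFrame(data, columns=list(samples),
                     index=[f"c{i}" for i in range(len(data))])
    )


class TestTableOperations:
    def test_singleton_policy(self):
        table = _table([[1, 0], [1, 1], [5, 0], [0, 1]])
        kept = remove_singletons(table)
        # c0 (one read, one sample) and c3 drop; c1 (one read in each of two
        # samples) and c2 (five reads, one sample) are retained
        assert list(kept.counts.index) == ["c1", "c2"]

    def test_shared_stats_disjoint_and_identical(self):
        disjoint = _table([[5, 0], [0, 5]])
        stats = shared_cluster_stats(disjoint, "A", "B")
        assert stats == {"shared_cluster_pct": 0.0, "shared_sequence_pct": 0.0}
        identical = _table([[5, 5], [3, 3]])
        stats = shared_cluster_stats(identical, "A", "B")
        assert stats == {"shared_cluster_pct": 100.0, "shared_sequence_pct": 100.0}

    def test_shared_stats_constructed_example(self):
        # 10 clusters across both samples, 1 shared, holding 30 of 100 reads
        counts = [[15, 15]] + [[10, 0]] * 4 + [[0, 7]] + [[0, 8]] + [[0, 5]] * 3
        table = _table(counts)
        stats = shared_cluster_stats(table, "A", "B")
        assert stats["shared_cluster_pct"] == pytest.approx(10.0)
        assert stats["shared_sequence_pct"] == pytest.approx(30.0)

    def test_concentration_uniform_and_skewed(self):
        uniform = _table([[10] for _ in range(10)], samples=("A",))
        assert abundance_concentration(uniform, 0.75) == pytest.approx(0.8)
        single = _table([[42]], samples=("A",))
        assert abundance_concentration(single) == 1.0
        skewed = _table([[75], [25]], samples=("A",))
        assert abundance_concentration(skewed, 0.75) == pytest.approx(0.5)

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            shared_cluster_stats(_table([[1, 1]]), "A", "Z")

    def test_build_table_from_clusters(self):
        uniques = [
            UniqueSequence("ACGT" * 30, 5, "A"),
            UniqueSequence("ACGT" * 30, 2, "B"),
            UniqueSequence("TTTT" * 30, 1, "B"),
        ]
        clusters = cluster_greedy(uniques, 0.97)
        table = build_abundance_table(clusters)
        assert table.counts.values.sum() == 8
        assert table.s_obs("B") == 2
        assert table.f1("B") == 1
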