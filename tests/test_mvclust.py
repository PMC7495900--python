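"""Clustering core: encoding, assignment, consensus, objectives, moves."""

import numpy as np
import pytest

from cmvmc.amosa import AnnealConfig
from cmvmc.datamodel import Partition
from cmvmc.mvclust import (
    MedoidString,
    ParentSolution,
    agreement_index,
    assign_genes,
    build_consensus,
    evaluate,
    init_solution,
    k_max,
    perturb,
    run_cmvmc,
    xb_index,
)

from .conftest import make_view, random_partition, random_view


def brute_force_ai(p1: Partition, p2: Partition) -> float:
    """Literal double loop over all n^2 ordered pairs of both agreement matrices."""
    n, ag = p1.n, 0
    for i in range(n):
        for j in range(n):
            co1 = p1.labels[i] == p1.labels[j]
            co2 = p2.labels[i] == p2.labels[j]
            ag += int(co1 == co2)
    return (ag + 1) / (n * n - ag + 1)


class TestInitSolution:
    def test_k_bounds_for_n_100(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sol = init_solution(100, rng)
            assert 2 <= sol.string1.K <= 10
            assert 2 <= sol.string2.K <= 10

    def test_n_4_forces_k_2(self):
        sol = init_solution(4, np.random.default_rng(1))
        assert sol.string1.K == sol.string2.K == 2

    def test_n_below_4_rejected(self):
        with pytest.raises(ValueError):
            init_solution(3, np.random.default_rng(0))

    def test_fixed_seed_reproducible(self):
        a = init_solution(50, np.random.default_rng(9))
        b = init_solution(50, np.random.default_rng(9))
        assert a.string1 == b.string1 and a.string2 == b.string2

    def test_string3_starts_null(self):
        sol = init_solution(16, np.random.default_rng(2))
        assert sol.string3 is None and sol.partition3 is None


class TestAssignGenes:
    def test_argmax_assignment(self):
        m = np.eye(3)
        m[2, 0], m[0, 2] = 0.9, 0.9
        m[2, 1], m[1, 2] = 0.1, 0.1
        p = assign_genes(MedoidString((0, 1)), make_view(m))
        assert p.labels[2] == 0

    def test_tie_goes_to_first_listed_medoid(self):
        m = np.eye(3)
        m[2, 0] = m[0, 2] = 0.5
        m[2, 1] = m[1, 2] = 0.5
        p = assign_genes(MedoidString((1, 0)), make_view(m))
        assert p.labels[2] == 0  # cluster 0 is medoid 1's (first in the string)

    def test_six_gene_two_block_example(self):
        # blocks {0,1,2} and {3,4,5}: within 0.8, across 0.2
        m = np.full((6, 6), 0.2)
        m[:3, :3] = 0.8
        m[3:, 3:] = 0.8
        np.fill_diagonal(m, 1.0)
        p = assign_genes(MedoidString((0, 3)), make_view(m))
        np.testing.assert_array_equal(p.labels, [0, 0, 0, 1, 1, 1])

    def test_every_medoid_in_own_cluster_property(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = random_view(12, rng)
            meds = tuple(int(x) for x in rng.choice(12, size=3, replace=False))
            p = assign_genes(MedoidString(meds), v)
            assert p.n == 12
            for k, m in enumerate(meds):
                assert p.labels[m] == k


def _two_block_views(n=6):
    m = np.full((n, n), 0.1)
    h = n // 2
    m[:h, :h] = 0.9
    m[h:, h:] = 0.9
    np.fill_diagonal(m, 1.0)
    return make_view(m), make_view(m.copy())


class TestBuildConsensus:
    def test_identical_partitions_are_identity(self):
        v1, v2 = _two_block_views()
        labels = np.array([0, 0, 0, 1, 1, 1])
        sol = ParentSolution(
            string1=MedoidString((0, 3)),
            string2=MedoidString((0, 3)),
            partition1=Partition(labels=labels.copy()),
            partition2=Partition(labels=labels.copy()),
        )
        _, p3 = build_consensus(sol, v1, v2)
        np.testing.assert_array_equal(
            p3.comembership(), Partition(labels=labels).comembership()
        )

    def test_crossed_example_cores_and_reassignment(self):
        # P1 = {0,1,2},{3,4,5}; P2 = {0,1,3},{2,4,5}
        # matched pairs (0,0) and (1,1); cores {0,1} and {4,5};
        # genes 2, 3 placed by maximum average combined similarity
        v1, v2 = _two_block_views()
        sol = ParentSolution(
            string1=MedoidString((0, 3)),
            string2=MedoidString((0, 4)),
            partition1=Partition(labels=np.array([0, 0, 0, 1, 1, 1])),
            partition2=Partition(labels=np.array([0, 0, 1, 0, 1, 1])),
        )
        ms, p3 = build_consensus(sol, v1, v2)
        assert p3.K == 2
        np.testing.assert_array_equal(p3.labels, [0, 0, 0, 1, 1, 1])
        assert ms.medoids == (0, 4)  # central gene of each core, lowest-index ties

    def test_single_matched_pair_falls_back_to_lower_xb_string(self):
        # P1 = {0,1},{2}; P2 = {0,2},{1}: only one nonzero matched pair
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.9
        v = make_view(m)
        sol = ParentSolution(
            string1=MedoidString((0, 2)),
            string2=MedoidString((0, 1)),
            partition1=Partition(labels=np.array([0, 0, 1])),
            partition2=Partition(labels=np.array([0, 1, 0])),
        )
        ms, p3 = build_consensus(sol, v, v)
        xb1 = xb_index(sol.partition1, sol.string1, v)
        xb2 = xb_index(sol.partition2, sol.string2, v)
        expected = sol.partition1 if xb1 <= xb2 else sol.partition2
        np.testing.assert_array_equal(p3.labels, expected.labels)


class TestXbIndex:
    def test_zero_numerator(self):
        # every gene coincides with its medoid: within-cluster d = 0
        m = np.full((4, 4), 0.0)
        m[0, 1] = m[1, 0] = 1.0
        m[2, 3] = m[3, 2] = 1.0
        np.fill_diagonal(m, 1.0)
        v = make_view(m)
        p = Partition(labels=np.array([0, 0, 1, 1]))
        assert xb_index(p, MedoidString((0, 2)), v) == 0.0

    def test_hand_arithmetic_four_genes(self):
        # within-medoid dissimilarities {0, 0.1, 0, 0.1}; medoid separation 1
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 0.9
        m[2, 3] = m[3, 2] = 0.9
        np.fill_diagonal(m, 1.0)
        v = make_view(m)
        p = Partition(labels=np.array([0, 0, 1, 1]))
        assert xb_index(p, MedoidString((0, 2)), v) == pytest.approx(0.005)

    def test_coincident_medoids_hit_sentinel(self):
        m = np.full((4, 4), 1.0)
        v = make_view(m)
        p = Partition(labels=np.array([0, 0, 1, 1]))
        assert xb_index(p, MedoidString((0, 2)), v) == np.inf

    def test_scale_consistency(self):
        # scaling all dissimilarities by c > 0 cancels in the ratio
        rng = np.random.default_rng(8)
        d = rng.uniform(0.2, 1.0, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        c = 0.5
        v_full = make_view(1 - d)
        v_half = make_view(1 - c * d)
        ms = MedoidString((0, 3))
        p = assign_genes(ms, v_full)
        assert xb_index(p, ms, v_full) == pytest.approx(
            xb_index(p, ms, v_half), rel=1e-12
        )

    def test_k_below_2_rejected(self):
        v = make_view(np.eye(3))
        with pytest.raises(ValueError):
            xb_index(Partition(labels=np.zeros(3, dtype=int)),
                     MedoidString((0, 1)), v)


class TestAgreementIndex:
    def test_identical_partitions_reach_maximum(self):
        p = Partition(labels=np.array([0, 1, 2]))
        assert agreement_index(p, p) == pytest.approx(10.0)  # n^2 + 1

    def test_crossed_four_element_example(self):
        p1 = Partition(labels=np.array([0, 0, 1, 1]))
        p2 = Partition(labels=np.array([0, 1, 0, 1]))
        assert agreement_index(p1, p2) == pytest.approx(1.0)  # AG = DG = 8

    def test_singletons_vs_lump(self):
        p1 = Partition(labels=np.array([0, 1, 2]))
        p2 = Partition(labels=np.array([0, 0, 0]))
        assert agreement_index(p1, p2) == pytest.approx(4 / 7)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            p1 = random_partition(n, int(rng.integers(2, n // 2 + 1)), rng)
            p2 = random_partition(n, int(rng.integers(2, n // 2 + 1)), rng)
            assert agreement_index(p1, p2) == pytest.approx(
                brute_force_ai(p1, p2), abs=0
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agreement_index(
                Partition(labels=np.array([0, 1])),
                Partition(labels=np.array([0, 1, 1])),
            )


class TestEvaluate:
    def test_vector_matches_componentwise_calls(self):
        rng = np.random.default_rng(3)
        v1, v2 = random_view(10, rng), random_view(10, rng)
        sol = init_solution(10, rng)
        ov = evaluate(sol, v1, v2)
        assert ov.values[0] == xb_index(sol.partition1, sol.string1, v1)
        assert ov.values[1] == xb_index(sol.partition2, sol.string2, v2)
        assert ov.values[2] == agreement_index(sol.partition1, sol.partition2)
        assert ov.directions == ("min", "min", "max")

    def test_consensus_refreshed_as_side_effect(self):
        rng = np.random.default_rng(6)
        v1, v2 = random_view(9, rng), random_view(9, rng)
        sol = init_solution(9, rng)
        evaluate(sol, v1, v2)
        assert sol.string3 is not None and sol.partition3 is not None

    def test_identical_views_and_strings_give_equal_xb_and_max_ai(self):
        v1, v2 = _two_block_views(8)
        ms = MedoidString((0, 4))
        sol = ParentSolution(string1=ms, string2=ms)
        ov = evaluate(sol, v1, v2)
        assert ov.values[0] == ov.values[1]
        assert ov.values[2] == pytest.approx(8 * 8 + 1)


class TestPerturb:
    @pytest.mark.parametrize("strings", ["single", "both"])
    def test_k_never_leaves_bounds(self, strings):
        rng = np.random.default_rng(0)
        n = 50
        sol = init_solution(n, rng)
        for _ in range(2000):
            sol = perturb(sol, n, rng, strings=strings)
            for ms in (sol.string1, sol.string2):
                assert 2 <= ms.K <= k_max(n)
                assert len(set(ms.medoids)) == ms.K

    def test_single_mode_changes_exactly_one_string(self):
        rng = np.random.default_rng(5)
        sol = init_solution(30, rng)
        for _ in range(100):
            new = perturb(sol, 30, rng)
            assert (new.string1 == sol.string1) != (new.string2 == sol.string2)
            sol = new

    def test_add_redrawn_at_upper_bound(self):
        rng = np.random.default_rng(1)
        n = 16  # k_max = 4
        ms = MedoidString((0, 1, 2, 3))
        sol = ParentSolution(string1=ms, string2=ms)
        for _ in range(200):
            new = perturb(sol, n, rng)
            assert new.string1.K <= 4 and new.string2.K <= 4

    def test_delete_redrawn_at_lower_bound(self):
        rng = np.random.default_rng(2)
        ms = MedoidString((0, 1))
        sol = ParentSolution(string1=ms, string2=ms)
        for _ in range(200):
            new = perturb(sol, 16, rng)
            assert new.string1.K >= 2 and new.string2.K >= 2


SMALL_CFG = AnnealConfig(tmax=10, tmin=0.05, iters_per_temp=10)


class TestRunCmvmc:
    def test_unaligned_views_rejected(self):
        va = make_view(np.eye(4), ["a", "b", "c", "d"])
        vb = make_view(np.eye(4), ["a", "b", "c", "e"])
        with pytest.raises(ValueError, match="align"):
            run_cmvmc(va, vb)

    def test_fixed_seed_identical_archive(self):
        rng = np.random.default_rng(5)
        v1, v2 = random_view(20, rng), random_view(20, rng)
        a = run_cmvmc(v1, v2, SMALL_CFG, np.random.default_rng(3))
        b = run_cmvmc(v1, v2, SMALL_CFG, np.random.default_rng(3))
        assert [m.objectives.values for m in a.members] == [
            m.objectives.values for m in b.members
        ]

    def test_identical_views_give_equal_xb_when_strings_coincide(self):
        v1, _ = _two_block_views(16)
        v2 = make_view(v1.matrix.copy())
        archive = run_cmvmc(v1, v2, SMALL_CFG, np.random.default_rng(11))
        for sol in archive.solutions():
            if sol.string1 == sol.string2:
                assert sol.objectives.values[0] == sol.objectives.values[1]
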