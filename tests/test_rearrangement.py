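"""Breakpoint and inversion distances, scenarios, encoding, inversions."""

import numpy as np
import pytest

from plastevo.rearrangement import (
    SignedPermutation,
    apply_inversion,
    apply_reversals,
    breakpoint_distance,
    encode_lcb_permutations,
    inversion_distance,
    inversion_distance_bfs,
    pairwise_distance_matrix,
    read_permutations_tsv,
    sorting_scenario,
    write_permutations_tsv,
)


def perm(blocks, taxon="p", frame="f"):
    return SignedPermutation(taxon, tuple(blocks), frame)


IDENT3 = perm([1, 2, 3], "id3")
IDENT20 = perm(range(1, 21), "id20")


class TestDistanceProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        order=st.permutations(list(range(1, 7))),
        signs=st.lists(st.sampled_from([-1, 1]), min_size=6, max_size=6),
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_distance_axioms_property(self, order, signs):
        p = perm([o * s for o, s in zip(order, signs)])
        ident = perm(range(1, 7), "id")
        for d in (inversion_distance, breakpoint_distance):
            assert d(p, ident) == d(ident, p)
            assert d(p, p) == 0
            assert (d(p, ident) == 0) == (p.blocks == ident.blocks)


class TestBreakpointDistance:
    def test_identical_zero(self):
        assert breakpoint_distance(IDENT20, perm(range(1, 21), "q")) == 0

    def test_single_sign_flip(self):
        # capped adjacencies of (+1,-2,+3): (1,-2) and (-2,3) are both broken
        assert breakpoint_distance(perm([1, -2, 3]), IDENT3) == 2

    def test_symmetric(self, rng):
        for _ in range(50):
            p = perm(rng.permutation(8) + 1)
            q = perm((rng.permutation(8) + 1) * rng.choice([-1, 1], 8), "q")
            assert breakpoint_distance(p, q) == breakpoint_distance(q, p)

    def test_frame_mismatch_errors(self):
        with pytest.raises(ValueError, match="frame"):
            breakpoint_distance(perm([1, 2]), perm([1, 2], frame="other"))


class TestInversionDistance:
    def test_identity_zero(self):
        assert inversion_distance(IDENT20, perm(range(1, 21), "q")) == 0

    def test_single_negation_is_one(self):
        assert inversion_distance(perm([-1]), perm([1], "q")) == 1

    def test_classic_hurdle(self):
        # (+2,+1) is the smallest unoriented hurdle: d = (n+1) - c + h = 3
        p, q = perm([2, 1]), perm([1, 2], "q")
        assert inversion_distance_bfs(p, q) == 3
        assert inversion_distance(p, q) == 3

    def test_nested_hurdle_pattern(self):
        p, q = perm([3, 2, 1]), perm([1, 2, 3], "q")
        assert inversion_distance(p, q) == inversion_distance_bfs(p, q)

    @pytest.mark.parametrize("n", [3, 4])
    def test_exhaustive_small(self, n):
        from itertools import permutations, product

        ident = perm(range(1, n + 1), "id")
        for order in permutations(range(1, n + 1)):
            for signs in product([-1, 1], repeat=n):
                p = perm([o * s for o, s in zip(order, signs)])
                assert inversion_distance(p, ident) == inversion_distance_bfs(p, ident)

    def test_lower_bound_half_breakpoints(self, rng):
        for _ in range(200):
            p = perm((rng.permutation(9) + 1) * rng.choice([-1, 1], 9))
            q = perm((rng.permutation(9) + 1) * rng.choice([-1, 1], 9), "q")
            assert inversion_distance(p, q) >= breakpoint_distance(p, q) / 2

    def test_metric_axioms_random_triples(self, rng):
        for _ in range(100):
            ps = [
                perm((rng.permutation(8) + 1) * rng.choice([-1, 1], 8), str(i))
                for i in range(3)
            ]
            for d in (inversion_distance, breakpoint_distance):
                d01, d02, d12 = d(ps[0], ps[1]), d(ps[0], ps[2]), d(ps[1], ps[2])
                assert d01 >= 0
                assert d01 <= d02 + d12
                assert (d01 == 0) == (ps[0].blocks == ps[1].blocks)

    def test_bfs_limit_errors(self):
        with pytest.raises(RuntimeError, match="limit"):
            inversion_distance_bfs(perm([3, 2, 1]), perm([1, 2, 3], "q"), limit=1)


class TestSortingScenario:
    def test_identity_empty(self):
        assert sorting_scenario(IDENT3, perm([1, 2, 3], "q")) == []

    def test_single_flip(self):
        assert sorting_scenario(perm([1, -2, 3]), IDENT3) == [(1, 1)]

    @pytest.mark.parametrize("seed", range(40))
    def test_replay_reaches_target(self, seed):
        rng = np.random.default_rng(seed)
        p = perm((rng.permutation(10) + 1) * rng.choice([-1, 1], 10))
        q = perm((rng.permutation(10) + 1) * rng.choice([-1, 1], 10), "q")
        scenario = sorting_scenario(p, q)
        assert len(scenario) == inversion_distance(p, q)
        # replaying on p must produce exactly q
        assert apply_reversals(p, scenario).blocks == q.blocks

    def test_deterministic(self):
        p = perm([3, -1, 2, 5, -4])
        q = perm([1, 2, 3, 4, 5], "q")
        assert sorting_scenario(p, q) == sorting_scenario(p, q)


class TestDistanceTable:
    def test_identical_permutations_zero_matrix(self):
        perms = [perm(range(1, 21), t) for t in "abcde"]
        table = pairwise_distance_matrix(perms)
        assert not table.bp.any() and not table.iv.any()

    def test_duplicate_taxa_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            pairwise_distance_matrix([perm([1, 2], "a"), perm([1, 2], "a")])

    def test_simulated_family_symmetry(self, rng):
        from plastevo.simulate import simulate_inversion_history

        start = perm(range(1, 15), "anc")
        perms = []
        for i in range(5):
            h = simulate_inversion_history(start, k=int(rng.integers(0, 4)), seed=i)
            perms.append(SignedPermutation(f"t{i}", h.end_perm.blocks, start.frame))
        table = pairwise_distance_matrix(perms)
        assert np.array_equal(table.bp, table.bp.T)
        assert not np.diag(table.bp).any() and not np.diag(table.iv).any()

    def test_tsv_layout(self):
        table = pairwise_distance_matrix([perm([1, 2], "a"), perm([-2, -1], "b")])
        tsv = table.to_tsv()
        assert tsv.splitlines()[2].startswith("b\t")
        assert "/" in tsv.splitlines()[2].split("\t")[1]

    def test_permutation_tsv_round_trip(self, tmp_path):
        perms = [perm([1, -3, 2], "a"), perm([2, 1, 3], "b")]
        path = tmp_path / "perms.tsv"
        write_permutations_tsv(perms, path)
        back = read_permutations_tsv(path)
        assert [(p.taxon, p.blocks, p.frame) for p in back] == [
            (p.taxon, p.blocks, p.frame) for p in perms
        ]


class TestEncode:
    def test_identical_records_single_block(self, fig5):
        from plastevo.simulate import ArchitectureSpec, RepeatSpec, simulate_architecture

        a = simulate_architecture(
            ArchitectureSpec(
                big_repeat=RepeatSpec(500, "direct"), lsc_bp=3000, ssc_bp=3000,
                n_genes=15, seed=2,
            )
        )
        b = a.copy()
        b.id = "other"
        pa, pb = encode_lcb_permutations(a, b)
        assert pa.blocks == (1,) and pb.blocks == (1,)

    def test_three_block_reversal(self):
        from plastevo.genome import Feature, GenomeRecord

        def rec(rid, order):
            feats = [
                Feature(f"{g}", "gene", i * 100, i * 100 + 50, s, {"gene": g})
                for i, (g, s) in enumerate(order)
            ]
            return GenomeRecord(rid, "A" * (len(order) * 100), "circular", feats)

        a = rec("a", [("g1", "+"), ("g2", "+"), ("g3", "+"), ("g4", "+"), ("g5", "+")])
        # reverse genes 3..4 with strands flipped -> middle block negated
        b = rec("b", [("g1", "+"), ("g2", "+"), ("g4", "-"), ("g3", "-"), ("g5", "+")])
        pa, pb = encode_lcb_permutations(a, b)
        assert pa.blocks == (1, 2, 3)
        assert pb.blocks == (1, -2, 3)

    def test_too_few_shared_genes_errors(self):
        from plastevo.genome import Feature, GenomeRecord

        a = GenomeRecord("a", "A" * 200, "circular", [Feature("g1", "gene", 0, 50, "+", {"gene": "g1"})])
        b = GenomeRecord("b", "A" * 200, "circular", [Feature("g2", "gene", 0, 50, "+", {"gene": "g2"})])
        with pytest.raises(ValueError, match="share"):
            encode_lcb_permutations(a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_simulated_history_bounds_encoded_distance(self, seed):
        from plastevo.genome import Feature, GenomeRecord
        from plastevo.rearrangement import _reversal

        rng = np.random.default_rng(seed)
        n = 20
        a_feats = [
            Feature(f"g{i}", "gene", i * 100, i * 100 + 60, "+", {"gene": f"g{i}"})
            for i in range(n)
        ]
        a = GenomeRecord("a", "A" * (n * 100), "circular", a_feats)
        order = tuple(range(1, n + 1))
        for _ in range(2):
            i, j = sorted(rng.integers(0, n, size=2))
            order = _reversal(order, int(i), int(j))
        b_feats = []
        for pos, signed in enumerate(order):
            g = f"g{abs(signed) - 1}"
            strand = "+" if signed > 0 else "-"
            b_feats.append(
                Feature(g, "gene", pos * 100, pos * 100 + 60, strand, {"gene": g})
            )
        b = GenomeRecord("b", "A" * (n * 100), "circular", b_feats)
        pa, pb = encode_lcb_permutations(a, b)
        assert inversion_distance(pa, pb) <= 2


class TestApplyInversion:
    def test_involution(self, fig5):
        rec = fig5["DR_only"]
        twice = apply_inversion(apply_inversion(rec, (100, 2000)), (100, 2000))
        assert twice.sequence == rec.sequence

    def test_bisecting_endpoint_errors(self, fig5):
        rec = fig5["DR_only"]
        copy = rec.features_of_kind("repeat_copy")[0]
        with pytest.raises(ValueError, match="bisects"):
            apply_inversion(rec, (copy.start + 10, copy.end + 10))

    def test_spanning_one_big_copy_flips_classification(self, fig5):
        from plastevo.recombination import classify_master_structure

        for name, expected in [("DR_only", "IR"), ("IRDR_uncinata", "DR")]:
            rec = fig5[name]
            copy = [
                f
                for f in rec.features_of_kind("repeat_copy")
                if f.attributes["pair_id"] == "big"
            ][0]
            flipped = apply_inversion(rec, (copy.start, copy.end))
            assert classify_master_structure(flipped) == expected
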