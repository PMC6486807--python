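"""The recombination state-graph model: flips, splits, closure, classes."""

import numpy as np
import pytest

from plastevo.recombination import (
    MoleculeForm,
    classify_dynamic,
    classify_master_structure,
    enumerate_forms,
    flip,
    master_form_from_record,
    split,
    stoichiometry,
)


def form(*segs):
    return MoleculeForm(tuple(segs))


# token-level master analogues of the three reference architectures
MASTER_5A = form(("R:big", 1), ("A1", 1), ("R:small", 1), ("A2", 1),
                 ("R:big", -1), ("A3", 1), ("R:small", -1), ("A4", 1))
MASTER_5B = form(("R:big", 1), ("A1", 1), ("R:small", 1), ("A2", 1),
                 ("R:big", 1), ("A3", 1), ("R:small", -1), ("A4", 1))
MASTER_5C = form(("R:big", 1), ("A1", 1), ("R:big", 1), ("A2", 1))
MASTER_IR_ONLY = form(("R:big", 1), ("A1", 1), ("R:big", -1), ("A2", 1))


class TestCanonicalKey:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    segments = st.lists(
        st.tuples(st.sampled_from(["R:a", "R:b", "S1", "S2", "S3"]), st.sampled_from([-1, 1])),
        min_size=1,
        max_size=8,
    )

    @given(segs=segments, rotation=st.integers(0, 7))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_canonical_key_invariance_property(self, segs, rotation):
        segs = tuple(segs)
        f0 = MoleculeForm(segs)
        r = rotation % len(segs)
        rotated = MoleculeForm(segs[r:] + segs[:r])
        reflected = MoleculeForm(tuple((s, -o) for s, o in reversed(segs)))
        assert rotated.canonical_key == f0.canonical_key
        assert reflected.canonical_key == f0.canonical_key

    @pytest.mark.parametrize("seed", range(30))
    def test_rotation_and_reflection_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        segs = tuple(
            (f"S{i}", int(rng.choice([-1, 1]))) for i in range(n)
        )
        f0 = MoleculeForm(segs)
        r = int(rng.integers(n))
        rotated = MoleculeForm(segs[r:] + segs[:r])
        reflected = MoleculeForm(tuple((s, -o) for s, o in reversed(segs)))
        assert rotated.canonical_key == f0.canonical_key
        assert reflected.canonical_key == f0.canonical_key

    def test_distinct_forms_distinct_keys(self):
        a = form(("X", 1), ("Y", 1))
        b = form(("X", 1), ("Z", 1))
        assert a.canonical_key != b.canonical_key


class TestFlip:
    def test_involution(self):
        once = flip(MASTER_5A, "R:big")
        assert flip(once, "R:big").canonical_key == MASTER_5A.canonical_key

    def test_flip_at_big_makes_small_direct(self):
        # flipping the arc between the large inverted copies reverses the
        # single-copy region holding one small copy: the small pair goes direct
        iso1 = flip(MASTER_5A, "R:big")
        assert iso1.pair_orientation("R:small") == "direct"
        assert iso1.pair_orientation("R:big") == "inverted"

    def test_flip_at_small_makes_big_direct(self):
        iso2 = flip(MASTER_5A, "R:small")
        assert iso2.pair_orientation("R:big") == "direct"
        assert iso2.pair_orientation("R:small") == "inverted"

    def test_flip_on_direct_pair_errors(self):
        with pytest.raises(ValueError, match="not inverted"):
            flip(MASTER_5C, "R:big")

    def test_either_arc_same_canonical_form(self):
        # flipping the complementary arc = flipping arc + whole-circle
        # reflection; canonical keys must coincide
        i, j = MASTER_5A.pair_positions("R:big")
        segs = MASTER_5A.segments
        other_arc = tuple((s, -o) for s, o in reversed(segs[j + 1 :] + segs[:i]))
        manual = MoleculeForm(segs[i : j + 1] + other_arc)
        assert manual.canonical_key == flip(MASTER_5A, "R:big").canonical_key


class TestSplit:
    def test_two_children_with_one_copy_each(self):
        c1, c2 = split(MASTER_5C, "R:big")
        for c in (c1, c2):
            assert c.kind == "subgenomic"
            assert sum(1 for s, _ in c.segments if s == "R:big") == 1

    def test_segment_conservation(self):
        c1, c2 = split(MASTER_5C, "R:big")
        combined = c1.segment_multiset() + c2.segment_multiset()
        assert combined == MASTER_5C.segment_multiset()

    def test_split_on_inverted_pair_errors(self):
        with pytest.raises(ValueError, match="not direct"):
            split(MASTER_5A, "R:big")

    def test_split_products_terminal(self):
        for child in split(flip(MASTER_5A, "R:big"), "R:small"):
            g = enumerate_forms(child, big_pair_id="R:big")
            assert len(g.forms) == 1  # no applicable events


class TestEnumerate:
    def test_dr_only_counts(self):
        g = enumerate_forms(MASTER_5C, big_pair_id="R:big")
        assert len(g.full_length_forms()) == 1
        assert len(g.subgenomic_forms()) == 2

    def test_ir_only_counts(self):
        g = enumerate_forms(MASTER_IR_ONLY, big_pair_id="R:big")
        assert len(g.full_length_forms()) == 2
        assert len(g.subgenomic_forms()) == 0

    def test_fig5a_three_isomers(self):
        g = enumerate_forms(MASTER_5A, big_pair_id="R:big")
        assert len(g.full_length_forms()) == 3

    def test_fig5b_three_isomers(self):
        g = enumerate_forms(MASTER_5B, big_pair_id="R:big")
        assert len(g.full_length_forms()) == 3

    def test_enumeration_rotation_independent(self):
        segs = MASTER_5A.segments
        for r in range(len(segs)):
            g = enumerate_forms(MoleculeForm(segs[r:] + segs[:r]), big_pair_id="R:big")
            ref = enumerate_forms(MASTER_5A, big_pair_id="R:big")
            assert set(g.forms) == set(ref.forms)

    def test_closure_start_independent(self):
        # starting the closure from any reachable full-length form yields the
        # same set of forms (event application order cannot matter)
        ref = enumerate_forms(MASTER_5A, big_pair_id="R:big")
        for f in ref.full_length_forms():
            g = enumerate_forms(f, big_pair_id="R:big")
            assert set(g.forms) == set(ref.forms)

    def test_from_genome_record(self, fig5):
        g = enumerate_forms(fig5["IRDR_uncinata"])
        assert len(g.full_length_forms()) == 3
        assert classify_dynamic(g) == "IRDR_coexisting"


class TestClassification:
    def test_master_structure(self, fig5):
        assert classify_master_structure(fig5["DR_only"]) == "DR"
        assert classify_master_structure(fig5["IRDR_uncinata"]) == "IR"
        assert classify_master_structure(fig5["DRIR_bisulcata"]) == "DR"

    def test_dynamic_classes(self):
        assert classify_dynamic(enumerate_forms(MASTER_5A, big_pair_id="R:big")) == "IRDR_coexisting"
        assert classify_dynamic(enumerate_forms(MASTER_5B, big_pair_id="R:big")) == "IRDR_coexisting"
        assert classify_dynamic(enumerate_forms(MASTER_5C, big_pair_id="R:big")) == "DR_only"
        assert classify_dynamic(enumerate_forms(MASTER_IR_ONLY, big_pair_id="R:big")) == "IR_only"

    def test_dr_ir_correspondence_under_spanning_inversion(self, fig5):
        # inverting across exactly one big copy maps the DR-master graph onto
        # an IR-master graph over the same segment set
        from plastevo.rearrangement import apply_inversion

        rec = fig5["DR_only"]
        copy = [
            f for f in rec.features_of_kind("repeat_copy")
            if f.attributes["pair_id"] == "big"
        ][0]
        flipped = apply_inversion(rec, (copy.start, copy.end))
        g = enumerate_forms(flipped)
        assert classify_dynamic(g) == "IR_only"
        assert len(g.full_length_forms()) == 2


class TestStoichiometry:
    def test_uniform_over_isomers(self):
        st = stoichiometry(enumerate_forms(MASTER_5A, big_pair_id="R:big"))
        assert len(st) == 3
        assert all(v == pytest.approx(1 / 3) for v in st.values())

    def test_single_master(self):
        st = stoichiometry(enumerate_forms(MASTER_5C, big_pair_id="R:big"))
        assert list(st.values()) == [1.0]

    @pytest.mark.parametrize("master", [MASTER_5A, MASTER_5B, MASTER_IR_ONLY])
    def test_sums_to_one(self, master):
        assert sum(stoichiometry(enumerate_forms(master, big_pair_id="R:big")).values()) == pytest.approx(1.0)


class TestRandomArchitectures:
    """Flip involution and split conservation over randomized token masters."""

    @staticmethod
    def random_master(rng):
        n_pairs = int(rng.integers(1, 4))
        tokens = []
        arc = 0
        for p in range(n_pairs):
            tokens += [(f"R:p{p}", 1), (f"R:p{p}", int(rng.choice([-1, 1])))]
        rng.shuffle(tokens)
        segs = []
        for tok in tokens:
            segs.append(tuple(tok))
            arc += 1
            segs.append((f"A{arc}", int(rng.choice([-1, 1]))))
        return MoleculeForm(tuple(segs))

    @pytest.mark.parametrize("seed", range(60))
    def test_invariants(self, seed):
        rng = np.random.default_rng(seed)
        master = self.random_master(rng)
        g = enumerate_forms(master, big_pair_id="R:p0")
        assert master.canonical_key in g.forms
        for f in g.full_length_forms():
            for s, _ in f.segments:
                if not s.startswith("R:"):
                    continue
                if f.pair_positions(s) != sorted(set(f.pair_positions(s))) or len(f.pair_positions(s)) != 2:
                    continue
                if f.pair_orientation(s) == "inverted":
                    assert flip(flip(f, s), s).canonical_key == f.canonical_key
                else:
                    c1, c2 = split(f, s)
                    assert c1.segment_multiset() + c2.segment_multiset() == f.segment_multiset()
        # closure is start-independent
        for f in g.full_length_forms():
            assert set(enumerate_forms(f, big_pair_id="R:p0").forms) == set(g.forms)
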