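"""Signed circular permutations, adjacency conservation, breakpoint distance."""

import numpy as np
import pytest

from plastocomp.genome_io import reflect_genome, rotate_genome
from plastocomp.synteny import (SignedPermutation, canonicalize,
                                collinear_blocks, compare_order,
                                compare_permutations, pairwise_matrix,
                                random_signed_permutation,
                                to_signed_permutation)


def _perm(spec, genome_id="p"):
    return SignedPermutation(genome_id, [(n, s) for n, s in spec])


def _brute_breakpoints(pa, pb):
    """Oracle: explicit enumeration of unordered adjacent pairs on both
    circles."""
    def pairs(p):
        n = len(p.order)
        return {frozenset((p.order[i][0], p.order[(i + 1) % n][0]))
                for i in range(n)}

    return len(pa.order) - len(pairs(pa) & pairs(pb))


CDS = "ATG" + "GGTACT" * 30 + "TAA"


def test_permutation_order_and_signs(build_genome):
    g = build_genome([
        ("a", "protein", "other_conserved", 1, CDS),
        ("b", "protein", "other_conserved", 1, CDS),
        ("c", "protein", "other_conserved", -1, CDS),
    ])
    p = to_signed_permutation(g, {"a", "b", "c"})
    assert p.order == [("a", 1), ("b", 1), ("c", -1)]


def test_rotation_gives_cyclic_rotation(build_genome):
    g = build_genome([(n, "protein", "other_conserved", 1, CDS)
                      for n in "abcd"])
    p0 = to_signed_permutation(g, set("abcd"))
    rotated = rotate_genome(g, g.features[2].start - 5)
    p1 = to_signed_permutation(rotated, set("abcd"))
    doubled = p0.order * 2
    i = doubled.index(p1.order[0])
    assert doubled[i: i + 4] == p1.order


def test_reflection_reverses_and_flips(build_genome):
    g = build_genome([("a", "protein", "other_conserved", 1, CDS),
                      ("b", "protein", "other_conserved", -1, CDS),
                      ("c", "protein", "other_conserved", 1, CDS)])
    p = to_signed_permutation(reflect_genome(g), {"a", "b", "c"})
    assert p.order == [("c", -1), ("b", 1), ("a", -1)]


def test_canonicalize_identity_and_idempotence():
    p = _perm([("x", 1), ("y", -1), ("z", 1)])
    assert canonicalize(p, "x").order == p.order
    once = canonicalize(p, "y", reflect=True)
    assert canonicalize(once, "y").order == once.order
    with pytest.raises(KeyError):
        canonicalize(p, "missing")


@pytest.mark.parametrize("seed", range(5))
def test_canonicalization_does_not_change_synteny(seed):
    rng = np.random.default_rng(seed)
    pa = random_signed_permutation(12, rng, "A")
    pb = random_signed_permutation(12, rng, "B")
    base = compare_permutations(pa, pb)
    anchor = pa.names()[int(rng.integers(12))]
    for reflect in (False, True):
        canon = canonicalize(pa, anchor, reflect)
        res = compare_permutations(canon, pb)
        assert res.conserved_adjacencies == base.conserved_adjacencies
        assert res.breakpoint_distance == base.breakpoint_distance


def test_identical_circles_are_fully_collinear():
    p = _perm([("a", 1), ("b", -1), ("c", 1), ("d", 1), ("e", -1)])
    res = compare_permutations(p, _perm(p.order, "q"))
    assert res.adjacency_fraction == 1.0
    assert res.breakpoint_distance == 0
    assert res.n_blocks == 1
    assert res.oriented_adjacencies == res.n_shared


def test_inverted_segment_costs_two_breakpoints():
    a = _perm([(n, 1) for n in "abcdefg"], "A")
    b = _perm([("a", 1), ("b", 1), ("e", -1), ("d", -1), ("c", -1),
               ("f", 1), ("g", 1)], "B")
    res = compare_permutations(a, b)
    assert res.breakpoint_distance == 2 == _brute_breakpoints(a, b)
    assert res.n_blocks == 2
    blocks = collinear_blocks(a, b)
    assert sorted(map(len, blocks)) == [3, 4]


@pytest.mark.parametrize("seed", range(8))
def test_breakpoint_distance_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    a = random_signed_permutation(15, rng, "A")
    b = random_signed_permutation(15, rng, "B")
    res = compare_permutations(a, b)
    assert res.breakpoint_distance == _brute_breakpoints(a, b)
    assert res.breakpoint_distance == \
        compare_permutations(b, a).breakpoint_distance


def test_synteny_invariant_under_rotation_and_reflection(study):
    ref, red = study.reference, study.reduced
    base = compare_order(ref, red)
    for variant in (rotate_genome(ref, 4321), reflect_genome(ref),
                    rotate_genome(reflect_genome(ref), 17)):
        res = compare_order(variant, red)
        assert res.conserved_adjacencies == base.conserved_adjacencies
        assert res.oriented_adjacencies == base.oriented_adjacencies
        assert res.breakpoint_distance == base.breakpoint_distance
    res = compare_order(ref, reflect_genome(red))
    assert res.breakpoint_distance == base.breakpoint_distance


def test_trna_exclusion_default(study):
    without = compare_order(study.reference, study.reduced)
    with_trna = compare_order(study.reference, study.reduced,
                              include_trna=True)
    assert with_trna.n_shared > without.n_shared


def test_fewer_than_two_shared_genes_is_flagged():
    res = compare_permutations(_perm([("a", 1)], "A"), _perm([("a", 1)], "B"))
    assert not res.defined
    assert res.n_blocks == res.n_shared == 1


def test_pairwise_matrix_symmetry(study):
    rng = np.random.default_rng(3)
    shuffled = rotate_genome(reflect_genome(study.reference),
                             int(rng.integers(1000)))
    shuffled.id = "variant"
    adj, bpd = pairwise_matrix([study.reference, study.reduced, shuffled])
    assert np.allclose(adj.values, adj.values.T, equal_nan=True)
    assert np.allclose(np.diag(adj.values), 1.0)
    assert np.allclose(np.diag(bpd.values), 0.0)
    # reflected+rotated copy is perfectly syntenic with the original
    assert adj.loc[study.reference.id, "variant"] == 1.0


def test_random_null_mean_is_small():
    rng = np.random.default_rng(5)
    base = random_signed_permutation(50, rng, "A")
    fracs = [compare_permutations(
        base, random_signed_permutation(50, rng, "B")).adjacency_fraction
        for _ in range(200)]
    assert np.mean(fracs) < 0.1
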