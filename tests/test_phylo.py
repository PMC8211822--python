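"""Distances, neighbor joining against brute-force oracles, and bootstrap."""

import math

import numpy as np
import pytest
import sympy

from cappscan.errors import IncomputableDistanceError, NewickParseError, SaturationError
from cappscan.phylo import (
    P_MAX,
    DistanceMatrix,
    MultipleAlignment,
    bipartitions,
    bootstrap_support,
    distance_matrix,
    kimura_distance,
    leaf_path_lengths,
    neighbor_joining,
    p_distance,
    read_newick,
    write_newick,
)
from cappscan.synthetic import EvolutionSpec, evolve_sequences, two_family_tree

from _oracles import best_tree_by_enumeration, random_additive_matrix, splits_of


# ---------------------------------------------------------------- distances

@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("AAAA", "AAAT", 0.25),
        ("AA-A", "AATA", 0.0),
        ("AXAA", "AAAA", 0.0),
    ],
)
def test_p_distance(a, b, expected):
    assert p_distance(a, b) == expected


def test_p_distance_incomputable():
    with pytest.raises(IncomputableDistanceError):
        p_distance("----", "AAAA")


def test_kimura_closed_form_against_sympy():
    """d = -ln(1 - p - 0.2 p^2), checked to 1e-12 against exact arithmetic."""
    assert kimura_distance(0.0) == 0.0
    for p in [0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 0.85]:
        exact = float(-sympy.log(1 - sympy.Rational(p) - sympy.Rational(1, 5) * sympy.Rational(p) ** 2).evalf(30))
        assert abs(kimura_distance(p) - exact) < 1e-12
    # frozen spot value: -ln(0.898) evaluated with 30-digit arithmetic
    assert abs(kimura_distance(0.1) - 0.10758521067993745) < 1e-12


def test_kimura_saturation_boundary():
    # p_max is the positive root of 0.2 p^2 + p - 1
    assert abs(0.2 * P_MAX**2 + P_MAX - 1.0) < 1e-12
    with pytest.raises(SaturationError):
        kimura_distance(0.86)
    with pytest.raises(SaturationError):
        kimura_distance(P_MAX)
    assert kimura_distance(0.86, cap=5.0) == 5.0


def test_kimura_monotone_and_dominates_p():
    ps = np.linspace(0.0, P_MAX - 1e-6, 200)
    ds = [kimura_distance(p) for p in ps]
    assert all(b > a for a, b in zip(ds, ds[1:]))
    assert all(d >= p for p, d in zip(ps, ds))


def test_distance_matrix_identical_rows_and_symmetry():
    aln = MultipleAlignment(ids=["a", "b", "c"], rows=["ACDE", "ACDE", "ACDE"])
    dm = distance_matrix(aln)
    assert np.all(dm.d == 0.0)

    aln2 = MultipleAlignment(ids=["a", "b", "c"], rows=["ACDEFGHIKL", "ACDEFGHIKM", "ACDEFGHIMM"])
    dm2 = distance_matrix(aln2)
    np.testing.assert_array_equal(dm2.d, dm2.d.T)
    assert dm2.d[0, 1] == pytest.approx(kimura_distance(0.1))


def test_distance_matrix_permutation_equivariance():
    rows = ["ACDEFGHIKL", "ACDEFGHIKM", "ACDEFGMMMM", "ACWWFGHIKL"]
    aln = MultipleAlignment(ids=list("abcd"), rows=rows)
    perm = [2, 0, 3, 1]
    aln_p = MultipleAlignment(ids=[aln.ids[i] for i in perm], rows=[rows[i] for i in perm])
    d1 = distance_matrix(aln).d
    d2 = distance_matrix(aln_p).d
    for i, pi in enumerate(perm):
        for j, pj in enumerate(perm):
            assert d1[pi, pj] == d2[i, j]


def test_saturated_pair_is_named():
    aln = MultipleAlignment(ids=["a", "b"], rows=["ACDEFGHIKL", "WYWYWYWYWY"])
    with pytest.raises(SaturationError, match="a.*b"):
        distance_matrix(aln)


# ------------------------------------------------------------------ NJ core

def _dm(labels, D):
    D = np.asarray(D, dtype=float)
    return DistanceMatrix(labels=list(labels), p=D.copy(), d=D)


def test_nj_three_taxa_closed_form():
    D = [[0, 3, 4], [3, 0, 5], [4, 5, 0]]
    tree = neighbor_joining(_dm("ABC", D))
    limbs = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert limbs == {"A": 1.0, "B": 2.0, "C": 3.0}


def test_nj_four_taxa_additive_example():
    """Additive 4-taxon matrix: AB|CD with limbs (1,2,3,4), internal edge 1."""
    labels = list("ABCD")
    D = [
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ]
    tree = neighbor_joining(_dm(labels, D))
    assert bipartitions(tree) == {frozenset({"A", "B"})}
    limbs = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert limbs == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
    internal = [
        nd.edge.length
        for nd in tree.preorder_node_iter()
        if not nd.is_leaf() and nd is not tree.seed_node
    ]
    assert internal == pytest.approx([1.0])
    # cross-check against the exhaustive least-squares oracle
    adj, rss, _ = best_tree_by_enumeration(labels, np.array(D, dtype=float))
    assert rss < 1e-18
    assert splits_of(adj, labels) == bipartitions(tree)


def test_nj_consistent_on_random_additive_matrices():
    """NJ reproduces the generating tree on 1000 random additive matrices.

    Additive matrices have a unique tree realization, so the generating tree
    is an exact oracle; splits must match and patristic distances must agree
    with the input matrix to 1e-9.
    """
    rng = np.random.default_rng(2024)
    for trial in range(1000):
        n = int(rng.integers(4, 7))
        labels = [f"L{i}" for i in range(n)]
        D, true_splits, _, _ = random_additive_matrix(labels, rng)
        tree = neighbor_joining(_dm(labels, D))
        assert bipartitions(tree) == true_splits, f"trial {trial}"
        paths = leaf_path_lengths(tree)
        for i in range(n):
            for j in range(i + 1, n):
                key = tuple(sorted((labels[i], labels[j])))
                assert abs(paths[key] - D[i, j]) < 1e-9, f"trial {trial} {key}"


def test_nj_matches_enumeration_oracle():
    """Exhaustive topology search agrees with NJ on a random additive batch."""
    rng = np.random.default_rng(7)
    for _ in range(60):
        n = int(rng.integers(4, 7))
        labels = [f"L{i}" for i in range(n)]
        D, _, _, _ = random_additive_matrix(labels, rng)
        tree = neighbor_joining(_dm(labels, D))
        adj, rss, _ = best_tree_by_enumeration(labels, D)
        assert rss < 1e-16
        assert splits_of(adj, labels) == bipartitions(tree)


def test_nj_agrees_with_skbio_on_noisy_matrix():
    """Independent implementation cross-check on a non-additive matrix."""
    skbio_tree = pytest.importorskip("skbio.tree")
    from skbio import DistanceMatrix as SkbioDM

    rng = np.random.default_rng(13)
    n = 7
    labels = [f"L{i}" for i in range(n)]
    D, _, _, _ = random_additive_matrix(labels, rng)
    noise = rng.uniform(0, 0.02, size=(n, n))
    noise = (noise + noise.T) / 2
    np.fill_diagonal(noise, 0.0)
    D = D + noise
    ours = neighbor_joining(_dm(labels, D))
    theirs = skbio_tree.nj(SkbioDM(D, ids=labels))
    their_splits = set()
    leaves = frozenset(labels)
    ref = min(labels)
    for node in theirs.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        if 2 <= len(below) <= n - 2:
            their_splits.add(below if ref in below else leaves - below)
    assert bipartitions(ours) == their_splits


def test_nj_refuses_nonfinite():
    D = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
    with pytest.raises(IncomputableDistanceError, match="L0.*L2"):
        neighbor_joining(_dm(["L0", "L1", "L2"], D))


def test_nj_recovers_clock_tree_from_simulation():
    """Ultrametric-ish simulated families: NJ recovers the guide topology."""
    tree, _ = two_family_tree(n_per_family=5, separation=0.8, seed=21)
    aln = evolve_sequences(EvolutionSpec(guide_tree=tree, n_sites=2000, seed=22))
    est = neighbor_joining(distance_matrix(aln))
    est_splits = bipartitions(est)
    # the deep family-separating split must always be recovered
    fam_a = frozenset(lab for lab in aln.ids if lab.startswith("A"))
    leaves = frozenset(aln.ids)
    key = fam_a if min(leaves) in fam_a else leaves - fam_a
    assert key in est_splits
    # on the exact (noise-free) patristic distances NJ is consistent:
    # it must recover every split of the guide tree
    true_paths = leaf_path_lengths(tree)
    labels = sorted(aln.ids)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = true_paths[tuple(sorted((labels[i], labels[j])))]
    exact = neighbor_joining(_dm(labels, D))
    assert bipartitions(exact) == bipartitions_from_guide(tree)


def bipartitions_from_guide(tree):
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(below) <= len(leaves) - 2:
            out.add(below if ref in below else leaves - below)
    return out


def test_path_length_recovery_within_band():
    """Kimura-corrected distances recover true path lengths to 15%.

    The 15% band is checked on the mean relative error over pairs at depth
    d <= 0.6, where the correction's systematic bias under the equal-rates
    generator (~+10% at d=0.6, growing to ~+19% at d=1) leaves headroom;
    individual pairs additionally carry binomial sampling noise (about
    +/-10% of d for short pairs at 1000 sites), so per-pair errors get a
    correspondingly wider 30% bound.
    """
    tree, _ = two_family_tree(n_per_family=4, separation=0.5, seed=31)
    true_paths = leaf_path_lengths(tree)
    aln = evolve_sequences(EvolutionSpec(guide_tree=tree, n_sites=1000, seed=32))
    dm = distance_matrix(aln)
    idx = {lab: i for i, lab in enumerate(dm.labels)}
    rel_errors = []
    for (a, b), d_true in true_paths.items():
        if d_true > 0.6 or d_true < 0.05:
            continue
        d_est = dm.d[idx[a], idx[b]]
        rel = abs(d_est - d_true) / d_true
        assert rel < 0.30, (a, b, d_true, d_est)
        rel_errors.append(rel)
    assert rel_errors
    assert np.mean(rel_errors) < 0.15


# ---------------------------------------------------------------- bootstrap

def test_bootstrap_strong_signal_supports_100():
    """A repeated-block alignment with overwhelming clade signal: every
    replicate rebuilds the reference topology, so all supports are 100.

    (A literally zero-variance alignment — one column pattern repeated —
    always has some pair at p = 1, which saturates the Kimura correction, so
    the saturating limit is approximated by a strongly repetitive block whose
    pairwise distances stay inside the correction's domain.)
    """
    rows = {
        "A1": "AAAACGAAAA",
        "A2": "AAAADGAAAA",
        "B1": "TTTTCGAAAA",
        "B2": "TTTTCHAAAA",
    }
    aln = MultipleAlignment(ids=list(rows), rows=[v * 30 for v in rows.values()])
    _, supports = bootstrap_support(aln, n_replicates=20, seed=3)
    assert supports
    assert all(v == 100.0 for v in supports.values())


def test_bootstrap_single_replicate_quantized(two_family_alignment):
    aln, _ = two_family_alignment
    _, supports = bootstrap_support(aln, n_replicates=1, seed=0)
    assert set(supports.values()) <= {0.0, 100.0}


def test_bootstrap_deterministic(two_family_alignment):
    aln, _ = two_family_alignment
    t1, s1 = bootstrap_support(aln, n_replicates=10, seed=42)
    t2, s2 = bootstrap_support(aln, n_replicates=10, seed=42)
    assert s1 == s2
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


def test_bootstrap_supports_on_tree_labels(two_family_alignment):
    aln, _ = two_family_alignment
    tree, supports = bootstrap_support(aln, n_replicates=10, seed=1)
    labelled = [
        nd.label
        for nd in tree.preorder_node_iter()
        if not nd.is_leaf() and nd is not tree.seed_node and nd.label is not None
    ]
    assert len(labelled) == len(supports)


# ------------------------------------------------------------------- newick

def test_newick_roundtrip(tmp_path, two_family_alignment):
    aln, _ = two_family_alignment
    tree, _ = bootstrap_support(aln, n_replicates=5, seed=2)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    again = read_newick(path)
    assert bipartitions(again) == bipartitions(tree)
    orig = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    back = {lf.taxon.label: lf.edge.length for lf in again.leaf_node_iter()}
    for k in orig:
        assert back[k] == pytest.approx(orig[k], abs=1e-8)


def test_newick_two_leaf_roundtrip(tmp_path):
    path = tmp_path / "two.nwk"
    path.write_text("(A:0.5,B:0.5);\n")
    tree = read_newick(path)
    assert sorted(lf.taxon.label for lf in tree.leaf_node_iter()) == ["A", "B"]
    out = tmp_path / "again.nwk"
    write_newick(tree, out)
    assert bipartitions(read_newick(out)) == bipartitions(tree)


def test_newick_malformed_raises(tmp_path):
    path = tmp_path / "bad.nwk"
    path.write_text("((A:0.5,B:0.5;\n")
    with pytest.raises(NewickParseError):
        read_newick(path)


def test_rotation_preserves_splits(tmp_path):
    p1 = tmp_path / "a.nwk"
    p2 = tmp_path / "b.nwk"
    p1.write_text("((A:1,B:1):1,(C:1,D:1):1,E:1);\n")
    p2.write_text("((B:1,A:1):1,E:1,(D:1,C:1):1);\n")
    assert bipartitions(read_newick(p1)) == bipartitions(read_newick(p2))
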