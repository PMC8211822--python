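"""Protein distances, neighbor joining, and bootstrap bipartition support.

Pipeline: an aligned protein family -> pairwise p-distances (pairwise
deletion over gaps and X) -> Kimura's multiple-hit correction
``d = -ln(1 - p - 0.2 p^2)`` -> Saitou-Nei neighbor joining -> column
bootstrap mapping split support onto the reference tree.  Trees are held as
unrooted :class:`dendropy.Tree` objects; Newick carries branch lengths and
support as internal-node labels.

The Kimura correction diverges at ``p_max = (-1 + sqrt(1.8)) / 0.4``
(~0.8541); pairs at or beyond it raise :class:`SaturationError` by default
because a single capped distance can distort the whole topology.  Pass
``cap`` to substitute a fixed maximum distance instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from cappscan.errors import (
    IncomputableDistanceError,
    NewickParseError,
    SaturationError,
)

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MISSING = {"-", "X"}

#: Domain boundary of the Kimura correction: positive root of 0.2 p^2 + p - 1.
P_MAX = (-1.0 + math.sqrt(1.8)) / 0.4

DEFAULT_BOOTSTRAP = 100


@dataclass
class MultipleAlignment:
    """An ungapped-or-gapped protein alignment: unique ids, equal-length rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids are not unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(row), id=name, description="") for name, row in zip(self.ids, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls(ids=[r.id for r in records], rows=[str(r.seq) for r in records])

    def resample_columns(self, rng: np.random.Generator) -> "MultipleAlignment":
        """Bootstrap replicate: sample columns with replacement to full length."""
        arr = np.array([list(r) for r in self.rows])
        cols = rng.integers(0, arr.shape[1], size=arr.shape[1])
        resampled = arr[:, cols]
        return MultipleAlignment(ids=list(self.ids), rows=["".join(r) for r in resampled])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances: raw p and Kimura-corrected d."""

    labels: list[str]
    p: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        n = len(self.labels)
        for m in (self.p, self.d):
            if m.shape != (n, n):
                raise ValueError("matrix shape does not match label count")

    def __len__(self) -> int:
        return len(self.labels)


def p_distance(row_i: str, row_j: str) -> float:
    """Proportion of differing residues over comparable columns.

    Columns where either row carries a gap ('-') or unknown ('X') are
    excluded (pairwise deletion).  Raises if no comparable column remains.
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows have different lengths")
    comparable = 0
    diffs = 0
    for a, b in zip(row_i.upper(), row_j.upper()):
        if a in MISSING or b in MISSING:
            continue
        comparable += 1
        if a != b:
            diffs += 1
    if comparable == 0:
        raise IncomputableDistanceError("no comparable columns between rows")
    return diffs / comparable


def kimura_distance(p: float, cap: float | None = None) -> float:
    """Kimura's protein distance ``d = -ln(1 - p - 0.2 p^2)``.

    Monotone increasing on [0, P_MAX) with d(0) = 0.  For p >= P_MAX the
    argument of the logarithm is non-positive; raises SaturationError
    unless ``cap`` provides a substitute maximum distance.
    """
    if p < 0 or p > 1:
        raise ValueError(f"p-distance must lie in [0,1], got {p}")
    if p >= P_MAX:
        if cap is not None:
            return cap
        raise SaturationError(
            f"p = {p:.6f} >= {P_MAX:.6f}: Kimura correction saturated", p=p
        )
    return -math.log(1.0 - p - 0.2 * p * p)


def distance_matrix(
    aln: MultipleAlignment,
    deletion: str = "pairwise",
    cap: float | None = None,
) -> DistanceMatrix:
    """All-pairs p and Kimura distances for an alignment.

    ``deletion`` is "pairwise" (default: drop gap/X columns per pair) or
    "complete" (drop any column with a gap/X in any row, once, up front).
    Saturated or incomputable pairs raise with the offending pair named,
    unless ``cap`` is given.
    """
    rows = aln.rows
    if deletion == "complete":
        keep = [
            i
            for i in range(aln.n_sites)
            if all(r[i] not in MISSING for r in rows)
        ]
        if not keep:
            raise IncomputableDistanceError("complete deletion removed every column")
        rows = ["".join(r[i] for i in keep) for r in rows]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = len(aln)
    p = np.zeros((n, n))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = (aln.ids[i], aln.ids[j])
            try:
                pij = p_distance(rows[i], rows[j])
                dij = kimura_distance(pij, cap=cap)
            except IncomputableDistanceError as exc:
                raise IncomputableDistanceError(f"pair {pair}: {exc}", pair=pair) from None
            except SaturationError as exc:
                raise SaturationError(f"pair {pair}: {exc}", pair=pair, p=exc.p) from None
            p[i, j] = p[j, i] = pij
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=list(aln.ids), p=p, d=d)


def _cluster_rep(reps: dict[int, str], i: int) -> str:
    return reps[i]


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining over Kimura-corrected distances.

    Iteratively joins the pair minimising
    ``Q(i,j) = (m-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``; limb lengths
    follow the standard formulas.  Ties in Q break on the lexicographically
    smallest pair of cluster representatives (the minimal leaf label in each
    cluster), so the result is deterministic.  Negative limb lengths are
    clamped to zero with the deficit moved to the sister limb, preserving the
    joined pair's distance.  Returns an unrooted tree (trifurcating seed).
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    if not np.all(np.isfinite(dm.d)):
        bad = [
            (labels[i], labels[j])
            for i in range(n)
            for j in range(i + 1, n)
            if not np.isfinite(dm.d[i, j])
        ]
        raise IncomputableDistanceError(f"non-finite distances for pairs: {bad}")

    tns = dendropy.TaxonNamespace(labels)
    D = dm.d.astype(float).copy()
    nodes: dict[int, dendropy.Node] = {}
    reps: dict[int, str] = {}
    for i, lab in enumerate(labels):
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        nodes[i] = nd
        reps[i] = lab
    active = list(range(n))
    next_id = n
    D_full = {(i, i): 0.0 for i in active}
    for i in active:
        for j in active:
            D_full[(i, j)] = D[i, j]

    def dist(a: int, b: int) -> float:
        return D_full[(a, b)]

    while len(active) > 3:
        m = len(active)
        rowsum = {i: sum(dist(i, k) for k in active) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - rowsum[i] - rowsum[j]
                tie_key = tuple(sorted((reps[i], reps[j])))
                cand = (q, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (rowsum[i] - rowsum[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            logger.debug("clamping negative limb %s: %.4g", reps[i], li)
            lj += li
            li = 0.0
        if lj < 0:
            logger.debug("clamping negative limb %s: %.4g", reps[j], lj)
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        u = next_id
        next_id += 1
        nodes[u] = parent
        reps[u] = min(reps[i], reps[j])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            D_full[(u, k)] = D_full[(k, u)] = duk
        D_full[(u, u)] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (dist(i, j) + dist(i, k) - dist(j, k))
    lj = 0.5 * (dist(i, j) + dist(j, k) - dist(i, k))
    lk = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
    center = dendropy.Node()
    for idx, limb in ((i, li), (j, lj), (k, lk)):
        if limb < 0:
            logger.debug("clamping negative terminal limb %s: %.4g", reps[idx], limb)
            limb = 0.0
        center.add_child(nodes[idx])
        nodes[idx].edge.length = limb
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits of the leaf set, one frozenset per internal edge.

    Each split is normalised to the side containing the lexicographically
    smallest leaf label, so splits compare across differently-rooted trees.
    Trivial splits (one leaf vs the rest) are excluded.
    """
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(leaves)
    n = len(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(below) <= n - 2:
            splits.add(below if ref in below else leaves - below)
    return splits


def bootstrap_support(
    aln: MultipleAlignment,
    n_replicates: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    deletion: str = "pairwise",
    cap: float | None = None,
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """Column-bootstrap support mapped onto the reference NJ tree.

    The reference tree is built from the full alignment; each replicate
    resamples columns with replacement to the original length and rebuilds
    NJ.  Support of each internal edge of the reference tree is the
    percentage of replicates whose tree contains the same bipartition, and
    is stored on the corresponding internal node's ``label``.

    Per-replicate RNG streams derive from (seed, attempt counter), so results
    do not depend on replicate execution order.  Replicates with saturated or
    incomputable pairs are rejected and redrawn; more than 50% rejections
    aborts the run.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ref_tree = neighbor_joining(distance_matrix(aln, deletion=deletion, cap=cap))
    ref_splits = bipartitions(ref_tree)
    hits = {split: 0 for split in ref_splits}
    accepted = 0
    attempt = 0
    max_attempts = 2 * n_replicates
    while accepted < n_replicates:
        if attempt >= max_attempts:
            raise RuntimeError(
                f"bootstrap aborted: >50% of replicates rejected "
                f"({attempt - accepted} rejections in {attempt} attempts)"
            )
        rng = np.random.default_rng([seed, attempt])
        attempt += 1
        replicate = aln.resample_columns(rng)
        try:
            rep_tree = neighbor_joining(distance_matrix(replicate, deletion=deletion, cap=cap))
        except (SaturationError, IncomputableDistanceError) as exc:
            logger.info("bootstrap replicate rejected (attempt %d): %s", attempt, exc)
            continue
        rep_splits = bipartitions(rep_tree)
        for split in hits:
            if split in rep_splits:
                hits[split] += 1
        accepted += 1
    supports = {split: 100.0 * k / n_replicates for split, k in hits.items()}

    leaves = frozenset(lf.taxon.label for lf in ref_tree.leaf_node_iter())
    ref = min(leaves)
    n_leaves = len(leaves)
    for node in ref_tree.preorder_node_iter():
        if node is ref_tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(below) <= n_leaves - 2:
            split = below if ref in below else leaves - below
            node.label = f"{supports[split]:g}"
    return ref_tree, supports


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write Newick with branch lengths and support as internal-node labels."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    with open(path, "w") as fh:
        fh.write(text)


def read_newick(path) -> dendropy.Tree:
    """Read a Newick tree (internal labels interpreted as support values)."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"{path}: {exc}") from None
    tree.is_rooted = False
    return tree


def leaf_path_lengths(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Patristic distances between all leaf pairs, keyed by sorted label pair."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            key = tuple(sorted((t1.label, t2.label)))
            out[key] = pdm.patristic_distance(t1, t2)
    return out
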