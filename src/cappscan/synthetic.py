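"""Seeded generators for genomes, operons, protein families and domain tables.

Every downstream stage of the pipeline is exercised on data produced here,
with a machine-readable :class:`TruthManifest` recording exactly what was
planted: operon locations and strands, focal genes, family membership of
simulated proteins, and the generating tree.  Generation is fully
deterministic given the spec and seed.

Genome model: per contig, a fixed number of non-overlapping genes on a linear
coordinate axis; operon templates (ordered product-name labels such as
["CAPP", "Cas1", "Cas2"]) are planted as consecutive genes, reversed in gene
order when the operon falls on the minus strand; all remaining genes draw
product names from a background pool screened to share no case-insensitive
substring with any tracked keyword, so planted-recovery tests are exact.

Sequence model: a 20-state equal-frequency, equal-rate Markov substitution
process (protein analogue of Jukes-Cantor) along a known guide tree.  Per
site and branch the substitution count is Poisson(rate x length) and each
substitution is uniform over the 19 non-identical residues.  No indels are
generated, so simulated sequences are trivially aligned.  Two leaves at
total path distance d then differ with probability
``p = (19/20) (1 - exp(-20 d / 19))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from cappscan.errors import SizingError, VocabularyError
from cappscan.neighborhood import GeneRecord, write_feature_table, write_gff3
from cappscan.phylo import AMINO_ACIDS, MultipleAlignment

DOMAIN_VOCABULARY = ("TPR", "AEP", "PriCT", "RT", "Helicase", "VirE_N")

#: Typical domain spans (aa) used to lay out plausible intervals.
_DOMAIN_SPANS = {
    "TPR": (90, 120),
    "AEP": (220, 260),
    "PriCT": (70, 110),
    "RT": (180, 240),
    "Helicase": (250, 320),
    "VirE_N": (180, 230),
}

#: Housekeeping-style product names containing none of the tracked keywords.
DEFAULT_BACKGROUND_POOL = (
    "DNA gyrase subunit A",
    "50S ribosomal protein L2",
    "30S ribosomal protein S12",
    "elongation factor Tu",
    "chaperonin GroEL",
    "ATP synthase subunit beta",
    "phosphoglycerate kinase",
    "enolase",
    "citrate synthase",
    "glyceraldehyde-3-phosphate dehydrogenase",
    "aminopeptidase N",
    "ABC transporter permease",
    "MFS transporter",
    "two-component sensor kinase",
    "cold-shock protein CspA",
    "acyl carrier protein",
    "hypothetical protein",
    "membrane protein of unknown function",
    "preprotein translocase subunit SecY",
    "signal peptidase I",
)

DEFAULT_TRACKED_KEYWORDS = (
    "CRISPR",
    "Cas1",
    "Cas2",
    "primase",
    "polymerase",
    "helicase",
    "nuclease",
    "transposase",
    "argonaute",
    "CAPP",
)


@dataclass
class SyntheticGenomeSpec:
    """Parameters of a synthetic annotated genome with planted operons.

    ``operon_templates`` is a list of (labels, frequency) pairs: ``labels``
    is the ordered product-name list of one operon and ``frequency`` the
    probability that one copy is planted on a given contig.
    """

    n_contigs: int = 3
    genes_per_contig: int = 50
    operon_templates: Sequence[tuple[Sequence[str], float]] = (
        (("CRISPR-associated primase-polymerase CAPP",
          "CRISPR-associated endonuclease Cas1",
          "CRISPR-associated protein Cas2"), 1.0),
    )
    background_name_pool: Sequence[str] = DEFAULT_BACKGROUND_POOL
    focal_label: str = "CAPP"
    strand_policy: float = 0.5
    tracked_keywords: Sequence[str] = DEFAULT_TRACKED_KEYWORDS
    seed: int = 0

    def validate(self) -> None:
        if self.n_contigs < 1 or self.genes_per_contig < 1:
            raise ValueError("n_contigs and genes_per_contig must be >= 1")
        longest = max((len(t) for t, _ in self.operon_templates), default=0)
        if longest > self.genes_per_contig:
            raise SizingError(
                f"longest operon template ({longest} genes) exceeds "
                f"genes_per_contig ({self.genes_per_contig})"
            )
        if not 0.0 <= self.strand_policy <= 1.0:
            raise ValueError("strand_policy must be a probability")
        lowered = [kw.lower() for kw in self.tracked_keywords]
        for name in self.background_name_pool:
            for kw in lowered:
                if kw in name.lower():
                    raise ValueError(
                        f"background name {name!r} contains tracked keyword {kw!r}"
                    )


@dataclass
class EvolutionSpec:
    """Parameters of sequence evolution along a guide tree.

    ``guide_tree`` is a dendropy tree with named leaves and non-negative
    branch lengths, or None to draw a random Yule tree with ``n_leaves``.
    """

    guide_tree: dendropy.Tree | None = None
    n_leaves: int = 10
    n_sites: int = 200
    subst_rate: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.subst_rate < 0:
            raise ValueError("subst_rate must be >= 0")


@dataclass
class TruthManifest:
    """Ground truth for planted structure; round-trips losslessly via JSON."""

    operons: list[dict] = field(default_factory=list)
    focal_genes: list[dict] = field(default_factory=list)
    families: dict[str, str] = field(default_factory=dict)
    tree_newick: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "operons": self.operons,
                    "focal_genes": self.focal_genes,
                    "families": self.families,
                    "tree_newick": self.tree_newick,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            operons=d["operons"],
            focal_genes=d["focal_genes"],
            families=d["families"],
            tree_newick=d["tree_newick"],
        )


def generate_genome(
    spec: SyntheticGenomeSpec, outdir
) -> tuple[dict[str, Path], TruthManifest]:
    """Generate one annotated genome set in both dialects plus its manifest.

    Returns a dict of written paths ({"tsv", "gff3", "manifest"}) and the
    :class:`TruthManifest`.  Gene coordinates are non-overlapping and
    strictly increasing per contig; a planted minus-strand operon appears
    with its template gene order reversed on the genome, so that reading the
    operon in its transcription direction restores template order.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    manifest = TruthManifest()
    records: list[GeneRecord] = []
    acc_counter = 0

    for c in range(spec.n_contigs):
        contig = f"contig{c + 1:02d}"
        n_genes = spec.genes_per_contig
        # decide plants for this contig: (start_rank, labels, strand)
        plants: list[tuple[int, Sequence[str], str]] = []
        occupied: set[int] = set()
        for labels, freq in spec.operon_templates:
            if rng.random() >= freq:
                continue
            strand = "-" if rng.random() < spec.strand_policy else "+"
            span = len(labels)
            # uniform placement among free runs; retry a bounded number of times
            placed = False
            for _ in range(200):
                start_rank = int(rng.integers(0, n_genes - span + 1))
                ranks = set(range(start_rank, start_rank + span))
                if not ranks & occupied:
                    occupied |= ranks
                    plants.append((start_rank, labels, strand))
                    placed = True
                    break
            if not placed:
                raise SizingError(
                    f"could not place operon {list(labels)} on {contig}: contig too crowded"
                )

        names = [None] * n_genes
        strands = [None] * n_genes
        planted_tags: dict[int, None] = {}
        for start_rank, labels, strand in plants:
            ordered = list(labels) if strand == "+" else list(labels)[::-1]
            for k, label in enumerate(ordered):
                names[start_rank + k] = label
                strands[start_rank + k] = strand
                planted_tags[start_rank + k] = None
        for i in range(n_genes):
            if names[i] is None:
                names[i] = str(rng.choice(np.array(spec.background_name_pool, dtype=object)))
                strands[i] = "+" if rng.random() < 0.5 else "-"

        pos = 0
        contig_records = []
        for i in range(n_genes):
            pos += int(rng.integers(20, 200))  # intergenic gap
            length = int(rng.integers(100, 500)) * 3
            tag = f"{contig}_g{i + 1:04d}"
            acc_counter += 1
            acc = f"SYN{acc_counter:06d}"
            contig_records.append(
                GeneRecord(
                    contig_id=contig,
                    start=pos,
                    end=pos + length,
                    strand=strands[i],
                    locus_tag=tag,
                    protein_accession=acc,
                    product_name=names[i],
                )
            )
            pos += length
        records.extend(contig_records)

        for start_rank, labels, strand in plants:
            span = len(labels)
            operon_recs = contig_records[start_rank : start_rank + span]
            # record locus tags in template (transcription) order
            tags = [r.locus_tag for r in operon_recs]
            if strand == "-":
                tags = tags[::-1]
            manifest.operons.append(
                {
                    "contig": contig,
                    "locus_tags": tags,
                    "strand": strand,
                    "template": list(labels),
                }
            )
            for rec in operon_recs:
                if spec.focal_label.lower() in rec.product_name.lower():
                    manifest.focal_genes.append(
                        {
                            "contig": contig,
                            "locus_tag": rec.locus_tag,
                            "protein_accession": rec.protein_accession,
                        }
                    )

    paths = {
        "tsv": outdir / "features.tsv",
        "gff3": outdir / "features.gff3",
        "manifest": outdir / "manifest.json",
    }
    write_feature_table(records, paths["tsv"])
    write_gff3(records, paths["gff3"])
    manifest.to_json(paths["manifest"])
    return paths, manifest


def _check_binary(tree: dendropy.Tree) -> None:
    leaves = [lf for lf in tree.leaf_node_iter()]
    if not leaves:
        raise ValueError("guide tree has no leaves")
    for node in tree.preorder_node_iter():
        nch = len(node.child_nodes())
        if node.is_leaf():
            continue
        if node is tree.seed_node:
            if nch not in (2, 3):
                raise ValueError(f"root has {nch} children; expected 2 or 3")
        elif nch != 2:
            raise ValueError(f"internal node has {nch} children; tree is not binary")
    for lf in leaves:
        if lf.taxon is None or not lf.taxon.label:
            raise ValueError("every leaf must be named")


def yule_tree(n_leaves: int, seed: int, branch_length_range=(0.02, 0.08),
              prefix: str = "t") -> dendropy.Tree:
    """Random binary tree by sequential attachment with uniform branch lengths.

    A lightweight stand-in for a Yule draw: leaf k+1 attaches to a uniformly
    chosen existing edge; branch lengths are iid uniform over the given range.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    labels = [f"{prefix}{i + 1:02d}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)

    def bl() -> float:
        return float(rng.uniform(*branch_length_range))

    root = dendropy.Node()
    a = dendropy.Node()
    a.taxon = tns.get_taxon(labels[0])
    b = dendropy.Node()
    b.taxon = tns.get_taxon(labels[1])
    root.add_child(a)
    a.edge.length = bl()
    root.add_child(b)
    b.edge.length = bl()
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    for label in labels[2:]:
        edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
        target = edges[int(rng.integers(0, len(edges)))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.edge.length = target.edge.length / 2.0
        mid.add_child(target)
        target.edge.length = target.edge.length / 2.0
        leaf = dendropy.Node()
        leaf.taxon = tns.get_taxon(label)
        mid.add_child(leaf)
        leaf.edge.length = bl()
    return tree


def two_family_tree(
    n_per_family: int = 10,
    separation: float = 1.0,
    seed: int = 0,
    within_branch_range=(0.02, 0.08),
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Guide tree of two clades (prefixes A/B) joined by a long internal edge.

    ``separation`` is the expected substitutions per site across the edge
    separating the families.  Returns the tree and a leaf -> family map.
    """
    rng = np.random.default_rng(seed)
    sub_a = yule_tree(n_per_family, int(rng.integers(0, 2**31 - 1)),
                      within_branch_range, prefix="A")
    sub_b = yule_tree(n_per_family, int(rng.integers(0, 2**31 - 1)),
                      within_branch_range, prefix="B")
    labels = [t.label for t in sub_a.taxon_namespace] + [
        t.label for t in sub_b.taxon_namespace
    ]
    tns = dendropy.TaxonNamespace(labels)
    root = dendropy.Node()

    def regraft(subtree: dendropy.Tree) -> dendropy.Node:
        node = subtree.seed_node
        for lf in node.leaf_iter():
            lf.taxon = tns.get_taxon(lf.taxon.label)
        return node

    na, nb = regraft(sub_a), regraft(sub_b)
    root.add_child(na)
    na.edge.length = separation / 2.0
    root.add_child(nb)
    nb.edge.length = separation / 2.0
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    families = {lab: ("A" if lab.startswith("A") else "B") for lab in labels}
    return tree, families


def evolve_sequences(spec: EvolutionSpec) -> MultipleAlignment:
    """Simulate protein sequences along the guide tree (no indels).

    Poisson substitution model: per site and branch the number of
    substitutions is Poisson(subst_rate x branch length), each substitution
    replacing the residue with one of the 19 others uniformly.  Row ids equal
    leaf names; rows are trivially aligned (equal length, no gaps).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tree = spec.guide_tree
    if tree is None:
        tree = yule_tree(spec.n_leaves, int(rng.integers(0, 2**31 - 1)))
    _check_binary(tree)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    root_seq = rng.integers(0, 20, size=spec.n_sites)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    ids, rows = [], []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = root_seq
        else:
            parent_seq = seqs[id(node.parent_node)]
            length = node.edge.length or 0.0
            if length < 0:
                raise ValueError("negative branch length in guide tree")
            seq = parent_seq.copy()
            n_subs = rng.poisson(spec.subst_rate * length, size=spec.n_sites)
            for site in np.nonzero(n_subs)[0]:
                state = seq[site]
                for _ in range(n_subs[site]):
                    # uniform over the 19 non-identical residues
                    step = int(rng.integers(1, 20))
                    state = (state + step) % 20
                seq[site] = state
            seqs[id(node)] = seq
        if node.is_leaf():
            ids.append(node.taxon.label)
            rows.append(aa[seq].tobytes().decode())
    return MultipleAlignment(ids=ids, rows=rows)


def expected_p_distance(d: float) -> float:
    """Closed-form leaf-pair difference probability of the 20-state model."""
    return 0.95 * (1.0 - np.exp(-20.0 * d / 19.0))


def two_family_dataset(
    n_per_family: int = 10,
    n_sites: int = 200,
    separation: float = 1.0,
    seed: int = 0,
) -> tuple[MultipleAlignment, TruthManifest]:
    """Alignment of two diverged protein families with its truth manifest."""
    tree, families = two_family_tree(n_per_family, separation, seed)
    aln = evolve_sequences(
        EvolutionSpec(guide_tree=tree, n_sites=n_sites, subst_rate=1.0, seed=seed)
    )
    manifest = TruthManifest(
        families=families,
        tree_newick=tree.as_string(schema="newick").strip(),
    )
    return aln, manifest


def generate_domain_annotations(
    assignments: Mapping[str, Sequence[str]], seed: int = 0
) -> pd.DataFrame:
    """Domain-architecture table (protein_id, domain, start, end) from labels.

    Labels must come from the controlled vocabulary; intervals are laid out
    N->C with plausible spans and short linkers.  Proteins with an empty
    label list yield no rows (and classify as unclassified downstream).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for protein_id, labels in assignments.items():
        pos = 1
        for label in labels:
            if label not in DOMAIN_VOCABULARY:
                raise VocabularyError(
                    f"{protein_id}: unknown domain label {label!r} "
                    f"(vocabulary: {DOMAIN_VOCABULARY})"
                )
            lo, hi = _DOMAIN_SPANS[label]
            span = int(rng.integers(lo, hi + 1))
            rows.append(
                {"protein_id": protein_id, "domain": label, "start": pos, "end": pos + span - 1}
            )
            pos += span + int(rng.integers(5, 30))  # linker
    return pd.DataFrame(rows, columns=["protein_id", "domain", "start", "end"])


def write_domain_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_domain_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain": str})
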