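"""CAPP class and type assignment from tree structure and domain architecture.

Two-level scheme: the top split of the homolog tree separates the two CAPP
classes (CAPP_A, seeded by a Marinitoga-like reference, and CAPP_B, seeded by
a Dysgonamonadaceae-like reference); CAPP_A members are then typed by their
N->C domain architecture into CAPP-TPR (TPR ... AEP), CAPP-RT (RT ... AEP)
or CAPP-Helicase (AEP ... Helicase).  CAPP_B architectures are a bare AEP
catalytic domain, typically annotated as VirE_N, without other discernible
fusions.  The class split is found as the longest internal edge on the tree
path between the two seed leaves — a deterministic proxy for the deep
divergence between the two homolog datasets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from cappscan.errors import FocalLookupError, VocabularyError
from cappscan.synthetic import DOMAIN_VOCABULARY

CAPP_A = "CAPP_A"
CAPP_B = "CAPP_B"
UNCLASSIFIED = "unclassified"

TYPE_TPR = "CAPP-TPR"
TYPE_RT = "CAPP-RT"
TYPE_HELICASE = "CAPP-Helicase"
TYPE_NONE = "none"

CAPP_B_ARCHITECTURE = "CAPP_B-architecture"


@dataclass
class DomainArchitecture:
    """Ordered N->C domain labels of one protein, with optional intervals."""

    protein_id: str
    domains: list[str]
    intervals: list[tuple[int, int]] | None = None

    def __post_init__(self):
        for d in self.domains:
            if d not in DOMAIN_VOCABULARY:
                raise VocabularyError(
                    f"{self.protein_id}: unknown domain label {d!r} "
                    f"(vocabulary: {DOMAIN_VOCABULARY})"
                )
        if self.intervals is not None:
            if len(self.intervals) != len(self.domains):
                raise ValueError("intervals and domains differ in length")
            prev_end = 0
            for start, end in self.intervals:
                if start <= prev_end:
                    raise ValueError("intervals overlap or are unordered")
                prev_end = end


@dataclass
class CappClassAssignment:
    protein_id: str
    capp_class: str
    capp_type: str = TYPE_NONE
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.capp_type != TYPE_NONE and self.capp_class != CAPP_A:
            raise ValueError("capp_type is only defined for CAPP_A members")


def classify_architecture(arch: DomainArchitecture | Sequence[str]) -> str:
    """Map a domain architecture to a CAPP_A type or the CAPP_B pattern.

    Rules, in order: TPR before AEP -> CAPP-TPR; RT before AEP -> CAPP-RT;
    AEP before Helicase -> CAPP-Helicase; a lone AEP or VirE_N catalytic
    domain (PriCT decoration allowed) -> CAPP_B-architecture; anything else
    (including an empty list) -> unclassified.
    """
    domains = list(arch.domains if isinstance(arch, DomainArchitecture) else arch)
    for d in domains:
        if d not in DOMAIN_VOCABULARY:
            raise VocabularyError(f"unknown domain label {d!r}")

    def before(a: str, b: str) -> bool:
        return a in domains and b in domains and domains.index(a) < domains.index(b)

    if before("TPR", "AEP"):
        return TYPE_TPR
    if before("RT", "AEP"):
        return TYPE_RT
    if before("AEP", "Helicase"):
        return TYPE_HELICASE
    present = set(domains)
    if present and present <= {"AEP", "VirE_N", "PriCT"} and present & {"AEP", "VirE_N"}:
        return CAPP_B_ARCHITECTURE
    return UNCLASSIFIED


def _leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == label:
            return lf
    raise FocalLookupError(f"seed leaf {label!r} not found in tree")


def _path_between(a: dendropy.Node, b: dendropy.Node) -> list[dendropy.Node]:
    """Node path from a to b through the (unrooted) tree."""
    def ancestors(node):
        out = [node]
        while out[-1].parent_node is not None:
            out.append(out[-1].parent_node)
        return out

    anc_a = ancestors(a)
    anc_b = ancestors(b)
    set_a = {id(n): i for i, n in enumerate(anc_a)}
    for j, node in enumerate(anc_b):
        if id(node) in set_a:
            i = set_a[id(node)]
            return anc_a[: i + 1] + anc_b[:j][::-1]
    raise ValueError("leaves are not in the same tree")


def assign_classes(
    tree: dendropy.Tree,
    seed_a_id: str,
    seed_b_id: str,
    architectures: Mapping[str, Sequence[str]] | None = None,
) -> list[CappClassAssignment]:
    """Split the tree into CAPP_A / CAPP_B and type the CAPP_A side.

    The internal edge of maximal length on the path between the two seed
    leaves defines the class boundary; leaves on the seed-A side become
    CAPP_A, the rest CAPP_B.  Ties on edge length break toward seed A.
    CAPP_A members are typed from ``architectures`` (protein id -> ordered
    domain labels); a CAPP_B-pattern architecture inside the CAPP_A clade is
    flagged, not overridden, and vice versa.
    """
    if seed_a_id == seed_b_id:
        raise ValueError("seed_a_id and seed_b_id must name different leaves")
    node_a = _leaf(tree, seed_a_id)
    node_b = _leaf(tree, seed_b_id)
    path = _path_between(node_a, node_b)

    # edges along the path as (child-side-closer-to-A index); internal edges
    # exclude the two terminal edges attached to the seed leaves themselves
    edges = []
    for i in range(len(path) - 1):
        u, v = path[i], path[i + 1]
        child = u if u.parent_node is v else v
        length = child.edge.length or 0.0
        edges.append((i, u, v, child, length))
    internal = [e for e in edges if not (e[1].is_leaf() or e[2].is_leaf())]
    if not internal:
        # seeds are adjacent (or 2-leaf tree): the single separating edge is
        # the path itself; split is just A vs everything on B's side
        internal = [edges[len(edges) // 2]]
    best = max(internal, key=lambda e: (e[4], -e[0]))
    _, u, v, child, _ = best

    # leaves reachable from u without crossing the chosen edge -> A side
    blocked = {id(u), id(v)}
    a_side: set[str] = set()
    stack = [u]
    seen = {id(u)}
    while stack:
        node = stack.pop()
        if node.is_leaf():
            a_side.add(node.taxon.label)
        neigh = list(node.child_nodes())
        if node.parent_node is not None:
            neigh.append(node.parent_node)
        for nb in neigh:
            if id(nb) in seen:
                continue
            if {id(node), id(nb)} == blocked:
                continue
            seen.add(id(nb))
            stack.append(nb)
    if seed_a_id not in a_side or seed_b_id in a_side:
        raise RuntimeError("class split failed to separate the seed leaves")

    architectures = architectures or {}
    assignments = []
    for lf in tree.leaf_node_iter():
        pid = lf.taxon.label
        capp_class = CAPP_A if pid in a_side else CAPP_B
        capp_type = TYPE_NONE
        flags: list[str] = []
        arch_label = None
        if pid in architectures:
            arch_label = classify_architecture(list(architectures[pid]))
        if capp_class == CAPP_A:
            if arch_label in (TYPE_TPR, TYPE_RT, TYPE_HELICASE):
                capp_type = arch_label
            elif arch_label == CAPP_B_ARCHITECTURE:
                flags.append("CAPP_B-architecture inside CAPP_A clade")
            elif arch_label == UNCLASSIFIED and pid in architectures:
                flags.append("unclassifiable architecture")
        else:
            if arch_label in (TYPE_TPR, TYPE_RT, TYPE_HELICASE):
                flags.append(f"{arch_label} architecture inside CAPP_B clade")
        assignments.append(
            CappClassAssignment(pid, capp_class, capp_type, flags)
        )
    return assignments


def count_classes(assignments: Sequence[CappClassAssignment]) -> dict:
    """Summary counts of classes and CAPP_A types; totals are conserved."""
    class_counts = Counter(a.capp_class for a in assignments)
    type_counts = Counter(
        a.capp_type for a in assignments if a.capp_class == CAPP_A and a.capp_type != TYPE_NONE
    )
    warnings = [f"{a.protein_id}: {f}" for a in assignments for f in a.flags]
    return {
        "n": len(assignments),
        "class_counts": dict(class_counts),
        "type_counts": dict(type_counts),
        "warnings": warnings,
    }


def write_assignments(assignments: Sequence[CappClassAssignment], path) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_id": a.protein_id,
                "capp_class": a.capp_class,
                "capp_type": a.capp_type,
                "flags": ";".join(a.flags),
            }
            for a in assignments
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def architectures_from_table(df: pd.DataFrame) -> dict[str, list[str]]:
    """Collapse a domain TSV (protein_id, domain, start, end) into ordered labels."""
    out: dict[str, list[str]] = {}
    if df.empty:
        return out
    for pid, grp in df.groupby("protein_id", sort=False):
        out[str(pid)] = list(grp.sort_values("start")["domain"])
    return out
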