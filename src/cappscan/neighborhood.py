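"""Genome annotation parsing and oriented gene-neighborhood extraction.

A *neighborhood* is the window of up to W annotated genes on each side of a
focal gene (a homolog hit), indexed by signed relative position.  Positions
are oriented along the focal gene's reading direction: -1 is the immediately
upstream gene, +1 the immediately downstream one, so operonic structure is
comparable across strands.  The default window of 20 genes per side mirrors
the 40-gene regions screened for CRISPR-Cas context in CAPP discovery.

Two on-disk dialects are supported and yield identical records: GFF3
(gene/CDS features with a ``product`` attribute) and a 7-column feature-table
TSV (contig_id, start, end, strand, locus_tag, protein_accession,
product_name).  Both use 1-based inclusive coordinates on disk; records are
held 0-based half-open in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from cappscan.errors import FeatureTableParseError, FocalLookupError

TSV_COLUMNS = (
    "contig_id",
    "start",
    "end",
    "strand",
    "locus_tag",
    "protein_accession",
    "product_name",
)

DEFAULT_WINDOW = 20


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One annotated gene. Coordinates are 0-based half-open internally."""

    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    protein_accession: str
    product_name: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"{self.locus_tag}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-', got {self.strand!r}")

    def to_dict(self) -> dict:
        return {
            "contig_id": self.contig_id,
            "start": self.start,
            "end": self.end,
            "strand": self.strand,
            "locus_tag": self.locus_tag,
            "protein_accession": self.protein_accession,
            "product_name": self.product_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneRecord":
        return cls(**d)


@dataclass
class Neighborhood:
    """A focal gene plus its position-indexed flanking genes.

    ``neighbors`` maps signed relative positions in [-window, +window] \\ {0}
    to genes on the focal gene's contig; negative positions are upstream of
    the focal gene's reading direction when oriented.
    """

    focal: GeneRecord
    neighbors: list[tuple[int, GeneRecord]]
    window: int

    def __post_init__(self):
        self.neighbors = sorted(self.neighbors, key=lambda t: t[0])
        positions = [p for p, _ in self.neighbors]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate neighbor positions")
        for p, rec in self.neighbors:
            if p == 0 or abs(p) > self.window:
                raise ValueError(f"position {p} outside [-{self.window},{self.window}]\\{{0}}")
            if rec.contig_id != self.focal.contig_id:
                raise ValueError("neighbor on a different contig than the focal gene")

    def gene_at(self, position: int) -> GeneRecord | None:
        for p, rec in self.neighbors:
            if p == position:
                return rec
        return None

    def to_dict(self) -> dict:
        return {
            "focal": self.focal.to_dict(),
            "window": self.window,
            "neighbors": [[p, rec.to_dict()] for p, rec in self.neighbors],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Neighborhood":
        return cls(
            focal=GeneRecord.from_dict(d["focal"]),
            neighbors=[(int(p), GeneRecord.from_dict(r)) for p, r in d["neighbors"]],
            window=int(d["window"]),
        )


def _parse_tsv(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if tuple(header.split("\t")) != TSV_COLUMNS:
            raise FeatureTableParseError(path, 1, f"unexpected header {header!r}")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(TSV_COLUMNS):
                raise FeatureTableParseError(
                    path, line_no, f"expected {len(TSV_COLUMNS)} columns, got {len(fields)}"
                )
            contig, start, end, strand, tag, acc, product = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FeatureTableParseError(path, line_no, "non-integer coordinates") from None
            try:
                records.append(
                    GeneRecord(contig, start_i - 1, end_i, strand, tag, acc, product)
                )
            except ValueError as exc:
                raise FeatureTableParseError(path, line_no, str(exc)) from None
    return records


def _parse_gff3(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise FeatureTableParseError(path, line_no, f"bad GFF3 line: {exc}") from None
            if feat.featuretype != "CDS":
                continue
            try:
                records.append(
                    GeneRecord(
                        contig_id=feat.seqid,
                        start=feat.start - 1,
                        end=feat.end,
                        strand=feat.strand,
                        locus_tag=feat.attributes["locus_tag"][0],
                        protein_accession=feat.attributes["protein_id"][0],
                        product_name=feat.attributes["product"][0],
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FeatureTableParseError(path, line_no, str(exc)) from None
    return records


def read_feature_table(path, dialect: str = "tsv") -> list[GeneRecord]:
    """Read a genome annotation into sorted :class:`GeneRecord` objects.

    Parameters
    ----------
    path : path-like
        Annotation file.
    dialect : {"tsv", "gff3"}
        On-disk format.  Both use 1-based inclusive coordinates and yield
        identical record lists for equivalent content.

    Returns
    -------
    list of GeneRecord, sorted by (contig_id, start).
    """
    path = Path(path)
    if dialect == "tsv":
        records = _parse_tsv(path)
    elif dialect == "gff3":
        records = _parse_gff3(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'gff3')")
    records.sort(key=lambda r: (r.contig_id, r.start))
    seen = set()
    for rec in records:
        key = (rec.contig_id, rec.locus_tag)
        if key in seen:
            raise ValueError(f"duplicate locus tag {key} in {path}")
        seen.add(key)
    return records


def write_feature_table(records: Iterable[GeneRecord], path) -> None:
    """Write the TSV dialect (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.contig_id,
                        str(rec.start + 1),
                        str(rec.end),
                        rec.strand,
                        rec.locus_tag,
                        rec.protein_accession,
                        rec.product_name,
                    ]
                )
                + "\n"
            )


def write_gff3(records: Iterable[GeneRecord], path) -> None:
    """Write the annotation as GFF3 CDS features with product attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = (
                f"ID=cds-{rec.locus_tag};locus_tag={rec.locus_tag};"
                f"protein_id={rec.protein_accession};product={rec.product_name}"
            )
            fh.write(
                "\t".join(
                    [
                        rec.contig_id,
                        "cappscan",
                        "CDS",
                        str(rec.start + 1),
                        str(rec.end),
                        ".",
                        rec.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def extract_neighborhood(
    genes: Sequence[GeneRecord],
    focal_accession: str,
    window: int = DEFAULT_WINDOW,
    orient: bool = True,
) -> Neighborhood:
    """Extract the +/-``window`` gene neighborhood around a focal accession.

    Genes must be sorted by (contig_id, start).  Up to ``window`` genes are
    returned per side, truncated at contig boundaries.  With ``orient=True``
    (default) the position axis follows the focal gene's reading direction:
    on a minus-strand focal gene the genomically-right neighbor carries
    position -1.  ``orient=False`` keeps raw genomic order.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    hits = [i for i, g in enumerate(genes) if g.protein_accession == focal_accession]
    if not hits:
        raise FocalLookupError(f"focal accession {focal_accession!r} not found")
    if len(hits) > 1:
        raise FocalLookupError(
            f"focal accession {focal_accession!r} occurs {len(hits)} times; expected once"
        )
    idx = hits[0]
    focal = genes[idx]
    neighbors: list[tuple[int, GeneRecord]] = []
    for offset in range(1, window + 1):
        left = idx - offset
        if left >= 0 and genes[left].contig_id == focal.contig_id:
            neighbors.append((-offset, genes[left]))
        right = idx + offset
        if right < len(genes) and genes[right].contig_id == focal.contig_id:
            neighbors.append((offset, genes[right]))
    if orient and focal.strand == "-":
        neighbors = [(-p, rec) for p, rec in neighbors]
    return Neighborhood(focal=focal, neighbors=neighbors, window=window)


def extract_neighborhoods(
    genes: Sequence[GeneRecord],
    focal_accessions: Iterable[str],
    window: int = DEFAULT_WINDOW,
    orient: bool = True,
) -> list[Neighborhood]:
    """One :class:`Neighborhood` per focal accession; windows are independent
    and never merged even when they overlap."""
    return [extract_neighborhood(genes, acc, window=window, orient=orient) for acc in focal_accessions]


def write_regions(neighborhoods: Iterable[Neighborhood], path) -> None:
    with open(path, "w") as fh:
        json.dump([n.to_dict() for n in neighborhoods], fh, indent=1)
        fh.write("\n")


def read_regions(path) -> list[Neighborhood]:
    with open(path) as fh:
        return [Neighborhood.from_dict(d) for d in json.load(fh)]
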