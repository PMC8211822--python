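import numpy as np
import pytest

from cappscan.neighborhood import GeneRecord, write_feature_table
from cappscan.synthetic import (
    DEFAULT_BACKGROUND_POOL,
    SyntheticGenomeSpec,
    generate_genome,
    two_family_dataset,
)

CAPP_NAME = "CRISPR-associated primase-polymerase CAPP"
CAS1_NAME = "CRISPR-associated endonuclease Cas1"
CAS2_NAME = "CRISPR-associated protein Cas2"


def build_contig(names_by_rank, n_genes=50, contig="c1", strand_by_rank=None, seed=0):
    """Explicit 50-gene contig: background names except at the given ranks.

    ``names_by_rank`` maps 0-based gene rank -> product name.  Deterministic
    coordinates; strand '+' unless overridden.
    """
    rng = np.random.default_rng(seed)
    records = []
    pos = 0
    strand_by_rank = strand_by_rank or {}
    for i in range(n_genes):
        pos += 50
        length = 900
        name = names_by_rank.get(i) or DEFAULT_BACKGROUND_POOL[
            int(rng.integers(0, len(DEFAULT_BACKGROUND_POOL)))
        ]
        records.append(
            GeneRecord(
                contig_id=contig,
                start=pos,
                end=pos + length,
                strand=strand_by_rank.get(i, "+"),
                locus_tag=f"{contig}_g{i + 1:04d}",
                protein_accession=f"{contig}_P{i + 1:04d}",
                product_name=name,
            )
        )
        pos += length
    return records


@pytest.fixture(scope="session")
def planted_genome(tmp_path_factory):
    """Three-contig genome with one planted [CAPP, Cas1, Cas2] operon each."""
    outdir = tmp_path_factory.mktemp("genome")
    spec = SyntheticGenomeSpec(n_contigs=3, genes_per_contig=50, seed=11)
    paths, manifest = generate_genome(spec, outdir)
    return paths, manifest


@pytest.fixture(scope="session")
def two_family_alignment():
    """2x8 protein family alignment, 200 sites, separation 1.0, known truth."""
    return two_family_dataset(n_per_family=8, n_sites=200, separation=1.0, seed=5)


@pytest.fixture()
def central_focal_table(tmp_path):
    """50-gene contig with a CAPP/Cas1/Cas2 operon starting at rank 24."""
    records = build_contig({24: CAPP_NAME, 25: CAS1_NAME, 26: CAS2_NAME})
    path = tmp_path / "features.tsv"
    write_feature_table(records, path)
    return path, records[24].protein_accession
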