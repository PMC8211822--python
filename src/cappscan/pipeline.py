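"""End-to-end orchestration: simulate -> neighborhoods -> heatmap -> tree -> classify.

A :class:`PipelineConfig` (YAML on disk) names the four inputs — feature
table, focal accession list, protein alignment, domain table — plus the
window size, keyword list, bootstrap replicate count and master seed.  The
run directory receives every stage's serialized output (regions.json,
heatmap.tsv, tree.nwk, assignments.tsv), a config snapshot, and a run log,
so each stage can be re-run standalone on the previous stage's output.
Re-running the same config on the same inputs is byte-reproducible.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from cappscan import association, classify, neighborhood, phylo, synthetic
from cappscan.errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    features: str
    focal_list: str
    alignment: str
    domains: str
    outdir: str
    dialect: str = "tsv"
    window: int = 20
    keywords: list[str] = field(default_factory=lambda: list(association.DEFAULT_KEYWORDS))
    first_filter: str = association.DEFAULT_FIRST_FILTER
    second_filter: str = association.DEFAULT_SECOND_FILTER
    bootstrap: int = 100
    seed: int = 0
    seed_a: str | None = None
    seed_b: str | None = None
    orient: bool = True

    def validate(self) -> None:
        if self.window < 1:
            raise ConfigError("window must be >= 1")
        if self.bootstrap < 1:
            raise ConfigError("bootstrap must be >= 1")
        if self.dialect not in ("tsv", "gff3"):
            raise ConfigError(f"unknown dialect {self.dialect!r}")
        for name in ("features", "focal_list", "alignment", "domains"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name} path does not exist: {p}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns the paths of the five run-directory outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cappscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    paths: dict[str, Path] = {"log": log_path, "config": outdir / "config.yaml"}
    try:
        config.to_yaml(paths["config"])

        stage = "neighborhoods"
        genes = neighborhood.read_feature_table(config.features, dialect=config.dialect)
        focal = [
            line.strip()
            for line in Path(config.focal_list).read_text().splitlines()
            if line.strip()
        ]
        logger.info("read %d gene records, %d focal accessions", len(genes), len(focal))
        regions = neighborhood.extract_neighborhoods(
            genes, focal, window=config.window, orient=config.orient
        )
        paths["regions"] = outdir / "regions.json"
        neighborhood.write_regions(regions, paths["regions"])

        stage = "heatmap"
        validated = [
            r
            for r in regions
            if association.validate_region(r, config.first_filter, config.second_filter)
        ]
        logger.info("%d/%d regions pass keyword validation", len(validated), len(regions))
        matrix = association.build_occurrence_matrix(validated, config.keywords)
        paths["heatmap"] = outdir / "heatmap.tsv"
        association.write_heatmap_table(matrix, paths["heatmap"])

        stage = "tree"
        aln = phylo.MultipleAlignment.from_fasta(config.alignment)
        tree, supports = phylo.bootstrap_support(
            aln, n_replicates=config.bootstrap, seed=config.seed
        )
        logger.info(
            "NJ tree over %d leaves; %d internal edges with support", len(aln), len(supports)
        )
        paths["tree"] = outdir / "tree.nwk"
        phylo.write_newick(tree, paths["tree"])

        stage = "classify"
        domains = synthetic.read_domain_table(config.domains)
        arch = classify.architectures_from_table(domains)
        seed_a = config.seed_a or aln.ids[0]
        seed_b = config.seed_b or aln.ids[-1]
        assignments = classify.assign_classes(tree, seed_a, seed_b, arch)
        summary = classify.count_classes(assignments)
        logger.info("class counts: %s; type counts: %s",
                    summary["class_counts"], summary["type_counts"])
        for w in summary["warnings"]:
            logger.warning("classification conflict: %s", w)
        paths["assignments"] = outdir / "assignments.tsv"
        classify.write_assignments(assignments, paths["assignments"])
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return paths


def demo_inputs(outdir, seed: int = 0, n_genomes: int = 3) -> PipelineConfig:
    """Generate a small self-contained input set and a matching config.

    Used by the `run --demo` path and the worked example: synthetic genomes
    with planted [CAPP, Cas1, Cas2] operons, a two-family alignment, and a
    domain table covering the three CAPP_A architectures plus CAPP_B.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = synthetic.SyntheticGenomeSpec(
        n_contigs=n_genomes, genes_per_contig=50, seed=seed
    )
    paths, manifest = synthetic.generate_genome(spec, outdir / "genome")
    focal_path = outdir / "focal.txt"
    focal_path.write_text(
        "".join(f"{g['protein_accession']}\n" for g in manifest.focal_genes)
    )
    aln, fam_manifest = synthetic.two_family_dataset(
        n_per_family=8, n_sites=200, separation=1.0, seed=seed
    )
    aln_path = outdir / "alignment.fasta"
    aln.to_fasta(aln_path)
    fam_manifest.to_json(outdir / "families.json")
    arch_request = {}
    a_archs = [["TPR", "AEP", "PriCT"], ["RT", "AEP"], ["AEP", "Helicase"]]
    for i, pid in enumerate(aln.ids):
        arch_request[pid] = ["VirE_N"] if pid.startswith("B") else a_archs[i % 3]
    domains = synthetic.generate_domain_annotations(arch_request, seed=seed)
    dom_path = outdir / "domains.tsv"
    synthetic.write_domain_table(domains, dom_path)
    return PipelineConfig(
        features=str(paths["tsv"]),
        focal_list=str(focal_path),
        alignment=str(aln_path),
        domains=str(dom_path),
        outdir=str(outdir / "run"),
        seed=seed,
        seed_a="A01",
        seed_b="B01",
        bootstrap=100,
    )
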