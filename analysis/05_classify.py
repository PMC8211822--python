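"""Assign CAPP classes from the tree and CAPP_A types from domain tables.

Splits the homolog tree at the longest internal edge between the two seed
leaves into CAPP_A / CAPP_B, types the CAPP_A side by domain architecture,
and writes results/run/assignments.tsv with a printed summary.
"""

from pathlib import Path

from cappscan.classify import architectures_from_table, assign_classes, count_classes, write_assignments
from cappscan.phylo import read_newick
from cappscan.pipeline import PipelineConfig
from cappscan.synthetic import read_domain_table

ROOT = Path(__file__).resolve().parents[1]


def main():
    config = PipelineConfig.from_yaml(ROOT / "results" / "data" / "config.yaml")
    outdir = Path(config.outdir)
    tree = read_newick(outdir / "tree.nwk")
    arch = architectures_from_table(read_domain_table(config.domains))
    assignments = assign_classes(tree, config.seed_a, config.seed_b, arch)
    write_assignments(assignments, outdir / "assignments.tsv")
    summary = count_classes(assignments)
    print(f"{summary['n']} proteins classified")
    print(f"  classes: {summary['class_counts']}")
    print(f"  CAPP_A types: {summary['type_counts']}")
    for w in summary["warnings"]:
        print(f"  warning: {w}")
    print(f"wrote {outdir / 'assignments.tsv'}")


if __name__ == "__main__":
    main()
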