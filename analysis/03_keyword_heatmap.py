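"""Validate windows by the CRISPR/Cas1 keyword screen and build the
keyword x position occurrence matrix.

Reads results/run/regions.json, keeps the regions passing both keyword
filters, and writes results/run/heatmap.tsv (plus a PNG rendering).  Prints
the non-zero cells — on the planted genomes Cas1 sits at +1 and Cas2 at +2
of every validated region.
"""

from pathlib import Path

from cappscan.association import (
    build_occurrence_matrix,
    render_heatmap,
    validate_region,
    write_heatmap_table,
)
from cappscan.neighborhood import read_regions
from cappscan.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]


def main():
    config = PipelineConfig.from_yaml(ROOT / "results" / "data" / "config.yaml")
    outdir = Path(config.outdir)
    regions = read_regions(outdir / "regions.json")
    validated = [r for r in regions if validate_region(r, config.first_filter, config.second_filter)]
    print(f"{len(validated)}/{len(regions)} regions pass the "
          f"{config.first_filter!r} then {config.second_filter!r} screen")
    matrix = build_occurrence_matrix(validated, config.keywords)
    write_heatmap_table(matrix, outdir / "heatmap.tsv")
    render_heatmap(matrix, outdir / "heatmap.png")
    pct = matrix.percentages()
    nonzero = pct.loc[(pct != 0).any(axis=1), (pct != 0).any(axis=0)]
    print("non-zero occurrence cells (%):")
    print(nonzero.to_string())
    print(f"wrote {outdir / 'heatmap.tsv'} and heatmap.png")


if __name__ == "__main__":
    main()
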