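"""Extract the oriented 40-gene window around every focal CAPP hit.

Reads the feature table and focal list from step 01 and writes
results/run/regions.json.  Reports how many windows are complete (40
neighbors) versus truncated at contig edges.
"""

from collections import Counter
from pathlib import Path

from cappscan.neighborhood import extract_neighborhoods, read_feature_table, write_regions
from cappscan.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]


def main():
    config = PipelineConfig.from_yaml(ROOT / "results" / "data" / "config.yaml")
    genes = read_feature_table(config.features, dialect=config.dialect)
    focal = [l.strip() for l in Path(config.focal_list).read_text().splitlines() if l.strip()]
    regions = extract_neighborhoods(genes, focal, window=config.window)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_regions(regions, outdir / "regions.json")
    sizes = Counter(len(r.neighbors) for r in regions)
    print(f"{len(genes)} genes, {len(focal)} focal hits -> {len(regions)} neighborhoods")
    for size, count in sorted(sizes.items(), reverse=True):
        note = "full window" if size == 2 * config.window else "truncated at contig edge"
        print(f"  {count} windows with {size} neighbors ({note})")
    print(f"wrote {outdir / 'regions.json'}")


if __name__ == "__main__":
    main()
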