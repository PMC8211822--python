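"""Generate the synthetic study inputs with planted ground truth.

Writes under results/data/: annotated genomes (TSV + GFF3) with one planted
[CAPP, Cas1, Cas2] operon per contig, the focal accession list, a two-family
protein alignment (2 x 8 sequences, 200 sites, 1.0 expected subs/site
between families), a domain table covering the three CAPP_A architectures
plus CAPP_B, the truth manifests, and the pipeline config used by the later
steps.
"""

from pathlib import Path

from cappscan.pipeline import demo_inputs

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main():
    data = ROOT / "results" / "data"
    config = demo_inputs(data, seed=SEED, n_genomes=5)
    config.outdir = str(ROOT / "results" / "run")
    config.to_yaml(data / "config.yaml")
    print(f"inputs written under {data}")
    print(f"  features:  {config.features}")
    print(f"  focal:     {config.focal_list}")
    print(f"  alignment: {config.alignment}")
    print(f"  domains:   {config.domains}")
    print(f"  config:    {data / 'config.yaml'}")


if __name__ == "__main__":
    main()
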