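"""Regenerate the bundled synthetic fixtures in src/necroscan/data/.

The FASTA panel and species metadata are synthetic stand-ins produced by
necroscan.synthetic with seed 0; tests assert that the bundled files match
the generator output, so rerun this script after changing the generators.
"""

from pathlib import Path

from necroscan import synthetic

DATA = Path(__file__).resolve().parent.parent / "src" / "necroscan" / "data"

DEMO_CONFIG = """\
# Demo pipeline config: generates synthetic inputs, then runs every stage.
seed: 1
simulate:
  trajectory_mode: inactive
  n_frames: 300
number: {}
scan: {}
geometry: {}
trajectory: {}
"""


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    seqs, metadata = synthetic.make_ortholog_panel(seed=0)
    synthetic.write_fasta(seqs, DATA / "synthetic_orthologs.fasta")
    metadata.to_csv(DATA / "synthetic_species_metadata.tsv", sep="\t",
                    index=False)
    (DATA / "demo_config.yaml").write_text(DEMO_CONFIG)
    print(f"wrote {len(seqs)} sequences + metadata + demo config to {DATA}")


if __name__ == "__main__":
    main()
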