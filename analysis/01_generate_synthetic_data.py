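#!/usr/bin/env python
"""Generate the synthetic study datasets.

Builds the default study design — 72 HLA class I alleles, 100 eluted-ligand
scores per allele, 50 T-cell-epitope scores per allele (plus 45 validation
epitopes for six alleles), and one shared 10,000-peptide background scored
for every allele — and writes the self-describing fixture to
scratch/synthetic_data/.  Downstream drivers read from there.
"""

from pathlib import Path

from hla_thresholds import synthetic

SEED = 2021
DATA_DIR = Path(__file__).resolve().parents[1] / "scratch" / "synthetic_data"


def main() -> None:
    cfg = synthetic.SyntheticConfig(rng_seed=SEED)
    dataset = synthetic.generate(cfg)
    synthetic.write_fixture(dataset, DATA_DIR)
    breadths = [p.repertoire_breadth for p in dataset.profiles]
    print(f"wrote fixture to {DATA_DIR}")
    print(
        f"alleles: {cfg.n_alleles}; ligands/allele: {cfg.n_ligands_per_allele}; "
        f"epitopes/allele: {cfg.n_epitopes_per_allele}; background: {cfg.n_background}"
    )
    print(
        f"repertoire breadth spans {min(breadths):.4f}-{max(breadths):.4f} "
        f"({max(breadths) / min(breadths):.1f}-fold across alleles)"
    )


if __name__ == "__main__":
    main()
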