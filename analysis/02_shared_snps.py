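#!/usr/bin/env python
"""Identify reliable shared bi-allelic SNPs over the simulated panel.

Reads the panel written by 01_simulate_panels.py, applies the shared-SNP
definition (bi-allelic in both species, identical allele pair, MAF > 0.05
in each), and writes the table of shared sites with per-species "k/n"
frequency strings.
"""

from pathlib import Path

from transbalance.orthoshare import find_shared_snps, shared_snps_table
from transbalance.simdata import read_panel

OUT = Path("results")


def main() -> None:
    genes = read_panel(OUT / "panel")
    scans = [find_shared_snps(g) for g in genes]
    table = shared_snps_table(scans)
    table.to_csv(OUT / "02_shared_snps.tsv", sep="\t", index=False)
    n_genes_hit = table["gene_id_a"].nunique() if len(table) else 0
    print(f"{len(table)} shared SNPs in {n_genes_hit} of {len(genes)} genes")
    print(f"table -> {OUT / '02_shared_snps.tsv'}")


if __name__ == "__main__":
    main()
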