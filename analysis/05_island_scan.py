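#!/usr/bin/env python
"""Compositional genomic-island scan on a simulated genome.

Simulates a genome with one planted island (G+C shift +0.15, skewed
synonymous codon usage), flags foreign genes (|G+C z| > 1.5 AND codon
chi-square P < 0.05), scans with a ten-gene window requiring four or
more foreign genes, and merges neighboring hits.  Writes the island
tracks (GFF3 + BED) and the per-gene statistics table under results/.
"""

from pathlib import Path

from strainflux.islands import (
    compose_genes,
    foreign_flags,
    per_gene_table,
    scan_islands,
    write_islands_bed,
    write_islands_gff3,
)
from strainflux.models import AnalysisConfig
from strainflux.synthetic_data import simulate_genome

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = AnalysisConfig()
    seq, gene_table, truth = simulate_genome(150, [(60, 12, 0.15, 8.0)], seed=SEED)
    genes = compose_genes(seq, gene_table)
    flags = foreign_flags(genes, config=config)
    calls = scan_islands(flags, genes, config)

    write_islands_gff3(calls, OUT / "islands.gff3")
    write_islands_bed(calls, OUT / "islands.bed")
    per_gene_table(genes, config).to_csv(OUT / "island_genes.tsv", sep="\t", index=False)

    print(f"{sum(flags)}/{len(genes)} genes flagged foreign")
    print(f"planted island: genes {truth.island_spans[0]}")
    for i, c in enumerate(calls, start=1):
        print(f"island_{i}: genes [{c.first_gene_index}, {c.last_gene_index}), "
              f"span {c.genomic_span[0]}-{c.genomic_span[1]} bp, "
              f"{c.n_foreign} foreign genes")


if __name__ == "__main__":
    main()
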