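#!/usr/bin/env python
"""Generate the synthetic study bundle used by the downstream analyses.

Emulates the study design: a bacterial tRNA pool (37 anticodons reading
all 61 sense codons), 1,000 coding genes whose highly expressed subset
is selected toward tRNA availability (beta = 2), protein/mRNA abundance
tables with protein-per-transcript coupled to gene tAI (gamma = 2), and
50,000 tRNA-seq reads.  Everything is written in the external formats
(FASTA, kallisto-layout TSV, PaxDb-like TSV, samtools-depth TSV) under
results/sim/.
"""

from pathlib import Path

from trnacodon.io_formats import write_fasta, write_trna_set
from trnacodon.synthetic_data import SimConfig, simulate_genes, simulate_reads, simulate_trna_pool
from trnacodon.trna_quant import assign_reads, depth_from_reads, tpm_from_counts

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED, beta=2.0, gamma=2.0, n_genes=1000, n_reads=50_000)
    trnas, pool = simulate_trna_pool(cfg)
    genes = simulate_genes(cfg, trnas, pool)
    reads = simulate_reads(pool, trnas, cfg)

    write_trna_set(trnas, OUT / "trnas.fasta")
    write_fasta(genes.cds, OUT / "cds.fasta")
    genes.mrna.write(OUT / "mrna_abundance.tsv")
    genes.protein.to_csv(OUT / "protein.tsv", sep="\t", header=True)
    genes.family_truth.to_csv(OUT / "planted_truth.tsv", sep="\t", index=False)
    genes.gene_truth.to_csv(OUT / "gene_truth.tsv", sep="\t", index=False,
                            float_format="%.6f")

    counts, dropped = assign_reads(reads, trnas)
    tpm_from_counts(counts, {t.id: len(t.sequence) for t in trnas}).write(
        OUT / "trna_abundance.tsv"
    )
    profiles = depth_from_reads(reads, trnas)
    with open(OUT / "depth.tsv", "w") as fh:
        for tid in sorted(profiles):
            for pos, depth in enumerate(profiles[tid], start=1):
                fh.write(f"{tid}\t{pos}\t{depth:.4f}\n")
    with open(OUT / "methylation_sites.tsv", "w") as fh:
        for t in trnas:
            for site in t.methylation_sites:
                fh.write(f"{t.id}\t{site}\tsynthetic\n")

    planted_pool = {t.id: pool.values[t.anticodon] for t in trnas}
    with open(OUT / "planted_pool.tsv", "w") as fh:
        fh.write("trna_id\tanticodon\tplanted_tpm\tcopy_number\n")
        for t in trnas:
            fh.write(f"{t.id}\t{t.anticodon}\t{planted_pool[t.id]:.4f}\t{t.copy_number}\n")

    print(f"wrote synthetic bundle to {OUT}")
    print(f"  {len(trnas)} unique tRNAs, {cfg.n_genes} genes, "
          f"{len(reads)} reads retained ({dropped} dropped in assignment)")


if __name__ == "__main__":
    main()
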