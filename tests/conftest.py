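import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from trnacodon.io_formats import TrnaSpecies
from trnacodon.synthetic_data import (
    SimConfig,
    simulate_genes,
    simulate_reads,
    simulate_trna_pool,
)
from trnacodon.trna_quant import TrnaAbundance, assign_reads, tpm_from_counts


def make_trna(anticodon: str, copies: int = 1, sites: tuple[int, ...] = ()) -> TrnaSpecies:
    """A synthetic tRNA with the anticodon embedded at sites 34-36."""
    body = "G" * 33 + anticodon + "G" * 37
    return TrnaSpecies(
        id=f"trna-{anticodon}",
        anticodon=anticodon,
        amino_acid="Xaa",
        sequence=body + "CCA",
        copy_number=copies,
        methylation_sites=sites,
    )


@pytest.fixture
def thr_trnas() -> list[TrnaSpecies]:
    """The two-tRNA Thr toy: GGU (reads ACC/ACU) and UGU (reads ACA/ACG/+mod)."""
    return [make_trna("GGU"), make_trna("UGU")]


@pytest.fixture(scope="session")
def study_run():
    """One full synthetic study at the default conditions (seed 1).

    beta=2, gamma=2, 1000 genes, 50k reads: the planted pool, genes,
    reads, and the read-estimated tpm abundance.
    """
    cfg = SimConfig(seed=1, beta=2.0, gamma=2.0, n_genes=1000, n_reads=50_000)
    trnas, pool = simulate_trna_pool(cfg)
    genes = simulate_genes(cfg, trnas, pool)
    reads = simulate_reads(pool, trnas, cfg)
    counts, _dropped = assign_reads(reads, trnas)
    table = tpm_from_counts(counts, {t.id: len(t.sequence) for t in trnas})
    estimated = TrnaAbundance.from_tpm(table, trnas, source="reads")
    return {
        "config": cfg,
        "trnas": trnas,
        "pool": pool,
        "genes": genes,
        "reads": reads,
        "abundance_table": table,
        "estimated": estimated,
    }
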