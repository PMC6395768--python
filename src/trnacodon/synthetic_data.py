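"""Seeded generators for the full analysis chain.

The generators emulate the study design the pipeline assumes: a
bacterial tRNA pool with anticodon-level abundances and correlated gene
copy numbers; coding sequences whose codon choice in highly expressed
genes (HEGs) is selected toward tRNA availability while lowly expressed
genes (LEGs) follow mutational GC3 bias; mRNA tpm and protein ppm with
protein-per-transcript coupled to gene tAI; and short reads drawn from
the tRNA sequences with optional truncation at annotated methylation
sites (mimicking reverse-transcriptase hard-stops).

Codon choice in HEGs concentrates first on the codons with the highest
total tRNA availability (weight ``availability^beta``) and, among
codons whose availability is *exactly* tied because they share a reader
set - the situation the two-step preference predictor is built for -
mass is concentrated on the codon with cognate decoding, reflecting the
higher efficiency of cognate pairing.  The planted truth per family is
therefore the lexicographic (availability, cognate abundance) argmax.

All randomness flows from a single seed; each stage draws from a
deterministically derived substream so stages are independently
reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_model import SENSE_CODONS, aa3_of_codon, codon_families, reverse_complement
from .io_formats import AbundanceTable, TrnaSpecies
from .pairing import PairingRules, default_rules
from .tai import gene_tai, tai_weights
from .trna_quant import TrnaAbundance, codon_availability

logger = logging.getLogger(__name__)

#: canonical methylation-susceptible sites (1-based linear positions)
METHYLATION_CANDIDATE_SITES = (18, 32, 34, 37, 46, 54)

TRNA_LENGTH = 76  # mature length incl. 3' CCA
_ANTICODON_START = 33  # 0-based; anticodon occupies sites 34-36


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators."""

    seed: int = 0
    n_genes: int = 1000
    heg_fraction: float = 0.3
    beta: float = 2.0  # selection strength coupling HEG codon choice to availability
    gc_bias: float = 0.5  # mutational GC3 bias driving LEG codon choice
    pool_mu: float = 9.0  # log-scale mean of anticodon abundance
    pool_sigma: float = 1.0  # log-scale sd of anticodon abundance
    copy_link: float = 0.8  # correlation between copy number and abundance
    gamma: float = 2.0  # coupling of protein-per-transcript to gene tAI
    read_length: int = 33
    n_reads: int = 50_000
    p_stop: float = 0.0  # truncation probability at an annotated methylation site
    min_gene_codons: int = 100
    max_gene_codons: int = 300

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0 < self.gc_bias < 1:
            raise ValueError("gc_bias must be in (0, 1)")
        if not 0 <= self.copy_link <= 1:
            raise ValueError("copy_link must be in [0, 1]")
        if not 0 <= self.p_stop <= 1:
            raise ValueError("p_stop must be in [0, 1]")
        if not 0 < self.heg_fraction < 1:
            raise ValueError("heg_fraction must be in (0, 1)")
        if self.read_length > TRNA_LENGTH:
            raise ValueError("read_length exceeds tRNA length")


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stage,)))


def default_anticodon_set() -> tuple[str, ...]:
    """A minimal anticodon repertoire reading every sense codon.

    Per 4-fold family a U34 and a G34 anticodon; per C/U-ending duet a
    single G34; per A/G-ending duet a U34 and a C34; G34 + U34 for Ile;
    plus the Met and Trp readers.  Chosen so the two-step predictor's
    cognate tie-break is exercised in every family with a structural
    availability tie.
    """
    antis: set[str] = {"CAU", "CCA"}  # Met, Trp readers
    for fam in codon_families():
        prefix = fam.codons[0][:2]
        thirds = {c[2] for c in fam.codons}
        if fam.fold >= 3:
            antis.add(reverse_complement(prefix + "A"))  # U34
            antis.add(reverse_complement(prefix + "C"))  # G34
        elif thirds == {"C", "U"}:
            antis.add(reverse_complement(prefix + "C"))  # G34 reads both
        else:  # {A, G} duet
            antis.add(reverse_complement(prefix + "A"))  # U34
            antis.add(reverse_complement(prefix + "G"))  # C34
    return tuple(sorted(antis))


def _random_trna_sequence(rng: np.random.Generator, anticodon: str, existing: set[str]) -> str:
    bases = np.array(list("ACGU"))
    for _ in range(100):
        head = "".join(rng.choice(bases, _ANTICODON_START))
        tail_len = TRNA_LENGTH - _ANTICODON_START - 3 - 3
        tail = "".join(rng.choice(bases, tail_len))
        seq = head + anticodon + tail + "CCA"
        if seq not in existing and not any(seq in s or s in seq for s in existing):
            return seq
    raise RuntimeError("could not generate a unique tRNA sequence")


def simulate_trna_pool(
    config: SimConfig, rules: PairingRules | None = None
) -> tuple[list[TrnaSpecies], TrnaAbundance]:
    """One tRNA per default anticodon, with abundances and copy numbers.

    Abundance ~ LogNormal(pool_mu, pool_sigma), normalized to tpm scale
    (sum 1e6).  Copy number is a rank-preserving discretization of
    abundance blended with independent noise by ``copy_link``.  Raises
    if the anticodon set leaves any sense codon unreadable under the
    rules.
    """
    rules = rules if rules is not None else default_rules()
    rng = _rng(config, stage=1)
    anticodons = default_anticodon_set()
    n = len(anticodons)

    raw = rng.lognormal(config.pool_mu, config.pool_sigma, n)
    abundance = 1e6 * raw / raw.sum()

    z = (np.log(raw) - np.log(raw).mean()) / (np.log(raw).std() or 1.0)
    noise = rng.standard_normal(n)
    latent = config.copy_link * z + math.sqrt(1.0 - config.copy_link**2) * noise
    rank = np.argsort(np.argsort(latent))
    frac = rank / max(n - 1, 1)
    copies = 1 + np.floor(7 * frac**2).astype(int)

    trnas: list[TrnaSpecies] = []
    existing: set[str] = set()
    for i, anticodon in enumerate(anticodons):
        seq = _random_trna_sequence(rng, anticodon, existing)
        existing.add(seq)
        n_sites = int(rng.integers(0, len(METHYLATION_CANDIDATE_SITES) + 1))
        sites = tuple(
            sorted(rng.choice(METHYLATION_CANDIDATE_SITES, size=n_sites, replace=False).tolist())
        )
        trnas.append(
            TrnaSpecies(
                id=f"trna-{anticodon}",
                anticodon=anticodon,
                amino_acid=aa3_of_codon(reverse_complement(anticodon)) or "Xaa",
                sequence=seq,
                copy_number=int(copies[i]),
                methylation_sites=sites,
            )
        )
    pool = TrnaAbundance(dict(zip(anticodons, abundance.tolist())), unit="tpm", source="planted")

    avail, _ = codon_availability(pool, trnas, rules)
    unreadable = [c for c in SENSE_CODONS if avail[c] <= 0]
    if unreadable:
        raise ValueError(f"anticodon set leaves codons unreadable: {unreadable}")
    return trnas, pool


def _heg_distribution(
    avail: Mapping[str, float], cognate: Mapping[str, float], codons: Sequence[str], beta: float
) -> np.ndarray:
    """Selection-weighted codon distribution within one family.

    Base weight availability^beta; mass of an exactly-tied availability
    group is redistributed within the group proportional to
    (cognate + kappa)^beta, kappa = quarter of the group's max cognate.
    """
    a = np.array([avail[c] for c in codons])
    cog = np.array([cognate[c] for c in codons])
    base = a**beta
    p = base.copy()
    remaining = list(range(len(codons)))
    while remaining:
        i = remaining[0]
        group = [j for j in remaining if math.isclose(a[j], a[i], rel_tol=1e-9)]
        if len(group) > 1:
            kappa = 0.25 * cog[group].max()
            if kappa <= 0:
                kappa = 1.0
            within = (cog[group] + kappa) ** beta
            p[group] = base[group].sum() * within / within.sum()
        remaining = [j for j in remaining if j not in group]
    return p / p.sum()


def _planted_optimum(
    avail: Mapping[str, float], cognate: Mapping[str, float], codons: Sequence[str]
) -> tuple[str, bool]:
    """Lexicographic (availability, cognate) argmax; flags residual ties."""
    best_a = max(avail[c] for c in codons)
    tier = [c for c in codons if math.isclose(avail[c], best_a, rel_tol=1e-9)]
    best_c = max(cognate[c] for c in tier)
    winners = sorted(c for c in tier if math.isclose(cognate[c], best_c, rel_tol=1e-9))
    return winners[0], len(winners) > 1


@dataclass
class SimulatedGenes:
    """Synthetic CDS set with matched expression tables and planted truth."""

    cds: list[tuple[str, str]]  # (gene_id, RNA sequence)
    protein: pd.Series  # ppm per gene
    mrna: AbundanceTable  # mRNA tpm table
    family_truth: pd.DataFrame  # family, planted_codon, ambiguous
    gene_truth: pd.DataFrame  # gene_id, is_heg, tai, n_codons


def simulate_genes(
    config: SimConfig,
    trnas: Sequence[TrnaSpecies],
    pool: TrnaAbundance,
    rules: PairingRules | None = None,
) -> SimulatedGenes:
    """Draw HEG/LEG coding sequences and coupled expression tables."""
    if config.beta < 0:
        raise ValueError("beta must be >= 0")
    rules = rules if rules is not None else default_rules()
    rng = _rng(config, stage=2)
    families = codon_families()
    avail, cognate = codon_availability(pool, trnas, rules)

    max_fold = max(f.fold for f in families)
    lookup = np.full((len(families), max_fold), "", dtype="<U3")
    heg_cdf = np.ones((len(families), max_fold))
    leg_cdf = np.ones((len(families), max_fold))
    truth_rows = []
    for fi, fam in enumerate(families):
        lookup[fi, : fam.fold] = fam.codons
        p_heg = _heg_distribution(avail, cognate, fam.codons, config.beta)
        w_leg = np.array([config.gc_bias if c[2] in "GC" else 1 - config.gc_bias for c in fam.codons])
        p_leg = w_leg / w_leg.sum()
        heg_cdf[fi, : fam.fold] = np.cumsum(p_heg)
        leg_cdf[fi, : fam.fold] = np.cumsum(p_leg)
        planted, ambiguous = _planted_optimum(avail, cognate, fam.codons)
        truth_rows.append({"family": fam.label, "planted_codon": planted, "ambiguous": ambiguous})
    family_truth = pd.DataFrame(truth_rows)

    model = tai_weights(pool, trnas, rules)
    n_heg = int(round(config.heg_fraction * config.n_genes))
    is_heg = np.zeros(config.n_genes, dtype=bool)
    is_heg[:n_heg] = True

    cds: list[tuple[str, str]] = []
    tais = np.zeros(config.n_genes)
    lengths = rng.integers(config.min_gene_codons, config.max_gene_codons + 1, config.n_genes)
    for g in range(config.n_genes):
        L = int(lengths[g])
        fam_idx = rng.integers(0, len(families), L)
        u = rng.random(L)
        cdf = heg_cdf if is_heg[g] else leg_cdf
        slot = (u[:, None] > cdf[fam_idx]).sum(axis=1)
        codons = lookup[fam_idx, slot]
        gene_id = f"g{g:05d}"
        cds.append((gene_id, "AUG" + "".join(codons) + "UAA"))
        counts: dict[str, float] = {"AUG": 1.0}
        flat = fam_idx * max_fold + slot
        for idx, n in zip(*np.unique(flat, return_counts=True)):
            codon = lookup[idx // max_fold, idx % max_fold]
            counts[codon] = counts.get(codon, 0.0) + float(n)
        tais[g] = gene_tai(model, counts)

    gene_ids = [gid for gid, _ in cds]
    mrna_raw = rng.lognormal(1.5, 1.0, config.n_genes)
    tpm = 1e6 * mrna_raw / mrna_raw.sum()
    nt_len = 3.0 * (lengths + 2)
    mrna = AbundanceTable(
        pd.DataFrame(
            {
                "target_id": gene_ids,
                "length": nt_len,
                "eff_length": nt_len,
                "est_counts": mrna_raw * 100.0,
                "tpm": tpm,
            }
        )
    )
    noise = rng.lognormal(0.0, 0.3, config.n_genes)
    ppm_raw = tpm * np.exp(config.gamma * (tais - tais.mean())) * noise
    ppm = pd.Series(
        1e6 * ppm_raw / ppm_raw.sum(), index=pd.Index(gene_ids, name="gene_id"), name="ppm"
    )
    gene_truth = pd.DataFrame(
        {"gene_id": gene_ids, "is_heg": is_heg, "tai": tais, "n_codons": lengths}
    )
    return SimulatedGenes(cds, ppm, mrna, family_truth, gene_truth)


def simulate_reads(
    pool: TrnaAbundance,
    trnas: Sequence[TrnaSpecies],
    config: SimConfig,
) -> list[str]:
    """Short reads sampled from tRNA sequences proportional to abundance.

    Uniform start positions; with probability ``p_stop`` a read crossing
    an annotated methylation site is truncated at that site (reads
    falling below the 25 nt retained-read floor are dropped).
    """
    rng = _rng(config, stage=3)
    weights = np.array([pool.values.get(t.anticodon, 0.0) for t in trnas], dtype=float)
    per_anticodon = {}
    for t in trnas:
        per_anticodon[t.anticodon] = per_anticodon.get(t.anticodon, 0) + 1
    weights = weights / np.array([per_anticodon[t.anticodon] for t in trnas])
    if weights.sum() <= 0:
        raise ValueError("pool has zero total abundance")
    p = weights / weights.sum()
    if config.n_reads == 0:
        return []
    choices = rng.choice(len(trnas), size=config.n_reads, p=p)
    highs = np.array([len(trnas[ti].sequence) - config.read_length + 1 for ti in choices])
    starts = rng.integers(0, highs)
    reads: list[str] = []
    for ti, start in zip(choices, starts):
        t = trnas[ti]
        start = int(start)  # 0-based
        end = start + config.read_length  # exclusive
        if config.p_stop > 0:
            for site in t.methylation_sites:  # ascending 1-based
                if start + 1 <= site < end and rng.random() < config.p_stop:
                    end = site  # read terminates at the modified base
                    break
        read = t.sequence[start:end]
        if len(read) >= 25:
            reads.append(read)
    return reads
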