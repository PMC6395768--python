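"""Genetic-code machinery and codon-usage statistics.

Everything here works on the bacterial genetic code (NCBI translation
table 11) over the RNA alphabet.  The unit of analysis is the *codon
family*: a group of synonymous codons after splitting the three 6-fold
degenerate amino acids (Leu, Arg, Ser) into a 2-fold and a 4-fold
family, following the convention of codon-usage software that keys
families on the first two codon positions.  Met and Trp are single-codon
and carry no synonymous signal, so they are excluded from families
(21 families covering 59 sense codons).

Provided statistics:

* RSCU  - relative synonymous codon usage, X_i * |F| / sum_F X
* GC3s  - G+C fraction at synonymously variable third positions
* Nc    - Wright's effective number of codons (with f(GC3s), its
          expectation under mutation alone)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

RNA_BASES = "ACGU"

_TABLE = CodonTable.unambiguous_rna_by_id[11]

#: codon -> one-letter amino acid, sense codons only
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(rna: str) -> str:
    """Reverse complement over the RNA alphabet."""
    return rna.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str | None:
    """One-letter amino acid for a sense codon, None for a stop."""
    return GENETIC_CODE.get(codon)


def aa3_of_codon(codon: str) -> str | None:
    """Three-letter amino-acid code for a sense codon, None for a stop."""
    aa = GENETIC_CODE.get(codon)
    return _AA3[aa] if aa else None


@dataclass(frozen=True)
class CodonFamily:
    """A synonymous codon group after 6-fold splitting."""

    label: str
    amino_acid: str  # 3-letter code
    codons: tuple[str, ...]
    fold: int

    def __post_init__(self) -> None:
        if len(self.codons) != self.fold:
            raise ValueError(f"{self.label}: fold {self.fold} != {len(self.codons)} codons")


@lru_cache(maxsize=None)
def codon_families() -> tuple[CodonFamily, ...]:
    """The 21 synonymous families of translation table 11.

    6-fold amino acids are split by the first two codon bases into a
    2-fold and a 4-fold family; Met, Trp and stops are excluded.
    """
    by_aa: dict[str, list[str]] = {}
    for codon, aa in GENETIC_CODE.items():
        by_aa.setdefault(aa, []).append(codon)
    families: list[CodonFamily] = []
    for aa, codons in sorted(by_aa.items()):
        if aa in ("M", "W"):
            continue
        codons = sorted(codons)
        prefixes = {c[:2] for c in codons}
        if len(codons) == 6:
            for prefix in sorted(prefixes):
                group = tuple(c for c in codons if c.startswith(prefix))
                # prefix groups of a 6-fold aa are one duet and one quartet
                tag = "2fold" if len(group) == 2 else "4fold"
                families.append(CodonFamily(f"{_AA3[aa]}-{tag}", _AA3[aa], group, len(group)))
        else:
            families.append(
                CodonFamily(f"{_AA3[aa]}-{len(codons)}fold", _AA3[aa], tuple(codons), len(codons))
            )
    return tuple(sorted(families, key=lambda f: f.label))


@lru_cache(maxsize=None)
def family_of_codon() -> Mapping[str, CodonFamily]:
    """Codon -> its family (59 family codons; Met/Trp absent)."""
    return {c: f for f in codon_families() for c in f.codons}


def _clean_sequences(cds_sequences: Iterable[str] | str) -> list[str]:
    if isinstance(cds_sequences, str):
        cds_sequences = [cds_sequences]
    return [s.upper().replace("T", "U") for s in cds_sequences]


def count_codons(
    cds_sequences: Iterable[str] | str, *, lenient: bool = False
) -> dict[str, int]:
    """Count sense codons over one or more CDS.

    Stops are never counted.  Internal stops are an error unless
    ``lenient``; non-triplet sequences are an error (skipped with a
    warning under ``lenient``).  Returns a mapping with all 61 sense
    codons present (zero-filled).
    """
    counts = {c: 0 for c in SENSE_CODONS}
    for idx, seq in enumerate(_clean_sequences(cds_sequences)):
        if len(seq) % 3 != 0:
            if lenient:
                logger.warning("sequence %d length %d not divisible by 3; skipped", idx, len(seq))
                continue
            raise ValueError(f"sequence {idx}: length {len(seq)} not divisible by 3")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        internal_stops = [c for c in codons[:-1] if c in STOP_CODONS]
        if internal_stops and not lenient:
            raise ValueError(f"sequence {idx}: internal stop codon {internal_stops[0]}")
        for codon in codons:
            if codon in counts:
                counts[codon] += 1
            # stops (terminal or lenient-internal) and ambiguous triplets dropped
    return counts


def rscu(counts: Mapping[str, int | float]) -> dict[str, float]:
    """Relative synonymous codon usage per family codon.

    RSCU_i = X_i * |F| / sum_{j in F} X_j.  Families with zero total
    yield NaN for each member.
    """
    out: dict[str, float] = {}
    for fam in codon_families():
        total = sum(counts.get(c, 0) for c in fam.codons)
        for c in fam.codons:
            out[c] = counts.get(c, 0) * fam.fold / total if total > 0 else math.nan
    return out


def gc3s(cds_sequences: Iterable[str] | str) -> float:
    """G+C fraction at third positions of synonymously variable codons.

    Met, Trp and stop codons contribute to neither numerator nor
    denominator.
    """
    fam = family_of_codon()
    n = gc = 0
    for seq in _clean_sequences(cds_sequences):
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon in fam:
                n += 1
                gc += codon[2] in "GC"
    if n == 0:
        raise ValueError("no synonymously variable codons in input")
    return gc / n


# ---------------------------------------------------------------------------
# Wright's effective number of codons

# intact-6-fold layout: degeneracy class -> (number of families, members)
def _nc_layout(split_sixfold: bool) -> dict[int, list[tuple[str, ...]]]:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in GENETIC_CODE.items():
        by_aa.setdefault(aa, []).append(codon)
    layout: dict[int, list[tuple[str, ...]]] = {}
    if split_sixfold:
        for f in codon_families():
            layout.setdefault(f.fold, []).append(f.codons)
    else:
        for aa, codons in by_aa.items():
            if aa in ("M", "W"):
                continue
            layout.setdefault(len(codons), []).append(tuple(sorted(codons)))
    return layout


def _family_homozygosity(counts: Mapping[str, int | float], codons: Sequence[str]) -> tuple[float, int] | None:
    """Codon homozygosity F = (n * sum p^2 - 1)/(n - 1); None when n <= 1."""
    xs = np.array([counts.get(c, 0) for c in codons], dtype=float)
    n = xs.sum()
    if n <= 1:
        return None
    p = xs / n
    return (n * float(np.sum(p * p)) - 1.0) / (n - 1.0), int(n)


def nc(
    counts: Mapping[str, int | float],
    *,
    split_sixfold: bool = False,
    min_codons: int = 30,
) -> float:
    """Wright's effective number of codons for a single gene.

    Class-averaged homozygosities; Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6
    under the intact layout (the ``split_sixfold`` layout uses
    2 + 12/F2 + 1/F3 + 8/F4).  A missing 3-fold class (no countable Ile)
    borrows (1/F2 + 1/F4)/2; any other missing class yields NaN.  The
    result is clamped to [20, 61].  Genes with fewer than ``min_codons``
    countable codons yield NaN with a warning.
    """
    layout = _nc_layout(split_sixfold)
    total = sum(counts.get(c, 0) for fams in layout.values() for f in fams for c in f)
    if total < min_codons:
        logger.warning("only %s countable codons (< %d); Nc not computed", total, min_codons)
        return math.nan
    if total < 100:
        logger.info("gene has %s sense codons (<100); Nc estimate may be noisy", total)
    fbar: dict[int, float] = {}
    for k, fams in layout.items():
        fs = [r[0] for f in fams if (r := _family_homozygosity(counts, f)) is not None]
        if fs and sum(fs) > 0:
            fbar[k] = float(np.mean(fs))
    terms = {k: len(fams) for k, fams in layout.items()}
    value = 2.0
    for k, n_fam in terms.items():
        if k in fbar and fbar[k] > 0:
            value += n_fam / fbar[k]
        elif k == 3 and 2 in fbar and 4 in fbar and fbar[2] > 0 and fbar[4] > 0:
            value += n_fam * (1.0 / fbar[2] + 1.0 / fbar[4]) / 2.0
        else:
            return math.nan
    return float(min(61.0, max(20.0, value)))


def expected_nc(gc3s_value: float) -> float:
    """Wright's expected Nc under mutation alone: f(s) = 2 + s + 29/(s^2 + (1-s)^2)."""
    s = float(gc3s_value)
    if s <= 0.0 or s >= 1.0:
        logger.warning("GC3s=%g outside (0,1); clamped", s)
        s = min(max(s, 1e-6), 1.0 - 1e-6)
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)
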