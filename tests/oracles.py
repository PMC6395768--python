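"""Independent reference implementations used only as test oracles.

These deliberately do not import the library's own computations: the
genetic code comes straight from Biopython and the formulas are written
out directly, so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Data import CodonTable

_CODE = CodonTable.unambiguous_rna_by_id[11].forward_table


def oracle_nc(counts: dict[str, float], *, split_sixfold: bool = False) -> float:
    """Direct-formula effective number of codons (Wright).

    Same conventions as the pipeline's definition (class-averaged
    homozygosities, borrowed 3-fold term, [20, 61] clamp) but written
    from scratch against Biopython's code table.
    """
    groups: dict[str, list[str]] = {}
    for codon, aa in _CODE.items():
        groups.setdefault(aa, []).append(codon)
    families: list[list[str]] = []
    for aa, codons in groups.items():
        if aa in ("M", "W"):
            continue
        if split_sixfold and len(codons) == 6:
            for prefix in sorted({c[:2] for c in codons}):
                families.append([c for c in codons if c[:2] == prefix])
        else:
            families.append(codons)

    class_f: dict[int, list[float]] = {}
    for fam in families:
        xs = [float(counts.get(c, 0)) for c in fam]
        n = sum(xs)
        if n <= 1:
            continue
        f = (n * sum((x / n) ** 2 for x in xs) - 1.0) / (n - 1.0)
        class_f.setdefault(len(fam), []).append(f)

    fbar = {k: float(np.mean(v)) for k, v in class_f.items() if v and float(np.mean(v)) > 0}
    n_families = {}
    for fam in families:
        n_families[len(fam)] = n_families.get(len(fam), 0) + 1

    value = 2.0
    for k, count in sorted(n_families.items()):
        if k in fbar:
            value += count / fbar[k]
        elif k == 3 and 2 in fbar and 4 in fbar:
            value += count * (1.0 / fbar[2] + 1.0 / fbar[4]) / 2.0
        else:
            return math.nan
    return min(61.0, max(20.0, value))


def oracle_predict(
    family_codons: list[str],
    availability: dict[str, float],
    cognate: dict[str, float],
) -> tuple[str, ...]:
    """Brute-force preferred-codon enumeration.

    Scores every codon by the lexicographic key (availability, cognate
    abundance) and returns the argmax set; availability ranking is
    equivalent to RTU ranking since RTU is availability over a
    family-constant denominator.
    """
    best: tuple[float, float] | None = None
    winners: list[str] = []
    for codon in family_codons:
        key = (availability[codon], cognate[codon])
        if best is None or _lex_gt(key, best):
            best, winners = key, [codon]
        elif _lex_eq(key, best):
            winners.append(codon)
    return tuple(sorted(winners))


def _close(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=1e-9, abs_tol=0.0) or a == b


def _lex_eq(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return _close(a[0], b[0]) and _close(a[1], b[1])


def _lex_gt(a: tuple[float, float], b: tuple[float, float]) -> bool:
    if not _close(a[0], b[0]):
        return a[0] > b[0]
    return not _close(a[1], b[1]) and a[1] > b[1]


def oracle_welch(a: list[float], b: list[float]) -> tuple[float, float]:
    """Textbook Welch t statistic and Welch-Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df
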