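"""tRNA abundance estimation and availability metrics.

Converts read counts into tpm, sums per-anticodon abundance into
per-codon availability through the pairing rules, derives relative tRNA
usage (RTU; the RSCU formula applied to availability), computes each
anticodon's readable codon usage, and provides the sequencing
diagnostics around tRNA methylation: heavy/light methylation classes
with a Welch t-test on tpm, and reverse-transcriptase hard-stop
detection on per-site depth profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_model import CodonFamily, codon_families, SENSE_CODONS
from .io_formats import AbundanceTable, TrnaSpecies
from .pairing import COGNATE, PairingRules, default_rules, readable_codons_with_s

logger = logging.getLogger(__name__)

MIN_READ_LENGTH = 25  # retained-read floor (nt)

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class TrnaAbundance:
    """Per-anticodon abundance with a unit tag and provenance label."""

    values: Mapping[str, float]
    unit: str = "tpm"  # tpm | gene_copy | fingerprint
    source: str = ""

    def __post_init__(self) -> None:
        for anticodon, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative abundance for {anticodon}")
            if len(anticodon) != 3 or any(b not in "ACGU" for b in anticodon):
                raise ValueError(f"invalid anticodon {anticodon!r}")

    @classmethod
    def from_tpm(cls, table: AbundanceTable, trnas: Sequence[TrnaSpecies], source: str = "") -> "TrnaAbundance":
        """Aggregate a tRNA abundance table to anticodon level (tpm summed)."""
        tpm = table.tpm
        values: dict[str, float] = {}
        for t in trnas:
            values[t.anticodon] = values.get(t.anticodon, 0.0) + float(tpm.get(t.id, 0.0))
        return cls(values, unit="tpm", source=source)

    @classmethod
    def from_copy_numbers(cls, trnas: Sequence[TrnaSpecies], source: str = "gtrnadb") -> "TrnaAbundance":
        values: dict[str, float] = {}
        for t in trnas:
            values[t.anticodon] = values.get(t.anticodon, 0.0) + float(t.copy_number)
        return cls(values, unit="gene_copy", source=source)


def tpm_from_counts(
    counts: Mapping[str, float], lengths: Mapping[str, float]
) -> AbundanceTable:
    """Plain-length tpm: rate_i = counts_i / length_i, scaled to sum 1e6.

    Effective-length correction is deliberately not applied: tRNAs are
    shorter than typical sequencing fragments, which makes effective
    length ill-defined for them.
    """
    ids = sorted(counts)
    length = np.array([lengths[i] for i in ids], dtype=float)
    if (length <= 0).any():
        raise ValueError("all lengths must be positive")
    c = np.array([counts[i] for i in ids], dtype=float)
    if c.sum() <= 0:
        raise ValueError("all counts are zero; cannot normalize to tpm")
    rate = c / length
    tpm = 1e6 * rate / rate.sum()
    df = pd.DataFrame(
        {"target_id": ids, "length": length, "eff_length": length, "est_counts": c, "tpm": tpm}
    )
    return AbundanceTable(df)


def assign_reads(
    reads: Iterable[str], trnas: Sequence[TrnaSpecies]
) -> tuple[dict[str, float], int]:
    """Assign reads to tRNAs by exact forward-strand substring match.

    A read matching k tRNA sequences contributes 1/k to each; reads
    matching none (or shorter than the 25 nt floor) are dropped and
    counted.  Returns (fractional counts per tRNA id, n_dropped).
    """
    counts = {t.id: 0.0 for t in trnas}
    seqs = [(t.id, t.sequence) for t in trnas]
    dropped = 0
    for read in reads:
        read = read.upper().replace("T", "U")
        if len(read) < MIN_READ_LENGTH:
            dropped += 1
            continue
        hits = [tid for tid, seq in seqs if read in seq]
        if not hits:
            dropped += 1
            continue
        share = 1.0 / len(hits)
        for tid in hits:
            counts[tid] += share
    return counts, dropped


def depth_from_reads(
    reads: Iterable[str], trnas: Sequence[TrnaSpecies]
) -> dict[str, np.ndarray]:
    """Per-site depth profiles from exact read placements.

    Multi-mapping reads contribute fractional depth to every matching
    tRNA at the first occurrence position.  Site indices are 1-based
    (vector index 0 = site 1).
    """
    profiles = {t.id: np.zeros(len(t.sequence)) for t in trnas}
    seqs = [(t.id, t.sequence) for t in trnas]
    for read in reads:
        read = read.upper().replace("T", "U")
        if len(read) < MIN_READ_LENGTH:
            continue
        hits = [(tid, seq.find(read)) for tid, seq in seqs if read in seq]
        if not hits:
            continue
        share = 1.0 / len(hits)
        for tid, start in hits:
            profiles[tid][start : start + len(read)] += share
    return profiles


def codon_availability(
    abundance: TrnaAbundance | Mapping[str, float],
    trnas: Sequence[TrnaSpecies],
    rules: PairingRules | None = None,
    *,
    s_weighted: bool = False,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-codon tRNA availability (total, cognate-only).

    availability(codon) = sum of abundance over every tRNA that reads
    the codon, all pairing classes unweighted by default (``s_weighted``
    applies the (1 - s) efficiency factors instead, for sensitivity
    analysis).  Returns (availability, cognate_availability) over all
    sense codons.
    """
    values = abundance.values if isinstance(abundance, TrnaAbundance) else abundance
    rules = rules if rules is not None else default_rules()
    known = {t.anticodon for t in trnas}
    missing = set(values) - known
    if missing:
        raise ValueError(f"abundance contains anticodons absent from tRNA set: {sorted(missing)}")
    avail = {c: 0.0 for c in SENSE_CODONS}
    cognate = {c: 0.0 for c in SENSE_CODONS}
    for anticodon in sorted(values):
        a = values[anticodon]
        for codon, cls, s in readable_codons_with_s(anticodon, rules):
            weight = (1.0 - s) if s_weighted else 1.0
            avail[codon] += weight * a
            if cls == COGNATE:
                cognate[codon] += a
    return avail, cognate


@dataclass
class RtuTable:
    """Relative tRNA usage per codon, plus all-tie family flags."""

    values: dict[str, float]
    flagged_families: tuple[str, ...] = ()  # families where every codon ties at RTU = 1

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]


def rtu(
    availability: Mapping[str, float],
    families: Sequence[CodonFamily] | None = None,
) -> RtuTable:
    """RTU_i = availability_i / (family mean availability).

    Mirrors RSCU with availability in place of codon counts; families
    with zero total availability yield NaN with a warning; families
    where every codon ties at RTU = 1 are flagged (they cannot rank
    synonymous codons).
    """
    families = families if families is not None else codon_families()
    values: dict[str, float] = {}
    flagged: list[str] = []
    for fam in families:
        avails = [availability.get(c, 0.0) for c in fam.codons]
        total = sum(avails)
        if total <= 0:
            logger.warning("family %s has zero total availability", fam.label)
            for c in fam.codons:
                values[c] = math.nan
            continue
        mean = total / fam.fold
        fam_rtu = [a / mean for a in avails]
        for c, r in zip(fam.codons, fam_rtu):
            values[c] = r
        if all(math.isclose(r, 1.0, rel_tol=1e-9) for r in fam_rtu):
            flagged.append(fam.label)
    return RtuTable(values, tuple(flagged))


def readable_codon_usage(
    trnas: Sequence[TrnaSpecies],
    rules: PairingRules | None,
    counts: Mapping[str, int | float],
) -> dict[str, float]:
    """Per-anticodon sum of usage over its readable codons."""
    rules = rules if rules is not None else default_rules()
    out: dict[str, float] = {}
    for anticodon in sorted({t.anticodon for t in trnas}):
        out[anticodon] = float(
            sum(counts.get(c, 0) for c, _cls, _s in readable_codons_with_s(anticodon, rules))
        )
    return out


# ---------------------------------------------------------------------------
# Methylation diagnostics


@dataclass
class MethylationReport:
    """Heavy/light methylation classes and the between-class Welch test."""

    per_trna: pd.DataFrame  # trna_id, n_potential_sites, methyl_class, tpm
    threshold: int
    t_statistic: float
    p_value: float

    @property
    def heavy_tpm(self) -> list[float]:
        df = self.per_trna
        return df.loc[df["methyl_class"] == "heavy", "tpm"].tolist()

    @property
    def light_tpm(self) -> list[float]:
        df = self.per_trna
        return df.loc[df["methyl_class"] == "light", "tpm"].tolist()


def methylation_classes(
    trnas: Sequence[TrnaSpecies],
    tpm: Mapping[str, float],
    threshold: int = 4,
) -> MethylationReport:
    """Classify tRNAs as heavily methylated (> ``threshold`` potential
    sites) vs light, and Welch-test their tpm distributions.

    The test is the two-sample two-tailed t-test with unequal variances;
    p is NaN when either class has fewer than two members.
    """
    rows = []
    for t in trnas:
        n_sites = len(t.methylation_sites)
        rows.append(
            {
                "trna_id": t.id,
                "n_potential_sites": n_sites,
                "methyl_class": "heavy" if n_sites > threshold else "light",
                "tpm": float(tpm.get(t.id, 0.0)),
            }
        )
    df = pd.DataFrame(rows)
    heavy = df.loc[df["methyl_class"] == "heavy", "tpm"].to_numpy()
    light = df.loc[df["methyl_class"] == "light", "tpm"].to_numpy()
    if len(heavy) >= 2 and len(light) >= 2:
        t_stat, p = stats.ttest_ind(heavy, light, equal_var=False)
        t_stat, p = float(t_stat), float(p)
    else:
        logger.warning("a methylation class has < 2 members; Welch p not computed")
        t_stat, p = math.nan, math.nan
    return MethylationReport(df, threshold, t_stat, p)


@dataclass(frozen=True)
class HardStop:
    trna_id: str
    site: int  # 1-based; depth collapses immediately downstream of this site
    upstream_mean: float
    downstream_mean: float


def detect_hard_stops(
    profiles: Mapping[str, np.ndarray],
    *,
    window: int = 5,
    ratio: float = 0.2,
    min_depth: float = 10.0,
) -> list[HardStop]:
    """Detect reverse-transcription hard-stops in depth profiles.

    A site s is a candidate iff mean depth over sites (s+1 .. s+window)
    <= ratio * mean depth over (s-window+1 .. s) and the upstream mean
    >= min_depth; sites within ``window`` of either end are excluded.
    Consecutive candidate runs (a single cliff triggers the rule at a
    few adjacent sites) are collapsed to the site with the largest
    upstream/downstream ratio, ties to the smallest site.
    """
    out: list[HardStop] = []
    for trna_id in sorted(profiles):
        depth = np.asarray(profiles[trna_id], dtype=float)
        length = len(depth)
        candidates: list[tuple[int, float, float]] = []
        for s in range(window, length - window + 1):  # 1-based site s
            up = float(depth[s - window : s].mean())
            down = float(depth[s : s + window].mean())
            if up >= min_depth and down <= ratio * up:
                candidates.append((s, up, down))
        run: list[tuple[int, float, float]] = []
        for cand in candidates + [(-10, 0.0, 0.0)]:  # sentinel flushes the last run
            if run and cand[0] != run[-1][0] + 1:
                best = max(run, key=lambda c: (c[1] / c[2] if c[2] > 0 else math.inf, -c[0]))
                out.append(HardStop(trna_id, best[0], best[1], best[2]))
                run = []
            if cand[0] > 0:
                run.append(cand)
    return out
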