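"""tRNA adaptation index and the S statistic.

tAI weights: for each codon c, W_c = sum over its reader tRNAs j of
(1 - s_j) * A_j, where A_j is the reader's abundance (gene copy number
for tAI, tpm for tAI') and s_j the selective constraint of that
particular codon-anticodon pairing.  Normalized weights w_c = W_c /
max W; codons with no reader receive the geometric mean of the nonzero
weights so the gene-level geometric mean stays defined.  Gene tAI is
the geometric mean of w over the gene's sense codons (Met and Trp
included; stops excluded).

The S statistic correlates gene tAI with the codon-usage deviation
f(GC3s) - Nc: genes whose codon bias exceeds the mutational expectation
should, under tRNA-driven selection, also score a high tAI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_model import SENSE_CODONS, expected_nc
from .io_formats import TrnaSpecies
from .pairing import PairingRules, default_rules, readable_codons_with_s
from .trna_quant import TrnaAbundance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaiModel:
    """Per-codon tAI weights derived from one abundance source."""

    source: str
    W: Mapping[str, float]  # raw availability-times-efficiency weights
    w: Mapping[str, float]  # normalized, zero-filled weights in (0, 1]
    w_fill: float  # geometric-mean fill used for zero-W codons

    def __post_init__(self) -> None:
        if not math.isclose(max(self.w.values()), 1.0, rel_tol=1e-9):
            raise ValueError("normalized weights must have max 1")
        if any(v <= 0 for v in self.w.values()):
            raise ValueError("all filled weights must be positive")


def tai_weights(
    abundance: TrnaAbundance | Mapping[str, float],
    trnas: Sequence[TrnaSpecies],
    rules: PairingRules | None = None,
) -> TaiModel:
    """Build a :class:`TaiModel` from per-anticodon abundance."""
    values = abundance.values if isinstance(abundance, TrnaAbundance) else abundance
    source = abundance.unit if isinstance(abundance, TrnaAbundance) else "custom"
    rules = rules if rules is not None else default_rules()
    known = {t.anticodon for t in trnas}
    missing = set(values) - known
    if missing:
        raise ValueError(f"abundance for anticodons absent from tRNA set: {sorted(missing)}")
    W = {c: 0.0 for c in SENSE_CODONS}
    for anticodon in sorted(values):
        a = values[anticodon]
        for codon, _cls, s in readable_codons_with_s(anticodon, rules):
            W[codon] += (1.0 - s) * a
    w_max = max(W.values())
    if w_max <= 0:
        raise ValueError("all tAI weights are zero")
    w = {c: v / w_max for c, v in W.items()}
    nonzero = [v for v in w.values() if v > 0]
    fill = float(np.exp(np.mean(np.log(nonzero))))
    w = {c: (v if v > 0 else fill) for c, v in w.items()}
    return TaiModel(source, W, w, fill)


def gene_tai(model: TaiModel, counts: Mapping[str, int | float]) -> float:
    """Geometric mean of w over a gene's sense codons."""
    n_total = 0.0
    log_sum = 0.0
    for codon, n in counts.items():
        if n <= 0 or codon not in model.w:
            continue
        n_total += n
        log_sum += n * math.log(model.w[codon])
    if n_total <= 0:
        raise ValueError("gene has no sense codons")
    return float(math.exp(log_sum / n_total))


@dataclass
class SResult:
    """Per-gene tAI/Nc table and the S correlation."""

    per_gene: pd.DataFrame  # gene_id, tai, nc, gc3s, f_gc3s, deviation
    S: float
    p_value: float
    method: str
    n: int


def s_statistic(
    tai_values: Mapping[str, float] | pd.Series,
    nc_values: Mapping[str, float] | pd.Series,
    gc3s_values: Mapping[str, float] | pd.Series,
    method: str = "pearson",
) -> SResult:
    """Correlate gene tAI with the deviation f(GC3s) - Nc.

    Genes missing any of the three quantities are dropped; at least
    three complete genes are required and both variables must vary.
    """
    tai_s = pd.Series(tai_values, dtype=float)
    nc_s = pd.Series(nc_values, dtype=float)
    gc3s_s = pd.Series(gc3s_values, dtype=float)
    df = pd.DataFrame({"tai": tai_s, "nc": nc_s, "gc3s": gc3s_s}).dropna()
    if len(df) < 3:
        raise ValueError(f"only {len(df)} genes with tai, Nc and GC3s; need >= 3")
    df["f_gc3s"] = [expected_nc(s) for s in df["gc3s"]]
    df["deviation"] = df["f_gc3s"] - df["nc"]
    if df["tai"].nunique() == 1 or df["deviation"].nunique() == 1:
        raise ValueError("zero variance in tAI or deviation; S undefined")
    if method == "pearson":
        r, p = stats.pearsonr(df["tai"], df["deviation"])
    elif method == "spearman":
        r, p = stats.spearmanr(df["tai"], df["deviation"])
    else:
        raise ValueError(f"unknown method {method!r}")
    df.index.name = "gene_id"
    return SResult(df.reset_index(), float(r), float(p), method, len(df))
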