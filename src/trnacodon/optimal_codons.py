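"""Optimal-codon calling and tRNA-availability prediction.

Two independent routes to a family's preferred codon:

* the *dual-criterion caller* works from codon usage: the optimal codon
  is the strict RSCU maximum in highly expressed genes, and only counts
  if that codon's HEG RSCU also exceeds its LEG RSCU (otherwise the
  abundant codon carries no evidence of translational selection);

* the *two-step availability predictor* works from the tRNA pool: rank
  synonymous codons by RTU, shortlist those sharing the maximum, then
  break the tie by cognate-only tRNA abundance (cognate pairing is the
  most efficient, so among equally-read codons the cognate-decoded one
  is preferred).

The match score between the two is the measure of how far tRNA
availability explains codon preference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .codon_model import CodonFamily, codon_families
from .trna_quant import RtuTable

logger = logging.getLogger(__name__)

_RTOL = 1e-9  # relative tolerance for detecting structural ties


@dataclass(frozen=True)
class OptimalCodonCall:
    """Per-family outcome of the dual-criterion caller."""

    family: str
    codon: str | None
    rscu_heg: float
    rscu_leg: float
    reason: str | None = None  # tie | criterion2_violated | zero_family when codon is None


@dataclass(frozen=True)
class PreferencePrediction:
    """Per-family outcome of the two-step availability predictor."""

    family: str
    codons: tuple[str, ...]  # singleton, or tied set
    tied: bool
    source: str = "tpm"
    reason: str | None = None  # zero_family when codons is empty

    @property
    def codon(self) -> str | None:
        return self.codons[0] if len(self.codons) == 1 else None


def _isclose(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=_RTOL, abs_tol=0.0)


def identify_optimal(
    rscu_heg: Mapping[str, float],
    rscu_leg: Mapping[str, float],
    families: Sequence[CodonFamily] | None = None,
) -> list[OptimalCodonCall]:
    """Dual-criterion optimal-codon calls, one per family.

    Candidate = unique strict argmax of HEG RSCU (exact ties yield no
    call); called iff its HEG RSCU > LEG RSCU.
    """
    families = families if families is not None else codon_families()
    calls: list[OptimalCodonCall] = []
    for fam in families:
        heg = {c: rscu_heg.get(c, math.nan) for c in fam.codons}
        if any(math.isnan(v) for v in heg.values()):
            calls.append(OptimalCodonCall(fam.label, None, math.nan, math.nan, "zero_family"))
            continue
        best = max(heg.values())
        top = [c for c, v in heg.items() if _isclose(v, best)]
        if len(top) > 1:
            calls.append(OptimalCodonCall(fam.label, None, best, math.nan, "tie"))
            continue
        candidate = top[0]
        leg = rscu_leg.get(candidate, math.nan)
        if math.isnan(leg) or heg[candidate] > leg:
            calls.append(OptimalCodonCall(fam.label, candidate, heg[candidate], leg))
        else:
            calls.append(
                OptimalCodonCall(fam.label, None, heg[candidate], leg, "criterion2_violated")
            )
    return calls


def predict_preferred(
    rtu_table: RtuTable | Mapping[str, float],
    cognate_availability: Mapping[str, float],
    families: Sequence[CodonFamily] | None = None,
    *,
    source: str = "tpm",
) -> list[PreferencePrediction]:
    """Two-step availability prediction, one per family.

    Shortlist codons sharing the maximal RTU (structural ties detected
    at relative tolerance 1e-9), then pick the shortlisted codon with
    maximal cognate-only abundance; remaining exact ties are returned
    as a flagged tied set.
    """
    families = families if families is not None else codon_families()
    values = rtu_table.values if isinstance(rtu_table, RtuTable) else rtu_table
    preds: list[PreferencePrediction] = []
    for fam in families:
        fam_rtu = {c: values.get(c, math.nan) for c in fam.codons}
        if any(math.isnan(v) for v in fam_rtu.values()):
            preds.append(PreferencePrediction(fam.label, (), False, source, "zero_family"))
            continue
        best = max(fam_rtu.values())
        shortlist = sorted(c for c, v in fam_rtu.items() if _isclose(v, best))
        if len(shortlist) == 1:
            preds.append(PreferencePrediction(fam.label, (shortlist[0],), False, source))
            continue
        cog = {c: cognate_availability.get(c, 0.0) for c in shortlist}
        best_cog = max(cog.values())
        winners = tuple(sorted(c for c, v in cog.items() if v == best_cog or _isclose(v, best_cog)))
        preds.append(PreferencePrediction(fam.label, winners, len(winners) > 1, source))
    return preds


def match_score(
    calls: Sequence[OptimalCodonCall],
    preds: Sequence[PreferencePrediction],
    *,
    strict: bool = True,
) -> tuple[int, int]:
    """(matched, determinable) between calls and predictions.

    determinable = families with a called optimal codon.  A singleton
    prediction matches iff equal to the call; a tied-set prediction
    counts as matched only when the call is in the set and ``strict``
    is off.
    """
    by_family = {p.family: p for p in preds}
    matched = determinable = 0
    for call in calls:
        if call.codon is None:
            continue
        determinable += 1
        pred = by_family.get(call.family)
        if pred is None or not pred.codons:
            continue
        if pred.tied:
            if not strict and call.codon in pred.codons:
                matched += 1
        elif pred.codons[0] == call.codon:
            matched += 1
    return matched, determinable


def confirm_predictions(
    preds_a: Sequence[PreferencePrediction], preds_b: Sequence[PreferencePrediction]
) -> dict[str, bool]:
    """Cross-dataset confirmation: identical prediction under both sources."""
    b = {p.family: p.codons for p in preds_b}
    return {p.family: (p.codons == b.get(p.family) and bool(p.codons)) for p in preds_a}
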