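"""Codon-anticodon readability model.

A tRNA reads its cognate codon (reverse complement of the anticodon)
plus near-cognate codons that share the first two codon positions and
pair at the third position through wobble geometry or anticodon
modifications.  Which third bases a given anticodon wobble base
(position 34, the 5' base of the anticodon) can read is a small,
configurable rule table:

* C34 reads G (cognate only);
* G34 reads C (cognate) and U (wobble);
* U34 reads A (cognate) and G (wobble); modified U34 (xo5U-type)
  additionally reads U and C, but only in 4-fold families and the
  3-fold Ile family where no cross-family misreading can result;
* A34 is deaminated to inosine, which reads U (Watson-Crick-equivalent),
  C, and - poorly - A.

Each non-cognate pairing carries a selective constraint s in [0, 1]
penalizing its efficiency; s enters the tAI weights only, never the
raw availability sums.  Pairings that would cross amino-acid families
(e.g. a Met anticodon reaching an Ile codon) are always removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import yaml

from .codon_model import (
    STOP_CODONS,
    family_of_codon,
    reverse_complement,
    translate_codon,
)

logger = logging.getLogger(__name__)

COGNATE = "cognate"
WOBBLE = "wobble"
MODIFIED = "modified"

SCOPE_ALL = "all"
SCOPE_EXPANDED = "34fold"  # 4-fold families plus the 3-fold Ile family


@dataclass(frozen=True)
class PairingRule:
    """One allowed (anticodon wobble base, codon third base) pairing."""

    wobble_base: str
    third_base: str
    pairing_class: str
    s_value: float
    family_scope: str = SCOPE_ALL

    def __post_init__(self) -> None:
        if self.wobble_base not in "ACGU" or self.third_base not in "ACGU":
            raise ValueError(f"invalid bases in rule {self}")
        if self.pairing_class not in (COGNATE, WOBBLE, MODIFIED):
            raise ValueError(f"unknown pairing class {self.pairing_class!r}")
        if not 0.0 <= self.s_value <= 1.0:
            raise ValueError(f"s_value {self.s_value} outside [0, 1]")
        if self.pairing_class == COGNATE and self.s_value != 0.0:
            raise ValueError("cognate pairings have s = 0")


@dataclass(frozen=True)
class PairingRules:
    """A complete rule table; at most one rule per (wobble, third) pair."""

    rules: tuple[PairingRule, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.rules:
            key = (r.wobble_base, r.third_base)
            if key in seen:
                raise ValueError(f"duplicate rule for pair {key}")
            seen.add(key)

    def for_wobble(self, base: str) -> tuple[PairingRule, ...]:
        return tuple(r for r in self.rules if r.wobble_base == base)

    # -- config round-trip ---------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump({"rules": [asdict(r) for r in self.rules]}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PairingRules":
        data = yaml.safe_load(text)
        return cls(tuple(PairingRule(**r) for r in data["rules"]))


def default_rules(*, include_modified: bool = True) -> PairingRules:
    """The default rule table (see module docstring).

    ``include_modified=False`` drops the modification-enabled pairings
    (xo5U-type U34 extensions and inosine's non-WC partners), leaving
    the classic cognate + wobble model.
    """
    rules = [
        PairingRule("C", "G", COGNATE, 0.0),
        PairingRule("G", "C", COGNATE, 0.0),
        PairingRule("G", "U", WOBBLE, 0.41),
        PairingRule("U", "A", COGNATE, 0.0),
        PairingRule("U", "G", WOBBLE, 0.68),
        PairingRule("A", "U", COGNATE, 0.0),  # inosine:U, WC-equivalent
    ]
    if include_modified:
        rules += [
            PairingRule("U", "U", MODIFIED, 0.68, SCOPE_EXPANDED),
            PairingRule("U", "C", MODIFIED, 0.68, SCOPE_EXPANDED),
            PairingRule("A", "C", MODIFIED, 0.28),
            PairingRule("A", "A", MODIFIED, 0.9999),
        ]
    return PairingRules(tuple(rules))


def _in_scope(codon: str, scope: str) -> bool:
    if scope == SCOPE_ALL:
        return True
    fam = family_of_codon().get(codon)
    return fam is not None and fam.fold >= 3


def readable_codons(
    anticodon: str, rules: PairingRules | None = None
) -> list[tuple[str, str]]:
    """Codons an anticodon can read, as (codon, pairing_class).

    Codons outside the anticodon's amino-acid family are removed; an
    anticodon whose cognate codon is a stop reads nothing.
    """
    rules = rules if rules is not None else default_rules()
    anticodon = anticodon.upper().replace("T", "U")
    if len(anticodon) != 3 or any(b not in "ACGU" for b in anticodon):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    cognate = reverse_complement(anticodon)
    if cognate in STOP_CODONS:
        logger.warning("anticodon %s decodes a stop codon; no readable codons", anticodon)
        return []
    aa = translate_codon(cognate)
    out: list[tuple[str, str]] = []
    for rule in rules.for_wobble(anticodon[0]):
        codon = cognate[:2] + rule.third_base
        if codon in STOP_CODONS or translate_codon(codon) != aa:
            continue
        if rule.pairing_class != COGNATE and not _in_scope(codon, rule.family_scope):
            continue
        out.append((codon, rule.pairing_class))
    # cognate first, then by codon for determinism
    out.sort(key=lambda t: (t[1] != COGNATE, t[0]))
    return out


def readable_codons_with_s(
    anticodon: str, rules: PairingRules | None = None
) -> list[tuple[str, str, float]]:
    """Like :func:`readable_codons` but carrying each pairing's s-value."""
    rules = rules if rules is not None else default_rules()
    s_of = {(r.wobble_base, r.third_base): r.s_value for r in rules.rules}
    return [
        (codon, cls, s_of[(anticodon.upper().replace("T", "U")[0], codon[2])])
        for codon, cls in readable_codons(anticodon, rules)
    ]


def codon_readers(
    codon: str, trna_set: Sequence, rules: PairingRules | None = None
) -> list[tuple[object, str, float]]:
    """tRNAs that read a codon, as (TrnaSpecies, pairing_class, s_value).

    Ordered by anticodon (then id) lexicographically; may be empty.
    """
    rules = rules if rules is not None else default_rules()
    codon = codon.upper().replace("T", "U")
    out = []
    for trna in sorted(trna_set, key=lambda t: (t.anticodon, t.id)):
        for c, cls, s in readable_codons_with_s(trna.anticodon, rules):
            if c == codon:
                out.append((trna, cls, s))
    return out


class ReadabilityMap:
    """Precomputed forward/inverse readability over a tRNA set."""

    def __init__(self, trna_set: Iterable, rules: PairingRules | None = None):
        self.rules = rules if rules is not None else default_rules()
        self.trnas = list(trna_set)
        self.by_anticodon: dict[str, list[tuple[str, str, float]]] = {}
        self.by_codon: dict[str, list[tuple[object, str, float]]] = {}
        for trna in sorted(self.trnas, key=lambda t: (t.anticodon, t.id)):
            entries = readable_codons_with_s(trna.anticodon, self.rules)
            self.by_anticodon.setdefault(trna.anticodon, entries)
            for codon, cls, s in entries:
                self.by_codon.setdefault(codon, []).append((trna, cls, s))

    def codons_of(self, anticodon: str) -> list[tuple[str, str, float]]:
        return self.by_anticodon.get(anticodon, [])

    def readers_of(self, codon: str) -> list[tuple[object, str, float]]:
        return self.by_codon.get(codon, [])
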