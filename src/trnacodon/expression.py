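"""Protein-per-transcript expression classes.

Translationally highly and lowly expressed gene sets (HEG / LEG) are
defined by the ratio of protein abundance (ppm) to mRNA abundance
(tpm): ranking genes by ppm/tpm decouples translation efficiency from
transcription.  The top and bottom 30% of each RNA-Seq dataset are
taken and intersected across datasets; ribosomal-protein annotations
provide a sanity check (ribosomal proteins should populate the HEG
set almost exclusively).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import AbundanceTable

logger = logging.getLogger(__name__)


def protein_per_transcript(protein: pd.Series, mrna: AbundanceTable) -> pd.DataFrame:
    """Join protein ppm with mRNA tpm and compute ppt = ppm / tpm.

    Only genes present in both tables with strictly positive ppm and
    tpm are retained; exclusions are logged.
    """
    tpm = mrna.tpm
    common = protein.index.intersection(tpm.index)
    if len(common) == 0:
        raise ValueError("protein and mRNA tables share no gene ids")
    df = pd.DataFrame({"ppm": protein.loc[common], "mrna_tpm": tpm.loc[common]})
    n_before = len(df)
    df = df[(df["ppm"] > 0) & (df["mrna_tpm"] > 0)]
    if len(df) < n_before:
        logger.info("excluded %d genes with zero ppm or tpm", n_before - len(df))
    df = df.copy()
    df["ppt"] = df["ppm"] / df["mrna_tpm"]
    df.index.name = "gene_id"
    return df.sort_index()


@dataclass
class GeneSets:
    """HEG/LEG sets plus the per-dataset intermediates."""

    heg: frozenset[str]
    leg: frozenset[str]
    per_dataset: tuple[tuple[frozenset[str], frozenset[str]], ...] = ()

    def __post_init__(self) -> None:
        if self.heg & self.leg:
            raise ValueError("HEG and LEG overlap")


def _rank_sets(df: pd.DataFrame, fraction: float) -> tuple[frozenset[str], frozenset[str]]:
    n = len(df)
    k = math.floor(fraction * n)
    # descending ppt; boundary ties broken by gene id for determinism
    tmp = df.reset_index()
    id_col = tmp.columns[0]
    ids = tmp.sort_values(["ppt", id_col], ascending=[False, True])[id_col].tolist()
    if k == 0:
        return frozenset(), frozenset()
    return frozenset(ids[:k]), frozenset(ids[n - k :])


def select_heg_leg(
    datasets: Sequence[pd.DataFrame], fraction: float = 0.30
) -> GeneSets:
    """Top/bottom ``fraction`` of ppt per dataset, intersected.

    With one dataset the HEG/LEG sets are that dataset's top/bottom
    sets.  Set sizes use floor(fraction * n) on post-filter n.
    """
    if not datasets or any(len(d) == 0 for d in datasets):
        raise ValueError("each dataset must be a nonempty ppt table")
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    per = [_rank_sets(d, fraction) for d in datasets]
    heg = frozenset.intersection(*(top for top, _ in per))
    leg = frozenset.intersection(*(bot for _, bot in per))
    for i, d in enumerate(datasets):
        logger.info("dataset %d: n=%d, set size=%d", i, len(d), math.floor(fraction * len(d)))
    if not heg or not leg:
        raise ValueError(
            "HEG or LEG empty after cross-dataset intersection; increase the fraction"
        )
    return GeneSets(heg, leg, tuple(per))


RIBOSOMAL_MARKERS = ("30s ribosomal protein", "50s ribosomal protein")


def ribosomal_validation(
    sets: GeneSets, annotations: Mapping[str, str]
) -> tuple[int, int]:
    """Count annotated 30S/50S ribosomal-protein genes in HEG and LEG."""

    def is_ribo(gene: str) -> bool:
        desc = annotations.get(gene, "").lower()
        return any(m in desc for m in RIBOSOMAL_MARKERS)

    return sum(map(is_ribo, sets.heg)), sum(map(is_ribo, sets.leg))
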