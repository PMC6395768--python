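"""Readers and writers for the pipeline's external formats.

Covers FASTA (strict: duplicate ids, malformed headers and empty
sequences are errors naming the offending line), tRNA-set preparation
(GtRNAdb-dialect headers, pseudo-tRNA filtering, deduplication of
identical sequences, CCA appending), kallisto ``abundance.tsv`` tables,
PaxDb-like protein-abundance tables, samtools-``depth`` per-site read
depth tables, and per-tRNA methylation-site annotations.

All sequences are normalized to the RNA alphabet (T -> U) when loaded
as tRNAs; plain FASTA round-trips preserve T/U as read.  All site
coordinates are 1-based (samtools convention).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_model import reverse_complement, translate_codon

logger = logging.getLogger(__name__)

_FASTA_ALPHABET = set("ACGTUN")


class FormatError(ValueError):
    """A malformed input file."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (id, uppercased sequence) pairs.

    The id is the first whitespace-delimited token of the header; the
    full header is not retained here (see :func:`load_trna_set` for
    header-aware tRNA loading).  Duplicate ids, empty sequences, data
    before the first header and characters outside {A,C,G,T,U,N} are
    format errors naming the line.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {name!r} (header line {header_line})")
        records.append((name, seq))

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError(f"{path}: malformed header at line {line_no}")
                if name in seen:
                    raise FormatError(f"{path}: duplicate id {name!r} at line {line_no}")
                seen.add(name)
                header_line = line_no
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence data before any header at line {line_no}")
                bad = set(line.upper()) - _FASTA_ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}: invalid characters {sorted(bad)} at line {line_no}"
                    )
                chunks.append(line)
        flush(-1)
    if name is None:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, *, width: int = 70) -> None:
    """Write (id, sequence) records as FASTA with wrapped lines."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# tRNA sets

_GTRNADB_RE = re.compile(r"tRNA-([A-Za-z]{3})-?([ACGTUNacgtun]{3})", re.ASCII)


@dataclass(frozen=True)
class TrnaSpecies:
    """One unique tRNA sequence.

    Identical genomic copies are collapsed into a single record whose
    ``copy_number`` is their multiplicity.  ``sequence`` is RNA and ends
    with the post-transcriptional 3' CCA; ``methylation_sites`` are
    1-based positions on that sequence.
    """

    id: str
    anticodon: str
    amino_acid: str
    sequence: str
    copy_number: int = 1
    methylation_sites: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3 or any(b not in "ACGU" for b in self.anticodon):
            raise ValueError(f"{self.id}: invalid anticodon {self.anticodon!r}")
        if not self.sequence.endswith("CCA"):
            # mature tRNAs carry a 3' CCA; tolerated so un-appended genomic
            # sequences can still be represented
            logger.warning("%s: sequence does not end in CCA", self.id)
        if self.copy_number < 1:
            raise ValueError(f"{self.id}: copy_number must be >= 1")
        bad = [s for s in self.methylation_sites if not 1 <= s <= len(self.sequence)]
        if bad:
            raise ValueError(f"{self.id}: methylation sites {bad} outside sequence")


def _parse_trna_header(header: str) -> tuple[str, str, str] | None:
    """Return (id, aa 3-letter, anticodon RNA) or None if unparseable.

    Accepts the GtRNAdb dialect (a ``tRNA-<Aa>-<anticodon>`` token
    anywhere in the header) and the simple dialect
    ``name|aa|anticodon[|copies]``.
    """
    token = header.split()[0]
    if "|" in token:
        parts = token.split("|")
        if len(parts) >= 3:
            return parts[0], parts[1], parts[2].upper().replace("T", "U")
        return None
    m = _GTRNADB_RE.search(header)
    if m:
        return token, m.group(1).capitalize(), m.group(2).upper().replace("T", "U")
    return None


def _header_copies(header: str) -> int:
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 4:
        try:
            return max(1, int(parts[3]))
        except ValueError:
            return 1
    return 1


def load_trna_set(
    path: str | Path, *, drop_pseudo: bool = True, append_cca: bool = True
) -> list[TrnaSpecies]:
    """Load and prepare a tRNA set from FASTA.

    Headers follow the GtRNAdb dialect or ``name|aa|anticodon[|copies]``.
    Records flagged "pseudo" in the header or with an anticodon
    containing N are removed when ``drop_pseudo``; unparseable headers
    are rejected with a warning.  Identical sequences are collapsed to
    one record (copy numbers summed) *before* CCA appending; CCA is
    appended iff the sequence's final three bases are not exactly CCA.
    """
    # raw parse keeping full headers (read_fasta drops them)
    raw: list[tuple[str, str]] = []
    with open(path) as fh:
        header: str | None = None
        chunks: list[str] = []
        for raw_line in fh:
            line = raw_line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    raw.append((header, "".join(chunks)))
                header, chunks = line[1:], []
            elif header is not None:
                chunks.append(line)
        if header is not None:
            raw.append((header, "".join(chunks)))

    kept: list[tuple[str, str, str, str, int]] = []  # id, aa, anticodon, seq, copies
    for header, seq in raw:
        seq = seq.upper().replace("T", "U")
        parsed = _parse_trna_header(header)
        if parsed is None:
            logger.warning("unparseable tRNA header %r; record rejected", header)
            continue
        name, aa, anticodon = parsed
        if drop_pseudo and ("pseudo" in header.lower() or "N" in anticodon):
            logger.info("dropping pseudo/unspecified-anticodon record %r", name)
            continue
        if any(b not in "ACGU" for b in anticodon) or len(anticodon) != 3:
            logger.warning("unparseable anticodon %r in %r; record rejected", anticodon, name)
            continue
        if not seq:
            logger.warning("empty sequence for %r; record rejected", name)
            continue
        kept.append((name, aa, anticodon, seq, _header_copies(header)))

    # deduplicate identical sequences first, then append CCA
    by_seq: dict[str, list[tuple[str, str, str, int]]] = {}
    order: list[str] = []
    for name, aa, anticodon, seq, copies in kept:
        if seq not in by_seq:
            order.append(seq)
        by_seq.setdefault(seq, []).append((name, aa, anticodon, copies))

    out: list[TrnaSpecies] = []
    for seq in order:
        group = by_seq[seq]
        name, aa, anticodon, _ = group[0]
        copies = sum(c for *_, c in group)
        if len(group) > 1:
            logger.info("collapsed %d identical sequences into %r", len(group), name)
        final = seq
        if append_cca and not final.endswith("CCA"):
            final = final + "CCA"
            if any(s.endswith(final) or final.endswith(s) for s in order if s != seq):
                logger.warning("%r differs from another record only by its CCA suffix", name)
        expected = translate_codon(reverse_complement(anticodon))
        from .codon_model import _AA3  # 3-letter lookup

        if expected is not None and _AA3.get(expected) != aa:
            logger.warning(
                "%r: header amino acid %s mismatches anticodon %s (decodes %s)",
                name, aa, anticodon, _AA3.get(expected),
            )
        out.append(TrnaSpecies(name, anticodon, aa, final, copies))
    if not out:
        raise FormatError(f"{path}: no usable tRNA records")
    return out


def write_trna_set(trnas: Sequence[TrnaSpecies], path: str | Path) -> None:
    """Write a tRNA set in the simple dialect ``name|aa|anticodon|copies``."""
    write_fasta(
        [(f"{t.id}|{t.amino_acid}|{t.anticodon}|{t.copy_number}", t.sequence) for t in trnas],
        path,
    )


# ---------------------------------------------------------------------------
# Abundance / protein / depth / methylation tables

ABUNDANCE_COLUMNS = ("target_id", "length", "eff_length", "est_counts", "tpm")
TPM_TOTAL = 1e6
TPM_RTOL = 1e-3


@dataclass
class AbundanceTable:
    """A kallisto-layout abundance table (tpm sums to 1e6)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ABUNDANCE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"abundance table missing columns {missing}")
        num = self.df[list(ABUNDANCE_COLUMNS[1:])]
        if (num.to_numpy() < 0).any():
            raise FormatError("abundance table contains negative values")
        total = float(self.df["tpm"].sum())
        if abs(total - TPM_TOTAL) > TPM_RTOL * TPM_TOTAL:
            raise FormatError(f"tpm sums to {total:.6g}, expected 1e6 (+/- 0.1%)")
        if self.df["target_id"].duplicated().any():
            raise FormatError("duplicate target_id in abundance table")

    @property
    def tpm(self) -> pd.Series:
        return self.df.set_index("target_id")["tpm"]

    @property
    def lengths(self) -> pd.Series:
        return self.df.set_index("target_id")["length"]

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_abundance_table(path: str | Path, *, renormalize: bool = False) -> AbundanceTable:
    """Read a kallisto ``abundance.tsv``; optionally renormalize tpm.

    Extra columns are ignored with a log message.  A tpm column not
    summing to 1e6 is an error unless ``renormalize``.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty abundance table") from exc
    missing = [c for c in ABUNDANCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in ABUNDANCE_COLUMNS]
    if extra:
        logger.info("%s: ignoring extra columns %s", path, extra)
    df = df[list(ABUNDANCE_COLUMNS)].copy()
    df["target_id"] = df["target_id"].astype(str).str.strip()
    for col in ABUNDANCE_COLUMNS[1:]:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: non-numeric values in column {col!r}")
        if (df[col] < 0).any():
            raise FormatError(f"{path}: negative values in column {col!r}")
    total = float(df["tpm"].sum())
    if abs(total - TPM_TOTAL) > TPM_RTOL * TPM_TOTAL:
        if renormalize and total > 0:
            logger.warning("%s: tpm sums to %.6g; renormalizing to 1e6", path, total)
            df["tpm"] = df["tpm"] * (TPM_TOTAL / total)
        else:
            raise FormatError(f"{path}: tpm sums to {total:.6g}, expected 1e6")
    return AbundanceTable(df)


def read_protein_table(path: str | Path) -> pd.Series:
    """Read a PaxDb-like TSV ``gene_id<TAB>ppm`` into a Series.

    Comment lines (#) and an optional header row are skipped; duplicate
    gene ids and non-numeric abundances are format errors.
    """
    ids: list[str] = []
    ppm: list[float] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: expected 2 columns at row {line_no}")
            if line_no == 1 or (not ids and parts[1].lower() in ("ppm", "abundance")):
                try:
                    float(parts[1])
                except ValueError:
                    continue  # header row
            try:
                value = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric abundance at row {line_no}") from exc
            if value < 0:
                raise FormatError(f"{path}: negative abundance at row {line_no}")
            ids.append(parts[0].strip())
            ppm.append(value)
    if not ids:
        raise FormatError(f"{path}: no protein abundance rows")
    series = pd.Series(ppm, index=pd.Index(ids, name="gene_id"), name="ppm")
    if series.index.duplicated().any():
        dup = series.index[series.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    return series


def read_depth_table(
    path: str | Path, lengths: Mapping[str, int] | None = None
) -> dict[str, np.ndarray]:
    """Read a samtools-``depth`` TSV into per-tRNA depth vectors.

    Positions are 1-based; vector index 0 is site 1.  Positions missing
    from the file are filled with 0 up to the known sequence length
    (``lengths``), else up to the maximum observed position.
    """
    sites: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: expected 3 columns at row {line_no}")
            ref = parts[0].strip()
            try:
                pos, depth = int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric pos/depth at row {line_no}") from exc
            if pos < 1:
                raise FormatError(f"{path}: position {pos} at row {line_no} (1-based)")
            if depth < 0:
                raise FormatError(f"{path}: negative depth at row {line_no}")
            sites.setdefault(ref, {})[pos] = depth
    if not sites:
        raise FormatError(f"{path}: no depth rows")
    out: dict[str, np.ndarray] = {}
    for ref, by_pos in sites.items():
        length = (lengths or {}).get(ref, max(by_pos))
        if max(by_pos) > length:
            raise FormatError(f"{path}: position {max(by_pos)} beyond length {length} for {ref!r}")
        vec = np.zeros(length)
        for pos, depth in by_pos.items():
            vec[pos - 1] = depth
        out[ref] = vec
    return out


def read_methylation_table(path: str | Path) -> dict[str, tuple[int, ...]]:
    """Read ``trna_id<TAB>site<TAB>label`` annotations (1-based sites)."""
    sites: dict[str, list[int]] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: expected >= 2 columns at row {line_no}")
            try:
                site = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer site at row {line_no}") from exc
            if site < 1:
                raise FormatError(f"{path}: site {site} at row {line_no} (1-based)")
            sites.setdefault(parts[0].strip(), []).append(site)
    return {k: tuple(sorted(set(v))) for k, v in sites.items()}


def attach_methylation(
    trnas: Sequence[TrnaSpecies], sites: Mapping[str, tuple[int, ...]]
) -> list[TrnaSpecies]:
    """Return tRNAs with methylation_sites filled from an annotation map."""
    return [replace(t, methylation_sites=tuple(sites.get(t.id, ()))) for t in trnas]
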