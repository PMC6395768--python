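"""End-to-end orchestration of the analysis.

Sequences the stages: tRNA set -> availability/RTU per abundance source
-> expression classes -> RSCU in HEGs/LEGs -> dual-criterion optimal
calls -> availability predictions and match scores per source -> tAI /
tAI' and the S statistic -> methylation and hard-stop diagnostics.
Outputs are TSVs (floats at 4 decimals, so reruns are byte-identical)
plus a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
import pandas as pd
import yaml

from . import __version__
from .codon_model import codon_families, count_codons, gc3s, nc, rscu
from .expression import protein_per_transcript, select_heg_leg
from .io_formats import (
    attach_methylation,
    load_trna_set,
    read_abundance_table,
    read_depth_table,
    read_fasta,
    read_methylation_table,
    read_protein_table,
)
from .optimal_codons import confirm_predictions, identify_optimal, match_score, predict_preferred
from .pairing import PairingRules, default_rules
from .tai import gene_tai, s_statistic, tai_weights
from .trna_quant import (
    TrnaAbundance,
    codon_availability,
    detect_hard_stops,
    methylation_classes,
    rtu,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.4f"


@dataclass
class RunConfig:
    """Inputs and switches for one pipeline run."""

    trna_fasta: str
    cds_fasta: str
    protein_table: str
    mrna_abundance: list[str]  # one or two RNA-Seq datasets (kallisto layout)
    trna_abundance: list[str]  # tRNA abundance tables, aligned with mrna_abundance
    out_dir: str
    depth_table: str | None = None
    methylation_table: str | None = None
    rules_file: str | None = None
    sources: tuple[str, ...] = ("tpm", "gene_copy")
    fraction: float = 0.30
    strict_ties: bool = True
    renormalize: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": [],
        "complete": False,
    }
    families = codon_families()

    def fail(stage_name: str, exc: Exception) -> None:
        manifest["failed_stage"] = stage_name
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        raise StageError(stage_name, exc) from exc

    def stage(name: str):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("load_trnas")
        rules = (
            PairingRules.from_yaml(Path(config.rules_file).read_text())
            if config.rules_file
            else default_rules()
        )
        trnas = load_trna_set(config.trna_fasta)
        if config.methylation_table:
            trnas = attach_methylation(trnas, read_methylation_table(config.methylation_table))
    except Exception as exc:
        fail("load_trnas", exc)

    try:
        stage("trna_abundance")
        abundances: dict[str, TrnaAbundance] = {}
        if "gene_copy" in config.sources:
            abundances["gene_copy"] = TrnaAbundance.from_copy_numbers(trnas)
        if "tpm" in config.sources:
            for i, path in enumerate(config.trna_abundance):
                table = read_abundance_table(path, renormalize=config.renormalize)
                abundances[f"tpm{i}" if len(config.trna_abundance) > 1 else "tpm"] = (
                    TrnaAbundance.from_tpm(table, trnas, source=str(path))
                )
    except Exception as exc:
        fail("trna_abundance", exc)

    try:
        stage("availability_rtu")
        avail_by_source = {}
        for name, ab in abundances.items():
            avail, cognate = codon_availability(ab, trnas, rules)
            rtu_table = rtu(avail, families)
            avail_by_source[name] = (avail, cognate, rtu_table)
            rows = [
                {
                    "family": fam.label,
                    "codon": c,
                    "availability": avail[c],
                    "cognate_availability": cognate[c],
                    "rtu": rtu_table.values.get(c, float("nan")),
                }
                for fam in families
                for c in fam.codons
            ]
            _write_tsv(pd.DataFrame(rows), out / f"availability_rtu_{name}.tsv")
    except Exception as exc:
        fail("availability_rtu", exc)

    try:
        stage("expression")
        protein = read_protein_table(config.protein_table)
        datasets = []
        for path in config.mrna_abundance:
            mrna = read_abundance_table(path, renormalize=config.renormalize)
            datasets.append(protein_per_transcript(protein, mrna))
        sets = select_heg_leg(datasets, fraction=config.fraction)
        for name, ids in (("heg", sets.heg), ("leg", sets.leg)):
            (out / f"{name}_genes.txt").write_text("\n".join(sorted(ids)) + "\n")
    except Exception as exc:
        fail("expression", exc)

    try:
        stage("rscu")
        cds = {gid: seq for gid, seq in read_fasta(config.cds_fasta)}
        heg_counts = count_codons([cds[g] for g in sorted(sets.heg) if g in cds])
        leg_counts = count_codons([cds[g] for g in sorted(sets.leg) if g in cds])
        rscu_heg, rscu_leg = rscu(heg_counts), rscu(leg_counts)
        rows = [
            {"family": fam.label, "codon": c, "scope": scope, "rscu": table[c]}
            for fam in families
            for c in fam.codons
            for scope, table in (("HEG", rscu_heg), ("LEG", rscu_leg))
        ]
        _write_tsv(pd.DataFrame(rows), out / "rscu.tsv")
    except Exception as exc:
        fail("rscu", exc)

    try:
        stage("optimal_codons")
        calls = identify_optimal(rscu_heg, rscu_leg, families)
        preds_by_source = {
            name: predict_preferred(parts[2], parts[1], families, source=name)
            for name, parts in avail_by_source.items()
        }
        confirm = None
        tpm_sources = [n for n in preds_by_source if n.startswith("tpm")]
        if len(tpm_sources) >= 2:
            confirm = confirm_predictions(
                preds_by_source[tpm_sources[0]], preds_by_source[tpm_sources[1]]
            )
        rows = []
        calls_by_family = {c.family: c for c in calls}
        for fam in families:
            call = calls_by_family[fam.label]
            row = {
                "family": fam.label,
                "synonymous_codons": ",".join(fam.codons),
                "optimal_codon": call.codon or "",
                "failure_reason": call.reason or "",
            }
            for name, preds in preds_by_source.items():
                pred = next(p for p in preds if p.family == fam.label)
                row[f"predicted_{name}"] = ",".join(pred.codons)
                matched, _ = match_score([call], [pred], strict=config.strict_ties)
                row[f"match_{name}"] = int(matched == 1) if call.codon else ""
            if confirm is not None:
                row["confirmed"] = int(confirm.get(fam.label, False))
            rows.append(row)
        _write_tsv(pd.DataFrame(rows), out / "table1.tsv")
        match_summary = {
            name: match_score(calls, preds, strict=config.strict_ties)
            for name, preds in preds_by_source.items()
        }
    except Exception as exc:
        fail("optimal_codons", exc)

    try:
        stage("tai_s")
        genes = sorted((sets.heg | sets.leg) | set(protein.index[protein > 0]) & set(cds))
        genes = [g for g in genes if g in cds]
        per_gene_counts = {g: count_codons(cds[g]) for g in genes}
        nc_vals = {g: nc(per_gene_counts[g]) for g in genes}
        gc3s_vals = {g: gc3s(cds[g]) for g in genes}
        s_rows = []
        for name, ab in abundances.items():
            model = tai_weights(ab, trnas, rules)
            tai_vals = {g: gene_tai(model, per_gene_counts[g]) for g in genes}
            result = s_statistic(tai_vals, nc_vals, gc3s_vals)
            _write_tsv(result.per_gene, out / f"tai_genes_{name}.tsv")
            s_rows.append(
                {"source": name, "S": result.S, "p": result.p_value,
                 "method": result.method, "n": result.n}
            )
        _write_tsv(pd.DataFrame(s_rows), out / "table3.tsv")
    except Exception as exc:
        fail("tai_s", exc)

    try:
        stage("diagnostics")
        tpm_ab = None
        if config.trna_abundance:
            table = read_abundance_table(config.trna_abundance[0], renormalize=config.renormalize)
            tpm_ab = table.tpm.to_dict()
        if tpm_ab is not None and any(t.methylation_sites for t in trnas):
            report = methylation_classes(trnas, tpm_ab)
            _write_tsv(report.per_trna, out / "methylation.tsv")
            manifest["methylation_p"] = report.p_value
        if config.depth_table:
            profiles = read_depth_table(
                config.depth_table, {t.id: len(t.sequence) for t in trnas}
            )
            stops = detect_hard_stops(profiles)
            _write_tsv(
                pd.DataFrame(
                    [
                        {"trna_id": h.trna_id, "site": h.site,
                         "upstream_mean": h.upstream_mean, "downstream_mean": h.downstream_mean}
                        for h in stops
                    ],
                    columns=["trna_id", "site", "upstream_mean", "downstream_mean"],
                ),
                out / "hardstops.tsv",
            )
    except Exception as exc:
        fail("diagnostics", exc)

    manifest["match_scores"] = {k: list(v) for k, v in match_summary.items()}
    manifest["n_heg"], manifest["n_leg"] = len(sets.heg), len(sets.leg)
    manifest["complete"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
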