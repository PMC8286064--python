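"""End-to-end orchestration: framework -> signal -> cleavage -> domains ->
features -> (gene structure) -> classification, with per-record fault
isolation.  Public irp corpora contain erroneous or incomplete records, so a
batch never aborts: failures are reported in their own row."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .classify import FamilyCall, FeatureVector, classify_family, extract_features
from .cleavage import CleavageSite, find_sites, predict_signal_cleavage
from .config import Config
from .cys_framework import (BridgeCall, CysFramework, classify_extra_cysteines,
                            find_core_framework, infer_bridges)
from .domains import (DomainAnnotation, TailFeatures, domain_gff3_lines,
                      f_domain_metrics, segment_domains, tail_features)
from .genes import compute_intron_phases, gene_signature, map_introns_to_domains
from .io import GeneModel, SequenceRecord

logger = logging.getLogger("irpkit")

__all__ = ["RecordResult", "annotate_record", "run_annotate", "report_table",
           "domain_gff3"]


@dataclass
class RecordResult:
    """Everything the pipeline derived for one precursor (or its failure)."""

    record: SequenceRecord
    framework: CysFramework | None = None
    signal_pos: int | None = None
    sites: list[CleavageSite] = field(default_factory=list)
    annotation: DomainAnnotation | None = None
    tail: TailFeatures | None = None
    f_metrics: tuple[int, float | None] | None = None
    bridges: BridgeCall | None = None
    features: FeatureVector | None = None
    call: FamilyCall | None = None
    introns: list = field(default_factory=list)
    gene_token: str | None = None
    failure: str | None = None


def annotate_record(record: SequenceRecord, config: Config | None = None,
                    gene: GeneModel | None = None,
                    signal_override: int | None = None,
                    f_references: list[str] | None = None) -> RecordResult:
    """Run every stage on a single record; failures are captured, not raised."""
    cfg = config or Config()
    result = RecordResult(record=record)
    seq = record.residues
    try:
        result.framework = find_core_framework(seq, cfg)
        if result.framework is None:
            result.features = extract_features(record, None, None, None, None, [])
            result.call = classify_family(result.features, cfg)
            result.failure = "no cysteine framework"
            return result
        override = signal_override if signal_override is not None \
            else record.signal_cleavage
        result.signal_pos = predict_signal_cleavage(seq, override, cfg)
        result.sites = find_sites(seq, result.signal_pos, result.framework, cfg)
        result.annotation = segment_domains(
            seq, result.signal_pos, result.framework, result.sites, cfg)
        extras = classify_extra_cysteines(seq, result.framework, result.annotation)
        result.framework = result.framework.with_extras(extras)
        result.bridges = infer_bridges(result.framework)
        result.tail = tail_features(seq, result.annotation)
        result.f_metrics = f_domain_metrics(seq, result.annotation,
                                            f_references, cfg)
        if gene is not None:
            introns = compute_intron_phases(gene)
            introns = map_introns_to_domains(
                introns, result.annotation, gene.cds_length, len(seq))
            result.introns = introns
            result.gene_token = gene_signature(introns, gene.cds_length, cfg).token
        result.features = extract_features(
            record, result.framework, result.annotation, result.tail,
            result.f_metrics, result.sites, result.gene_token)
        result.call = classify_family(result.features, cfg)
    except ValueError as exc:
        logger.warning("%s: %s", record.id, exc)
        result.failure = str(exc)
        if result.call is None:
            result.call = FamilyCall("unclassified", "low", ("pipeline-error",))
    return result


def run_annotate(records: list[SequenceRecord], config: Config | None = None,
                 genes: dict[str, GeneModel] | None = None,
                 signal_overrides: dict[str, int] | None = None,
                 f_references: list[str] | None = None) -> list[RecordResult]:
    """Annotate a batch; every input record yields exactly one result."""
    cfg = config or Config()
    genes = genes or {}
    overrides = signal_overrides or {}
    return [
        annotate_record(rec, cfg, genes.get(rec.id), overrides.get(rec.id),
                        f_references)
        for rec in records
    ]


def report_table(results: list[RecordResult]) -> pd.DataFrame:
    """One row per input record, including failures (with their reason)."""
    rows = []
    for res in results:
        fw = res.framework
        row = {
            "id": res.record.id,
            "length": len(res.record.residues),
            "core_cys_positions": ",".join(str(p + 1) for p in fw.core_positions)
                                  if fw else "",
            "n_extra_cys": len(fw.extra_cys) if fw else 0,
            "n_bridges": res.bridges.n_bridges if res.bridges else "",
            "signal_end": res.signal_pos + 1 if res.signal_pos is not None else "",
            "chain_mode": res.annotation.chain_mode if res.annotation else "",
            "domains": ";".join(
                f"{tag}:{s + 1}-{e}" for tag, (s, e) in
                sorted(res.annotation.intervals.items(), key=lambda kv: kv[1])
            ) if res.annotation else "",
            "sites": ";".join(
                f"{s.pos + 1}:{s.kind}:{s.verdict}" +
                (":" + ",".join(s.reasons) if s.reasons else "")
                for s in res.sites),
            "tail_len": res.tail.tail_len if res.tail else "",
            "charged_fraction": round(res.tail.charged_fraction, 3)
                                if res.tail else "",
            "f_len": res.f_metrics[0] if res.f_metrics else "",
            "gene_signature": res.gene_token or "",
            "label": res.call.label if res.call else "",
            "confidence": res.call.confidence if res.call else "",
            "runner_up": res.call.runner_up or "" if res.call else "",
            "evidence": ";".join(res.call.evidence) if res.call else "",
            "failure": res.failure or "",
        }
        rows.append(row)
    return pd.DataFrame(rows)


def domain_gff3(results: list[RecordResult]) -> str:
    lines = ["##gff-version 3"]
    for res in results:
        if res.annotation is not None:
            lines.extend(domain_gff3_lines(res.record.id, res.annotation))
    return "\n".join(lines) + "\n"
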