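"""End-to-end orchestration: prefilter -> inheritance -> annotation ->
cascade -> novelty -> validation screens -> ranked report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from pedexome import io as pio
from pedexome.cascade import (
    AnnotationRecord,
    CascadeReport,
    CascadeResources,
    ConfigurationError,
    novelty_filter,
    prefilter_multiallelic,
    run_cascade,
)
from pedexome.consequence import ReferenceMismatchError, TranscriptModel, classify_variant
from pedexome.pedigree import (
    InheritanceModel,
    Pedigree,
    SiteGenotypes,
    applicable_models,
    filter_by_inheritance,
)
from pedexome.prioritize import PredictionProfile, ValidationRecord, rank_candidates

logger = logging.getLogger("pedexome")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_stages", "run_on_dataset"]


@dataclass
class PipelineConfig:
    """File-level configuration; every path must exist at run time."""

    vcf: str
    ped: str
    transcripts: str
    cds_fasta: str
    conserved_bed: str
    segdup_bed: str
    dbsnp: str
    freq_1000g: str
    freq_esp: str | None = None
    predictions: str | None = None
    validations: str | None = None
    disease_genes: str | None = None
    outdir: str | None = None
    maf_threshold: float = 0.05
    splice_window: int = 2
    models: str | Sequence[str] = "auto"
    lenient_consensus: bool = False

    def __post_init__(self):
        if not 0.0 <= self.maf_threshold <= 1.0:
            raise ConfigurationError(f"maf_threshold {self.maf_threshold} outside [0,1]")
        required = [
            self.vcf, self.ped, self.transcripts, self.cds_fasta,
            self.conserved_bed, self.segdup_bed, self.dbsnp, self.freq_1000g,
        ]
        for p in required:
            if not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    ranked: list[dict]
    candidates: list[AnnotationRecord]
    survivors: list[AnnotationRecord]
    cascade_report: CascadeReport
    per_model_reports: dict[str, CascadeReport]
    inheritance_counts: dict[str, int]
    excluded_scopes: set[str]
    n_input: int = 0
    n_multiallelic_dropped: int = 0
    n_reference_mismatch: int = 0
    logs: list[str] = field(default_factory=list)

    @property
    def top_candidate(self) -> dict | None:
        return self.ranked[0] if self.ranked else None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ranked = [
            {**row, "uninformative_carriers": ";".join(row["uninformative_carriers"]) or "."}
            for row in self.ranked
        ]
        cols = ["rank", "gene", "chrom", "pos", "ref", "alt", "consensus_deleterious",
                "family_specific", "cosegregates", "disease_gene", "validated",
                "uninformative_carriers"]
        pd.DataFrame(ranked, columns=cols).to_csv(outdir / "report.tsv", sep="\t", index=False)
        pio.write_json(
            {
                "ranked": ranked,
                "inheritance_counts": self.inheritance_counts,
                "excluded_scopes": sorted(self.excluded_scopes),
                "cascade": self.cascade_report.rows(),
                "cascade_per_model": {
                    m: rep.rows() for m, rep in self.per_model_reports.items()
                },
                "n_input": self.n_input,
                "n_multiallelic_dropped": self.n_multiallelic_dropped,
                "n_reference_mismatch": self.n_reference_mismatch,
                "logs": self.logs,
            },
            outdir / "report.json",
        )
        pd.DataFrame(self.cascade_report.rows()).to_csv(
            outdir / "cascade.tsv", sep="\t", index=False
        )


def _annotate_sites(
    sites: Sequence[SiteGenotypes],
    transcripts: Sequence[TranscriptModel],
    splice_window: int,
    logs: list[str],
) -> tuple[list[AnnotationRecord], int]:
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_chrom.setdefault(tx.chrom, []).append(tx)
    records: list[AnnotationRecord] = []
    mismatches = 0
    for site in sites:
        try:
            cons = classify_variant(
                by_chrom.get(site.chrom, []), site.chrom, site.pos, site.ref,
                site.alt, splice_window,
            )
        except ReferenceMismatchError as exc:
            mismatches += 1
            logs.append(f"reference mismatch, site skipped: {exc}")
            continue
        records.append(
            AnnotationRecord(
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                alt=site.alt,
                gene=cons.gene,
                function=cons.region,
                exonic_function=cons.category if cons.region == "exonic" else None,
                site=site,
            )
        )
    return records, mismatches


def run_stages(
    raw_sites: Sequence,
    pedigree: Pedigree,
    transcripts: Sequence[TranscriptModel],
    resources: CascadeResources,
    predictions: Mapping[str, PredictionProfile] | None = None,
    validations: Mapping[tuple, ValidationRecord] | None = None,
    disease_genes: set[str] | None = None,
    maf_threshold: float = 0.05,
    splice_window: int = 2,
    models: str | Sequence[str] = "auto",
    lenient: bool = False,
) -> PipelineResult:
    """Run every stage on in-memory inputs."""
    logs: list[str] = []
    n_input = len(raw_sites)

    sites, n_multi = prefilter_multiallelic(raw_sites)
    if n_multi:
        logs.append(f"dropped {n_multi} multi-allelic loci at the pre-filter")

    auto_models, excluded = applicable_models(pedigree)
    if models == "auto":
        selected = auto_models
    else:
        selected = {InheritanceModel(m) for m in models}
    logs.append(
        "applicable models: "
        + ",".join(sorted(m.value for m in selected))
        + (f"; excluded scopes: {','.join(sorted(excluded))}" if excluded else "")
    )
    inh = filter_by_inheritance(sites, pedigree, models=selected)
    union = inh.union()
    logs.append(
        "inheritance filter retained "
        + ", ".join(f"{m.value}: {len(s)}" for m, s in inh.by_model.items())
        + f"; dropped {len(inh.dropped_excluded_chrom)} on excluded chromosomes"
    )

    records, n_mismatch = _annotate_sites(union, transcripts, splice_window, logs)
    by_key = {r.key: r for r in records}

    # accounting reconciliation: nothing between inheritance and annotation
    # vanishes except logged reference mismatches
    assert len(records) + n_mismatch == len(union)

    survivors, report = run_cascade(records, resources, maf_threshold)
    per_model: dict[str, CascadeReport] = {}
    for model, model_sites in inh.by_model.items():
        model_records = [by_key[s.key] for s in model_sites if s.key in by_key]
        _, model_report = run_cascade(model_records, None, maf_threshold)
        per_model[model.value] = model_report

    candidates = novelty_filter(survivors, resources.freq_1000g, resources.freq_esp)
    logs.append(
        f"cascade retained {len(survivors)}; novelty filter retained {len(candidates)}"
    )

    ranked = rank_candidates(
        candidates,
        predictions or {},
        validations or {},
        disease_genes or set(),
        pedigree=pedigree,
        lenient=lenient,
    )
    n_calling_errors = len(candidates) - len(ranked)
    if n_calling_errors:
        logs.append(f"removed {n_calling_errors} candidates marked as calling errors")

    for line in logs:
        logger.info(line)
    return PipelineResult(
        ranked=ranked,
        candidates=candidates,
        survivors=survivors,
        cascade_report=report,
        per_model_reports=per_model,
        inheritance_counts=inh.counts,
        excluded_scopes=excluded,
        n_input=n_input,
        n_multiallelic_dropped=n_multi,
        n_reference_mismatch=n_mismatch,
        logs=logs,
    )


def run_on_dataset(dataset, **kwargs) -> PipelineResult:
    """Run all stages on a :class:`pedexome.simulate.FamilyDataset`."""
    resources = CascadeResources(
        conserved=dataset.conserved,
        segdup=dataset.segdup,
        dbsnp=set(dataset.dbsnp),
        freq_1000g=dataset.freq_1000g,
        freq_esp=dataset.freq_esp,
    )
    return run_stages(
        dataset.raw_sites,
        dataset.pedigree,
        dataset.transcripts,
        resources,
        predictions=dataset.predictions,
        validations=dataset.validations,
        disease_genes=dataset.disease_genes,
        **kwargs,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load every input file, run all stages and write reports."""
    pedigree = pio.read_ped(config.ped)
    raw_sites = pio.read_vcf(config.vcf, pedigree)
    # sequenced status follows the VCF sample sheet when the PED lacks flags
    transcripts = pio.read_transcripts(config.transcripts, config.cds_fasta)
    resources = CascadeResources(
        conserved=pio.read_bed(config.conserved_bed),
        segdup=pio.read_bed(config.segdup_bed),
        dbsnp=set(pio.read_dbsnp_table(config.dbsnp)),
        freq_1000g=pio.read_freq_table(config.freq_1000g),
        freq_esp=pio.read_freq_table(config.freq_esp) if config.freq_esp else {},
    )
    predictions = pio.read_predictions(config.predictions) if config.predictions else {}
    validations = pio.read_validations(config.validations) if config.validations else {}
    disease = pio.read_gene_list(config.disease_genes) if config.disease_genes else set()
    result = run_stages(
        raw_sites,
        pedigree,
        transcripts,
        resources,
        predictions=predictions,
        validations=validations,
        disease_genes=disease,
        maf_threshold=config.maf_threshold,
        splice_window=config.splice_window,
        models=config.models,
        lenient=config.lenient_consensus,
    )
    if config.outdir:
        result.write(config.outdir)
    return result
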