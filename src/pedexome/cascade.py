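"""Staged annotation/frequency filter with per-step accounting.

Order of operations, each recorded in the :class:`CascadeReport`:

1. keep region class in {exonic, splicing}
2. drop synonymous SNVs (indels are exempt)
3. keep variants in conserved regions
4. drop variants in segmental-duplication regions
5. drop known-variant (dbSNP-style) members, keyed by (chrom,pos,ref,alt)
6. drop variants with a population frequency >= the MAF threshold
   (absent frequency retains the variant)

The separate :func:`novelty_filter` then removes *any* variant with a
reported frequency entry in either population table, regardless of
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pedexome.intervals import GenomeIntervals
from pedexome.pedigree import SiteGenotypes

__all__ = [
    "AnnotationRecord",
    "CascadeReport",
    "CascadeResources",
    "ConfigurationError",
    "prefilter_multiallelic",
    "annotate_resources",
    "run_cascade",
    "novelty_filter",
    "CASCADE_STEPS",
]

VariantKey = tuple[str, int, str, str]


class ConfigurationError(ValueError):
    """A required resource is missing or malformed."""


@dataclass
class AnnotationRecord:
    """One variant with everything the cascade consumes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    function: str = "intergenic"           # region class
    exonic_function: str | None = None     # Consequence category when exonic
    conserved: bool = False
    segdup: bool = False
    dbsnp_id: str | None = None
    maf_1000g: float | None = None
    maf_esp: float | None = None
    predictions: object | None = None
    site: SiteGenotypes | None = None

    def __post_init__(self):
        for maf in (self.maf_1000g, self.maf_esp):
            if maf is not None and not 0.0 <= maf <= 1.0:
                raise ValueError(f"allele frequency {maf} outside [0,1]")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class CascadeReport:
    """Ordered (step name, retained SNVs, retained indels) accounting."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, records: Sequence[AnnotationRecord]) -> None:
        indels = sum(1 for r in records if r.is_indel)
        self.steps.append((name, len(records) - indels, indels))

    def rows(self) -> list[dict]:
        return [
            {"step": name, "snvs": s, "indels": i, "total": s + i}
            for name, s, i in self.steps
        ]

    def __iter__(self):
        return iter(self.steps)


@dataclass
class CascadeResources:
    """Frozen resource snapshots consulted by the cascade."""

    conserved: GenomeIntervals
    segdup: GenomeIntervals
    dbsnp: set[VariantKey]
    freq_1000g: dict[VariantKey, float]
    freq_esp: dict[VariantKey, float] = field(default_factory=dict)


def prefilter_multiallelic(
    sites: Iterable[SiteGenotypes | tuple],
) -> tuple[list[SiteGenotypes], int]:
    """Retain strictly biallelic sites; return (retained, dropped count).

    Accepts raw (chrom, pos, ref, alts, calls) tuples as produced by the
    VCF reader, where ``alts`` may list several alternates.
    """
    kept: list[SiteGenotypes] = []
    dropped = 0
    for s in sites:
        if isinstance(s, SiteGenotypes):
            kept.append(s)
            continue
        chrom, pos, ref, alts, calls = s
        alts = [alts] if isinstance(alts, str) else list(alts)
        if len(alts) != 1:
            dropped += 1
            continue
        kept.append(SiteGenotypes(chrom, pos, ref, alts[0], calls))
    return kept, dropped


def annotate_resources(
    records: Iterable[AnnotationRecord], resources: CascadeResources
) -> list[AnnotationRecord]:
    """Fill conserved/segdup flags and known-variant/frequency fields in place."""
    out = []
    for r in records:
        r.conserved = resources.conserved.overlaps_span(r.chrom, r.pos, r.ref)
        r.segdup = resources.segdup.overlaps_span(r.chrom, r.pos, r.ref)
        if r.key in resources.dbsnp:
            r.dbsnp_id = r.dbsnp_id or "known"
        r.maf_1000g = resources.freq_1000g.get(r.key, r.maf_1000g)
        r.maf_esp = resources.freq_esp.get(r.key, r.maf_esp)
        out.append(r)
    return out


CASCADE_STEPS = [
    "input",
    "exonic_or_splicing",
    "drop_synonymous_snv",
    "keep_conserved",
    "drop_segdup",
    "drop_known_variant",
    "maf_threshold",
]


def run_cascade(
    records: Sequence[AnnotationRecord],
    resources: CascadeResources | None = None,
    maf_threshold: float = 0.05,
) -> tuple[list[AnnotationRecord], CascadeReport]:
    """Apply the six filter steps in order, recording per-step counts.

    When ``resources`` is given, interval/known-variant/frequency fields
    are (re)derived from it first; otherwise the fields already present on
    the records are trusted.
    """
    if resources is not None:
        records = annotate_resources(records, resources)
    records = list(records)
    report = CascadeReport()
    report.add(CASCADE_STEPS[0], records)

    records = [r for r in records if r.function in ("exonic", "splicing")]
    report.add(CASCADE_STEPS[1], records)

    records = [
        r for r in records if r.is_indel or r.exonic_function != "synonymous SNV"
    ]
    report.add(CASCADE_STEPS[2], records)

    records = [r for r in records if r.conserved]
    report.add(CASCADE_STEPS[3], records)

    records = [r for r in records if not r.segdup]
    report.add(CASCADE_STEPS[4], records)

    records = [r for r in records if r.dbsnp_id is None]
    report.add(CASCADE_STEPS[5], records)

    records = [
        r for r in records if r.maf_1000g is None or r.maf_1000g < maf_threshold
    ]
    report.add(CASCADE_STEPS[6], records)

    return records, report


def novelty_filter(
    survivors: Sequence[AnnotationRecord],
    freq_1000g: dict[VariantKey, float] | None = None,
    freq_esp: dict[VariantKey, float] | None = None,
) -> list[AnnotationRecord]:
    """Drop any survivor with a reported entry in either frequency table.

    Unlike the cascade's threshold step, magnitude is irrelevant here: a
    reported frequency of any size marks the variant as known.
    """
    freq_1000g = freq_1000g or {}
    freq_esp = freq_esp or {}
    out = []
    for r in survivors:
        known = (
            r.maf_1000g is not None
            or r.maf_esp is not None
            or r.key in freq_1000g
            or r.key in freq_esp
        )
        if not known:
            out.append(r)
    return out
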