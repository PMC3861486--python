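"""Readers and writers for the pipeline's file formats.

PED is 6-column whitespace-delimited (family, id, father, mother, sex 1/2,
phenotype 1/2/0) with an optional 7th ``sequenced`` column; VCF goes
through :mod:`pysam`; transcripts are a minimal TSV plus a FASTA of CDS
sequences; resource tables are headered TSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from pedexome.consequence import TranscriptModel
from pedexome.intervals import GenomeIntervals
from pedexome.pedigree import (
    Affection,
    GenotypeCall,
    MISSING_CALL,
    Member,
    Pedigree,
    Sex,
    is_x,
)
from pedexome.prioritize import PredictionProfile, ValidationRecord

VariantKey = tuple[str, int, str, str]

_SEX_CODE = {Sex.MALE: "1", Sex.FEMALE: "2"}
_SEX_FROM = {"1": Sex.MALE, "2": Sex.FEMALE}
_AFF_CODE = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2", Affection.UNKNOWN: "0"}
_AFF_FROM = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED, "0": Affection.UNKNOWN,
             "-9": Affection.UNKNOWN}


class FormatError(ValueError):
    """Malformed input, reported with file/line context."""


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(
    path: str | Path,
    sequenced_ids: Iterable[str] | None = None,
) -> Pedigree:
    """Parse a PED file; ``sequenced_ids`` overrides any 7th column."""
    sequenced = set(sequenced_ids) if sequenced_ids is not None else None
    members: list[Member] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: expected >=6 PED columns, got {len(fields)}")
        _, mid, father, mother, sex, pheno = fields[:6]
        if sex not in _SEX_FROM:
            raise FormatError(f"{path}:{lineno}: bad sex code {sex!r}")
        if pheno not in _AFF_FROM:
            raise FormatError(f"{path}:{lineno}: bad phenotype code {pheno!r}")
        if sequenced is not None:
            seq_flag = mid in sequenced
        else:
            seq_flag = len(fields) > 6 and fields[6] in ("1", "yes", "true")
        members.append(
            Member(
                id=mid,
                sex=_SEX_FROM[sex],
                affection=_AFF_FROM[pheno],
                father_id=None if father in ("0", ".") else father,
                mother_id=None if mother in ("0", ".") else mother,
                sequenced=seq_flag,
            )
        )
    return Pedigree(members)


def write_ped(pedigree: Pedigree, path: str | Path, family_id: str = "FAM1") -> None:
    lines = []
    for m in pedigree:
        lines.append(
            "\t".join(
                [
                    family_id,
                    m.id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    _SEX_CODE[m.sex],
                    _AFF_CODE[m.affection],
                    "1" if m.sequenced else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _call_from_gt(alleles: tuple, on_x: bool, male: bool) -> GenotypeCall:
    vals = [a for a in alleles if a is not None]
    if not vals:
        return MISSING_CALL
    if len(alleles) == 1:
        return GenotypeCall(vals[0], hemizygous=True)
    alt = sum(1 for a in vals if a > 0)
    if on_x and male and len(set(vals)) == 1:
        # homozygous-style male X call collapses to a hemizygous one
        return GenotypeCall(min(alt, 1), hemizygous=True)
    return GenotypeCall(alt)


def read_vcf(path: str | Path, pedigree: Pedigree | None = None) -> list[tuple]:
    """Read raw sites as (chrom, pos, ref, alts, calls) tuples.

    Multi-allelic records are passed through untouched so the cascade's
    pre-filter can account for them.
    """
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            on_x = is_x(rec.chrom)
            calls: dict[str, GenotypeCall] = {}
            for sid in samples:
                male = pedigree is not None and sid in pedigree and pedigree[sid].sex is Sex.MALE
                gt = rec.samples[sid].get("GT", (None,))
                calls[sid] = _call_from_gt(tuple(gt), on_x, male)
            alts = list(rec.alts) if rec.alts else []
            out.append((rec.chrom, rec.pos, rec.ref, alts, calls))
    return out


def write_vcf(
    sites: Sequence,
    sample_ids: Sequence[str],
    path: str | Path,
    contigs: Sequence[str] | None = None,
) -> None:
    """Write biallelic SiteGenotypes (or raw tuples) as an uncompressed VCF."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    seen_contigs = contigs or list(dict.fromkeys(
        s.chrom if hasattr(s, "chrom") else s[0] for s in sites
    ))
    for c in seen_contigs:
        header.contigs.add(c)
    for sid in sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sites:
            if hasattr(s, "chrom"):
                chrom, pos, ref, alts, calls = s.chrom, s.pos, s.ref, [s.alt], s.calls
            else:
                chrom, pos, ref, alts, calls = s
            rec = vcf.new_record(
                contig=chrom, start=pos - 1, alleles=(ref, *alts), filter="PASS"
            )
            for sid in sample_ids:
                call = calls.get(sid, MISSING_CALL)
                if call.missing:
                    rec.samples[sid]["GT"] = (None, None)
                elif call.hemizygous:
                    rec.samples[sid]["GT"] = (call.alt_count,)
                else:
                    gt = [(0, 0), (0, 1), (1, 1)][call.alt_count]
                    rec.samples[sid]["GT"] = gt
            vcf.write(rec)


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------

def write_transcripts(
    transcripts: Sequence[TranscriptModel], tsv_path: str | Path, fasta_path: str | Path
) -> None:
    rows = []
    records = []
    for tx in transcripts:
        rows.append(
            {
                "gene": tx.gene,
                "transcript_id": tx.transcript_id,
                "chrom": tx.chrom,
                "strand": tx.strand,
                "exons": ",".join(f"{a}-{b}" for a, b in tx.exons),
                "cds_start": tx.cds_start,
                "cds_end": tx.cds_end,
            }
        )
        records.append(SeqRecord(Seq(tx.cds_sequence), id=tx.transcript_id, description=""))
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    SeqIO.write(records, str(fasta_path), "fasta")


def read_transcripts(tsv_path: str | Path, fasta_path: str | Path) -> list[TranscriptModel]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        if row.transcript_id not in seqs:
            raise FormatError(f"{fasta_path}: no CDS sequence for {row.transcript_id}")
        exons = []
        for part in str(row.exons).split(","):
            a, b = part.split("-")
            exons.append((int(a), int(b)))
        out.append(
            TranscriptModel(
                gene=row.gene,
                transcript_id=row.transcript_id,
                chrom=str(row.chrom),
                strand=row.strand,
                exons=exons,
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                cds_sequence=seqs[row.transcript_id],
            )
        )
    return out


# ---------------------------------------------------------------------------
# BED and TSV resource tables
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> GenomeIntervals:
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
        rows.append((fields[0], int(fields[1]), int(fields[2])))
    return GenomeIntervals.from_bed_rows(rows)


def write_bed(intervals: GenomeIntervals, path: str | Path) -> None:
    lines = [f"{c}\t{s}\t{e}" for c, s, e in intervals.to_bed_rows()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_freq_table(path: str | Path) -> dict[VariantKey, float]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (str(r.chrom), int(r.pos), r.ref, r.alt): float(r.af)
        for r in df.itertuples(index=False)
    }


def write_freq_table(freqs: dict[VariantKey, float], path: str | Path) -> None:
    rows = [
        {"chrom": c, "pos": p, "ref": r, "alt": a, "af": af}
        for (c, p, r, a), af in sorted(freqs.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"]).to_csv(
        path, sep="\t", index=False
    )


def read_dbsnp_table(path: str | Path) -> dict[VariantKey, str]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (str(r.chrom), int(r.pos), r.ref, r.alt): str(r.id)
        for r in df.itertuples(index=False)
    }


def write_dbsnp_table(entries: dict[VariantKey, str], path: str | Path) -> None:
    rows = [
        {"chrom": c, "pos": p, "ref": r, "alt": a, "id": rid}
        for (c, p, r, a), rid in sorted(entries.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "id"]).to_csv(
        path, sep="\t", index=False
    )


_PRED_COLS = ["phylop", "sift", "polyphen", "lrt", "mutation_taster", "gerp", "sift2013"]


def read_predictions(path: str | Path) -> dict[str, PredictionProfile]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = {}
    for r in df.itertuples(index=False):
        out[str(r.gene)] = PredictionProfile(
            **{c: getattr(r, c) for c in _PRED_COLS}
        )
    return out


def write_predictions(profiles: dict[str, PredictionProfile], path: str | Path) -> None:
    rows = [
        {"gene": gene, **dict(zip(_PRED_COLS, prof.as_tuple()))}
        for gene, prof in sorted(profiles.items())
    ]
    pd.DataFrame(rows, columns=["gene", *_PRED_COLS]).to_csv(path, sep="\t", index=False)


def _genotypes_to_str(genotypes) -> str:
    parts = []
    for mid in sorted(genotypes):
        call = genotypes[mid]
        parts.append(f"{mid}={'.' if call.missing else call.alt_count}")
    return ";".join(parts)


def _genotypes_from_str(text: str) -> dict[str, GenotypeCall]:
    out: dict[str, GenotypeCall] = {}
    if not text or text == ".":
        return out
    for part in text.split(";"):
        mid, val = part.split("=")
        out[mid] = MISSING_CALL if val == "." else GenotypeCall(int(val))
    return out


def read_validations(path: str | Path) -> dict[VariantKey, ValidationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    out = {}
    for r in df.itertuples(index=False):
        rec = ValidationRecord(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            family_genotypes=_genotypes_from_str(str(r.family_genotypes)),
            control_carrier_count=int(r.control_carriers),
            control_n=int(r.control_n),
            validated=str(r.validated).lower() in ("1", "true", "yes"),
        )
        out[rec.key] = rec
    return out


def write_validations(records: dict[VariantKey, ValidationRecord], path: str | Path) -> None:
    rows = []
    for key in sorted(records):
        v = records[key]
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "family_genotypes": _genotypes_to_str(v.family_genotypes) or ".",
                "control_carriers": v.control_carrier_count,
                "control_n": v.control_n,
                "validated": str(v.validated).lower(),
            }
        )
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "family_genotypes",
                 "control_carriers", "control_n", "validated"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
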