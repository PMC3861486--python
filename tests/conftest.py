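"""Shared fixtures: pedigrees and toy transcript models."""

import pytest

from pedexome.consequence import TranscriptModel
from pedexome.pedigree import Affection, Member, Pedigree, Sex
from pedexome.simulate import default_family

A, U, K = Affection.AFFECTED, Affection.UNAFFECTED, Affection.UNKNOWN
M, F = Sex.MALE, Sex.FEMALE


@pytest.fixture
def family7() -> Pedigree:
    """The default 7-member study-style family (5 sequenced)."""
    return default_family()


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        [
            Member("dad", M, U, sequenced=True),
            Member("mom", F, U, sequenced=True),
            Member("kid", M, A, "dad", "mom", sequenced=True),
        ]
    )


@pytest.fixture
def quartet() -> Pedigree:
    return Pedigree(
        [
            Member("dad", M, A, sequenced=True),
            Member("mom", F, U, sequenced=True),
            Member("son", M, A, "dad", "mom", sequenced=True),
            Member("dau", F, U, "dad", "mom", sequenced=True),
        ]
    )


@pytest.fixture
def sextet() -> Pedigree:
    """Three generations, mixed affection, one unknown, partial sequencing."""
    return Pedigree(
        [
            Member("gpa", M, A),
            Member("gma", F, U, sequenced=True),
            Member("dad", M, A, "gpa", "gma", sequenced=True),
            Member("mom", F, U, sequenced=True),
            Member("kid1", F, A, "dad", "mom", sequenced=True),
            Member("kid2", M, Affection.UNKNOWN, "dad", "mom", sequenced=True),
        ]
    )


def _toy_cds(codon232: str = "GGG", n_codons: int = 300) -> str:
    codons = ["ATG"] + ["GCT"] * (n_codons - 2) + ["TAA"]
    codons[231] = codon232  # codon index 232
    return "".join(codons)


@pytest.fixture
def plus_tx() -> TranscriptModel:
    """Single-exon plus-strand transcript; codon 232 is GGG (Gly)."""
    cds = _toy_cds()
    return TranscriptModel(
        gene="TOY1",
        transcript_id="TOYTX1.1",
        chrom="1",
        strand="+",
        exons=[(1000, 1000 + len(cds) - 1)],
        cds_start=1000,
        cds_end=1000 + len(cds) - 1,
        cds_sequence=cds,
    )


@pytest.fixture
def minus_tx() -> TranscriptModel:
    """Minus-strand sibling of plus_tx (same CDS in coding orientation)."""
    cds = _toy_cds()
    return TranscriptModel(
        gene="TOY2",
        transcript_id="TOYTX2.1",
        chrom="1",
        strand="-",
        exons=[(5000, 5000 + len(cds) - 1)],
        cds_start=5000,
        cds_end=5000 + len(cds) - 1,
        cds_sequence=cds,
    )


@pytest.fixture
def split_tx() -> TranscriptModel:
    """Two-exon plus-strand transcript with an intron (CDS spans both exons)."""
    return TranscriptModel(
        gene="TOY3",
        transcript_id="TOYTX3.1",
        chrom="2",
        strand="+",
        exons=[(100, 129), (200, 229)],
        cds_start=100,
        cds_end=229,
        cds_sequence="ATG" + "GCT" * 18 + "TAA",  # 60 bases
    )
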