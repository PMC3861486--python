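"""Transcript-model consequence classification and HGVS c./p. naming.

Coordinates are genomic 1-based inclusive internally; BED-style inputs are
converted at the I/O boundary.  CDS positions are 1-based indices into the
spliced coding sequence in coding orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = [
    "TranscriptModel",
    "Consequence",
    "ReferenceMismatchError",
    "SEVERITY_ORDER",
    "cds_to_codon",
    "codon_to_cds",
    "genomic_to_cds",
    "cds_to_genomic",
    "classify_variant",
    "translate_codon",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceMismatchError(ValueError):
    """Observed REF allele disagrees with the transcript CDS sequence."""


@dataclass
class TranscriptModel:
    """A coding transcript: exon structure, CDS bounds and CDS sequence.

    ``exons`` are genomic 1-based inclusive intervals, sorted and
    non-overlapping.  ``cds_sequence`` is the spliced coding sequence in
    coding orientation; its length must equal the genomic CDS footprint.
    A CDS length not divisible by 3 is allowed (partial transcript) but
    flagged via :attr:`partial`.
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    cds_sequence: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if a > b:
                raise ValueError(f"exon interval reversed: {a}-{b}")
        for (_, b1), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 <= b1:
                raise ValueError("exons overlap or are unsorted")
        self.cds_sequence = self.cds_sequence.upper()
        expect = sum(
            max(0, min(b, self.cds_end) - max(a, self.cds_start) + 1) for a, b in self.exons
        )
        if expect != len(self.cds_sequence):
            raise ValueError(
                f"{self.transcript_id}: spliced CDS footprint {expect} != sequence length "
                f"{len(self.cds_sequence)}"
            )

    @property
    def partial(self) -> bool:
        return len(self.cds_sequence) % 3 != 0

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def contains(self, gpos: int) -> bool:
        lo, hi = self.span
        return lo <= gpos <= hi

    def in_exon(self, gpos: int) -> bool:
        return any(a <= gpos <= b for a, b in self.exons)

    def _coding_segments(self) -> list[tuple[int, int]]:
        segs = []
        for a, b in self.exons:
            lo, hi = max(a, self.cds_start), min(b, self.cds_end)
            if lo <= hi:
                segs.append((lo, hi))
        return segs


def cds_to_codon(cds_pos: int) -> tuple[int, int]:
    """Map a 1-based coding nucleotide index to (codon index, offset 1..3)."""
    if cds_pos < 1:
        raise ValueError(f"cds_pos must be >= 1, got {cds_pos}")
    return (cds_pos - 1) // 3 + 1, (cds_pos - 1) % 3 + 1


def codon_to_cds(codon_index: int, offset: int) -> int:
    """Inverse of :func:`cds_to_codon`."""
    if codon_index < 1 or offset not in (1, 2, 3):
        raise ValueError("codon_index >= 1 and offset in {1,2,3} required")
    return (codon_index - 1) * 3 + offset


def genomic_to_cds(transcript: TranscriptModel, gpos: int) -> int | None:
    """1-based coding position of ``gpos``, or ``None`` if non-coding."""
    offset = 0
    segs = transcript._coding_segments()
    if transcript.strand == "-":
        for a, b in reversed(segs):
            if a <= gpos <= b:
                return offset + (b - gpos) + 1
            offset += b - a + 1
        return None
    for a, b in segs:
        if a <= gpos <= b:
            return offset + (gpos - a) + 1
        offset += b - a + 1
    return None


def cds_to_genomic(transcript: TranscriptModel, cds_pos: int) -> int:
    """Genomic position of coding index ``cds_pos`` (inverse of genomic_to_cds)."""
    if cds_pos < 1 or cds_pos > len(transcript.cds_sequence):
        raise ValueError(f"cds_pos {cds_pos} outside CDS of {transcript.transcript_id}")
    remaining = cds_pos
    segs = transcript._coding_segments()
    if transcript.strand == "-":
        for a, b in reversed(segs):
            n = b - a + 1
            if remaining <= n:
                return b - remaining + 1
            remaining -= n
    else:
        for a, b in segs:
            n = b - a + 1
            if remaining <= n:
                return a + remaining - 1
            remaining -= n
    raise AssertionError("unreachable")


def translate_codon(codon: str) -> str:
    """One-letter amino acid (or '*' for stop) for a complete codon."""
    return str(Seq(codon).translate(table=standard_dna_table))


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


SEVERITY_ORDER = [
    "stopgain",
    "stoploss",
    "frameshift indel",
    "splicing",
    "nonsynonymous SNV",
    "nonframeshift indel",
    "synonymous SNV",
    "UTR",
    "intronic",
    "intergenic",
]
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

_EXONIC_CATEGORIES = {
    "stopgain",
    "stoploss",
    "frameshift indel",
    "nonframeshift indel",
    "nonsynonymous SNV",
    "synonymous SNV",
}


@dataclass
class Consequence:
    """Classified effect of one variant, with per-transcript detail."""

    category: str
    gene: str | None = None
    transcript_id: str | None = None
    hgvs_c: str | None = None
    hgvs_c_legacy: str | None = None
    hgvs_p: str | None = None
    hgvs_p_legacy: str | None = None
    cds_pos: int | None = None
    codon_index: int | None = None
    per_transcript: list["Consequence"] = field(default_factory=list)

    @property
    def region(self) -> str:
        """ANNOVAR-style region class: exonic / splicing / intronic / UTR / intergenic."""
        if self.category in _EXONIC_CATEGORIES:
            return "exonic"
        return self.category if self.category in ("splicing", "intronic", "UTR", "intergenic") else "intergenic"


def _near_splice(transcript: TranscriptModel, gpos: int, window: int) -> bool:
    """Within ``window`` intronic bases of an internal exon boundary."""
    if window <= 0 or len(transcript.exons) < 2:
        return False
    for (_, b1), (a2, _) in zip(transcript.exons, transcript.exons[1:]):
        if b1 < gpos < a2 and (gpos - b1 <= window or a2 - gpos <= window):
            return True
    return False


def _classify_one(
    tx: TranscriptModel,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    splice_window: int,
) -> Consequence | None:
    if chrom != tx.chrom or not tx.contains(pos):
        return None
    is_indel = len(ref) != len(alt)
    cds_pos = genomic_to_cds(tx, pos)
    if cds_pos is None:
        if tx.in_exon(pos):
            return Consequence("UTR", gene=tx.gene, transcript_id=tx.transcript_id)
        if _near_splice(tx, pos, splice_window):
            return Consequence("splicing", gene=tx.gene, transcript_id=tx.transcript_id)
        return Consequence("intronic", gene=tx.gene, transcript_id=tx.transcript_id)

    if is_indel:
        delta = abs(len(ref) - len(alt))
        cat = "frameshift indel" if delta % 3 else "nonframeshift indel"
        hgvs_c = f"c.{cds_pos}{'del' if len(ref) > len(alt) else 'ins'}"
        return Consequence(
            cat,
            gene=tx.gene,
            transcript_id=tx.transcript_id,
            hgvs_c=hgvs_c,
            hgvs_c_legacy=hgvs_c,
            cds_pos=cds_pos,
        )

    # SNV in CDS
    ref_c, alt_c = (revcomp(ref), revcomp(alt)) if tx.strand == "-" else (ref, alt)
    if tx.cds_sequence[cds_pos - 1] != ref_c:
        raise ReferenceMismatchError(
            f"{tx.transcript_id} c.{cds_pos}: transcript has "
            f"{tx.cds_sequence[cds_pos - 1]!r}, variant REF is {ref_c!r}"
        )
    codon_index, offset = cds_to_codon(cds_pos)
    start = (codon_index - 1) * 3
    codon = tx.cds_sequence[start:start + 3]
    hgvs_c = f"c.{cds_pos}{ref_c}>{alt_c}"
    legacy_c = f"c.{ref_c}{cds_pos}{alt_c}"
    if len(codon) < 3:  # partial terminal codon
        return Consequence(
            "nonsynonymous SNV",
            gene=tx.gene,
            transcript_id=tx.transcript_id,
            hgvs_c=hgvs_c,
            hgvs_c_legacy=legacy_c,
            cds_pos=cds_pos,
            codon_index=codon_index,
        )
    mutant = codon[: offset - 1] + alt_c + codon[offset:]
    aa_ref, aa_alt = translate_codon(codon), translate_codon(mutant)
    if aa_ref == aa_alt:
        cat = "synonymous SNV"
    elif aa_alt == "*":
        cat = "stopgain"
    elif aa_ref == "*":
        cat = "stoploss"
    else:
        cat = "nonsynonymous SNV"
    return Consequence(
        cat,
        gene=tx.gene,
        transcript_id=tx.transcript_id,
        hgvs_c=hgvs_c,
        hgvs_c_legacy=legacy_c,
        hgvs_p=f"p.{_aa3(aa_ref)}{codon_index}{_aa3(aa_alt)}",
        hgvs_p_legacy=f"p.{aa_ref}{codon_index}{aa_alt}",
        cds_pos=cds_pos,
        codon_index=codon_index,
    )


def classify_variant(
    transcript_set: Iterable[TranscriptModel],
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    splice_window: int = 2,
) -> Consequence:
    """Classify one variant against a set of transcripts.

    The most severe per-transcript consequence is promoted to the top
    level; every per-transcript call is retained in ``per_transcript``.
    Variants overlapping no transcript span are intergenic.
    """
    if splice_window < 0:
        raise ValueError("splice_window must be >= 0")
    per_tx: list[Consequence] = []
    for tx in transcript_set:
        c = _classify_one(tx, chrom, pos, ref, alt, splice_window)
        if c is not None:
            per_tx.append(c)
    if not per_tx:
        return Consequence("intergenic")
    best = min(per_tx, key=lambda c: _SEVERITY_RANK[c.category])
    return Consequence(
        best.category,
        gene=best.gene,
        transcript_id=best.transcript_id,
        hgvs_c=best.hgvs_c,
        hgvs_c_legacy=best.hgvs_c_legacy,
        hgvs_p=best.hgvs_p,
        hgvs_p_legacy=best.hgvs_p_legacy,
        cds_pos=best.cds_pos,
        codon_index=best.codon_index,
        per_transcript=per_tx,
    )
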