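"""Consensus deleteriousness, control screening, cosegregation and ranking."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from pedexome.pedigree import Affection, GenotypeCall, Pedigree

__all__ = [
    "PredictionProfile",
    "ValidationRecord",
    "CosegregationResult",
    "consensus_deleterious",
    "control_screen",
    "cosegregation_check",
    "rank_candidates",
]

_ALPHABETS = {
    "phylop": {"C", "N", "NA"},
    "sift": {"D", "T", "NA"},
    "polyphen": {"D", "P", "B", "NA"},
    "lrt": {"D", "N", "NA"},
    "mutation_taster": {"D", "N", "NA"},
    "gerp": {"C", "N", "NA"},
    "sift2013": {"D", "T", "B", "NA"},
}

# per-predictor values counted as damaging under strict consensus
_DAMAGING = {
    "phylop": {"C"},
    "sift": {"D"},
    "polyphen": {"D"},
    "lrt": {"D"},
    "mutation_taster": {"D"},
    "gerp": {"C"},
    "sift2013": {"D"},
}

_FIELDS = tuple(_ALPHABETS)


@dataclass(frozen=True)
class PredictionProfile:
    """Categorical calls from seven prediction programs.

    C conserved / N not conserved (PhyloP, GERP); D deleterious /
    T tolerated / B benign / P possibly damaging; NA not applicable.
    """

    phylop: str = "NA"
    sift: str = "NA"
    polyphen: str = "NA"
    lrt: str = "NA"
    mutation_taster: str = "NA"
    gerp: str = "NA"
    sift2013: str = "NA"

    def __post_init__(self):
        for name in _FIELDS:
            value = getattr(self, name)
            if value not in _ALPHABETS[name]:
                raise ValueError(
                    f"{name}={value!r} not in alphabet {sorted(_ALPHABETS[name])}"
                )

    @classmethod
    def from_values(cls, values: Sequence[str]) -> "PredictionProfile":
        return cls(**dict(zip(_FIELDS, values)))

    def as_tuple(self) -> tuple[str, ...]:
        return tuple(getattr(self, f) for f in _FIELDS)


def consensus_deleterious(profile: PredictionProfile, lenient: bool = False) -> bool:
    """Strict consensus: every predictor present *and* damaging.

    P, B, T, N and NA all fail; with ``lenient=True`` PolyPhen's
    "possibly damaging" (P) is additionally accepted.
    """
    for name in _FIELDS:
        value = getattr(profile, name)
        damaging = _DAMAGING[name]
        if lenient and name == "polyphen":
            damaging = damaging | {"P"}
        if value not in damaging:
            return False
    return True


@dataclass
class ValidationRecord:
    """Orthogonal (Sanger-style) validation facts for one candidate."""

    chrom: str
    pos: int
    ref: str
    alt: str
    family_genotypes: Mapping[str, GenotypeCall] = field(default_factory=dict)
    control_carrier_count: int = 0
    control_n: int = 0
    validated: bool = True

    def __post_init__(self):
        if not 0 <= self.control_carrier_count <= self.control_n:
            raise ValueError(
                f"carriers {self.control_carrier_count} outside [0, {self.control_n}]"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def control_screen(record: ValidationRecord) -> str:
    """'polymorphism' if any control carries the variant, else 'family_specific'."""
    if not record.validated:
        raise ValueError("control_screen requires a validated record")
    return "polymorphism" if record.control_carrier_count >= 1 else "family_specific"


@dataclass
class CosegregationResult:
    status: str  # cosegregates | violated | indeterminate
    uninformative_carriers: list[str] = field(default_factory=list)

    @property
    def cosegregates(self) -> bool:
        return self.status == "cosegregates"


def cosegregation_check(
    record: ValidationRecord, pedigree: Pedigree
) -> CosegregationResult:
    """Does the variant track with affection through the genotyped family?

    Violated when an affected member lacks the variant or an unaffected
    member carries it.  Carriers of unknown affection are listed as
    uninformative, not violations.  With no informative (affected or
    unaffected, non-missing) genotype at all the result is indeterminate.
    """
    uninformative: list[str] = []
    informative = 0
    violated = False
    for mid in sorted(record.family_genotypes):
        call = record.family_genotypes[mid]
        if call.missing:
            continue
        member = pedigree[mid]
        if member.affection is Affection.UNKNOWN:
            if call.carries_alt:
                uninformative.append(mid)
            continue
        informative += 1
        if member.affection is Affection.AFFECTED and not call.carries_alt:
            violated = True
        elif member.affection is Affection.UNAFFECTED and call.carries_alt:
            violated = True
    if informative == 0:
        return CosegregationResult("indeterminate", uninformative)
    return CosegregationResult("violated" if violated else "cosegregates", uninformative)


def rank_candidates(
    candidates: Sequence,
    profiles: Mapping[str, PredictionProfile],
    validations: Mapping[tuple, ValidationRecord] | None = None,
    disease_genes: set[str] | None = None,
    pedigree: Pedigree | None = None,
    lenient: bool = False,
) -> list[dict]:
    """Deterministically rank candidates and report every predicate.

    ``candidates`` carry ``gene`` and ``key`` attributes (AnnotationRecord
    quacks).  ``profiles`` is keyed by gene name.  Candidates whose
    validation record is marked ``validated=False`` (calling errors) are
    removed before ranking.  Sort key: consensus-deleterious, then
    family-specific, then cosegregating, then known-disease-gene
    membership, all descending, with gene name as the ascending tie-break.
    """
    validations = validations or {}
    disease_genes = disease_genes or set()
    rows: list[dict] = []
    for cand in candidates:
        gene = getattr(cand, "gene", None) or "?"
        key = getattr(cand, "key")
        validation = validations.get(key)
        if validation is not None and not validation.validated:
            continue  # calling error
        profile = profiles.get(gene)
        consensus = consensus_deleterious(profile, lenient) if profile else False
        family_specific = False
        cosegregates = False
        uninformative: list[str] = []
        if validation is not None:
            family_specific = control_screen(validation) == "family_specific"
            if pedigree is not None and validation.family_genotypes:
                coseg = cosegregation_check(validation, pedigree)
                cosegregates = coseg.cosegregates
                uninformative = coseg.uninformative_carriers
        rows.append(
            {
                "gene": gene,
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "consensus_deleterious": consensus,
                "family_specific": family_specific,
                "cosegregates": cosegregates,
                "uninformative_carriers": uninformative,
                "disease_gene": gene in disease_genes,
                "validated": validation.validated if validation is not None else None,
            }
        )
    rows.sort(
        key=lambda r: (
            not r["consensus_deleterious"],
            not r["family_specific"],
            not r["cosegregates"],
            not r["disease_gene"],
            r["gene"],
        )
    )
    for i, r in enumerate(rows, 1):
        r["rank"] = i
    return rows
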