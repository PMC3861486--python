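"""Seeded generation of complete synthetic family-exome datasets.

:func:`simulate_family_dataset` produces everything the pipeline consumes —
multi-sample genotype calls, pedigree, toy transcript models with real codon
content, conserved/segmental-duplication intervals, frequency and
known-variant tables, prediction profiles, validation facts — plus a truth
table tying every emitted variant to its generated attributes.

One planted causal variant is guaranteed to satisfy the configured
inheritance model, survive every cascade predicate and pass strict
consensus; background variants are neutral draws from population
frequencies; optional genotyping errors, missing calls, multi-allelic loci
and pedigree-consistent false-positive calls exercise the failure modes.

The module also packages the published 19-row candidate prediction table
and the validation facts for the screened candidates, used as worked-example
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from pedexome import io as pio
from pedexome.cascade import AnnotationRecord
from pedexome.consequence import (
    TranscriptModel,
    cds_to_codon,
    cds_to_genomic,
    revcomp,
    translate_codon,
)
from pedexome.intervals import GenomeIntervals
from pedexome.pedigree import (
    Affection,
    GenotypeCall,
    InheritanceModel,
    MISSING_CALL,
    Member,
    Pedigree,
    Sex,
    SiteGenotypes,
    enumerate_assignments,
    is_x,
)
from pedexome.prioritize import PredictionProfile, ValidationRecord

VariantKey = tuple[str, int, str, str]

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "FamilyDataset",
    "default_family",
    "simulate_family_dataset",
    "sample_family_genotypes",
    "candidate_profile_fixture",
    "candidate_validation_fixture",
    "candidate_sites",
    "disease_gene_fixture",
]


def default_family() -> Pedigree:
    """The default 7-member, 5-sequenced study family.

    An affected father and three affected children (two sons, one
    daughter), an unaffected mother, an unaffected paternal uncle, and a
    grandson of unestablished phenotype.  The mother, the three affected
    children and the grandson are sequenced.
    """
    return Pedigree(
        [
            Member("I-1", Sex.MALE, Affection.UNAFFECTED),
            Member("I-2", Sex.MALE, Affection.AFFECTED),
            Member("I-3", Sex.FEMALE, Affection.UNAFFECTED, sequenced=True),
            Member("II-2", Sex.MALE, Affection.AFFECTED, "I-2", "I-3", sequenced=True),
            Member("II-3", Sex.MALE, Affection.AFFECTED, "I-2", "I-3", sequenced=True),
            Member("II-4", Sex.FEMALE, Affection.AFFECTED, "I-2", "I-3", sequenced=True),
            Member("III-1", Sex.MALE, Affection.UNKNOWN, father_id="II-2", sequenced=True),
        ]
    )


@dataclass
class SimulationConfig:
    """Knobs for one simulated dataset; ``seed`` is mandatory."""

    seed: int
    model: InheritanceModel = InheritanceModel.AD
    n_background: int = 1000
    maf_beta: tuple[float, float] = (0.2, 2.0)
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    frac_exonic: float = 0.65
    frac_synonymous: float = 0.30   # among exonic SNVs
    frac_conserved: float = 0.50
    frac_segdup: float = 0.08
    frac_dbsnp: float = 0.50
    frac_known_1000g: float = 0.40
    frac_known_esp: float = 0.25
    frac_x: float = 0.04
    n_false_positive_calls: int = 2
    n_multiallelic: int = 0
    n_genes: int = 30
    control_n: int = 100
    pedigree: Pedigree = field(default_factory=default_family)

    def __post_init__(self):
        for name in (
            "genotype_error_rate", "missing_rate", "frac_exonic", "frac_synonymous",
            "frac_conserved", "frac_segdup", "frac_dbsnp", "frac_known_1000g",
            "frac_known_esp", "frac_x",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if not isinstance(self.model, InheritanceModel):
            self.model = InheritanceModel(self.model)


class ConfigurationError(ValueError):
    """Planted-variant constraints unsatisfiable for the pedigree."""


@dataclass
class TruthTable:
    """Generated ground truth covering every emitted variant."""

    planted_key: VariantKey
    planted_model: str
    attributes: dict[str, dict] = field(default_factory=dict)
    errors: list[dict] = field(default_factory=list)
    masked: list[dict] = field(default_factory=list)
    false_positive_keys: list[VariantKey] = field(default_factory=list)
    multiallelic_keys: list[tuple] = field(default_factory=list)

    @staticmethod
    def key_str(key: VariantKey) -> str:
        return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"

    def planted_hit_by_error(self) -> bool:
        planted = self.key_str(self.planted_key)
        return any(e["key"] == planted for e in self.errors)

    def to_json(self) -> dict:
        return {
            "planted": {
                "key": self.key_str(self.planted_key),
                "model": self.planted_model,
            },
            "attributes": self.attributes,
            "errors": self.errors,
            "masked": self.masked,
            "false_positives": [self.key_str(k) for k in self.false_positive_keys],
            "multiallelic": [f"{k[0]}:{k[1]}" for k in self.multiallelic_keys],
        }


@dataclass
class FamilyDataset:
    """In-memory form of one simulated dataset, writable to a directory."""

    config: SimulationConfig
    pedigree: Pedigree
    raw_sites: list            # (chrom, pos, ref, alts, calls) incl. multi-allelic
    transcripts: list[TranscriptModel]
    conserved: GenomeIntervals
    segdup: GenomeIntervals
    dbsnp: dict[VariantKey, str]
    freq_1000g: dict[VariantKey, float]
    freq_esp: dict[VariantKey, float]
    predictions: dict[str, PredictionProfile]
    validations: dict[VariantKey, ValidationRecord]
    disease_genes: set[str]
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_vcf(self.raw_sites, self.pedigree.sequenced_ids, outdir / "study.vcf")
        pio.write_ped(self.pedigree, outdir / "family.ped")
        pio.write_transcripts(self.transcripts, outdir / "transcripts.tsv", outdir / "cds.fa")
        pio.write_bed(self.conserved, outdir / "conserved.bed")
        pio.write_bed(self.segdup, outdir / "segdup.bed")
        pio.write_freq_table(self.freq_1000g, outdir / "freq_1000g.tsv")
        pio.write_freq_table(self.freq_esp, outdir / "freq_esp.tsv")
        pio.write_dbsnp_table(self.dbsnp, outdir / "dbsnp.tsv")
        pio.write_predictions(self.predictions, outdir / "predictions.tsv")
        pio.write_validations(self.validations, outdir / "validations.tsv")
        (outdir / "disease_genes.txt").write_text(
            "\n".join(sorted(self.disease_genes)) + "\n"
        )
        pio.write_json(self.truth.to_json(), outdir / "truth.json")


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------

_NON_STOP_CODONS = sorted(
    "".join(c)
    for c in __import__("itertools").product("ACGT", repeat=3)
    if translate_codon("".join(c)) != "*"
)


def _build_genome(rng: np.random.Generator, n_genes: int, frac_x: float) -> list[TranscriptModel]:
    """Toy transcripts: two 300-bp exons, fully coding, real codon content."""
    autosomes = [str(c) for c in range(1, 23)]
    txs = []
    n_x = max(1, int(round(n_genes * frac_x))) if frac_x > 0 else 0
    per_chrom: dict[str, int] = {}
    for i in range(n_genes):
        chrom = "X" if i < n_x else autosomes[(i - n_x) % len(autosomes)]
        slot = per_chrom.get(chrom, 0)
        per_chrom[chrom] = slot + 1
        # 200 kb between slots: intergenic draws (< 40 kb past a gene) stay clear
        start = 100_000 + 200_000 * slot
        exon1 = (start, start + 299)
        exon2 = (start + 500, start + 799)
        n_codons = 200
        body = rng.choice(_NON_STOP_CODONS, size=n_codons - 2)
        cds = "ATG" + "".join(body) + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        txs.append(
            TranscriptModel(
                gene=f"GENE{i + 1:04d}",
                transcript_id=f"TX{i + 1:04d}.1",
                chrom=chrom,
                strand=strand,
                exons=[exon1, exon2],
                cds_start=exon1[0],
                cds_end=exon2[1],
                cds_sequence=cds,
            )
        )
    return txs


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------

def sample_family_genotypes(
    pedigree: Pedigree,
    maf: float,
    rng: np.random.Generator,
    x_linked: bool = False,
) -> dict[str, GenotypeCall]:
    """Founders from Hardy-Weinberg at ``maf``; offspring by gamete sampling.

    A parent absent from the pedigree contributes a population allele.
    """
    geno: dict[str, int] = {}
    for m in pedigree.topological_order():
        male_x = x_linked and m.sex is Sex.MALE
        founder = m.father_id is None and m.mother_id is None
        if founder:
            if male_x:
                geno[m.id] = int(rng.random() < maf)
            else:
                geno[m.id] = int(rng.random() < maf) + int(rng.random() < maf)
        else:
            def allele_from(parent_id: str | None, paternal: bool) -> int:
                if parent_id is None:
                    return int(rng.random() < maf)
                g = geno[parent_id]
                parent_male_x = x_linked and pedigree[parent_id].sex is Sex.MALE
                if parent_male_x:
                    return g
                return int(rng.random() < 0.5) if g == 1 else g // 2
            if male_x:
                geno[m.id] = allele_from(m.mother_id, paternal=False)
            else:
                geno[m.id] = allele_from(m.father_id, True) + allele_from(m.mother_id, False)
    return {
        mid: GenotypeCall(g, hemizygous=x_linked and pedigree[mid].sex is Sex.MALE)
        for mid, g in geno.items()
    }


def _planted_assignment(
    pedigree: Pedigree, model: InheritanceModel, chrom: str
) -> dict[str, int]:
    """A deterministic full-penetrance-consistent genotype assignment."""
    probe = SiteGenotypes(chrom, 1, "A", "C", {})
    assignments = enumerate_assignments(probe, pedigree, model)
    if not assignments:
        raise ConfigurationError(
            f"no genotype assignment satisfies model {model.value} for this pedigree"
        )
    return assignments[0]


# ---------------------------------------------------------------------------
# Variant placement helpers
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _coding_snv(
    tx: TranscriptModel,
    rng: np.random.Generator,
    synonymous: bool,
    used: set[tuple[str, int]],
    max_tries: int = 200,
) -> tuple[int, str, str] | None:
    """Pick (gpos, ref, alt) in the CDS with the requested synonymy.

    Alleles are returned on the genomic plus strand.
    """
    n = len(tx.cds_sequence)
    for _ in range(max_tries):
        cds_pos = int(rng.integers(4, n - 2))  # avoid start/stop codons
        codon_index, offset = cds_to_codon(cds_pos)
        start = (codon_index - 1) * 3
        codon = tx.cds_sequence[start:start + 3]
        ref_c = codon[offset - 1]
        alts = [b for b in _BASES if b != ref_c]
        for j in rng.permutation(3):
            alt_c = alts[int(j)]
            mutant = codon[:offset - 1] + alt_c + codon[offset:]
            same = translate_codon(codon) == translate_codon(mutant)
            if same != synonymous or translate_codon(mutant) == "*":
                continue
            gpos = cds_to_genomic(tx, cds_pos)
            if (tx.chrom, gpos) in used:
                break
            if tx.strand == "-":
                return gpos, revcomp(ref_c), revcomp(alt_c)
            return gpos, ref_c, alt_c
    return None


def _noncoding_position(
    tx: TranscriptModel, rng: np.random.Generator, used: set[tuple[str, int]]
) -> tuple[int, str] | None:
    """An intronic (clear of the splice window) or intergenic position."""
    for _ in range(50):
        if rng.random() < 0.5 and len(tx.exons) > 1:
            a = tx.exons[0][1] + 5
            b = tx.exons[1][0] - 5
            pos = int(rng.integers(a, b + 1))
            kind = "intronic"
        else:
            lo, hi = tx.span
            pos = int(rng.integers(hi + 1000, hi + 40_000))
            kind = "intergenic"
        if (tx.chrom, pos) not in used:
            return pos, kind
    return None


def _flip_call(call: GenotypeCall, rng: np.random.Generator) -> GenotypeCall:
    domain = (0, 1) if call.hemizygous else (0, 1, 2)
    others = [g for g in domain if g != call.alt_count]
    return GenotypeCall(int(rng.choice(others)), hemizygous=call.hemizygous)


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def _random_profile(rng: np.random.Generator) -> PredictionProfile:
    """A background profile guaranteed to fail strict consensus."""
    pick = lambda options: str(rng.choice(options))  # noqa: E731
    return PredictionProfile(
        phylop=pick(["C", "N", "NA"]),
        sift=pick(["D", "T", "NA"]),
        polyphen=pick(["D", "P", "B", "NA"]),
        lrt=pick(["D", "N", "NA"]),
        mutation_taster=pick(["D", "N", "NA"]),
        gerp=pick(["C", "N"]),
        sift2013=pick(["T", "B"]),  # never D: consensus must fail
    )


def simulate_family_dataset(config: SimulationConfig) -> FamilyDataset:
    """Generate one complete dataset; identical configs give identical output."""
    rng = np.random.default_rng(config.seed)
    ped = config.pedigree
    model = config.model
    sequenced = ped.sequenced_ids
    transcripts = _build_genome(rng, config.n_genes, config.frac_x)
    x_txs = [t for t in transcripts if is_x(t.chrom)]
    auto_txs = [t for t in transcripts if not is_x(t.chrom)]

    used: set[tuple[str, int]] = set()
    attributes: dict[str, dict] = {}
    sites: list[SiteGenotypes] = []
    conserved_pts: list[tuple[str, int, int]] = []
    segdup_pts: list[tuple[str, int, int]] = []
    dbsnp: dict[VariantKey, str] = {}
    freq_1000g: dict[VariantKey, float] = {}
    freq_esp: dict[VariantKey, float] = {}
    validations: dict[VariantKey, ValidationRecord] = {}
    gene_profiles: dict[str, PredictionProfile] = {}

    def register(key: VariantKey, **attrs) -> None:
        attributes[TruthTable.key_str(key)] = attrs

    # --- planted causal variant ------------------------------------------
    pool = x_txs if model.x_linked else auto_txs
    if not pool:
        raise ConfigurationError(f"no transcript available in scope of {model.value}")
    planted_tx = pool[int(rng.integers(len(pool)))]
    placed = _coding_snv(planted_tx, rng, synonymous=False, used=used)
    if placed is None:
        raise ConfigurationError("could not place the planted coding variant")
    ppos, pref, palt = placed
    assignment = _planted_assignment(ped, model, planted_tx.chrom)
    x_linked = model.x_linked
    planted_calls = {
        mid: GenotypeCall(
            assignment[mid],
            hemizygous=x_linked and ped[mid].sex is Sex.MALE,
        )
        for mid in sequenced
    }
    planted = SiteGenotypes(planted_tx.chrom, ppos, pref, palt, planted_calls)
    used.add((planted_tx.chrom, ppos))
    sites.append(planted)
    conserved_pts.append((planted_tx.chrom, ppos, ppos))
    register(
        planted.key,
        role="planted", gene=planted_tx.gene, region="exonic",
        exonic_function="nonsynonymous SNV", conserved=True, segdup=False,
        dbsnp=False, known_1000g=False, known_esp=False, maf=0.0,
    )
    gene_profiles[planted_tx.gene] = PredictionProfile("C", "D", "D", "D", "D", "C", "D")
    # profiles are keyed by gene, so keep other variants out of the planted gene
    x_txs = [t for t in x_txs if t is not planted_tx]
    auto_txs = [t for t in auto_txs if t is not planted_tx]
    pool = [t for t in pool if t is not planted_tx]
    validations[planted.key] = ValidationRecord(
        *planted.key,
        family_genotypes={
            mid: GenotypeCall(
                assignment[mid], hemizygous=x_linked and ped[mid].sex is Sex.MALE
            )
            for mid in assignment
        },
        control_carrier_count=0,
        control_n=config.control_n,
        validated=True,
    )

    # --- false-positive calls --------------------------------------------
    # always autosomal and AD-consistent: AD is applicable to every pedigree
    fp_keys: list[VariantKey] = []
    fp_assignment: dict[str, int] | None = None
    for _ in range(config.n_false_positive_calls):
        if not auto_txs:
            break
        tx = auto_txs[int(rng.integers(len(auto_txs)))]
        if fp_assignment is None:
            fp_assignment = _planted_assignment(ped, InheritanceModel.AD, tx.chrom)
        placed = _coding_snv(tx, rng, synonymous=False, used=used)
        if placed is None:
            continue
        gpos, ref, alt = placed
        calls = {mid: GenotypeCall(fp_assignment[mid]) for mid in sequenced}
        site = SiteGenotypes(tx.chrom, gpos, ref, alt, calls)
        used.add((tx.chrom, gpos))
        sites.append(site)
        fp_keys.append(site.key)
        conserved_pts.append((tx.chrom, gpos, gpos))
        register(
            site.key,
            role="false_positive", gene=tx.gene, region="exonic",
            exonic_function="nonsynonymous SNV", conserved=True, segdup=False,
            dbsnp=False, known_1000g=False, known_esp=False, maf=0.0,
        )
        gene_profiles.setdefault(tx.gene, _random_profile(rng))
        validations[site.key] = ValidationRecord(
            *site.key, control_carrier_count=0, control_n=config.control_n,
            validated=False,
        )

    # --- background variants ---------------------------------------------
    a, b = config.maf_beta
    for _ in range(config.n_background):
        maf = float(np.clip(rng.beta(a, b), 0.001, 0.5))
        on_x = bool(rng.random() < config.frac_x) and bool(x_txs)
        tx_pool = x_txs if on_x else auto_txs
        tx = tx_pool[int(rng.integers(len(tx_pool)))]
        exonic = rng.random() < config.frac_exonic
        if exonic:
            synonymous = rng.random() < config.frac_synonymous
            placed = _coding_snv(tx, rng, synonymous=synonymous, used=used)
            if placed is None:
                continue
            gpos, ref, alt = placed
            region, exo = "exonic", ("synonymous SNV" if synonymous else "nonsynonymous SNV")
        else:
            spot = _noncoding_position(tx, rng, used)
            if spot is None:
                continue
            gpos, region = spot
            exo = None
            ref = _BASES[int(rng.integers(4))]
            alt = str(rng.choice([bb for bb in _BASES if bb != ref]))
        calls_all = sample_family_genotypes(ped, maf, rng, x_linked=is_x(tx.chrom))
        calls = {mid: calls_all[mid] for mid in sequenced}
        site = SiteGenotypes(tx.chrom, gpos, ref, alt, calls)
        used.add((tx.chrom, gpos))
        sites.append(site)
        conserved_flag = rng.random() < config.frac_conserved
        segdup_flag = rng.random() < config.frac_segdup
        in_dbsnp = rng.random() < config.frac_dbsnp
        known_1000g = rng.random() < config.frac_known_1000g
        known_esp = rng.random() < config.frac_known_esp
        if conserved_flag:
            conserved_pts.append((tx.chrom, gpos, gpos))
        if segdup_flag:
            segdup_pts.append((tx.chrom, gpos, gpos))
        if in_dbsnp:
            dbsnp[site.key] = f"rs{900000 + len(dbsnp)}"
        if known_1000g:
            freq_1000g[site.key] = round(maf, 4)
        if known_esp:
            freq_esp[site.key] = round(min(0.5, maf * float(rng.uniform(0.5, 1.5))), 4)
        register(
            site.key,
            role="background", gene=tx.gene, region=region, exonic_function=exo,
            conserved=conserved_flag, segdup=segdup_flag, dbsnp=in_dbsnp,
            known_1000g=known_1000g, known_esp=known_esp, maf=round(maf, 5),
        )
        gene_profiles.setdefault(tx.gene, _random_profile(rng))
        carrier_p = 1.0 - (1.0 - maf) ** 2
        validations[site.key] = ValidationRecord(
            *site.key,
            family_genotypes=calls_all,
            control_carrier_count=int(rng.binomial(config.control_n, carrier_p)),
            control_n=config.control_n,
            validated=True,
        )

    truth = TruthTable(
        planted_key=planted.key,
        planted_model=model.value,
        attributes=attributes,
        false_positive_keys=fp_keys,
    )

    # --- genotyping error and missingness --------------------------------
    if config.genotype_error_rate > 0 or config.missing_rate > 0:
        for site in sites:
            new_calls = dict(site.calls)
            for mid in sequenced:
                call = new_calls[mid]
                if config.genotype_error_rate > 0 and rng.random() < config.genotype_error_rate:
                    flipped = _flip_call(call, rng)
                    truth.errors.append(
                        {
                            "key": TruthTable.key_str(site.key),
                            "member": mid,
                            "from": call.alt_count,
                            "to": flipped.alt_count,
                        }
                    )
                    call = flipped
                if config.missing_rate > 0 and rng.random() < config.missing_rate:
                    if not call.missing:
                        truth.masked.append(
                            {"key": TruthTable.key_str(site.key), "member": mid}
                        )
                    call = MISSING_CALL
                new_calls[mid] = call
            site.calls = new_calls

    # --- raw site list (multi-allelic injections last) --------------------
    raw_sites: list = list(sites)
    for j in range(config.n_multiallelic):
        tx = auto_txs[int(rng.integers(len(auto_txs)))]
        for _ in range(50):
            gpos = int(rng.integers(tx.span[0], tx.span[1] + 1))
            if (tx.chrom, gpos) not in used:
                break
        used.add((tx.chrom, gpos))
        ref = _BASES[int(rng.integers(4))]
        alts = [bb for bb in _BASES if bb != ref][:2]
        calls = {mid: GenotypeCall(1) for mid in sequenced}
        raw_sites.append((tx.chrom, gpos, ref, alts, calls))
        truth.multiallelic_keys.append((tx.chrom, gpos))

    raw_sites.sort(key=lambda s: ((s.chrom, s.pos) if hasattr(s, "chrom") else (s[0], s[1])))

    disease_genes = {planted_tx.gene}
    extra = [t.gene for t in transcripts if t.gene != planted_tx.gene]
    disease_genes.update(str(g) for g in rng.choice(extra, size=min(4, len(extra)), replace=False))

    return FamilyDataset(
        config=config,
        pedigree=ped,
        raw_sites=raw_sites,
        transcripts=transcripts,
        conserved=GenomeIntervals.from_intervals(conserved_pts),
        segdup=GenomeIntervals.from_intervals(segdup_pts),
        dbsnp=dbsnp,
        freq_1000g=freq_1000g,
        freq_esp=freq_esp,
        predictions=gene_profiles,
        validations=validations,
        disease_genes=disease_genes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Published worked-example fixtures
# ---------------------------------------------------------------------------

_PROFILE_ROWS: list[tuple[str, tuple[str, ...]]] = [
    ("SLC39A1", ("C", "D", "P", "D", "D", "C", "T")),
    ("LMNA", ("C", "D", "D", "D", "D", "C", "D")),
    ("SACM1L", ("NA", "NA", "NA", "NA", "NA", "C", "NA")),
    ("ADH4", ("N", "D", "D", "N", "D", "C", "D")),
    ("MFSD8", ("N", "T", "P", "N", "D", "N", "T")),
    ("DLK2", ("C", "D", "D", "D", "N", "C", "T")),
    ("MDN1", ("C", "T", "B", "D", "N", "C", "T")),
    ("ODZ4", ("NA", "NA", "NA", "NA", "NA", "C", "B")),
    ("ANGPTL5", ("C", "T", "D", "D", "D", "C", "T")),
    ("L2HGDH", ("C", "T", "P", "D", "D", "C", "T")),
    ("ZNF646", ("C", "T", "D", "NA", "NA", "C", "T")),
    ("LONP2", ("C", "T", "D", "D", "D", "C", "T")),
    ("MMP2", ("C", "T", "P", "D", "D", "C", "T")),
    ("ZFHX3", ("C", "NA", "P", "D", "D", "C", "T")),
    ("MVD", ("C", "D", "B", "D", "D", "C", "T")),
    ("KCNH6", ("C", "T", "D", "D", "D", "C", "T")),
    ("USF2", ("C", "T", "B", "N", "N", "C", "T")),
    ("MYH7B", ("C", "NA", "NA", "N", "N", "C", "T")),
    ("ARHGAP40", ("NA", "NA", "NA", "NA", "NA", "C", "T")),
]


def candidate_profile_fixture() -> list[tuple[str, PredictionProfile]]:
    """The 19 candidate genes with their categorical prediction profiles."""
    return [(gene, PredictionProfile.from_values(vals)) for gene, vals in _PROFILE_ROWS]


# Screened-candidate site keys; the four sequencing-confirmed family-specific
# variants carry their genomic positions, the rest are stable placeholders.
_CANDIDATE_KEYS: dict[str, VariantKey] = {
    "LMNA": ("1", 156104651, "G", "T"),
    "MMP2": ("16", 55519584, "G", "A"),
    "ZFHX3": ("16", 72830334, "G", "A"),
    "ANGPTL5": ("11", 101773401, "C", "T"),
    "MYH7B": ("20", 33588956, "G", "A"),
    "KCNH6": ("17", 61600000, "G", "A"),
    "SACM1L": ("3", 45730000, "C", "T"),
}


def candidate_sites() -> dict[str, VariantKey]:
    """A (chrom,pos,ref,alt) key for each of the 19 candidate genes."""
    keys = dict(_CANDIDATE_KEYS)
    for i, (gene, _) in enumerate(_PROFILE_ROWS):
        if gene not in keys:
            keys[gene] = (str(2 + i % 20), 10_000_000 + 1000 * i, "G", "A")
    return keys


def candidate_validation_fixture() -> dict[VariantKey, ValidationRecord]:
    """Validation facts for the seven sequencing-screened candidates.

    Affected siblings are heterozygous carriers for the four confirmed
    family-specific variants; the grandson (unknown phenotype) carries two
    of them; one variant appeared in 2 of 100 controls; two failed
    re-sequencing and are flagged as calling errors.
    """
    het = GenotypeCall(1)
    ref = GenotypeCall(0)
    keys = candidate_sites()

    def fam(i31_carrier: bool) -> dict[str, GenotypeCall]:
        return {
            "I-1": ref, "I-3": ref,
            "II-2": het, "II-3": het, "II-4": het,
            "III-1": het if i31_carrier else ref,
        }

    records = {
        keys["LMNA"]: ValidationRecord(*keys["LMNA"], family_genotypes=fam(False),
                                       control_carrier_count=0, control_n=252),
        keys["MMP2"]: ValidationRecord(*keys["MMP2"], family_genotypes=fam(True),
                                       control_carrier_count=0, control_n=100),
        keys["ZFHX3"]: ValidationRecord(*keys["ZFHX3"], family_genotypes=fam(True),
                                        control_carrier_count=0, control_n=100),
        keys["ANGPTL5"]: ValidationRecord(*keys["ANGPTL5"], family_genotypes=fam(False),
                                          control_carrier_count=0, control_n=100),
        keys["MYH7B"]: ValidationRecord(*keys["MYH7B"], family_genotypes=fam(False),
                                        control_carrier_count=2, control_n=100),
        keys["KCNH6"]: ValidationRecord(*keys["KCNH6"], validated=False),
        keys["SACM1L"]: ValidationRecord(*keys["SACM1L"], validated=False),
    }
    return records


def disease_gene_fixture() -> set[str]:
    """Candidate genes with prior links to cardiovascular disease."""
    return {"LMNA", "ZFHX3", "MMP2", "ANGPTL5", "MYH7B", "KCNH6"}


def candidate_records() -> list[AnnotationRecord]:
    """The 19 candidates as annotation records (for ranking demos/tests)."""
    keys = candidate_sites()
    return [
        AnnotationRecord(
            *keys[gene],
            gene=gene,
            function="splicing" if gene == "SACM1L" else "exonic",
            exonic_function=None if gene == "SACM1L" else "nonsynonymous SNV",
            conserved=True,
        )
        for gene, _ in _PROFILE_ROWS
    ]
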