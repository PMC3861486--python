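"""Pedigree model, inheritance-model applicability and genotype consistency.

A variant site is retained by the inheritance filter when there *exists* a
full-penetrance genotype assignment to every pedigree member (sequenced or
not) that (a) agrees with every observed, non-missing call, (b) obeys
Mendelian transmission from parents to children, and (c) makes the risk
genotype exactly co-extensive with the affected phenotype.  Members of
unknown affection are constrained by transmission only.

Two routes compute the same answer: :func:`site_matches_model` is a
depth-first search with early constraint checking, while
:func:`enumerate_assignments` is a plain exhaustive product over every
member's full genotype domain.  Their equivalence is a tested invariant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Sex",
    "Affection",
    "InheritanceModel",
    "Member",
    "Pedigree",
    "PedigreeError",
    "CapacityError",
    "ScopeError",
    "GenotypeCall",
    "MISSING_CALL",
    "SiteGenotypes",
    "normalize_chrom",
    "is_autosome",
    "is_x",
    "applicable_models",
    "site_matches_model",
    "enumerate_assignments",
    "filter_by_inheritance",
    "InheritanceFilterResult",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class InheritanceModel(str, Enum):
    """Single-locus full-penetrance transmission models."""

    AD = "AD"
    AR = "AR"
    XLD = "XLD"
    XLR = "XLR"

    @property
    def chromosome_scope(self) -> str:
        return "X" if self in (InheritanceModel.XLD, InheritanceModel.XLR) else "autosome"

    @property
    def x_linked(self) -> bool:
        return self.chromosome_scope == "X"


class PedigreeError(ValueError):
    """Structural problem in a pedigree definition."""


class CapacityError(RuntimeError):
    """Pedigree exceeds the exhaustive-search bound."""


class ScopeError(ValueError):
    """Site chromosome incompatible with the model's chromosome scope."""


@dataclass(frozen=True)
class Member:
    id: str
    sex: Sex
    affection: Affection
    father_id: str | None = None
    mother_id: str | None = None
    sequenced: bool = False


class Pedigree:
    """A validated collection of :class:`Member` records.

    Raises :class:`PedigreeError` on duplicate ids, sex-discordant parent
    links, ancestry cycles, or when no member is sequenced.
    """

    def __init__(self, members: Iterable[Member]):
        self.members: list[Member] = list(members)
        self._by_id = {m.id: m for m in self.members}
        self._validate()

    def _validate(self) -> None:
        if len(self._by_id) != len(self.members):
            seen: set[str] = set()
            dup = next(m.id for m in self.members if m.id in seen or seen.add(m.id))
            raise PedigreeError(f"duplicate member id: {dup!r}")
        for m in self.members:
            for pid, want in ((m.father_id, Sex.MALE), (m.mother_id, Sex.FEMALE)):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    raise PedigreeError(f"member {m.id!r}: unknown parent {pid!r}")
                if parent.sex is not want:
                    raise PedigreeError(
                        f"member {m.id!r}: parent {pid!r} has sex {parent.sex.value}, "
                        f"expected {want.value}"
                    )
        self._check_acyclic()
        if not any(m.sequenced for m in self.members):
            raise PedigreeError("pedigree has no sequenced member")

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(mid: str) -> None:
            if state.get(mid) == 1:
                return
            if state.get(mid) == 0:
                raise PedigreeError(f"member {mid!r} is its own ancestor")
            state[mid] = 0
            m = self._by_id[mid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid)
            state[mid] = 1

        for m in self.members:
            visit(m.id)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, member_id: str) -> bool:
        return member_id in self._by_id

    def __getitem__(self, member_id: str) -> Member:
        return self._by_id[member_id]

    @property
    def sequenced_ids(self) -> list[str]:
        return [m.id for m in self.members if m.sequenced]

    @property
    def affected(self) -> list[Member]:
        return [m for m in self.members if m.affection is Affection.AFFECTED]

    def children_of(self, member_id: str) -> list[Member]:
        return [m for m in self.members if member_id in (m.father_id, m.mother_id)]

    def topological_order(self) -> list[Member]:
        """Members ordered parents-before-children."""
        order: list[Member] = []
        done: set[str] = set()

        def visit(m: Member) -> None:
            if m.id in done:
                return
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(self._by_id[pid])
            done.add(m.id)
            order.append(m)

        for m in self.members:
            visit(m)
        return order


@dataclass(frozen=True)
class GenotypeCall:
    """Number of alternate alleles carried; ``None`` means missing.

    ``hemizygous`` marks single-copy calls (male X), where ``alt_count`` is
    0 or 1.
    """

    alt_count: int | None
    hemizygous: bool = False

    def __post_init__(self):
        if self.alt_count is not None:
            hi = 1 if self.hemizygous else 2
            if not 0 <= self.alt_count <= hi:
                raise ValueError(f"alt_count {self.alt_count} out of range (hemizygous={self.hemizygous})")

    @property
    def missing(self) -> bool:
        return self.alt_count is None

    @property
    def carries_alt(self) -> bool:
        return bool(self.alt_count)


MISSING_CALL = GenotypeCall(None)


def normalize_chrom(chrom: str) -> str:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return "MT" if c.upper() in ("M", "MT") else c.upper() if c.upper() in ("X", "Y") else c


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) not in ("X", "Y", "MT")


def is_x(chrom: str) -> bool:
    return normalize_chrom(chrom) == "X"


@dataclass
class SiteGenotypes:
    """Observed calls for one biallelic site across sequenced members."""

    chrom: str
    pos: int
    ref: str
    alt: str | Sequence[str]
    calls: Mapping[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.alt, str):
            if len(self.alt) != 1:
                raise ValueError(f"site {self.chrom}:{self.pos} is not biallelic: alts={list(self.alt)}")
            self.alt = self.alt[0]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


# ---------------------------------------------------------------------------
# Model applicability
# ---------------------------------------------------------------------------

def applicable_models(pedigree: Pedigree) -> tuple[set[InheritanceModel], set[str]]:
    """Return (applicable models, excluded scopes) for a pedigree.

    Structural exclusion rules:

    * ``Y`` is excluded when any affected member is female;
    * ``MT`` is excluded when the disease demonstrably enters through a
      father (an affected member whose mother is unaffected while the
      father is affected);
    * ``XLD`` is excluded by male-to-male transmission (an affected male
      with an affected son).

    AD and AR are always applicable; XLR is returned by default.
    """
    excluded: set[str] = set()
    if any(m.sex is Sex.FEMALE for m in pedigree.affected):
        excluded.add("Y")
    for m in pedigree.affected:
        father = pedigree[m.father_id] if m.father_id else None
        mother = pedigree[m.mother_id] if m.mother_id else None
        if (
            father is not None
            and father.affection is Affection.AFFECTED
            and mother is not None
            and mother.affection is Affection.UNAFFECTED
        ):
            excluded.add("MT")
        if m.sex is Sex.MALE:
            for child in pedigree.children_of(m.id):
                if child.sex is Sex.MALE and child.affection is Affection.AFFECTED:
                    excluded.add("XLD")
    models = {InheritanceModel.AD, InheritanceModel.AR, InheritanceModel.XLR}
    if "XLD" not in excluded:
        models.add(InheritanceModel.XLD)
    return models, excluded


# ---------------------------------------------------------------------------
# Genotype domains, transmission and penetrance
# ---------------------------------------------------------------------------

def _domain(member: Member, x_linked: bool) -> tuple[int, ...]:
    if x_linked and member.sex is Sex.MALE:
        return (0, 1)  # hemizygous
    return (0, 1, 2)


def _gametes(genotype: int) -> tuple[int, ...]:
    # diploid genotype -> transmissible allele values
    return ((0,), (0, 1), (1,))[genotype]


_ANY_ALLELE = (0, 1)


def _mendel_ok(
    child: Member,
    geno: int,
    father_g: int | None,
    mother_g: int | None,
    x_linked: bool,
) -> bool:
    """Can ``child`` carry ``geno`` given parental genotypes?

    A parent absent from the pedigree (or, internally, not yet assigned)
    contributes an unconstrained allele.
    """
    if x_linked:
        if child.sex is Sex.MALE:
            # single X from the mother
            maternal = _ANY_ALLELE if mother_g is None else _gametes(mother_g)
            return geno in maternal
        paternal = _ANY_ALLELE if father_g is None else (father_g,)
        maternal = _ANY_ALLELE if mother_g is None else _gametes(mother_g)
        return any(geno == p + m for p in paternal for m in maternal)
    paternal = _ANY_ALLELE if father_g is None else _gametes(father_g)
    maternal = _ANY_ALLELE if mother_g is None else _gametes(mother_g)
    return any(geno == p + m for p in paternal for m in maternal)


def _is_risk(model: InheritanceModel, member: Member, geno: int) -> bool:
    if model is InheritanceModel.AD:
        return geno >= 1
    if model is InheritanceModel.AR:
        return geno == 2
    if model is InheritanceModel.XLD:
        return geno >= 1
    # XLR
    if member.sex is Sex.MALE:
        return geno == 1
    return geno == 2


def _affection_ok(model: InheritanceModel, member: Member, geno: int) -> bool:
    if member.affection is Affection.UNKNOWN:
        return True
    risk = _is_risk(model, member, geno)
    return risk if member.affection is Affection.AFFECTED else not risk


def _check_scope(site: SiteGenotypes, model: InheritanceModel) -> None:
    if model.x_linked and not is_x(site.chrom):
        raise ScopeError(f"model {model.value} requires chromosome X, got {site.chrom}")
    if not model.x_linked and not is_autosome(site.chrom):
        raise ScopeError(f"model {model.value} requires an autosome, got {site.chrom}")


def _observed(site: SiteGenotypes, pedigree: Pedigree) -> dict[str, int]:
    """Non-missing observed alt counts, keyed by member id."""
    obs: dict[str, int] = {}
    for mid, call in site.calls.items():
        if mid not in pedigree:
            raise KeyError(f"call for unknown member {mid!r}")
        if not pedigree[mid].sequenced:
            raise KeyError(f"call for unsequenced member {mid!r}")
        if not call.missing:
            obs[mid] = call.alt_count
    return obs


# ---------------------------------------------------------------------------
# Constraint matcher (DFS) and exhaustive oracle
# ---------------------------------------------------------------------------

def site_matches_model(
    site: SiteGenotypes,
    pedigree: Pedigree,
    model: InheritanceModel,
) -> bool:
    """True iff some full genotype assignment satisfies all constraints.

    Depth-first search in parents-before-children order; each candidate
    genotype is checked against the observation, the affection constraint
    and Mendelian transmission as soon as it is placed.
    """
    _check_scope(site, model)
    obs = _observed(site, pedigree)
    x = model.x_linked
    order = pedigree.topological_order()
    assigned: dict[str, int] = {}

    def extend(i: int) -> bool:
        if i == len(order):
            return True
        m = order[i]
        domain = (obs[m.id],) if m.id in obs else _domain(m, x)
        for g in domain:
            if g not in _domain(m, x):
                continue  # observed diploid code impossible for hemizygote
            if not _affection_ok(model, m, g):
                continue
            fg = assigned.get(m.father_id) if m.father_id else None
            mg = assigned.get(m.mother_id) if m.mother_id else None
            if not _mendel_ok(m, g, fg, mg, x):
                continue
            assigned[m.id] = g
            if extend(i + 1):
                return True
            del assigned[m.id]
        return False

    return extend(0)


def enumerate_assignments(
    site: SiteGenotypes,
    pedigree: Pedigree,
    model: InheritanceModel,
    max_members: int = 15,
) -> list[dict[str, int]]:
    """Exhaustively enumerate every satisfying full assignment.

    Iterates the cartesian product of every member's full genotype domain
    and filters complete vectors; deliberately free of search-order
    cleverness so it can serve as an independent oracle for
    :func:`site_matches_model`.
    """
    _check_scope(site, model)
    if len(pedigree) > max_members:
        raise CapacityError(
            f"pedigree has {len(pedigree)} members, exhaustive bound is {max_members}"
        )
    obs = _observed(site, pedigree)
    x = model.x_linked
    members = pedigree.members
    idx = {m.id: i for i, m in enumerate(members)}
    domains = [_domain(m, x) for m in members]
    out: list[dict[str, int]] = []
    for vec in itertools.product(*domains):
        ok = True
        for i, m in enumerate(members):
            g = vec[i]
            if m.id in obs and g != obs[m.id]:
                ok = False
                break
            if not _affection_ok(model, m, g):
                ok = False
                break
            fg = vec[idx[m.father_id]] if m.father_id else None
            mg = vec[idx[m.mother_id]] if m.mother_id else None
            if not _mendel_ok(m, g, fg, mg, x):
                ok = False
                break
        if ok:
            out.append({m.id: vec[i] for i, m in enumerate(members)})
    return out


# ---------------------------------------------------------------------------
# Cohort-level filtering
# ---------------------------------------------------------------------------

@dataclass
class InheritanceFilterResult:
    """Per-model retained sites plus accounting."""

    by_model: dict[InheritanceModel, list[SiteGenotypes]]
    dropped_excluded_chrom: list[SiteGenotypes]
    dropped_no_model: list[SiteGenotypes]

    @property
    def counts(self) -> dict[str, int]:
        return {m.value: len(sites) for m, sites in self.by_model.items()}

    def union(self) -> list[SiteGenotypes]:
        """All retained sites, deduplicated by key, input order preserved."""
        seen: set[tuple] = set()
        out: list[SiteGenotypes] = []
        for sites in self.by_model.values():
            for s in sites:
                if s.key not in seen:
                    seen.add(s.key)
                    out.append(s)
        out.sort(key=lambda s: (s.chrom, s.pos, s.ref, s.alt))
        return out


def filter_by_inheritance(
    sites: Iterable[SiteGenotypes],
    pedigree: Pedigree,
    models: set[InheritanceModel] | None = None,
) -> InheritanceFilterResult:
    """Assign each biallelic site to every applicable model it satisfies.

    Sites on structurally excluded chromosomes (Y, MT) are dropped
    unconditionally; autosomal sites are tested against AD/AR and X sites
    against the applicable X-linked models.
    """
    if models is None:
        models, excluded = applicable_models(pedigree)
    else:
        _, excluded = applicable_models(pedigree)
    by_model: dict[InheritanceModel, list[SiteGenotypes]] = {m: [] for m in sorted(models, key=lambda m: m.value)}
    dropped_chrom: list[SiteGenotypes] = []
    dropped_nomodel: list[SiteGenotypes] = []
    for site in sites:
        chrom = normalize_chrom(site.chrom)
        if chrom in ("Y", "MT") and chrom in excluded:
            dropped_chrom.append(site)
            continue
        matched = False
        for model in by_model:
            if model.x_linked != is_x(site.chrom):
                continue
            if not model.x_linked and not is_autosome(site.chrom):
                continue
            if site_matches_model(site, pedigree, model):
                by_model[model].append(site)
                matched = True
        if not matched:
            dropped_nomodel.append(site)
    return InheritanceFilterResult(by_model, dropped_chrom, dropped_nomodel)
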