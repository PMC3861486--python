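"""Unit and property tests for the pedigree / inheritance-model module."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedexome.pedigree import (
    Affection,
    CapacityError,
    GenotypeCall,
    InheritanceModel,
    MISSING_CALL,
    Member,
    Pedigree,
    PedigreeError,
    ScopeError,
    Sex,
    SiteGenotypes,
    applicable_models,
    enumerate_assignments,
    filter_by_inheritance,
    site_matches_model,
)

A, U, K = Affection.AFFECTED, Affection.UNAFFECTED, Affection.UNKNOWN
M, F = Sex.MALE, Sex.FEMALE
AD, AR, XLD, XLR = InheritanceModel


def site(chrom, calls, pos=100, ref="G", alt="T"):
    return SiteGenotypes(chrom, pos, ref, alt, calls)


def auto_calls(**alt_counts):
    return {k: GenotypeCall(v) if v is not None else MISSING_CALL for k, v in alt_counts.items()}


QUINTET = dict(zip(["I-3", "II-2", "II-3", "II-4", "III-1"], [0, 1, 1, 1, 0]))


# ---------------------------------------------------------------------------
# Pedigree validation
# ---------------------------------------------------------------------------

class TestPedigreeValidation:
    def test_duplicate_id(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            Pedigree([Member("a", M, A, sequenced=True), Member("a", F, U)])

    def test_parent_sex_mismatch(self):
        with pytest.raises(PedigreeError, match="sex"):
            Pedigree(
                [
                    Member("p", F, U, sequenced=True),
                    Member("c", M, A, father_id="p"),
                ]
            )

    def test_unknown_parent(self):
        with pytest.raises(PedigreeError, match="unknown parent"):
            Pedigree([Member("c", M, A, father_id="ghost", sequenced=True)])

    def test_cycle(self):
        with pytest.raises(PedigreeError, match="ancestor"):
            Pedigree(
                [
                    Member("a", M, A, father_id="b", sequenced=True),
                    Member("b", M, U, father_id="a"),
                ]
            )

    def test_no_sequenced_member(self):
        with pytest.raises(PedigreeError, match="sequenced"):
            Pedigree([Member("a", M, A)])

    def test_topological_order(self, family7):
        order = [m.id for m in family7.topological_order()]
        assert order.index("I-2") < order.index("II-2") < order.index("III-1")


# ---------------------------------------------------------------------------
# applicable_models
# ---------------------------------------------------------------------------

class TestApplicableModels:
    def test_study_family(self, family7):
        models, excluded = applicable_models(family7)
        assert models == {AD, AR, XLR}
        assert excluded == {"Y", "MT", "XLD"}

    def test_single_affected_male(self):
        ped = Pedigree([Member("p", M, A, sequenced=True)])
        models, excluded = applicable_models(ped)
        assert models == {AD, AR, XLD, XLR}
        assert excluded == set()

    def test_affected_mother_daughter(self):
        ped = Pedigree(
            [
                Member("mom", F, A, sequenced=True),
                Member("dau", F, A, mother_id="mom", sequenced=True),
            ]
        )
        models, excluded = applicable_models(ped)
        # affected female -> Y out; no male-to-male, no paternal-origin proof
        assert excluded == {"Y"}
        assert XLD in models

    def test_paternal_origin_excludes_mt(self):
        ped = Pedigree(
            [
                Member("dad", M, A),
                Member("mom", F, U),
                Member("kid", M, A, "dad", "mom", sequenced=True),
            ]
        )
        _, excluded = applicable_models(ped)
        assert "MT" in excluded
        assert "Y" not in excluded  # no affected female


# ---------------------------------------------------------------------------
# site_matches_model
# ---------------------------------------------------------------------------

class TestSiteMatches:
    def test_quintet_ad_true(self, family7):
        s = site("1", auto_calls(**QUINTET))
        assert site_matches_model(s, family7, AD) is True

    def test_quintet_unsequenced_father_forced_carrier(self, family7):
        s = site("1", auto_calls(**QUINTET))
        for assign in enumerate_assignments(s, family7, AD):
            assert assign["I-2"] >= 1

    def test_all_ref_ad_false(self, family7):
        s = site("1", auto_calls(**{k: 0 for k in QUINTET}))
        assert site_matches_model(s, family7, AD) is False

    def test_trio_ar_father_missing(self, trio):
        ped = Pedigree(
            [
                Member("dad", M, U, sequenced=True),
                Member("mom", F, U, sequenced=True),
                Member("kid", M, A, "dad", "mom", sequenced=True),
            ]
        )
        s = site("1", auto_calls(dad=None, mom=1, kid=2))
        assert site_matches_model(s, ped, AR) is True
        # brute-force over the father's three genotypes agrees
        by_hand = any(
            bool(enumerate_assignments(site("1", auto_calls(dad=g, mom=1, kid=2)), ped, AR))
            for g in (0, 1, 2)
        )
        assert by_hand is True

    def test_scope_error(self, family7):
        with pytest.raises(ScopeError):
            site_matches_model(site("X", {}), family7, AD)
        with pytest.raises(ScopeError):
            site_matches_model(site("1", {}), family7, XLR)

    def test_unknown_member_key_error(self, family7):
        with pytest.raises(KeyError):
            site_matches_model(site("1", auto_calls(nobody=1)), family7, AD)

    def test_unsequenced_member_key_error(self, family7):
        with pytest.raises(KeyError):
            site_matches_model(site("1", auto_calls(**{"I-2": 1})), family7, AD)


# ---------------------------------------------------------------------------
# enumerate_assignments
# ---------------------------------------------------------------------------

class TestEnumerate:
    def test_unconstrained_affected_singleton(self):
        ped = Pedigree([Member("p", M, A, sequenced=True)])
        vecs = enumerate_assignments(site("1", {}), ped, AD)
        assert sorted(v["p"] for v in vecs) == [1, 2]

    def test_ar_mendelian_impossibility(self, trio):
        s = site("1", auto_calls(dad=0, mom=0, kid=2))
        assert enumerate_assignments(s, trio, AR) == []
        assert site_matches_model(s, trio, AR) is False

    def test_capacity_error(self):
        members = [Member("f0", M, U, sequenced=True)] + [
            Member(f"m{i}", F, U) for i in range(16)
        ]
        ped = Pedigree(members)
        with pytest.raises(CapacityError):
            enumerate_assignments(site("1", {}), ped, AD)

    def test_xlr_affected_female_forces_father_hemizygote(self):
        ped = Pedigree(
            [
                Member("dad", M, K),
                Member("mom", F, K),
                Member("dau", F, A, "dad", "mom", sequenced=True),
            ]
        )
        s = site("X", {"dau": GenotypeCall(2)})
        vecs = enumerate_assignments(s, ped, XLR)
        assert vecs
        assert all(v["dad"] == 1 for v in vecs)


# ---------------------------------------------------------------------------
# Matcher == oracle, and missingness monotonicity
# ---------------------------------------------------------------------------

def _observation_vectors(pedigree, x_linked):
    seq = [pedigree[mid] for mid in pedigree.sequenced_ids]
    domains = [
        (0, 1) if (x_linked and m.sex is M) else (0, 1, 2) for m in seq
    ]
    for vec in itertools.product(*domains):
        yield {
            m.id: GenotypeCall(g, hemizygous=x_linked and m.sex is M)
            for m, g in zip(seq, vec)
        }


@pytest.mark.parametrize("model", [AD, AR])
def test_matcher_equals_oracle_autosomal(quartet, model):
    for calls in _observation_vectors(quartet, x_linked=False):
        s = site("5", calls)
        assert site_matches_model(s, quartet, model) == bool(
            enumerate_assignments(s, quartet, model)
        )


@pytest.mark.parametrize("model", [XLD, XLR])
def test_matcher_equals_oracle_x(quartet, model):
    for calls in _observation_vectors(quartet, x_linked=True):
        s = site("X", calls)
        assert site_matches_model(s, quartet, model) == bool(
            enumerate_assignments(s, quartet, model)
        )


@settings(max_examples=120, deadline=None)
@given(vec=st.tuples(*[st.integers(0, 2)] * 5), drop=st.integers(0, 4))
def test_missingness_never_flips_true_to_false(vec, drop):
    ped = default_family_cached()
    ids = ped.sequenced_ids
    calls = {mid: GenotypeCall(g) for mid, g in zip(ids, vec)}
    s = site("3", calls)
    before = site_matches_model(s, ped, AD)
    calls2 = dict(calls)
    calls2[ids[drop]] = MISSING_CALL
    after = site_matches_model(site("3", calls2), ped, AD)
    if before:
        assert after


_PED_CACHE = {}


def default_family_cached():
    if "ped" not in _PED_CACHE:
        from pedexome.simulate import default_family

        _PED_CACHE["ped"] = default_family()
    return _PED_CACHE["ped"]


# ---------------------------------------------------------------------------
# filter_by_inheritance
# ---------------------------------------------------------------------------

class TestFilterByInheritance:
    def test_empty(self, family7):
        result = filter_by_inheritance([], family7)
        assert all(v == [] for v in result.by_model.values())
        assert result.union() == []

    def test_excluded_chromosomes_dropped(self, family7):
        sites = [site("Y", {}, pos=1), site("MT", {}, pos=2)]
        result = filter_by_inheritance(sites, family7)
        assert len(result.dropped_excluded_chrom) == 2

    def test_site_in_both_ad_and_ar_buckets(self):
        ped = Pedigree(
            [
                Member("dad", M, K),
                Member("mom", F, K),
                Member("kid1", M, A, "dad", "mom", sequenced=True),
                Member("kid2", F, U, "dad", "mom", sequenced=True),
            ]
        )
        s = site("4", auto_calls(kid1=2, kid2=0))
        result = filter_by_inheritance([s], ped, models={AD, AR})
        assert s in result.by_model[AD]
        assert s in result.by_model[AR]

    def test_planted_variant_lands_in_ad_bucket(self, family7):
        from pedexome.cascade import prefilter_multiallelic
        from pedexome.simulate import SimulationConfig, simulate_family_dataset

        ds = simulate_family_dataset(SimulationConfig(seed=11, n_background=200))
        sites_list, _ = prefilter_multiallelic(ds.raw_sites)
        result = filter_by_inheritance(sites_list, family7)
        assert ds.truth.planted_key in {s.key for s in result.by_model[AD]}


# ---------------------------------------------------------------------------
# GenotypeCall
# ---------------------------------------------------------------------------

def test_genotype_call_bounds():
    with pytest.raises(ValueError):
        GenotypeCall(3)
    with pytest.raises(ValueError):
        GenotypeCall(2, hemizygous=True)
    assert MISSING_CALL.missing


def test_site_rejects_multiallelic():
    with pytest.raises(ValueError, match="biallelic"):
        SiteGenotypes("1", 5, "A", ["C", "G"], {})
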