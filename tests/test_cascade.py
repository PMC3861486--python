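"""Tests for the staged filter cascade and interval overlap."""

import itertools

import numpy as np
import pytest

from pedexome.cascade import (
    AnnotationRecord,
    CascadeResources,
    novelty_filter,
    prefilter_multiallelic,
    run_cascade,
)
from pedexome.intervals import GenomeIntervals
from pedexome.pedigree import GenotypeCall, SiteGenotypes


def record(i=0, **kw):
    defaults = dict(
        chrom="1", pos=1000 + i, ref="G", alt="T", gene=f"G{i}",
        function="exonic", exonic_function="nonsynonymous SNV",
        conserved=True, segdup=False, dbsnp_id=None, maf_1000g=None, maf_esp=None,
    )
    defaults.update(kw)
    return AnnotationRecord(**defaults)


class TestPrefilterMultiallelic:
    def test_two_alts_dropped(self):
        kept, dropped = prefilter_multiallelic([("1", 5, "A", ["C", "G"], {})])
        assert kept == [] and dropped == 1

    def test_biallelic_retained(self):
        kept, dropped = prefilter_multiallelic([("1", 5, "A", ["C"], {"s": GenotypeCall(1)})])
        assert dropped == 0
        assert kept[0].key == ("1", 5, "A", "C")

    def test_counts(self):
        raw = [("1", i, "A", ["C", "G"] if i < 3 else ["C"], {}) for i in range(10)]
        kept, dropped = prefilter_multiallelic(raw)
        assert (len(kept), dropped) == (7, 3)


class TestRunCascade:
    def test_clean_record_survives_all_steps(self):
        survivors, report = run_cascade([record()])
        assert len(survivors) == 1
        assert [s for _, s, _ in report] == [1] * 7

    def test_maf_above_threshold_dropped(self):
        survivors, report = run_cascade([record(maf_1000g=0.20)])
        assert survivors == []
        assert report.steps[-1] == ("maf_threshold", 0, 0)

    def test_maf_below_threshold_survives_cascade(self):
        survivors, _ = run_cascade([record(maf_1000g=0.01)])
        assert len(survivors) == 1

    def test_absent_maf_retained(self):
        survivors, _ = run_cascade([record(maf_1000g=None)])
        assert len(survivors) == 1

    def test_indels_bypass_synonymous_step(self):
        # an indel never carries 'synonymous SNV' but must not be caught either
        r = record(ref="GAT", alt="G", exonic_function="frameshift indel")
        survivors, _ = run_cascade([r])
        assert survivors == [r]

    def test_synonymous_snv_dropped(self):
        survivors, report = run_cascade([record(exonic_function="synonymous SNV")])
        assert survivors == []
        assert report.steps[2] == ("drop_synonymous_snv", 0, 0)

    def test_first_entry_equals_input_size(self):
        records = [record(i) for i in range(9)]
        _, report = run_cascade(records)
        name, s, i = report.steps[0]
        assert (name, s + i) == ("input", 9)

    def test_counts_monotone_non_increasing(self):
        rng = np.random.default_rng(5)
        records = [
            record(
                i,
                function=str(rng.choice(["exonic", "splicing", "intronic", "intergenic"])),
                exonic_function=str(rng.choice(["synonymous SNV", "nonsynonymous SNV"])),
                conserved=bool(rng.random() < 0.6),
                segdup=bool(rng.random() < 0.2),
                dbsnp_id="rs1" if rng.random() < 0.4 else None,
                maf_1000g=float(rng.random()) if rng.random() < 0.5 else None,
            )
            for i in range(300)
        ]
        _, report = run_cascade(records)
        totals = [s + ind for _, s, ind in report]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_planted_survivor_fixture(self):
        """500 records built predicate-by-predicate; 12 planted survivors."""
        rng = np.random.default_rng(17)
        records, planted = [], []
        for i in range(500):
            if i % 42 == 0 and len(planted) < 12:
                r = record(i)  # passes every predicate
                planted.append(r)
            else:
                # break exactly one predicate, chosen round-robin
                breaker = i % 6
                r = record(
                    i,
                    function="intronic" if breaker == 0 else "exonic",
                    exonic_function="synonymous SNV" if breaker == 1 else "nonsynonymous SNV",
                    conserved=breaker != 2,
                    segdup=breaker == 3,
                    dbsnp_id="rs9" if breaker == 4 else None,
                    maf_1000g=0.3 if breaker == 5 else None,
                )
            records.append(r)
        records = [records[int(j)] for j in rng.permutation(len(records))]
        survivors, report = run_cascade(records)
        assert {s.key for s in survivors} == {p.key for p in planted}
        assert report.steps[0][1] + report.steps[0][2] == 500

    def test_step_order_permutation_same_final_set(self):
        rng = np.random.default_rng(23)
        records = [
            record(
                i,
                function=str(rng.choice(["exonic", "intronic"])),
                exonic_function=str(rng.choice(["synonymous SNV", "nonsynonymous SNV"])),
                conserved=bool(rng.random() < 0.7),
                segdup=bool(rng.random() < 0.3),
                dbsnp_id="rs1" if rng.random() < 0.3 else None,
                maf_1000g=float(rng.random()) if rng.random() < 0.4 else None,
            )
            for i in range(200)
        ]
        survivors, _ = run_cascade(records)
        predicates = [
            lambda r: r.function in ("exonic", "splicing"),
            lambda r: r.is_indel or r.exonic_function != "synonymous SNV",
            lambda r: r.conserved,
            lambda r: not r.segdup,
            lambda r: r.dbsnp_id is None,
            lambda r: r.maf_1000g is None or r.maf_1000g < 0.05,
        ]
        for perm in itertools.islice(itertools.permutations(predicates), 0, 720, 103):
            kept = [r for r in records if all(p(r) for p in perm)]
            assert {r.key for r in kept} == {s.key for s in survivors}

    def test_resources_derive_flags(self):
        r = record(conserved=False, segdup=True)
        resources = CascadeResources(
            conserved=GenomeIntervals.from_intervals([("1", r.pos, r.pos)]),
            segdup=GenomeIntervals.from_intervals([]),
            dbsnp=set(),
            freq_1000g={},
        )
        survivors, _ = run_cascade([r], resources)
        assert survivors == [r]
        assert r.conserved and not r.segdup

    def test_dbsnp_matching_by_key(self):
        r = record()
        resources = CascadeResources(
            conserved=GenomeIntervals.from_intervals([("1", r.pos, r.pos)]),
            segdup=GenomeIntervals.from_intervals([]),
            dbsnp={r.key},
            freq_1000g={},
        )
        survivors, report = run_cascade([r], resources)
        assert survivors == []
        assert report.steps[5] == ("drop_known_variant", 0, 0)


class TestNoveltyFilter:
    def test_low_maf_survivor_dropped_here(self):
        r = record(maf_1000g=0.01)
        survivors, _ = run_cascade([r])
        assert survivors  # passed step 6
        assert novelty_filter(survivors) == []

    def test_unknown_variant_retained(self):
        r = record()
        assert novelty_filter([r]) == [r]

    def test_esp_entry_drops(self):
        r = record(maf_esp=0.001)
        assert novelty_filter([r]) == []

    def test_52_to_19(self):
        """52 survivors, 33 with table entries -> 19 candidates."""
        rng = np.random.default_rng(4)
        records = [record(i) for i in range(52)]
        known = rng.choice(52, size=33, replace=False)
        freq_1000g, freq_esp = {}, {}
        for j, i in enumerate(known):
            table = freq_1000g if j % 2 == 0 else freq_esp
            table[records[int(i)].key] = 0.01
        out = novelty_filter(records, freq_1000g, freq_esp)
        assert len(out) == 19


class TestIntervalOverlap:
    @staticmethod
    def _brute_force(bed_rows, chrom, start, end):
        bases = set()
        for c, s, e in bed_rows:
            if c == chrom:
                bases.update(range(s + 1, e + 1))  # 0-based half-open -> 1-based
        return any(p in bases for p in range(start, end + 1))

    def test_agrees_with_per_base_scan(self):
        rng = np.random.default_rng(99)
        bed = [
            ("1", int(s), int(s + rng.integers(1, 30)))
            for s in rng.integers(0, 500, size=25)
        ] + [("2", 100, 200)]
        gi = GenomeIntervals.from_bed_rows(bed)
        for _ in range(400):
            chrom = str(rng.choice(["1", "2", "3"]))
            start = int(rng.integers(1, 600))
            end = start + int(rng.integers(0, 5))
            assert gi.overlaps(chrom, start, end) == self._brute_force(bed, chrom, start, end)

    def test_span_uses_ref_length(self):
        gi = GenomeIntervals.from_intervals([("1", 105, 110)])
        assert not gi.overlaps_span("1", 100, "AAA")   # 100-102
        assert gi.overlaps_span("1", 100, "AAAAAA")    # 100-105 touches


def test_annotation_record_maf_bounds():
    with pytest.raises(ValueError):
        AnnotationRecord("1", 1, "A", "C", maf_1000g=1.2)


def test_site_passthrough_prefilter():
    s = SiteGenotypes("1", 9, "A", "C", {})
    kept, dropped = prefilter_multiallelic([s])
    assert kept == [s] and dropped == 0
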