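"""Filter-cascade rules: boundary semantics, conjunctivity and audit."""

import itertools

import numpy as np
import pytest

from prca_panel import AnnotatedVariant, ClinicalAssertions, PopulationFrequencies, Thresholds
from prca_panel.filter_cascade import (
    RULE_ORDER,
    filter_clinical,
    filter_consequence,
    filter_inhouse,
    filter_maf,
    filter_quality,
    merge_callers,
    run_cascade,
)
from prca_panel.models import ClinicalCall, Consequence


def variant(**kwargs):
    base = dict(
        chrom="1", pos=100, ref="C", alt="T", gene="ATM",
        consequence=Consequence.MISSENSE, depth=100, vaf=0.5,
    )
    base.update(kwargs)
    return AnnotatedVariant(**base)


T = Thresholds()


@pytest.mark.parametrize(
    "fraction,kept",
    [(0.12, False), (0.10, True), (0.0, True), (0.101, False)],
)
def test_inhouse_recurrence_strictly_above_ten_percent(fraction, kept):
    decision = filter_inhouse(PopulationFrequencies(inhouse_fraction=fraction), T)
    assert decision.kept is kept


def test_missing_inhouse_fraction_kept_with_warning(caplog):
    with caplog.at_level("WARNING"):
        assert filter_inhouse(PopulationFrequencies(), T).kept
    assert "in-house" in caplog.text


@pytest.mark.parametrize(
    "depth,vaf,kept",
    [
        (21, 0.45, True),
        (20, 0.50, False),  # coverage bound is strict
        (100, 0.20, False),  # below the mosaicism band
        (100, 0.30, True),  # band is inclusive
        (100, 0.70, True),
        (100, 0.71, False),
    ],
)
def test_quality_depth_and_allele_fraction(depth, vaf, kept):
    assert filter_quality(variant(depth=depth, vaf=vaf), T).kept is kept


@pytest.mark.parametrize(
    "freqs,kept",
    [
        (PopulationFrequencies(maf_exac=0.002), False),
        (PopulationFrequencies(), True),  # absent from all databases
        (PopulationFrequencies(maf_1000g=0.001), True),  # inclusive bound
        (PopulationFrequencies(maf_1000g=0.0001, maf_evs=0.005), False),  # max rule
    ],
)
def test_maf_maximum_over_available_databases(freqs, kept):
    assert filter_maf(freqs, T).kept is kept


@pytest.mark.parametrize(
    "consequence,distance,kept",
    [
        (Consequence.SYNONYMOUS, 0, False),
        (Consequence.INTRONIC, 13, False),
        (Consequence.INTRONIC, 12, True),
        (Consequence.MISSENSE, 0, True),
        (Consequence.SPLICE_SITE, 1, True),
    ],
)
def test_consequence_exclusions(consequence, distance, kept):
    v = variant(consequence=consequence, intron_distance=max(distance, 0))
    assert filter_consequence(v, T).kept is kept


@pytest.mark.parametrize(
    "clinvar,kept",
    [
        (ClinicalCall.BENIGN, False),
        (ClinicalCall.LIKELY_BENIGN, False),
        (ClinicalCall.VUS, True),
        (ClinicalCall.LIKELY_PATHOGENIC, True),
        (ClinicalCall.CONFLICTING, True),
        (ClinicalCall.ABSENT, True),
    ],
)
def test_clinical_benign_assertions_discarded(clinvar, kept):
    assert filter_clinical(ClinicalAssertions(clinvar=clinvar)).kept is kept


def test_benign_in_any_database_removes(caplog):
    a = ClinicalAssertions(clinvar=ClinicalCall.VUS, lovd_class=ClinicalCall.BENIGN)
    assert not filter_clinical(a).kept


class TestMergeCallers:
    def test_dedup_records_full_support(self):
        v = variant()
        merged = merge_callers({"c1": [v], "c2": [v], "c3": [v]})
        assert len(merged) == 1
        assert merged[0].caller_set == {"c1", "c2", "c3"}

    def test_union_retains_single_caller_variant(self):
        merged = merge_callers({"c1": [variant()], "c2": [], "c3": []})
        assert len(merged) == 1
        assert merged[0].caller_set == {"c1"}

    def test_majority_mode_needs_two_callers(self):
        merged = merge_callers({"c1": [variant()], "c2": [], "c3": []}, mode="majority")
        assert merged == []

    def test_empty_inputs(self):
        assert merge_callers({"c1": [], "c2": []}) == []

    def test_conflicting_ref_alleles_rejected(self):
        with pytest.raises(ValueError, match="conflicting REF"):
            merge_callers({"c1": [variant(ref="C")], "c2": [variant(ref="G", alt="A")]})


def _random_inputs(n=50, seed=42):
    rng = np.random.default_rng(seed)
    consequences = list(Consequence)
    variants, freqs, assertions = [], {}, {}
    calls = list(ClinicalCall)
    for i in range(n):
        cons = consequences[rng.integers(len(consequences))]
        v = variant(
            pos=1000 + i,
            consequence=cons,
            intron_distance=int(rng.integers(1, 25)) if cons is Consequence.INTRONIC else 0,
            depth=int(rng.integers(0, 60)),
            vaf=float(rng.random()),
        )
        variants.append(v)
        freqs[v.key] = PopulationFrequencies(
            maf_exac=float(rng.random() * 0.004) if rng.random() < 0.7 else None,
            inhouse_fraction=float(rng.random() * 0.2),
        )
        assertions[v.key] = ClinicalAssertions(clinvar=calls[rng.integers(len(calls))])
    return variants, freqs, assertions


class TestCascade:
    def test_all_fixture_variants_survive(self, fixture_cohort, thresholds):
        """Every published panel variant passes the full cascade."""
        kept, audit = run_cascade(
            fixture_cohort.variants.values(),
            fixture_cohort.frequencies,
            fixture_cohort.assertions,
            thresholds,
        )
        assert len(kept) == len(fixture_cohort.variants)
        assert audit == []

    def test_audit_completeness_and_single_row_per_removal(self):
        variants, freqs, assertions = _random_inputs()
        kept, audit = run_cascade(variants, freqs, assertions, T)
        assert len(kept) + len(audit) == len(variants)
        assert len({r["variant_key"] for r in audit}) == len(audit)

    def test_kept_set_equals_intersection_of_per_filter_kept_sets(self):
        """Conjunctivity: the cascade keeps exactly the variants every
        individual filter keeps (independent recount)."""
        variants, freqs, assertions = _random_inputs(seed=7)
        kept, _ = run_cascade(variants, freqs, assertions, T)
        expected = {
            v.key
            for v in variants
            if filter_inhouse(freqs[v.key], T).kept
            and filter_quality(v, T).kept
            and filter_maf(freqs[v.key], T).kept
            and filter_consequence(v, T).kept
            and filter_clinical(assertions[v.key]).kept
        }
        assert {v.key for v in kept} == expected

    def test_kept_set_invariant_under_all_filter_orderings(self):
        """Applying the five filters sequentially in any of the 120 orders
        yields the same kept set."""
        variants, freqs, assertions = _random_inputs(seed=13)
        filters = {
            "inhouse": lambda v: filter_inhouse(freqs[v.key], T).kept,
            "quality": lambda v: filter_quality(v, T).kept,
            "maf": lambda v: filter_maf(freqs[v.key], T).kept,
            "consequence": lambda v: filter_consequence(v, T).kept,
            "clinical": lambda v: filter_clinical(assertions[v.key]).kept,
        }
        reference = None
        for order in itertools.permutations(RULE_ORDER):
            surviving = list(variants)
            for rule in order:
                surviving = [v for v in surviving if filters[rule](v)]
            keys = {v.key for v in surviving}
            reference = keys if reference is None else reference
            assert keys == reference
        kept, _ = run_cascade(variants, freqs, assertions, T)
        assert {v.key for v in kept} == reference
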