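"""Variant filtering rules with a per-variant audit trail.

Five conjunctive rules mirror the study's selection: in-house recurrence
(remove if carried by more than 10% of cases), call quality (coverage
strictly above 20x, alternative allele fraction between 30% and 70%
inclusive — outside that band reads as mosaicism or artefact), rarity
(maximum reference-population MAF at or below 0.1%), consequence class
(drop synonymous and intronic calls more than 12 bp from a splice
boundary), and clinical-database benign assertions.  Because the rules are
conjunctive, the kept set is order-invariant; the audit table records, for
every removed variant, the first rule that failed in the canonical order.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

from .config import Thresholds
from .models import (
    AnnotatedVariant,
    ClinicalAssertions,
    ClinicalCall,
    Consequence,
    FilterDecision,
    PopulationFrequencies,
)

logger = logging.getLogger(__name__)

#: Canonical rule order; used only for audit reporting, never for the result.
RULE_ORDER = ("inhouse", "quality", "maf", "consequence", "clinical")

_BENIGN_CALLS = {ClinicalCall.BENIGN, ClinicalCall.LIKELY_BENIGN}


def filter_inhouse(freqs: PopulationFrequencies, t: Thresholds) -> FilterDecision:
    """Remove variants carried by more than ``max_inhouse`` of the cohort
    (recurrent platform artefacts and local polymorphisms)."""
    fraction = freqs.inhouse_fraction
    if fraction is None:
        logger.warning("missing in-house fraction; treating as 0")
        fraction = 0.0
    if fraction > t.max_inhouse:
        return FilterDecision(kept=False, failed_rules=("inhouse",))
    return FilterDecision(kept=True)


def filter_quality(v: AnnotatedVariant, t: Thresholds) -> FilterDecision:
    """Keep calls with depth strictly above ``min_depth`` and allele
    fraction inside [``vaf_low``, ``vaf_high``]."""
    ok = v.depth > t.min_depth and t.vaf_low <= v.vaf <= t.vaf_high
    return FilterDecision(kept=ok, failed_rules=() if ok else ("quality",))


def filter_maf(freqs: PopulationFrequencies, t: Thresholds) -> FilterDecision:
    """Keep variants rare in every available reference population.

    The maximum over available MAFs (1000 Genomes, EVS, ExAC) is compared
    against the cutoff inclusively; a variant absent from all databases is
    kept.
    """
    mafs = freqs.available_mafs()
    if mafs and max(mafs) > t.max_maf:
        return FilterDecision(kept=False, failed_rules=("maf",))
    return FilterDecision(kept=True)


def filter_consequence(v: AnnotatedVariant, t: Thresholds) -> FilterDecision:
    """Drop synonymous variants and intronic variants more than
    ``max_intron_distance`` bases from the nearest exon-intron boundary."""
    removed = v.consequence is Consequence.SYNONYMOUS or (
        v.consequence is Consequence.INTRONIC
        and v.intron_distance > t.max_intron_distance
    )
    return FilterDecision(kept=not removed, failed_rules=() if not removed else ("consequence",))


def filter_clinical(a: ClinicalAssertions) -> FilterDecision:
    """Discard variants any clinical database asserts (likely) benign.

    Conflicting, VUS and absent assertions are retained for review.
    """
    removed = any(call in _BENIGN_CALLS for call in a.calls())
    return FilterDecision(kept=not removed, failed_rules=() if not removed else ("clinical",))


def merge_callers(
    per_caller_variants: Mapping[str, Sequence[AnnotatedVariant]],
    mode: str = "union",
) -> list[AnnotatedVariant]:
    """Merge per-caller variant lists into one deduplicated list.

    ``union`` keeps every variant called by at least one caller; ``majority``
    requires at least two of three.  Provenance is recorded in
    ``caller_set``.  Conflicting REF alleles at the same site are a
    validation error, not a silent overwrite.
    """
    if mode not in {"union", "majority"}:
        raise ValueError(f"unknown merge mode {mode!r}")
    merged: dict[str, AnnotatedVariant] = {}
    callers: dict[str, set[str]] = {}
    by_site_ref: dict[tuple[str, int], str] = {}
    for caller, variant_list in per_caller_variants.items():
        for v in variant_list:
            site = (v.chrom, v.pos)
            if site in by_site_ref and by_site_ref[site] != v.ref:
                raise ValueError(
                    f"conflicting REF alleles at {v.chrom}:{v.pos}: "
                    f"{by_site_ref[site]!r} vs {v.ref!r}"
                )
            by_site_ref[site] = v.ref
            merged.setdefault(v.key, v)
            callers.setdefault(v.key, set()).add(caller)
    out = []
    for key, v in merged.items():
        support = frozenset(callers[key])
        if mode == "majority" and len(support) < 2:
            continue
        out.append(
            AnnotatedVariant(
                **{**v.__dict__, "caller_set": support}
            )
        )
    return out


def run_cascade(
    variants: Iterable[AnnotatedVariant],
    freqs: Mapping[str, PopulationFrequencies],
    assertions: Mapping[str, ClinicalAssertions],
    t: Optional[Thresholds] = None,
) -> tuple[list[AnnotatedVariant], list[dict]]:
    """Apply all five filters; return (kept variants, audit rows).

    ``freqs`` and ``assertions`` are keyed by variant key; a variant with no
    entry gets empty annotations (which never remove it).  Every removed
    variant yields exactly one audit row naming all failed rules and the
    first in canonical order.
    """
    t = t or Thresholds()
    kept: list[AnnotatedVariant] = []
    audit: list[dict] = []
    for v in variants:
        f = freqs.get(v.key, PopulationFrequencies())
        a = assertions.get(v.key, ClinicalAssertions())
        decisions = {
            "inhouse": filter_inhouse(f, t),
            "quality": filter_quality(v, t),
            "maf": filter_maf(f, t),
            "consequence": filter_consequence(v, t),
            "clinical": filter_clinical(a),
        }
        failed = tuple(rule for rule in RULE_ORDER if not decisions[rule].kept)
        if failed:
            audit.append(
                {
                    "variant_key": v.key,
                    "gene": v.gene,
                    "first_failed_rule": failed[0],
                    "failed_rules": ";".join(failed),
                }
            )
        else:
            kept.append(v)
    return kept, audit
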