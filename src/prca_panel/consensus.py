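"""Predictor-consensus tiering of filtered variants.

Filtered variants are promoted to one of two tiers:

* ``truncating_deleterious`` — nonsense and frameshift changes, plus
  splice-site changes supported by at least 3 of 4 splice predictors or by
  a pathogenic/likely-pathogenic clinical assertion;
* ``potentially_pathogenic_missense`` — missense changes called pathogenic
  by at least 12 of the 15 in-silico predictors, of which at least three
  must be conservation tools.

Everything else stays ``unclassified``.  In-frame indels are unclassified
unless a clinical database asserts them pathogenic (the incidental-finding
route).  A missing predictor output counts against qualification: the
denominator stays fixed at 15 (a config flag switches to an
of-available-tools denominator, off by default).
"""

from __future__ import annotations

import logging
from typing import Optional

from .config import Thresholds
from .models import (
    AnnotatedVariant,
    ClinicalAssertions,
    ClinicalCall,
    Consequence,
    PredictorCall,
    PredictorProfile,
    SpliceCall,
    SplicePredictions,
    Tier,
    VariantTier,
)

logger = logging.getLogger(__name__)

_PATHOGENIC_ASSERTIONS = {ClinicalCall.PATHOGENIC, ClinicalCall.LIKELY_PATHOGENIC}


def call_from_rankscore(rankscore: float, cutoff: float = 0.5) -> PredictorCall:
    """Binarize a percentile-normalized rankscore; >= cutoff is pathogenic."""
    if not 0.0 <= rankscore <= 1.0:
        raise ValueError(f"rankscore out of [0, 1]: {rankscore}")
    return PredictorCall.PATHOGENIC if rankscore >= cutoff else PredictorCall.BENIGN


def evaluate_missense_consensus(
    p: PredictorProfile, t: Optional[Thresholds] = None, denominator_mode: str = "fixed"
) -> tuple[bool, int, int]:
    """Return (qualifies, n_pathogenic, n_conservation_pathogenic).

    ``fixed`` mode keeps the quorum at ``consensus_min_calls`` regardless of
    missing tools; ``available`` rescales the quorum to the number of
    non-missing tools.
    """
    t = t or Thresholds()
    n_cons = sum(
        1 for c in p.conservation_calls.values() if c is PredictorCall.PATHOGENIC
    )
    n_func = sum(
        1 for c in p.functional_calls.values() if c is PredictorCall.PATHOGENIC
    )
    n_pathogenic = n_func + n_cons
    min_calls = t.consensus_min_calls
    if denominator_mode == "available":
        available = sum(
            1
            for c in list(p.functional_calls.values()) + list(p.conservation_calls.values())
            if c is not PredictorCall.MISSING
        )
        # keep the same fraction of the (reduced) panel
        min_calls = -(-t.consensus_min_calls * available // t.consensus_total)
    qualifies = n_pathogenic >= min_calls and n_cons >= t.consensus_min_conservation
    return qualifies, n_pathogenic, n_cons


def evaluate_splice_consensus(
    s: SplicePredictions, t: Optional[Thresholds] = None
) -> tuple[bool, int]:
    """Return (qualifies, n_affected): quorum is 3 of the 4 splice tools;
    a missing prediction counts as unaffected."""
    t = t or Thresholds()
    n_affected = sum(1 for c in s.calls.values() if c is SpliceCall.AFFECTED)
    return n_affected >= t.splice_min_calls, n_affected


def assign_tier(
    v: AnnotatedVariant,
    profile: Optional[PredictorProfile],
    splice: Optional[SplicePredictions],
    assertions: Optional[ClinicalAssertions] = None,
    t: Optional[Thresholds] = None,
    denominator_mode: str = "fixed",
) -> VariantTier:
    """Dispatch a filtered variant to its tier by consequence class."""
    t = t or Thresholds()
    a = assertions or ClinicalAssertions()

    if v.consequence in (Consequence.NONSENSE, Consequence.FRAMESHIFT):
        return VariantTier(
            tier=Tier.TRUNCATING_DELETERIOUS,
            basis=f"{v.consequence.value} change {v.protein_change}",
        )

    if v.consequence is Consequence.SPLICE_SITE:
        if splice is not None:
            qualifies, n_affected = evaluate_splice_consensus(splice, t)
            if qualifies:
                return VariantTier(
                    tier=Tier.TRUNCATING_DELETERIOUS,
                    basis=f"splice consensus {n_affected}/{t.splice_total}",
                )
        if a.clinvar in _PATHOGENIC_ASSERTIONS:
            return VariantTier(
                tier=Tier.TRUNCATING_DELETERIOUS,
                basis=f"splice site with ClinVar {a.clinvar.value} assertion",
            )
        return VariantTier(tier=Tier.UNCLASSIFIED)

    if v.consequence is Consequence.MISSENSE:
        if profile is None:
            logger.warning("missense variant %s has no predictor profile", v.key)
            return VariantTier(tier=Tier.UNCLASSIFIED)
        qualifies, n_path, n_cons = evaluate_missense_consensus(
            profile, t, denominator_mode=denominator_mode
        )
        if qualifies:
            return VariantTier(
                tier=Tier.POTENTIALLY_PATHOGENIC_MISSENSE,
                basis=(
                    f"missense consensus {n_path}/{t.consensus_total} "
                    f"({n_cons} conservation)"
                ),
            )
        return VariantTier(tier=Tier.UNCLASSIFIED)

    if v.consequence is Consequence.INFRAME_INDEL and a.clinvar is ClinicalCall.PATHOGENIC:
        return VariantTier(
            tier=Tier.TRUNCATING_DELETERIOUS,
            basis="in-frame indel asserted pathogenic in clinical database",
        )

    return VariantTier(tier=Tier.UNCLASSIFIED)
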