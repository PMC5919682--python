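"""ACMG-AMP evidence combination with a manual-evidence overlay.

Evidence codes (PVS1, PS1-4, PM1-6, PP1-5, BA1, BS1-4, BP1-7) are inputs —
typically exported from an automated interpreter — except PS4, which
:func:`evaluate_ps4` can derive from case-control carrier counts.  The
combining rules are the standard 2015 joint-consensus rules: a verdict of
pathogenic or likely pathogenic requires one of the fixed pathogenic-side
combinations, benign/likely benign one of the benign-side combinations, and
anything else (including a simultaneous firing of both sides) is a variant
of uncertain significance.  A lone benign-supporting code does not veto a
pathogenic-side combination; only a complete benign-side rule does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .case_control import fisher_exact
from .models import ContingencyTable

PATHOGENIC_VERY_STRONG = ("PVS1",)
PATHOGENIC_STRONG = tuple(f"PS{i}" for i in range(1, 5))
PATHOGENIC_MODERATE = tuple(f"PM{i}" for i in range(1, 7))
PATHOGENIC_SUPPORTING = tuple(f"PP{i}" for i in range(1, 6))
BENIGN_STANDALONE = ("BA1",)
BENIGN_STRONG = tuple(f"BS{i}" for i in range(1, 5))
BENIGN_SUPPORTING = tuple(f"BP{i}" for i in range(1, 8))

VALID_CODES: frozenset[str] = frozenset(
    PATHOGENIC_VERY_STRONG
    + PATHOGENIC_STRONG
    + PATHOGENIC_MODERATE
    + PATHOGENIC_SUPPORTING
    + BENIGN_STANDALONE
    + BENIGN_STRONG
    + BENIGN_SUPPORTING
)


class Verdict(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


#: Ordering used by the monotonicity property (benign < ... < pathogenic).
VERDICT_ORDER = (
    Verdict.BENIGN,
    Verdict.LIKELY_BENIGN,
    Verdict.VUS,
    Verdict.LIKELY_PATHOGENIC,
    Verdict.PATHOGENIC,
)


@dataclass(frozen=True)
class ACMGEvidence:
    """A set of fulfilled criteria with per-code provenance."""

    criteria: frozenset[str]
    provenance: Mapping[str, str] = field(default_factory=dict)  # code -> automatic|manual

    def __post_init__(self) -> None:
        unknown = self.criteria - VALID_CODES
        if unknown:
            raise ValueError(f"unknown ACMG-AMP codes: {sorted(unknown)}")

    @classmethod
    def from_codes(cls, codes: Iterable[str], provenance: str = "automatic") -> "ACMGEvidence":
        codes = frozenset(codes)
        return cls(criteria=codes, provenance={c: provenance for c in codes})


@dataclass(frozen=True)
class ACMGClass:
    verdict: Verdict
    fired_rule: str = "none"


def _counts(criteria: frozenset[str]) -> tuple[int, int, int, int, int, int, int]:
    pvs = sum(1 for c in criteria if c in PATHOGENIC_VERY_STRONG)
    ps = sum(1 for c in criteria if c in PATHOGENIC_STRONG)
    pm = sum(1 for c in criteria if c in PATHOGENIC_MODERATE)
    pp = sum(1 for c in criteria if c in PATHOGENIC_SUPPORTING)
    ba = sum(1 for c in criteria if c in BENIGN_STANDALONE)
    bs = sum(1 for c in criteria if c in BENIGN_STRONG)
    bp = sum(1 for c in criteria if c in BENIGN_SUPPORTING)
    return pvs, ps, pm, pp, ba, bs, bp


def _pathogenic_rule(pvs: int, ps: int, pm: int, pp: int) -> str | None:
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2):
        return "P.i"
    if ps >= 2:
        return "P.ii"
    if ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        return "P.iii"
    return None


def _likely_pathogenic_rule(pvs: int, ps: int, pm: int, pp: int) -> str | None:
    if pvs == 1 and pm == 1:
        return "LP.i"
    if ps == 1 and 1 <= pm <= 2:
        return "LP.ii"
    if ps == 1 and pp >= 2:
        return "LP.iii"
    if pm >= 3:
        return "LP.iv"
    if pm == 2 and pp >= 2:
        return "LP.v"
    if pm == 1 and pp >= 4:
        return "LP.vi"
    return None


def combine_criteria(e: ACMGEvidence) -> ACMGClass:
    """Combine fulfilled criteria into a five-class verdict."""
    pvs, ps, pm, pp, ba, bs, bp = _counts(e.criteria)

    path_rule = _pathogenic_rule(pvs, ps, pm, pp)
    lp_rule = None if path_rule else _likely_pathogenic_rule(pvs, ps, pm, pp)

    benign_rule = None
    if ba >= 1:
        benign_rule = "B.standalone"
    elif bs >= 2:
        benign_rule = "B.ii"
    lb_rule = None
    if benign_rule is None and ((bs >= 1 and bp >= 1) or bp >= 2):
        lb_rule = "LB"

    pathogenic_side = path_rule or lp_rule
    benign_side = benign_rule or lb_rule

    if pathogenic_side and benign_side:
        return ACMGClass(verdict=Verdict.VUS, fired_rule=f"conflict:{pathogenic_side}|{benign_side}")
    if path_rule:
        return ACMGClass(verdict=Verdict.PATHOGENIC, fired_rule=path_rule)
    if lp_rule:
        return ACMGClass(verdict=Verdict.LIKELY_PATHOGENIC, fired_rule=lp_rule)
    if benign_rule:
        return ACMGClass(verdict=Verdict.BENIGN, fired_rule=benign_rule)
    if lb_rule:
        return ACMGClass(verdict=Verdict.LIKELY_BENIGN, fired_rule=lb_rule)
    return ACMGClass(verdict=Verdict.VUS, fired_rule="none")


def apply_manual_overlay(e: ACMGEvidence, additions: Iterable[str]) -> ACMGEvidence:
    """Union the evidence with manually asserted codes (idempotent)."""
    additions = frozenset(additions)
    unknown = additions - VALID_CODES
    if unknown:
        raise ValueError(f"unknown ACMG-AMP codes: {sorted(unknown)}")
    provenance = dict(e.provenance)
    for code in additions:
        provenance.setdefault(code, "manual")
    return ACMGEvidence(criteria=e.criteria | additions, provenance=provenance)


def evaluate_ps4(
    case_carriers: int,
    n_cases: int,
    control_carriers: int,
    n_controls: int,
    alpha: float = 0.05,
) -> bool:
    """PS4: prevalence in affected individuals significantly above controls.

    True when the two-sided Fisher exact p-value is below ``alpha`` and the
    case carrier fraction exceeds the control fraction.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("group sizes must be positive")
    if not 0 <= case_carriers <= n_cases or not 0 <= control_carriers <= n_controls:
        raise ValueError("carrier counts must lie within group sizes")
    table = ContingencyTable(
        a=case_carriers,
        b=n_cases - case_carriers,
        c=control_carriers,
        d=n_controls - control_carriers,
    )
    p = fisher_exact(table)
    enriched = case_carriers / n_cases > control_carriers / n_controls
    return p < alpha and enriched
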