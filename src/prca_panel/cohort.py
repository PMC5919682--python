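"""Family-history criteria, carrier accounting and cohort summaries.

The study's eligibility rules define two overlapping groups:

* **A — familial/hereditary prostate cancer.**  A1: at least three
  first-degree relatives with PrCa at any age.  A2: two first-degree
  relatives with PrCa, average age at diagnosis of the affected set
  (including the index) at or below 65, at least one affected diagnosed
  before 61.  A3: index diagnosed before 61, at least two first- or
  second-degree relatives with PrCa, average of the three youngest affected
  (including the index) at or below 65.
* **B — early onset and/or aggregation of other cancers.**  B1: index
  diagnosed before 56 with at least three first- or second-degree relatives
  with cancer and the three youngest diagnoses (including the index)
  averaging at or below 55.  B2: a second primary cancer besides PrCa.
  B3: relatives with early-onset and/or rare cancers (bilateral breast,
  male breast, brain) and/or a clustering of other cancers (breast, colon,
  gastric).

"Cases"/"diagnoses" in the averaging clauses are read as the affected set
including the index; relative counts exclude the index (both behaviours
config-switchable).  Early onset for the index means diagnosis at or
before 55.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

from .config import DEFAULT_CLUSTERING_CANCERS, DEFAULT_RARE_CANCERS
from .models import (
    AnnotatedVariant,
    CarrierAssignment,
    CohortSummary,
    CriteriaFlags,
    Degree,
    PatientRecord,
    Tier,
    VariantTier,
)

logger = logging.getLogger(__name__)

PROSTATE = "prostate"

QUALIFYING_TIERS = {Tier.TRUNCATING_DELETERIOUS, Tier.POTENTIALLY_PATHOGENIC_MISSENSE}


def round_pct(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, rounding half away from zero."""
    if denominator == 0:
        return 0.0
    x = 100.0 * numerator / denominator
    return int(x * 10 + (0.5 if x >= 0 else -0.5)) / 10


def _ages(values: Iterable[Optional[float]]) -> Optional[list[float]]:
    out = []
    for v in values:
        if v is None:
            return None
        out.append(float(v))
    return out


def classify_criteria(
    p: PatientRecord,
    rare_cancer_list: Sequence[str] = DEFAULT_RARE_CANCERS,
    clustering_list: Sequence[str] = DEFAULT_CLUSTERING_CANCERS,
    relative_early_onset_age: float = 50.0,
    a1_includes_index: bool = False,
) -> CriteriaFlags:
    """Evaluate the six eligibility clauses for one index case."""
    prca_first = [r for r in p.relatives if r.cancer_type == PROSTATE and r.degree is Degree.FIRST]
    prca_any = [r for r in p.relatives if r.cancer_type == PROSTATE]
    cancer_any = [r for r in p.relatives if r.cancer_type]

    # --- A1: three first-degree PrCa relatives, ages irrelevant
    required = 2 if a1_includes_index else 3
    a1 = len(prca_first) >= required

    # --- A2: two first-degree PrCa relatives, affected-set average <= 65,
    #         one affected diagnosed before 61
    a2 = False
    if len(prca_first) >= 2:
        ages = _ages([p.age_at_dx] + [r.age_at_dx for r in prca_first])
        if ages is None:
            logger.warning("%s: missing ages, A2 not evaluable", p.patient_id)
        else:
            a2 = sum(ages) / len(ages) <= 65 and min(ages) < 61

    # --- A3: index before 61, two first/second-degree PrCa relatives,
    #         three youngest affected average <= 65
    a3 = False
    if p.age_at_dx < 61 and len(prca_any) >= 2:
        ages = _ages([p.age_at_dx] + [r.age_at_dx for r in prca_any])
        if ages is None:
            logger.warning("%s: missing ages, A3 not evaluable", p.patient_id)
        else:
            youngest = sorted(ages)[:3]
            a3 = sum(youngest) / len(youngest) <= 65

    # --- B1: index before 56, three relatives with cancer,
    #         three youngest diagnoses average <= 55
    b1 = False
    if p.age_at_dx < 56 and len(cancer_any) >= 3:
        known = [p.age_at_dx] + [r.age_at_dx for r in cancer_any if r.age_at_dx is not None]
        if len(known) < 3:
            logger.warning("%s: missing ages, B1 not evaluable", p.patient_id)
        else:
            youngest = sorted(float(a) for a in known)[:3]
            b1 = sum(youngest) / len(youngest) <= 55

    # --- B2: second primary cancer besides PrCa
    b2 = len(p.second_primaries) > 0

    # --- B3: early-onset / rare / clustered cancers in relatives (non-PrCa)
    other = [r for r in p.relatives if r.cancer_type != PROSTATE]
    rare = {c.lower() for c in rare_cancer_list}
    clustering = {c.lower() for c in clustering_list}
    b3 = (
        any(r.cancer_type.lower() in rare for r in other)
        or any(
            r.age_at_dx is not None and r.age_at_dx <= relative_early_onset_age
            for r in other
        )
        or sum(1 for r in other if r.cancer_type.lower() in clustering) >= 2
    )

    return CriteriaFlags(A1=a1, A2=a2, A3=a3, B1=b1, B2=b2, B3=b3)


def assemble_carriers(
    patient_variants: Mapping[str, Sequence[AnnotatedVariant]],
    tiers: Mapping[str, VariantTier],
    verdicts: Optional[Mapping[str, str]] = None,
    ihc: Optional[Mapping[str, Mapping[str, bool]]] = None,
    incidental: Optional[set[tuple[str, str]]] = None,
) -> list[CarrierAssignment]:
    """Apply exclusion rules and collect the surviving carriers.

    A patient is a carrier iff at least one variant in a qualifying tier
    survives two exclusions: (i) missense variants in a gene whose matched
    tumor immunohistochemistry shows retained protein expression, and
    (ii) variants flagged as incidental findings.
    """
    verdicts = verdicts or {}
    ihc = ihc or {}
    incidental = incidental or set()
    out: list[CarrierAssignment] = []

    for pid, variants in patient_variants.items():
        patient_genes = {v.gene for v in variants}
        for gene in ihc.get(pid, {}):
            if gene not in patient_genes:
                logger.warning("%s: IHC result for %s but no variant in that gene", pid, gene)

        assignment = CarrierAssignment(patient_id=pid)
        for v in variants:
            tier_rec = tiers.get(v.key)
            if tier_rec is None or tier_rec.tier not in QUALIFYING_TIERS:
                continue
            if (pid, v.key) in incidental:
                assignment.excluded_variants.append((v, "incidental_finding"))
                continue
            if (
                tier_rec.tier is Tier.POTENTIALLY_PATHOGENIC_MISSENSE
                and ihc.get(pid, {}).get(v.gene) is True
            ):
                assignment.excluded_variants.append((v, "ihc_retained_expression"))
                continue
            assignment.variants.append((v, tier_rec.tier, verdicts.get(v.key)))
        if assignment.variants or assignment.excluded_variants:
            out.append(assignment)
    return out


def attribute_gene(
    c: CarrierAssignment,
    gene_pvalues: Optional[Mapping[str, float]] = None,
) -> str:
    """Pick the one gene credited with the patient's risk.

    A truncating/deleterious variant always outranks a co-occurring
    missense; remaining ties break by smaller case-control p-value, then
    alphabetically.
    """
    if not c.variants:
        raise ValueError(f"{c.patient_id}: no surviving variants to attribute")
    truncating = [v for v, tier, _ in c.variants if tier is Tier.TRUNCATING_DELETERIOUS]
    pool = truncating or [v for v, _, _ in c.variants]
    gene_pvalues = gene_pvalues or {}
    genes = sorted({v.gene for v in pool}, key=lambda g: (gene_pvalues.get(g, 1.0), g))
    return genes[0]


def summarize(
    patients: Sequence[PatientRecord],
    flags: Mapping[str, CriteriaFlags],
    carriers: Sequence[CarrierAssignment],
    gene_pvalues: Optional[Mapping[str, float]] = None,
    early_onset_age: float = 55.0,
) -> CohortSummary:
    """Carrier counts and fractions with the study's denominators.

    Fractions are reported against the whole cohort, the A and B groups,
    the early-onset set (diagnosis at or before ``early_onset_age``) and
    the carrier set.  Per-gene counts are reported both by attributed gene
    (one gene per carrier) and raw (every carrier of a surviving variant in
    the gene).
    """
    n_patients = len(patients)
    carrying = [c for c in carriers if c.is_carrier]
    carrier_ids = {c.patient_id for c in carrying}
    n_carriers = len(carrier_ids)

    group_a = {pid for pid, f in flags.items() if f.group_a}
    group_b = {pid for pid, f in flags.items() if f.group_b}
    early = {p.patient_id for p in patients if p.age_at_dx <= early_onset_age}

    per_gene_attr: dict[str, int] = {}
    per_gene_raw: dict[str, int] = {}
    for c in carrying:
        gene = c.attributed_gene or attribute_gene(c, gene_pvalues)
        per_gene_attr[gene] = per_gene_attr.get(gene, 0) + 1
        for g in {v.gene for v, _, _ in c.variants}:
            per_gene_raw[g] = per_gene_raw.get(g, 0) + 1

    n_a = len(carrier_ids & group_a)
    n_b = len(carrier_ids & group_b)
    n_early = len(carrier_ids & early)

    return CohortSummary(
        n_patients=n_patients,
        n_carriers=n_carriers,
        pct_carriers=round_pct(n_carriers, n_patients),
        per_gene_attributed={
            g: (n, round_pct(n, n_patients)) for g, n in sorted(per_gene_attr.items())
        },
        per_gene_raw={g: (n, round_pct(n, n_patients)) for g, n in sorted(per_gene_raw.items())},
        n_group_a=len(group_a),
        n_group_b=len(group_b),
        n_carriers_group_a=n_a,
        n_carriers_group_b=n_b,
        pct_carriers_in_group_a=round_pct(n_a, n_carriers),
        pct_carriers_in_group_b=round_pct(n_b, n_carriers),
        pct_group_a_carrying=round_pct(n_a, len(group_a)),
        pct_group_b_carrying=round_pct(n_b, len(group_b)),
        n_early_onset=len(early),
        n_early_onset_carriers=n_early,
        pct_early_onset_carriers=round_pct(n_early, n_carriers),
        pct_early_onset_group_carrying=round_pct(n_early, len(early)),
    )
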