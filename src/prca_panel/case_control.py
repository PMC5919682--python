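"""Exact 2x2 association tests for carrier frequencies.

Carrier-level tables (one row per individual) are used against genotyped
control panels; allele-level tables against reference populations where only
allele counts are public (e.g. ExAC NFE).  The two-sided p-value is the
conventional Fisher summation of all tables, with margins fixed, whose
point hypergeometric probability does not exceed that of the observed
table.  No multiplicity adjustment is applied anywhere.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .models import ContingencyTable, ControlCounts


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table."""
    if min(t.a + t.b, t.c + t.d) == 0 or (t.a + t.c) + (t.b + t.d) == 0:
        # a degenerate margin carries no information
        return 1.0
    _, p = stats.fisher_exact(t.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def fisher_exact_one_sided(t: ContingencyTable) -> float:
    """One-sided (enrichment in row 1) Fisher exact p-value."""
    _, p = stats.fisher_exact(t.as_array(), alternative="greater")
    return float(min(p, 1.0))


def build_carrier_table(
    case_carriers: int,
    n_cases: int,
    ctrl: ControlCounts,
    variant_key: str,
) -> ContingencyTable:
    """Case vs control carrier counts for one variant.

    A variant absent from the control panel's carrier map counts as zero
    control carriers.
    """
    if not 0 <= case_carriers <= n_cases:
        raise ValueError("case carriers exceed group size")
    control_carriers = ctrl.carriers_of(variant_key)
    if control_carriers > ctrl.n_individuals:
        raise ValueError("control carriers exceed panel size")
    return ContingencyTable(
        a=case_carriers,
        b=n_cases - case_carriers,
        c=control_carriers,
        d=ctrl.n_individuals - control_carriers,
    )


def compare_reference_alleles(
    case_alt: int,
    case_total_alleles: int,
    ref_alt: int,
    ref_total_alleles: int,
) -> float:
    """Fisher two-sided p on an allele-count 2x2 (cases vs reference)."""
    if case_alt > case_total_alleles or ref_alt > ref_total_alleles:
        raise ValueError("alt allele counts exceed totals")
    table = ContingencyTable(
        a=case_alt,
        b=case_total_alleles - case_alt,
        c=ref_alt,
        d=ref_total_alleles - ref_alt,
    )
    return fisher_exact(table)


def clinicopath_association(
    carrier_flags: Sequence[bool],
    feature: Sequence[object],
) -> Mapping[object, float]:
    """Fisher p-value per feature level (level vs rest against carrier status).

    Each categorical level is collapsed to a 2x2 table of carrier status
    against membership of that level.  Raises on an empty or degenerate
    stratification (all patients carriers, or a single level covering
    everyone in a two-level design is fine — the table is still 2x2 with
    positive margins).
    """
    if len(carrier_flags) != len(feature):
        raise ValueError("carrier_flags and feature must cover the same patients")
    if len(carrier_flags) == 0:
        raise ValueError("empty patient universe")
    flags = np.asarray(carrier_flags, dtype=bool)
    if flags.all() or not flags.any():
        raise ValueError("degenerate carrier margin: need both carriers and non-carriers")
    levels = sorted(set(feature), key=str)
    out: dict[object, float] = {}
    values = np.asarray(feature, dtype=object)
    for level in levels:
        in_level = values == level
        table = ContingencyTable(
            a=int((flags & in_level).sum()),
            b=int((flags & ~in_level).sum()),
            c=int((~flags & in_level).sum()),
            d=int((~flags & ~in_level).sum()),
        )
        out[level] = fisher_exact(table)
    return out
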