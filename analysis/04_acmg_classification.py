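#!/usr/bin/env python
"""ACMG-AMP classification of the missense variants, with and without the
manually curated evidence (PS3 functional studies for CHEK2 p.Arg117Gly,
PS4 case-control enrichment for ATM p.Arg2854Cys).

All automatic evidence sets combine to VUS; the two manual additions each
upgrade their variant to likely pathogenic.  Writes results/verdicts.tsv.
"""

from pathlib import Path

from prca_panel import load_paper_fixtures
from prca_panel.acmg import ACMGEvidence, apply_manual_overlay, combine_criteria
from prca_panel.pipeline import _write_tsv

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = load_paper_fixtures()
    rows = []
    for key, record in cohort.acmg.items():
        v = cohort.variants[key]
        if record is None:
            rows.append([key, v.gene, v.cdna_change, ".", "not_determined", "not_determined"])
            continue
        auto = combine_criteria(ACMGEvidence.from_codes(record.automatic))
        full = combine_criteria(
            apply_manual_overlay(ACMGEvidence.from_codes(record.automatic), record.manual)
        )
        codes = ";".join(sorted(record.automatic | record.manual))
        rows.append([key, v.gene, v.cdna_change, codes, auto.verdict.value, full.verdict.value])
        marker = " -> " + full.verdict.value if full.verdict != auto.verdict else ""
        print(f"{v.gene:6s} {v.cdna_change:14s} [{codes}] {auto.verdict.value}{marker}")
    OUT.mkdir(parents=True, exist_ok=True)
    _write_tsv(OUT / "verdicts.tsv",
               ["variant_key", "gene", "cdna", "criteria", "verdict_automatic", "verdict_with_manual"],
               rows)


if __name__ == "__main__":
    main()
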