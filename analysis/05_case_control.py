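#!/usr/bin/env python
"""Fisher exact carrier comparisons against the two control panels
(710 healthy individuals; 504 non-prostate cancer cases sequenced with the
same panel).  Writes results/associations.tsv.

Note the printed per-variant p-values of the original screen derive from
supplementary genotype frequencies that are not part of the packaged
fixtures; the carrier-mode tables computed here use the main-text counts.
"""

from pathlib import Path

from prca_panel import load_paper_fixtures
from prca_panel.case_control import build_carrier_table, fisher_exact
from prca_panel.pipeline import _write_tsv

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = load_paper_fixtures()
    carriers_by_key: dict[str, set[str]] = {}
    for pid, v in cohort.planted_variants:
        carriers_by_key.setdefault(v.key, set()).add(pid)
    n_cases = len(cohort.patients)
    rows = []
    for label, panel in cohort.control_panels.items():
        for key, v in cohort.variants.items():
            table = build_carrier_table(len(carriers_by_key.get(key, ())), n_cases, panel, key)
            p = fisher_exact(table)
            rows.append([key, v.gene, v.cdna_change, label,
                         table.a, table.b, table.c, table.d, format(p, ".4g")])
            if p < 0.05:
                print(f"{v.gene} {v.cdna_change} vs {label}: "
                      f"{table.a}/{n_cases} vs {table.c}/{panel.n_individuals}, p={p:.4g}")
    OUT.mkdir(parents=True, exist_ok=True)
    _write_tsv(OUT / "associations.tsv",
               ["variant_key", "gene", "cdna", "group", "a", "b", "c", "d", "p"], rows)
    print(f"wrote {len(rows)} comparisons to {OUT}/associations.tsv")


if __name__ == "__main__":
    main()
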