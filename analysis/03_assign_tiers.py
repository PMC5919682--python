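#!/usr/bin/env python
"""Tier the filtered variants by predictor consensus.

Nonsense/frameshift calls and splice-site calls with 3-of-4 splice-predictor
support are truncating/deleterious; missense calls need 12 of 15 pathogenic
predictions including three conservation tools.  Writes results/tiers.tsv.
"""

from collections import Counter
from pathlib import Path

from prca_panel import Thresholds, load_paper_fixtures
from prca_panel.consensus import assign_tier
from prca_panel.pipeline import _write_tsv

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = load_paper_fixtures()
    t = Thresholds()
    rows = []
    counts: Counter = Counter()
    for key, v in cohort.variants.items():
        tier = assign_tier(v, cohort.profiles.get(key), cohort.splice.get(key),
                           cohort.assertions.get(key), t)
        rows.append([key, v.gene, v.cdna_change, tier.tier.value, tier.basis or "."])
        counts[tier.tier.value] += 1
    OUT.mkdir(parents=True, exist_ok=True)
    _write_tsv(OUT / "tiers.tsv", ["variant_key", "gene", "cdna", "tier", "basis"], rows)
    for tier, n in sorted(counts.items()):
        print(f"{tier}: {n} variants")


if __name__ == "__main__":
    main()
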