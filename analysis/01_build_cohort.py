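#!/usr/bin/env python
"""Materialize the 121-patient fixture cohort as VCF + TSV inputs.

Writes the multi-sample VCF, the annotation table (population frequencies,
clinical assertions, 15 predictor rankscores, 4 splice calls) and the
patient metadata table under results/cohort/.
"""

from pathlib import Path

from prca_panel import load_paper_fixtures
from prca_panel import vcf_io

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    cohort = load_paper_fixtures()
    OUT.mkdir(parents=True, exist_ok=True)
    vcf_io.write_vcf(OUT / "cohort.vcf", cohort)
    vcf_io.write_annotation_tsv(OUT / "annotations.tsv", cohort)
    vcf_io.write_patient_tsv(OUT / "patients.tsv", cohort.patients)
    n_carriers = len(set(cohort.carrier_ids()))
    print(f"cohort: {len(cohort.patients)} patients, "
          f"{len(cohort.variants)} distinct variants planted in {n_carriers} patients")
    print(f"wrote {OUT}/cohort.vcf, annotations.tsv, patients.tsv")


if __name__ == "__main__":
    main()
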