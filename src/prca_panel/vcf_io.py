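"""Readers and writers for the pipeline's on-disk formats.

Formats: VCF v4.2 (GRCh37, 1-based; one sample column per patient, GT
field), the annotation TSV dialect (tab-separated, UTF-8, header row, "."
for missing), a patient metadata TSV, and control-count JSON.  VCF records
are written as plain text and read back through cyvcf2; multi-allelic
records are decomposed into biallelic records on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

from .models import (
    ALL_PREDICTORS,
    SPLICE_PREDICTORS,
    AnnotatedVariant,
    ClinicalAssertions,
    ClinicalCall,
    Consequence,
    ControlCounts,
    Degree,
    PatientRecord,
    PopulationFrequencies,
    PredictorProfile,
    Relative,
    SpliceCall,
    SplicePredictions,
)
from .synthetic_data import FixtureCohort, profile_from_rankscores

ANNOTATION_COLUMNS = (
    ["chrom", "pos", "ref", "alt", "gene", "transcript", "cdna", "protein",
     "consequence", "intron_distance", "depth", "vaf",
     "maf_1000g", "maf_evs", "maf_exac", "maf_exac_nfe", "inhouse_fraction",
     "clinvar", "bic", "lovd"]
    + [f"rs_{t}" for t in ALL_PREDICTORS]
    + [f"sp_{t}" for t in SPLICE_PREDICTORS]
)


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(path: str | Path, cohort: FixtureCohort) -> None:
    """Write the cohort's planted variants as a multi-sample VCF v4.2."""
    sample_ids = [p.patient_id for p in cohort.patients]
    carriers_by_key: dict[str, set[str]] = {}
    for pid, v in cohort.planted_variants:
        carriers_by_key.setdefault(v.key, set()).add(pid)

    def chrom_key(chrom: str):
        return (0, int(chrom)) if chrom.isdigit() else (1, chrom)

    def sort_key(v: AnnotatedVariant):
        return chrom_key(v.chrom)

    contigs = sorted({v.chrom for v in cohort.variants.values()}, key=chrom_key)
    lines = [
        "##fileformat=VCFv4.2",
        "##reference=GRCh37",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]

    for v in sorted(cohort.variants.values(), key=lambda v: (sort_key(v), v.pos)):
        carriers = carriers_by_key.get(v.key, set())
        gts = ["0/1" if pid in carriers else "0/0" for pid in sample_ids]
        lines.append(
            "\t".join(
                [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", f"GENE={v.gene}", "GT"]
                + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(
    path: str | Path,
    annotations: Optional[dict] = None,
) -> tuple[list[AnnotatedVariant], dict[str, set[str]], list[str]]:
    """Read a VCF; return (variants, carriers-by-key, join failures).

    Multi-allelic records are decomposed into one biallelic record per ALT.
    When an ``annotations`` bundle (from :func:`read_annotation_tsv`) is
    supplied, records are joined by chrom:pos:ref:alt and keys that fail to
    join are reported, not dropped silently.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[AnnotatedVariant] = []
    carriers: dict[str, set[str]] = {}
    failures: list[str] = []
    ann_variants = annotations["variants"] if annotations else {}

    for record in vcf:
        for alt_index, alt in enumerate(record.ALT):
            key = f"{record.CHROM}:{record.POS}:{record.REF}:{alt}"
            if annotations is not None and key in ann_variants:
                v = ann_variants[key]
            else:
                if annotations is not None:
                    failures.append(key)
                gene = dict(record.INFO).get("GENE", ".")
                v = AnnotatedVariant(
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    gene=gene,
                )
            variants.append(v)
            allele = alt_index + 1
            carrier_ids = {
                samples[i]
                for i, gt in enumerate(record.genotypes)
                if allele in gt[:-1]
            }
            carriers[key] = carrier_ids
    return variants, carriers, failures


# ---------------------------------------------------------------------------
# annotation TSV
# ---------------------------------------------------------------------------

def write_annotation_tsv(path: str | Path, cohort: FixtureCohort) -> None:
    rows = ["\t".join(ANNOTATION_COLUMNS)]
    for key, v in cohort.variants.items():
        f: PopulationFrequencies = cohort.frequencies.get(key, PopulationFrequencies())
        a = cohort.assertions.get(key, ClinicalAssertions())
        profile = cohort.profiles.get(key)
        splice = cohort.splice.get(key)
        values = [
            v.chrom, str(v.pos), v.ref, v.alt, v.gene, v.transcript, v.cdna_change,
            v.protein_change, v.consequence.value, str(v.intron_distance),
            str(v.depth), _fmt(v.vaf),
            _fmt(f.maf_1000g), _fmt(f.maf_evs), _fmt(f.maf_exac), _fmt(f.maf_exac_nfe),
            _fmt(f.inhouse_fraction),
            a.clinvar.value, a.bic_class.value, a.lovd_class.value,
        ]
        scores = profile.rankscores if profile and profile.rankscores else {}
        values += [_fmt(scores.get(t)) for t in ALL_PREDICTORS]
        calls = splice.calls if splice else {}
        values += [
            c.value if (c := calls.get(t)) and c is not SpliceCall.MISSING else "."
            for t in SPLICE_PREDICTORS
        ]
        rows.append("\t".join(values))
    Path(path).write_text("\n".join(rows) + "\n")


def read_annotation_tsv(path: str | Path) -> dict:
    """Parse the annotation TSV into keyed bundles of domain records."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    out = {"variants": {}, "frequencies": {}, "assertions": {}, "profiles": {}, "splice": {}}
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        v = AnnotatedVariant(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            gene=row["gene"],
            transcript=row["transcript"],
            cdna_change=row["cdna"],
            protein_change=row["protein"],
            consequence=Consequence(row["consequence"]),
            intron_distance=int(row["intron_distance"]),
            depth=int(row["depth"]),
            vaf=float(row["vaf"]),
        )
        key = v.key
        out["variants"][key] = v

        def opt(col: str) -> Optional[float]:
            return None if row[col] == "." else float(row[col])

        out["frequencies"][key] = PopulationFrequencies(
            maf_1000g=opt("maf_1000g"),
            maf_evs=opt("maf_evs"),
            maf_exac=opt("maf_exac"),
            maf_exac_nfe=opt("maf_exac_nfe"),
            inhouse_fraction=opt("inhouse_fraction"),
        )
        out["assertions"][key] = ClinicalAssertions(
            clinvar=ClinicalCall(row["clinvar"]),
            bic_class=ClinicalCall(row["bic"]),
            lovd_class=ClinicalCall(row["lovd"]),
        )
        score_cells = {t: row[f"rs_{t}"] for t in ALL_PREDICTORS}
        if all(cell != "." for cell in score_cells.values()):
            out["profiles"][key] = profile_from_rankscores(
                {t: float(cell) for t, cell in score_cells.items()}
            )
        else:
            out["profiles"][key] = None
        splice_cells = {t: row[f"sp_{t}"] for t in SPLICE_PREDICTORS}
        if any(cell != "." for cell in splice_cells.values()):
            out["splice"][key] = SplicePredictions(
                calls={
                    t: SpliceCall(cell) if cell != "." else SpliceCall.MISSING
                    for t, cell in splice_cells.items()
                }
            )
        else:
            out["splice"][key] = None
    return out


# ---------------------------------------------------------------------------
# patient metadata TSV
# ---------------------------------------------------------------------------

def write_patient_tsv(path: str | Path, patients: Iterable[PatientRecord]) -> None:
    rows = ["patient_id\tage_at_dx\trelatives\tsecond_primaries\tihc"]
    for p in patients:
        rels = "|".join(
            f"{r.degree.value}:{r.cancer_type}:{_fmt(r.age_at_dx)}" for r in p.relatives
        )
        second = ",".join(p.second_primaries)
        ihc = (
            "|".join(
                f"{g}:{'retained' if kept else 'lost'}"
                for g, kept in sorted(p.ihc_results.items())
            )
            if p.ihc_results
            else "."
        )
        rows.append(
            f"{p.patient_id}\t{_fmt(p.age_at_dx)}\t{rels or '.'}\t{second or '.'}\t{ihc}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def read_patient_tsv(path: str | Path) -> list[PatientRecord]:
    lines = Path(path).read_text().splitlines()
    patients = []
    for line in lines[1:]:
        if not line.strip():
            continue
        pid, age, rels, second, ihc = line.split("\t")
        relatives = []
        if rels != ".":
            for cell in rels.split("|"):
                degree, cancer, rel_age = cell.split(":")
                relatives.append(
                    Relative(
                        degree=Degree(degree),
                        cancer_type=cancer,
                        age_at_dx=None if rel_age == "." else float(rel_age),
                    )
                )
        ihc_map = None
        if ihc != ".":
            ihc_map = {
                cell.split(":")[0]: cell.split(":")[1] == "retained"
                for cell in ihc.split("|")
            }
        patients.append(
            PatientRecord(
                patient_id=pid,
                age_at_dx=float(age),
                relatives=tuple(relatives),
                second_primaries=tuple(second.split(",")) if second != "." else (),
                ihc_results=ihc_map,
            )
        )
    return patients


def read_control_counts(path: str | Path) -> dict[str, ControlCounts]:
    payload = json.loads(Path(path).read_text())
    return {
        p["label"]: ControlCounts(
            label=p["label"],
            n_individuals=int(p["n_individuals"]),
            carriers=dict(p.get("carriers", {})),
            allele_counts={k: tuple(v) for k, v in p.get("allele_counts", {}).items()},
        )
        for p in payload["panels"]
    }
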