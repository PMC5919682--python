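"""End-to-end orchestration: filter cascade → tiering → ACMG-AMP →
case-control tests → criteria classification → carrier accounting.

The stages run in the published order, but the result cannot depend on it:
the filter cascade is conjunctive and every later stage consumes keyed
tables.  A rerun with the same configuration and inputs produces identical
outputs; a manifest records the configuration hash and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

from . import acmg as acmg_mod
from . import case_control, cohort as cohort_mod, consensus, filter_cascade, vcf_io
from .config import PipelineConfig
from .models import CriteriaFlags
from .synthetic_data import FixtureCohort, load_paper_fixtures

logger = logging.getLogger(__name__)

STAGE_VERSION = "1"


@dataclasses.dataclass(frozen=True)
class RunManifest:
    config_hash: str
    input_checksums: dict[str, str]
    stage_version: str
    timestamp: float

    @property
    def hash(self) -> str:
        payload = json.dumps(
            {
                "config": self.config_hash,
                "inputs": self.input_checksums,
                "stage_version": self.stage_version,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_on_cohort(
    cohort: FixtureCohort, config: Optional[PipelineConfig] = None
) -> dict:
    """Run every stage on an in-memory cohort; return all stage outputs."""
    config = config or PipelineConfig()
    t = config.thresholds
    out: dict = {}

    # -- filter cascade ----------------------------------------------------
    try:
        kept, audit = filter_cascade.run_cascade(
            cohort.variants.values(), cohort.frequencies, cohort.assertions, t
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("filter_cascade", exc)
    out["kept"], out["audit"] = kept, audit
    logger.info("filter cascade: %d kept, %d removed", len(kept), len(audit))

    # -- consensus tiering -------------------------------------------------
    tiers = {}
    for v in kept:
        tiers[v.key] = consensus.assign_tier(
            v,
            cohort.profiles.get(v.key),
            cohort.splice.get(v.key),
            cohort.assertions.get(v.key),
            t,
            denominator_mode=config.consensus_denominator_mode,
        )
    out["tiers"] = tiers

    # -- ACMG-AMP ----------------------------------------------------------
    verdicts: dict[str, Optional[str]] = {}
    for v in kept:
        record = cohort.acmg.get(v.key)
        if record is None:
            verdicts[v.key] = None  # evidence not determined
            continue
        evidence = acmg_mod.ACMGEvidence.from_codes(record.automatic)
        evidence = acmg_mod.apply_manual_overlay(evidence, record.manual)
        verdicts[v.key] = acmg_mod.combine_criteria(evidence).verdict.value
    out["verdicts"] = verdicts

    # -- case-control ------------------------------------------------------
    carriers_by_key: dict[str, set[str]] = {}
    for pid, v in cohort.planted_variants:
        carriers_by_key.setdefault(v.key, set()).add(pid)
    n_cases = len(cohort.patients)
    association_rows = []
    gene_pvalues: dict[str, float] = {}
    for panel in cohort.control_panels.values():
        for v in kept:
            table = case_control.build_carrier_table(
                len(carriers_by_key.get(v.key, ())), n_cases, panel, v.key
            )
            p = case_control.fisher_exact(table)
            association_rows.append(
                {
                    "variant_key": v.key,
                    "gene": v.gene,
                    "group": panel.label,
                    "a": table.a,
                    "b": table.b,
                    "c": table.c,
                    "d": table.d,
                    "p": p,
                }
            )
            if panel.label == "healthy_controls":
                gene_pvalues[v.gene] = min(gene_pvalues.get(v.gene, 1.0), p)
    out["associations"] = association_rows

    # -- criteria classification -------------------------------------------
    flags: dict[str, CriteriaFlags] = {
        p.patient_id: cohort_mod.classify_criteria(
            p,
            rare_cancer_list=config.rare_cancers,
            clustering_list=config.clustering_cancers,
            relative_early_onset_age=config.relative_early_onset_age,
            a1_includes_index=config.a1_includes_index,
        )
        for p in cohort.patients
    }
    out["criteria"] = flags

    # -- carrier accounting ------------------------------------------------
    patient_variants: dict[str, list] = {}
    for pid, v in cohort.planted_variants:
        patient_variants.setdefault(pid, []).append(v)
    ihc = {
        p.patient_id: dict(p.ihc_results)
        for p in cohort.patients
        if p.ihc_results
    }
    carriers = cohort_mod.assemble_carriers(
        patient_variants,
        tiers,
        verdicts,
        ihc=ihc,
        incidental=cohort.incidental,
    )
    for c in carriers:
        if c.is_carrier:
            c.attributed_gene = cohort_mod.attribute_gene(c, gene_pvalues)
    out["carriers"] = carriers

    out["summary"] = cohort_mod.summarize(
        cohort.patients,
        flags,
        carriers,
        gene_pvalues,
        early_onset_age=t.early_onset_age,
    )
    return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """File-level entry point: read inputs (or the packaged fixture cohort
    when no paths are configured), run all stages, write stage TSVs and the
    summary JSON atomically, and return the run manifest."""
    out_path = Path(out_dir)
    out_path.mkdir(parents=True, exist_ok=True)

    checksums: dict[str, str] = {}
    if config.vcf and config.annotations and config.patients:
        try:
            annotations = vcf_io.read_annotation_tsv(config.annotations)
            variants, carriers_by_key, failures = vcf_io.read_vcf(config.vcf, annotations)
            patients = vcf_io.read_patient_tsv(config.patients)
        except Exception as exc:
            raise StageError("io", exc)
        if failures:
            logger.warning("%d VCF records failed annotation join", len(failures))
        panels = (
            vcf_io.read_control_counts(config.controls) if config.controls else {}
        )
        cohort = FixtureCohort(
            patients=patients,
            planted_variants=[
                (pid, v)
                for v in variants
                for pid in sorted(carriers_by_key.get(v.key, ()))
            ],
            variants={v.key: v for v in variants},
            frequencies=annotations["frequencies"],
            assertions=annotations["assertions"],
            profiles=annotations["profiles"],
            splice=annotations["splice"],
            acmg={v.key: None for v in variants},
            control_panels=panels,
        )
        for name in ("vcf", "annotations", "patients", "controls"):
            value = getattr(config, name)
            if value:
                checksums[name] = _checksum(Path(value))
    else:
        cohort = load_paper_fixtures()
        checksums["fixtures"] = "packaged"

    result = run_on_cohort(cohort, config)

    _write_tsv(
        out_path / "kept.tsv",
        ["variant_key", "gene", "consequence"],
        [[v.key, v.gene, v.consequence.value] for v in result["kept"]],
    )
    _write_tsv(
        out_path / "audit.tsv",
        ["variant_key", "gene", "first_failed_rule", "failed_rules"],
        [
            [r["variant_key"], r["gene"], r["first_failed_rule"], r["failed_rules"]]
            for r in result["audit"]
        ],
    )
    _write_tsv(
        out_path / "tiers.tsv",
        ["variant_key", "tier", "basis"],
        [[k, tr.tier.value, tr.basis or "."] for k, tr in result["tiers"].items()],
    )
    _write_tsv(
        out_path / "verdicts.tsv",
        ["variant_key", "verdict"],
        [[k, v or "not_determined"] for k, v in result["verdicts"].items()],
    )
    _write_tsv(
        out_path / "associations.tsv",
        ["variant_key", "gene", "group", "a", "b", "c", "d", "p"],
        [
            [r["variant_key"], r["gene"], r["group"], r["a"], r["b"], r["c"], r["d"],
             format(r["p"], ".6g")]
            for r in result["associations"]
        ],
    )
    _write_tsv(
        out_path / "carriers.tsv",
        ["patient_id", "attributed_gene", "n_variants", "excluded"],
        [
            [
                c.patient_id,
                c.attributed_gene or ".",
                len(c.variants),
                ";".join(f"{v.key}:{reason}" for v, reason in c.excluded_variants) or ".",
            ]
            for c in result["carriers"]
        ],
    )

    summary = result["summary"]
    summary_payload = dataclasses.asdict(summary)
    (out_path / "summary.json").write_text(json.dumps(summary_payload, indent=2, sort_keys=True))

    manifest = RunManifest(
        config_hash=config.config_hash(),
        input_checksums=checksums,
        stage_version=STAGE_VERSION,
        timestamp=time.time(),
    )
    (out_path / "manifest.json").write_text(
        json.dumps(
            {
                "hash": manifest.hash,
                "config_hash": manifest.config_hash,
                "inputs": manifest.input_checksums,
                "stage_version": manifest.stage_version,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return manifest


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    text = "\n".join(["\t".join(header)] + ["\t".join(str(c) for c in row) for row in rows])
    tmp.write_text(text + "\n")
    tmp.replace(path)
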