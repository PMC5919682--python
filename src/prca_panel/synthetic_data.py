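"""Fixture cohort and fully synthetic cohorts.

Two sources of test data, neither requiring any download:

* :func:`load_paper_fixtures` rebuilds the 121-patient study cohort from
  packaged data files: the 19 carrier index cases hold the published panel
  variants (with their annotation profiles and eligibility flags), and the
  102 remaining patients are generated deterministically from family-history
  templates so that the cohort marginals match the published composition
  (45 familial/hereditary "A" cases, 86 early-onset/other-cancer "B" cases,
  10 fulfilling both, 64 diagnosed at or before 55).

* :func:`simulate_cohort` draws cohorts with configurable per-gene carrier
  frequencies, eligibility-criteria prevalences, predictor noise and a
  control panel, for parameter-recovery and null-calibration tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np

from .models import (
    ALL_PREDICTORS,
    CONSERVATION_PREDICTORS,
    FUNCTIONAL_PREDICTORS,
    SPLICE_PREDICTORS,
    AnnotatedVariant,
    ClinicalAssertions,
    ClinicalCall,
    Consequence,
    ControlCounts,
    Degree,
    PatientRecord,
    PredictorCall,
    PredictorProfile,
    Relative,
    SpliceCall,
    SplicePredictions,
)

_CALLERS = frozenset({"isaac", "bwa_enrichment", "nextgene"})


class FixtureError(RuntimeError):
    """Raised when a packaged fixture file is missing or corrupt."""


@dataclass
class ACMGRecord:
    """Evidence codes printed for a variant: automatic plus manual overlay."""

    automatic: frozenset[str]
    manual: frozenset[str]


@dataclass
class FixtureCohort:
    """A cohort plus everything downstream stages need about its variants."""

    patients: list[PatientRecord]
    planted_variants: list[tuple[str, AnnotatedVariant]]  # (patient_id, variant)
    variants: dict[str, AnnotatedVariant] = field(default_factory=dict)  # key -> variant
    frequencies: dict[str, "object"] = field(default_factory=dict)
    assertions: dict[str, ClinicalAssertions] = field(default_factory=dict)
    profiles: dict[str, Optional[PredictorProfile]] = field(default_factory=dict)
    splice: dict[str, Optional[SplicePredictions]] = field(default_factory=dict)
    acmg: dict[str, Optional[ACMGRecord]] = field(default_factory=dict)
    incidental: set[tuple[str, str]] = field(default_factory=set)  # (patient_id, key)
    control_panels: dict[str, ControlCounts] = field(default_factory=dict)
    expected_criteria: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def control_panel(self) -> Optional[ControlCounts]:
        return self.control_panels.get("healthy_controls")

    def variants_of(self, patient_id: str) -> list[AnnotatedVariant]:
        return [v for pid, v in self.planted_variants if pid == patient_id]

    def carrier_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid, _ in self.planted_variants:
            seen.setdefault(pid)
        return list(seen)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the cohort simulator.

    Default criteria prevalences are chosen so that the expected group
    composition approximates the study cohort (about 37% of patients with
    familial/hereditary flags and 70% with early-onset/other-cancer flags).
    """

    n_patients: int = 121
    per_gene_carrier_freq: Mapping[str, float] = field(default_factory=dict)
    criteria_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "A1": 0.06,
            "A2": 0.25,
            "A3": 0.12,
            "B1": 0.40,
            "B2": 0.20,
            "B3": 0.35,
        }
    )
    predictor_noise: float = 0.0
    n_controls: int = 710
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_controls < 0:
            raise ValueError("n_controls must be >= 0")
        for gene, p in self.per_gene_carrier_freq.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"carrier frequency for {gene} must be in [0, 1]")
        for code, p in self.criteria_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {code} must be in [0, 1]")
        if not 0.0 <= self.predictor_noise <= 1.0:
            raise ValueError("predictor_noise must be in [0, 1]")


# ---------------------------------------------------------------------------
# fixture loading
# ---------------------------------------------------------------------------

def _missing(value: str) -> Optional[float]:
    return None if value in {".", ""} else float(value)


def _read_packaged(name: str) -> str:
    try:
        return (resources.files("prca_panel") / "data" / name).read_text()
    except (FileNotFoundError, OSError) as exc:  # pragma: no cover
        raise FixtureError(f"packaged fixture file {name!r} unreadable: {exc}") from exc


def _parse_variant_table(text: str):
    from .models import PopulationFrequencies

    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    required = {"gene", "chrom", "pos", "ref", "alt", "consequence", "carriers"}
    if not required <= set(header):
        raise FixtureError("fixture variant table missing required columns")
    rows = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise FixtureError("fixture variant table row width mismatch")
        rows.append(dict(zip(header, fields)))

    variants: dict[str, AnnotatedVariant] = {}
    frequencies: dict[str, PopulationFrequencies] = {}
    assertions: dict[str, ClinicalAssertions] = {}
    profiles: dict[str, Optional[PredictorProfile]] = {}
    splice: dict[str, Optional[SplicePredictions]] = {}
    acmg: dict[str, Optional[ACMGRecord]] = {}
    planted: list[tuple[str, AnnotatedVariant]] = []
    incidental: set[tuple[str, str]] = set()

    for row in rows:
        variant = AnnotatedVariant(
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
            caller_set=_CALLERS,
        )
        key = variant.key
        variants[key] = variant
        frequencies[key] = PopulationFrequencies(
            maf_1000g=_missing(row["maf_1000g"]),
            maf_evs=_missing(row["maf_evs"]),
            maf_exac=_missing(row["maf_exac"]),
            maf_exac_nfe=_missing(row["maf_exac_nfe"]),
            inhouse_fraction=_missing(row["inhouse_fraction"]),
        )
        assertions[key] = ClinicalAssertions(
            clinvar=ClinicalCall(row["clinvar"]) if row["clinvar"] != "." else ClinicalCall.ABSENT,
            bic_class=ClinicalCall(row["bic"]) if row["bic"] != "." else ClinicalCall.ABSENT,
            lovd_class=ClinicalCall(row["lovd"]) if row["lovd"] != "." else ClinicalCall.ABSENT,
        )

        if variant.consequence is Consequence.MISSENSE:
            scores = {tool: float(row[f"rs_{tool}"]) for tool in ALL_PREDICTORS}
            profiles[key] = profile_from_rankscores(scores)
        else:
            profiles[key] = None

        sp_calls = {tool: row[f"sp_{tool}"] for tool in SPLICE_PREDICTORS}
        if any(v != "." for v in sp_calls.values()):
            splice[key] = SplicePredictions(
                calls={
                    tool: SpliceCall(v) if v != "." else SpliceCall.MISSING
                    for tool, v in sp_calls.items()
                }
            )
        else:
            splice[key] = None

        if row["acmg"] != ".":
            auto = frozenset(row["acmg"].split(";"))
            manual = frozenset(row["acmg_manual"].split(";")) if row["acmg_manual"] != "." else frozenset()
            acmg[key] = ACMGRecord(automatic=auto, manual=manual)
        else:
            acmg[key] = None

        for pid in row["carriers"].split(","):
            planted.append((pid, variant))
            if row["incidental"] == "1":
                incidental.add((pid, key))

    return variants, frequencies, assertions, profiles, splice, acmg, planted, incidental


def profile_from_rankscores(
    scores: Mapping[str, float], cutoff: float = 0.5
) -> PredictorProfile:
    """Build a categorical predictor profile from rankscores (>= cutoff is
    a pathogenic call)."""
    func = {
        t: PredictorCall.PATHOGENIC if scores[t] >= cutoff else PredictorCall.BENIGN
        for t in FUNCTIONAL_PREDICTORS
    }
    cons = {
        t: PredictorCall.PATHOGENIC if scores[t] >= cutoff else PredictorCall.BENIGN
        for t in CONSERVATION_PREDICTORS
    }
    return PredictorProfile(functional_calls=func, conservation_calls=cons, rankscores=dict(scores))


def _filler_patients() -> list[PatientRecord]:
    """Deterministic non-carrier patients completing the cohort marginals.

    Template counts are fixed so that, together with the 19 variant-carrying
    index cases, the cohort holds exactly 45 A-group, 86 B-group, 10 dual and
    64 early-onset patients.  Individual ages cycle over small offsets that
    preserve every criteria inequality.
    """

    def rel(degree: str, cancer: str, age: float) -> Relative:
        return Relative(degree=Degree(degree), cancer_type=cancer, age_at_dx=age)

    patients: list[PatientRecord] = []
    idx = 0

    def add(age: float, relatives: tuple[Relative, ...], second: tuple[str, ...] = ()) -> None:
        nonlocal idx
        idx += 1
        patients.append(
            PatientRecord(
                patient_id=f"PT{idx:03d}",
                age_at_dx=age,
                relatives=relatives,
                second_primaries=second,
            )
        )

    # 29 familial-only patients (A2): two first-degree PrCa relatives, one
    # diagnosed before 61, family average at or below 65.
    for i in range(29):
        add(64 + i % 3, (rel("first", "prostate", 60), rel("first", "prostate", 67)))
    # 8 dual patients (A3 + B1): early-onset index with PrCa in first- and
    # second-degree relatives plus another early family cancer.
    for i in range(8):
        add(
            52 + i % 3,
            (
                rel("first", "prostate", 61),
                rel("second", "prostate", 58),
                rel("first", "pancreatic", 53),
            ),
        )
    # 49 early-onset patients (B1): three relatives with cancer, young diagnoses.
    for i in range(49):
        add(
            52 + i % 3,
            (
                rel("first", "lung", 55),
                rel("second", "ovarian", 54),
                rel("second", "pancreatic", 58),
            ),
        )
    # 8 second-primary patients (B2), diagnosed after 55.
    for i in range(8):
        add(63 + i % 3, (rel("first", "lung", 70),), ("kidney",))
    # 8 family-clustering patients (B3), diagnosed after 55.
    for i in range(8):
        add(62 + i % 3, (rel("first", "breast", 52), rel("second", "breast", 49)))
    return patients


def load_paper_fixtures() -> FixtureCohort:
    """Rebuild the 121-patient fixture cohort from packaged data files."""
    variant_text = _read_packaged("fixture_variants.tsv")
    try:
        (
            variants,
            frequencies,
            assertions,
            profiles,
            splice,
            acmg,
            planted,
            incidental,
        ) = _parse_variant_table(variant_text)
    except (KeyError, ValueError) as exc:
        raise FixtureError(f"corrupt fixture variant table: {exc}") from exc

    try:
        payload = json.loads(_read_packaged("carrier_patients.json"))
        carrier_rows = payload["patients"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise FixtureError(f"corrupt carrier patient file: {exc}") from exc

    patients: list[PatientRecord] = []
    expected: dict[str, frozenset[str]] = {}
    for row in carrier_rows:
        patients.append(
            PatientRecord(
                patient_id=row["patient_id"],
                age_at_dx=float(row["age_at_dx"]),
                relatives=tuple(
                    Relative(
                        degree=Degree(r["degree"]),
                        cancer_type=r["cancer_type"],
                        age_at_dx=r.get("age_at_dx"),
                    )
                    for r in row["relatives"]
                ),
                second_primaries=tuple(row.get("second_primaries", ())),
                ihc_results=row.get("ihc_results"),
            )
        )
        expected[row["patient_id"]] = frozenset(row["expected_criteria"])

    known_ids = {p.patient_id for p in patients}
    for pid, _ in planted:
        if pid not in known_ids:
            raise FixtureError(f"planted variant references unknown patient {pid}")

    patients.extend(_filler_patients())
    if len({p.patient_id for p in patients}) != len(patients):
        raise FixtureError("duplicate patient ids in fixture cohort")

    try:
        panels_payload = json.loads(_read_packaged("control_counts.json"))
        panels = {
            p["label"]: ControlCounts(
                label=p["label"],
                n_individuals=int(p["n_individuals"]),
                carriers=dict(p.get("carriers", {})),
                allele_counts={
                    k: tuple(v) for k, v in p.get("allele_counts", {}).items()
                },
            )
            for p in panels_payload["panels"]
        }
    except (json.JSONDecodeError, KeyError) as exc:
        raise FixtureError(f"corrupt control counts file: {exc}") from exc

    return FixtureCohort(
        patients=patients,
        planted_variants=planted,
        variants=variants,
        frequencies=frequencies,
        assertions=assertions,
        profiles=profiles,
        splice=splice,
        acmg=acmg,
        incidental=incidental,
        control_panels=panels,
        expected_criteria=expected,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

#: Per-criterion family-history motifs used by the simulator; each motif is
#: (max index age or None, relatives, second primaries).
_MOTIFS = {
    "A1": (None, (("first", "prostate", 62), ("first", "prostate", 66), ("first", "prostate", 69)), ()),
    "A2": (None, (("first", "prostate", 60), ("first", "prostate", 67)), ()),
    "A3": (60, (("second", "prostate", 63), ("second", "prostate", 68)), ()),
    "B1": (55, (("first", "lung", 55), ("second", "ovarian", 54), ("second", "pancreatic", 58)), ()),
    "B2": (None, (), ("urothelial",)),
    "B3": (None, (("first", "breast", 52), ("second", "breast", 44)), ()),
}


def _template_variant(gene: str, index: int) -> AnnotatedVariant:
    """A clean truncating variant for ``gene`` that survives every filter."""
    return AnnotatedVariant(
        chrom=str(1 + index % 22),
        pos=1_000_000 + 1000 * index,
        ref="C",
        alt="T",
        gene=gene,
        transcript=".",
        cdna_change=f"c.{100 + index}C>T",
        protein_change="p.(Gln34Ter)",
        consequence=Consequence.NONSENSE,
        depth=100,
        vaf=0.5,
        caller_set=_CALLERS,
    )


def simulate_cohort(params: SimulationParams) -> FixtureCohort:
    """Draw a cohort with carriers planted at the requested per-gene rates."""
    from .models import PopulationFrequencies

    rng = np.random.default_rng(params.seed)
    genes = sorted(params.per_gene_carrier_freq)
    templates = {g: _template_variant(g, i) for i, g in enumerate(genes)}

    patients: list[PatientRecord] = []
    planted: list[tuple[str, AnnotatedVariant]] = []
    variants: dict[str, AnnotatedVariant] = {}
    frequencies: dict[str, PopulationFrequencies] = {}
    assertions: dict[str, ClinicalAssertions] = {}
    profiles: dict[str, Optional[PredictorProfile]] = {}
    splice: dict[str, Optional[SplicePredictions]] = {}

    codes = ("A1", "A2", "A3", "B1", "B2", "B3")
    for i in range(params.n_patients):
        pid = f"SIM{i:05d}"
        drawn = [c for c in codes if rng.random() < params.criteria_prevalence.get(c, 0.0)]
        age = 64.0
        relatives: list[Relative] = []
        second: list[str] = []
        for code in drawn:
            age_cap, rels, sps = _MOTIFS[code]
            if age_cap is not None:
                age = min(age, float(age_cap - 1 + rng.integers(0, 2)))
            for degree, cancer, rel_age in rels:
                relatives.append(
                    Relative(degree=Degree(degree), cancer_type=cancer, age_at_dx=rel_age)
                )
            second.extend(sps)
        patients.append(
            PatientRecord(
                patient_id=pid,
                age_at_dx=age,
                relatives=tuple(relatives),
                second_primaries=tuple(second),
            )
        )
        for gene in genes:
            if rng.random() < params.per_gene_carrier_freq[gene]:
                v = templates[gene]
                planted.append((pid, v))
                if v.key not in variants:
                    variants[v.key] = v
                    frequencies[v.key] = PopulationFrequencies(inhouse_fraction=0.0)
                    assertions[v.key] = ClinicalAssertions()
                    profiles[v.key] = None
                    splice[v.key] = None

    panel = ControlCounts(label="simulated_controls", n_individuals=params.n_controls)
    return FixtureCohort(
        patients=patients,
        planted_variants=planted,
        variants=variants,
        frequencies=frequencies,
        assertions=assertions,
        profiles=profiles,
        splice=splice,
        acmg={k: None for k in variants},
        control_panels={"healthy_controls": panel} if params.n_controls else {},
    )


@dataclass
class PredictorMatrixResult:
    """Rankscore matrix with ground truth and the exact noise flips applied."""

    scores: np.ndarray  # (n_variants, 15) rankscores in [0, 1)
    labels: np.ndarray  # (n_variants,) bool: qualifying before noise
    flips: np.ndarray  # (n_variants, 15) bool: call flipped by noise
    columns: tuple[str, ...] = ALL_PREDICTORS


def simulate_predictor_matrix(
    n_variants: int,
    fraction_qualifying: float,
    noise: float = 0.0,
    seed: int = 0,
) -> PredictorMatrixResult:
    """Draw per-variant rankscores for the 15 missense predictors.

    Ground-truth qualifying variants satisfy the >=12-of-15 consensus with
    at least three supporting conservation tools *before* noise; ``noise``
    then flips each categorical call independently (a flipped score crosses
    the 0.5 boundary).  The flip log is returned so recovery accuracy can be
    recomputed independently of the consensus implementation.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not 0.0 <= fraction_qualifying <= 1.0:
        raise ValueError("fraction_qualifying must be in [0, 1]")
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n_cons = len(CONSERVATION_PREDICTORS)
    n_func = len(FUNCTIONAL_PREDICTORS)
    calls = np.zeros((n_variants, 15), dtype=bool)  # functional cols 0..10, conservation 11..14
    labels = rng.random(n_variants) < fraction_qualifying

    for i in range(n_variants):
        if labels[i]:
            total = int(rng.integers(12, 16))
            cons = int(rng.integers(max(3, total - n_func), min(n_cons, total) + 1))
        else:
            total = int(rng.integers(0, 12))
            cons = int(rng.integers(max(0, total - n_func), min(n_cons, total) + 1))
        func = total - cons
        func_idx = rng.choice(n_func, size=func, replace=False)
        cons_idx = n_func + rng.choice(n_cons, size=cons, replace=False)
        calls[i, func_idx] = True
        calls[i, cons_idx] = True

    scores = np.where(
        calls, 0.5 + 0.5 * rng.random(calls.shape), 0.5 * rng.random(calls.shape)
    )
    flips = rng.random(calls.shape) < noise
    scores = np.where(flips, np.where(scores >= 0.5, scores - 0.5, scores + 0.5), scores)
    return PredictorMatrixResult(scores=scores, labels=labels, flips=flips)
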