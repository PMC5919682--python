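"""Domain records shared across the prioritization pipeline.

The pipeline consumes germline panel calls (VCF + a tab-separated annotation
table) for a cohort of prostate-cancer index cases, together with per-patient
family-history metadata and control genotype counts.  These dataclasses are
the in-memory currency every stage exchanges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence


class Consequence(str, Enum):
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    SPLICE_SITE = "splice_site"
    INTRONIC = "intronic"
    INFRAME_INDEL = "inframe_indel"


class ClinicalCall(str, Enum):
    """Assertion recorded in a clinical database snapshot (ClinVar/BIC/LOVD)."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    CONFLICTING = "conflicting"
    ABSENT = "absent"


#: Missense pathogenicity predictors whose calls feed the consensus rule.
FUNCTIONAL_PREDICTORS: tuple[str, ...] = (
    "SIFT",
    "PolyPhen2",
    "LRT",
    "MutationTaster",
    "PROVEAN",
    "FATHMM",
    "CADD",
    "MutationAssessor",
    "MetaLR",
    "MetaSVM",
    "VEST3",
)

#: Conservation tools counted separately by the consensus rule.
CONSERVATION_PREDICTORS: tuple[str, ...] = ("PhyloP", "GERP++", "PhastCons", "SiPhy")

ALL_PREDICTORS: tuple[str, ...] = FUNCTIONAL_PREDICTORS + CONSERVATION_PREDICTORS

#: Splice-impact predictors; a variant qualifies at >=3/4 "affected" calls.
SPLICE_PREDICTORS: tuple[str, ...] = (
    "HumanSplicingFinder3",
    "MaxEntScan",
    "NNSPLICE",
    "NetGene2",
)


@dataclass(frozen=True)
class AnnotatedVariant:
    """One called variant with quality and annotation context.

    Coordinates are 1-based GRCh37, matching VCF convention.
    ``intron_distance`` is the distance in bases from the nearest
    exon-intron boundary (0 for exonic positions, 1 = first intronic base).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str = "."
    cdna_change: str = "."
    protein_change: str = "."
    consequence: Consequence = Consequence.MISSENSE
    intron_distance: int = 0
    depth: int = 0
    vaf: float = 0.0
    caller_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.consequence is Consequence.INTRONIC and self.intron_distance < 1:
            raise ValueError("intronic variant requires intron_distance >= 1")

    @property
    def key(self) -> str:
        """Stable variant key used to join tables across stages."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def _check_frequency(name: str, value: Optional[float]) -> None:
    if value is not None and not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class PopulationFrequencies:
    """Reference-population MAFs plus the in-house cohort fraction.

    Any reference MAF may be missing (variant absent from that database);
    missing values never count against a variant.
    """

    maf_1000g: Optional[float] = None
    maf_evs: Optional[float] = None
    maf_exac: Optional[float] = None
    maf_exac_nfe: Optional[float] = None
    inhouse_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("maf_1000g", "maf_evs", "maf_exac", "maf_exac_nfe", "inhouse_fraction"):
            _check_frequency(name, getattr(self, name))

    def available_mafs(self) -> list[float]:
        return [
            m
            for m in (self.maf_1000g, self.maf_evs, self.maf_exac)
            if m is not None
        ]


@dataclass(frozen=True)
class ClinicalAssertions:
    clinvar: ClinicalCall = ClinicalCall.ABSENT
    bic_class: ClinicalCall = ClinicalCall.ABSENT
    lovd_class: ClinicalCall = ClinicalCall.ABSENT

    def calls(self) -> tuple[ClinicalCall, ClinicalCall, ClinicalCall]:
        return (self.clinvar, self.bic_class, self.lovd_class)


class PredictorCall(str, Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    MISSING = "missing"


class SpliceCall(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    MISSING = "missing"


@dataclass(frozen=True)
class PredictorProfile:
    """Calls of the 11 functional + 4 conservation missense predictors."""

    functional_calls: Mapping[str, PredictorCall]
    conservation_calls: Mapping[str, PredictorCall]
    rankscores: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if set(self.functional_calls) != set(FUNCTIONAL_PREDICTORS):
            raise ValueError("functional_calls must cover exactly the 11 functional tools")
        if set(self.conservation_calls) != set(CONSERVATION_PREDICTORS):
            raise ValueError("conservation_calls must cover exactly the 4 conservation tools")
        if self.rankscores is not None:
            for tool, score in self.rankscores.items():
                if not 0.0 <= score <= 1.0:
                    raise ValueError(f"rankscore for {tool} out of [0, 1]: {score}")


@dataclass(frozen=True)
class SplicePredictions:
    calls: Mapping[str, SpliceCall]

    def __post_init__(self) -> None:
        if set(self.calls) != set(SPLICE_PREDICTORS):
            raise ValueError("calls must cover exactly the 4 splice predictors")


class Tier(str, Enum):
    TRUNCATING_DELETERIOUS = "truncating_deleterious"
    POTENTIALLY_PATHOGENIC_MISSENSE = "potentially_pathogenic_missense"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class VariantTier:
    tier: Tier
    basis: str = ""

    def __post_init__(self) -> None:
        if self.tier is not Tier.UNCLASSIFIED and not self.basis:
            raise ValueError("classified tier requires a non-empty basis")


class Degree(str, Enum):
    FIRST = "first"
    SECOND = "second"


@dataclass(frozen=True)
class Relative:
    degree: Degree
    cancer_type: str
    age_at_dx: Optional[float] = None


@dataclass(frozen=True)
class PatientRecord:
    """Index case with family history, second primaries and optional IHC."""

    patient_id: str
    age_at_dx: float
    relatives: tuple[Relative, ...] = ()
    second_primaries: tuple[str, ...] = ()
    ihc_results: Optional[Mapping[str, bool]] = None  # gene -> expression retained

    def __post_init__(self) -> None:
        if self.age_at_dx < 0:
            raise ValueError("age_at_dx must be >= 0")


@dataclass(frozen=True)
class CriteriaFlags:
    """Study eligibility flags: A = familial/hereditary PrCa, B = early-onset
    and/or aggregation of other cancers."""

    A1: bool = False
    A2: bool = False
    A3: bool = False
    B1: bool = False
    B2: bool = False
    B3: bool = False

    @property
    def group_a(self) -> bool:
        return self.A1 or self.A2 or self.A3

    @property
    def group_b(self) -> bool:
        return self.B1 or self.B2 or self.B3

    def as_set(self) -> frozenset[str]:
        return frozenset(
            code for code in ("A1", "A2", "A3", "B1", "B2", "B3") if getattr(self, code)
        )

    @classmethod
    def from_codes(cls, codes: Sequence[str]) -> "CriteriaFlags":
        known = {"A1", "A2", "A3", "B1", "B2", "B3"}
        bad = set(codes) - known
        if bad:
            raise ValueError(f"unknown criteria codes: {sorted(bad)}")
        return cls(**{code: code in set(codes) for code in known})


@dataclass(frozen=True)
class FilterDecision:
    kept: bool
    failed_rules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kept != (len(self.failed_rules) == 0):
            raise ValueError("kept must hold exactly when no rule failed")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows = cases/controls, columns = carrier/non-carrier."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be >= 0")

    def as_array(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class ControlCounts:
    """Carrier counts observed in one control panel.

    ``allele_counts`` holds (alt alleles, total alleles) pairs for
    reference-population comparisons where individual genotypes are
    unavailable (e.g. ExAC NFE).
    """

    label: str
    n_individuals: int
    carriers: Mapping[str, int] = field(default_factory=dict)
    allele_counts: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        for key, n in self.carriers.items():
            if not 0 <= n <= self.n_individuals:
                raise ValueError(f"carrier count for {key} exceeds panel size")

    def carriers_of(self, variant_key: str) -> int:
        return int(self.carriers.get(variant_key, 0))


@dataclass
class CarrierAssignment:
    """One patient after exclusion and gene-attribution rules."""

    patient_id: str
    variants: list[tuple[AnnotatedVariant, Tier, Optional[str]]] = field(default_factory=list)
    attributed_gene: Optional[str] = None
    excluded_variants: list[tuple[AnnotatedVariant, str]] = field(default_factory=list)

    @property
    def is_carrier(self) -> bool:
        return len(self.variants) > 0


@dataclass
class CohortSummary:
    n_patients: int
    n_carriers: int
    pct_carriers: float
    per_gene_attributed: dict[str, tuple[int, float]]
    per_gene_raw: dict[str, tuple[int, float]]
    n_group_a: int
    n_group_b: int
    n_carriers_group_a: int
    n_carriers_group_b: int
    pct_carriers_in_group_a: float  # carriers with A flags / carriers
    pct_carriers_in_group_b: float
    pct_group_a_carrying: float  # carriers with A flags / group-A size
    pct_group_b_carrying: float
    n_early_onset: int
    n_early_onset_carriers: int
    pct_early_onset_carriers: float  # early-onset carriers / carriers
    pct_early_onset_group_carrying: float  # early-onset carriers / early-onset set
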