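"""Pipeline configuration.

All study thresholds live here as validated defaults so no stage hard-codes
them: read-depth and allele-fraction bounds for the quality filter, the rare
minor-allele-frequency cutoff, the in-house recurrence cutoff, the
synonymous/deep-intronic exclusion distance, and the predictor-consensus
quorums.  A YAML file with the same field names can override any of them;
unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class Thresholds(BaseModel):
    """Filtering and consensus constants.

    Boundary semantics follow the study text literally: depth strictly
    greater than ``min_depth`` ("coverage >20x"), in-house recurrence
    strictly greater than ``max_inhouse`` removed ("more than 10% of the
    cases"), MAF inclusive ("MAF <=0.1%"), allele fraction inclusive
    between ``vaf_low`` and ``vaf_high``, intron distance inclusive up to
    ``max_intron_distance``.
    """

    model_config = ConfigDict(extra="forbid")

    min_depth: int = Field(default=20, ge=0)
    vaf_low: float = Field(default=0.30, ge=0.0, le=1.0)
    vaf_high: float = Field(default=0.70, ge=0.0, le=1.0)
    max_maf: float = Field(default=0.001, ge=0.0, le=1.0)
    max_inhouse: float = Field(default=0.10, ge=0.0, le=1.0)
    max_intron_distance: int = Field(default=12, ge=0)
    consensus_min_calls: int = Field(default=12, ge=0)
    consensus_total: int = Field(default=15, ge=1)
    consensus_min_conservation: int = Field(default=3, ge=0)
    splice_min_calls: int = Field(default=3, ge=0)
    splice_total: int = Field(default=4, ge=1)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    rankscore_cutoff: float = Field(default=0.5, ge=0.0, le=1.0)
    early_onset_age: float = Field(default=55.0, gt=0.0)

    @model_validator(mode="after")
    def _check_bounds(self) -> "Thresholds":
        if self.vaf_low >= self.vaf_high:
            raise ValueError("vaf_low must be < vaf_high")
        if self.consensus_min_calls > self.consensus_total:
            raise ValueError("consensus_min_calls must be <= consensus_total")
        if self.splice_min_calls > self.splice_total:
            raise ValueError("splice_min_calls must be <= splice_total")
        return self


#: Relative cancer types the study treats as rare for the B3 criterion.
DEFAULT_RARE_CANCERS = ("bilateral breast", "male breast", "brain")

#: Cancer types whose familial clustering (>=2 relatives) triggers B3.
DEFAULT_CLUSTERING_CANCERS = ("breast", "colon", "gastric")


class PipelineConfig(BaseModel):
    """Whole-run configuration: thresholds, file paths and mode flags."""

    model_config = ConfigDict(extra="forbid")

    thresholds: Thresholds = Field(default_factory=Thresholds)
    per_tool_rankscore_cutoffs: dict[str, float] = Field(default_factory=dict)
    rare_cancers: tuple[str, ...] = DEFAULT_RARE_CANCERS
    clustering_cancers: tuple[str, ...] = DEFAULT_CLUSTERING_CANCERS
    #: age at/below which a relative's non-prostate cancer counts as early onset (B3)
    relative_early_onset_age: float = Field(default=50.0, gt=0.0)
    seed: int = 0
    #: 'union' keeps variants called by any caller; 'majority' needs >=2 of 3
    caller_merge_mode: str = "union"
    #: 'fixed' keeps the consensus denominator at 15; 'available' uses non-missing tools
    consensus_denominator_mode: str = "fixed"
    #: whether the A1 count of affected first-degree relatives includes the index
    a1_includes_index: bool = False

    # optional file paths for the end-to-end command
    vcf: Optional[str] = None
    annotations: Optional[str] = None
    patients: Optional[str] = None
    controls: Optional[str] = None

    @model_validator(mode="after")
    def _check_modes(self) -> "PipelineConfig":
        if self.caller_merge_mode not in {"union", "majority"}:
            raise ValueError("caller_merge_mode must be 'union' or 'majority'")
        if self.consensus_denominator_mode not in {"fixed", "available"}:
            raise ValueError("consensus_denominator_mode must be 'fixed' or 'available'")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def config_hash(self) -> str:
        """Stable hash of the fully-resolved configuration."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
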