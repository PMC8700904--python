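"""Run configuration: thresholds, allowlists, per-gene overrides.

The defaults encode the laboratory policy: a 3% MAF prefilter, the 5%
BA1 stand-alone frequency ceiling, strict predictor concordance, a
500-aa "very large domain" ceiling for the PM1 downgrade suggestion,
and the two known hypomorphic variants (ABCA4 c.5603A>T, TYR
c.1205G>A) exempted from BA1 and reported as phenotype modifiers.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator


HYPOMORPHIC_DEFAULTS = (
    "NM_000350(ABCA4):c.5603A>T",
    "NM_000372(TYR):c.1205G>A",
)


class GeneOverride(BaseModel):
    """Per-gene corrections layered over the evidence's GeneContext."""

    inheritance: Optional[set[Literal["AD", "AR", "XL"]]] = None
    late_onset: Optional[bool] = None
    bs1_frequency_ceiling: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    high_penetrance: Optional[bool] = None


class RunConfig(BaseModel):
    maf_threshold: float = Field(default=0.03, gt=0.0, le=1.0)
    ba1_threshold: float = Field(default=0.05, gt=0.0, le=1.0)
    hypomorphic_allowlist: set[str] = Field(
        default_factory=lambda: set(HYPOMORPHIC_DEFAULTS)
    )
    benign_filter_exceptions: set[str] = Field(default_factory=set)
    gene_overrides: dict[str, GeneOverride] = Field(default_factory=dict)
    concordance_mode: Literal["strict", "majority"] = "strict"
    pm1_domain_size_ceiling: int = Field(default=500, ge=1)
    seed: int = 0

    @field_validator("hypomorphic_allowlist", "benign_filter_exceptions", mode="before")
    @classmethod
    def _coerce_list(cls, v):
        if isinstance(v, (list, tuple)):
            return set(v)
        return v

    @property
    def ba1_exempt(self) -> set[str]:
        """Variants never assigned BA1 and kept through the benign filter."""
        return self.hypomorphic_allowlist | self.benign_filter_exceptions

    def to_yaml(self) -> str:
        data = self.model_dump(mode="json")
        # sets serialize as sorted lists for determinism
        data["hypomorphic_allowlist"] = sorted(data["hypomorphic_allowlist"])
        data["benign_filter_exceptions"] = sorted(data["benign_filter_exceptions"])
        for ov in data["gene_overrides"].values():
            if ov.get("inheritance"):
                ov["inheritance"] = sorted(ov["inheritance"])
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)


def load_config(path: Optional[str]) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        return RunConfig.from_yaml(fh.read())
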