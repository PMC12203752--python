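"""Pipeline-wide configuration: significance thresholds, window geometry, seeds."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .types import ValidationError


@dataclass
class PipelineConfig:
    """Thresholds and geometry for the full discovery → enrichment → survival run.

    Defaults follow the study design this pipeline emulates: a permissive
    DE call (adj-p <= 0.1) feeding stricter control filters (adj-p < 0.01),
    TF-window enrichment at adj-p < 0.15 over a -15 kb/+2 kb TSS window,
    and survival screening at p < 0.05.
    """

    alpha_de: float = 0.1          # discovery DE call, inclusive (<=)
    alpha_filter: float = 0.01     # tissue-control filters, strict (<)
    alpha_enrich: float = 0.15     # TF enrichment, strict (<)
    alpha_surv: float = 0.05       # log-rank screen / Cox independence, strict (<)
    upstream: int = 15000          # bp upstream of TSS in the regulatory window
    downstream: int = 2000         # bp downstream of TSS
    max_divergent_patients: int = 2
    background_includes_degs: bool = False
    two_primary_rule: str = "any"  # 'any' (divergent if any comparison is) or 'mean'
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_filter", "alpha_enrich", "alpha_surv"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {a}")
        if self.upstream < 0 or self.downstream < 0:
            raise ValidationError("window offsets must be >= 0")
        if self.max_divergent_patients < 0:
            raise ValidationError("max_divergent_patients must be >= 0")
        if self.two_primary_rule not in ("any", "mean"):
            raise ValidationError("two_primary_rule must be 'any' or 'mean'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
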