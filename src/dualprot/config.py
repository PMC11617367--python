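"""Pipeline configuration.

Concentrations are stored in SI (g/L) internally; the conventional
plasma-proteomics display units are μg/mL (= mg/L) for the high tier
boundary and ng/mL (= μg/L) for the mid/low boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

from .errors import ConfigError

#: 1 μg/mL expressed in g/L — proteins above this are "high-abundance".
UG_PER_ML_IN_G_PER_L = 1e-3
#: 10 ng/mL expressed in g/L — proteins below this are "low-abundance".
TEN_NG_PER_ML_IN_G_PER_L = 1e-5


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the dual-strategy pipeline.

    Defaults follow the published analysis settings: de Bruijn k-mer
    size 8, a 75% identity gate for mapping contigs to the reference,
    95% identity for greedy clustering, abundance-tier bounds at
    1 μg/mL and 10 ng/mL, and a ≥10-sample detection filter.
    """

    kmer_size: int = 8
    map_identity_min: float = 75.0
    cluster_identity_min: float = 95.0
    tier_high_min: float = UG_PER_ML_IN_G_PER_L   # g/L
    tier_mid_min: float = TEN_NG_PER_ML_IN_G_PER_L  # g/L
    min_samples_detected: int = 10
    group_specific_min_case: int = 9
    group_specific_max_control: int = 5
    missed_cleavages_max: int = 2
    min_peptide_len: int = 6
    min_contig_len: int = 10
    sasa_probe_radius: float = 1.4  # Å
    sasa_n_points: int = 960
    ai_round: str = "half_up"
    il_equivalent: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.tier_mid_min < self.tier_high_min):
            raise ConfigError(
                "tier bounds must satisfy 0 < tier_mid_min < tier_high_min"
            )
        if not (0 < self.map_identity_min <= self.cluster_identity_min <= 100):
            raise ConfigError(
                "identity gates must satisfy "
                "0 < map_identity_min <= cluster_identity_min <= 100"
            )
        if self.kmer_size < 2:
            raise ConfigError("kmer_size must be >= 2")
        if self.ai_round != "half_up":
            raise ConfigError("ai_round: only 'half_up' is supported")
        for name in ("min_samples_detected", "group_specific_min_case",
                     "missed_cleavages_max"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
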