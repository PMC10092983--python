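"""Run configuration: one validated object drives the whole pipeline."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from . import constants as _const


class ConstantsConfig(BaseModel):
    droplet_volume_nl: float = _const.DROPLET_VOLUME_NL
    pg_per_hge: float = _const.PG_PER_HGE
    reaction_volume_ul: float = _const.REACTION_VOLUME_UL
    input_fraction: float = _const.INPUT_FRACTION
    min_positive_droplets: int = _const.MIN_POSITIVE_DROPLETS

    @field_validator(
        "droplet_volume_nl", "pg_per_hge", "reaction_volume_ul", "input_fraction"
    )
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("constants must be positive")
        return v


class SampleConfig(BaseModel):
    """One simulated patient sample run in replicate wells."""

    sample_id: str
    biofluid_volume_ml: float | None = None
    target_concentrations: dict[str, float] = Field(default_factory=dict)
    reference_concentration: float = 50.0
    n_replicates: int = 3


class RunConfig(BaseModel):
    """Panel, constants, controls and seeds for one pipeline run."""

    targets: list[str]
    reference_assay: str = "ABCC9"
    constants: ConstantsConfig = Field(default_factory=ConstantsConfig)
    samples: list[SampleConfig] = Field(default_factory=list)
    nc_wells: int = _const.NC_WELLS_DEFAULT
    nc_reference_concentration: float = 50.0
    fp_rate: float = 0.0
    n_droplets: int = _const.N_DROPLETS_DEFAULT
    seed: int = 0
    output_dir: str = "ddmrd_out"

    @field_validator("targets")
    @classmethod
    def _nonempty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("panel needs at least one target")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
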