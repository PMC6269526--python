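"""Run configuration with schema validation and provenance hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field


class StudyLayout(BaseModel):
    """Demo study design: groups, sampling days and replicates per group."""

    model_config = ConfigDict(extra="forbid")

    groups: list[str] = Field(default=["treated", "vehicle"])
    days: list[int] = Field(default=[0, 3, 6, 10])
    n_per_group: int = 4


class RunConfig(BaseModel):
    """All tunable stage parameters; unknown keys are rejected.

    Every field is echoed verbatim into the JSON sidecar written next to each
    output, together with the config hash and seed, so any artifact can be
    traced back to the exact run settings.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    # PAM simulation / processing
    pixel_size_um: float = 2.0
    fluence_ratio: float = 1.0
    noise_sd: float = 0.02
    noise_floor: float = 0.05
    prf_hz: float = 2000.0
    beam_waist_um: float = 3.0
    so2_threshold: float = 0.75
    # ratiometric oxygen mapping
    ksv: float = 1.0
    gray_bounds: tuple[float, float] | None = None
    red_floor: float | None = None
    # wound / PK
    wound_r0_mm: float = 3.0
    wound_pixel_mm: float = 0.02
    shrink_treated: float = 0.05
    shrink_vehicle: float = 0.0215
    pk_ka: float = 0.43
    pk_ke: float = 0.0435
    pk_scale: float = 51.83
    study: StudyLayout = Field(default_factory=StudyLayout)

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    """Load a JSON config file, applying CLI overrides on top.

    Unknown keys raise a schema error naming the offending key.
    """
    data = {}
    if path is not None:
        data = json.loads(Path(path).read_text())
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
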