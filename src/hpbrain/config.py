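"""Pipeline configuration: a validated, human-readable single config file.

The config is YAML (or an equivalent dict) validated by pydantic before any
stage runs; unknown keys are rejected so typos fail loudly.  All randomness
flows from the single ``seed``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

MAX_SEED = 2**31 - 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    repetition_time: float = 0.5
    frame_interval: float = 4.0
    flip_angle: float = 15.0
    n_frames: int = 15
    n_echoes: int = 7
    echo_spacing: float = 1.1e-3
    field_strength: float = 3.0
    slice_thickness: float = 0.03
    slice_select_gradient: float = 3.6e-3


class BasisConfig(_Strict):
    include_hydrate: bool = False


class PhantomConfig(_Strict):
    enabled: bool = True
    grid: Tuple[int, int, int] = (30, 24, 24)
    thin_slice_thickness: float = 0.005
    noise_sigma: float = 0.0
    b0_amplitude_hz: float = 20.0
    input_dir: Optional[str] = None  # echo stacks to use when disabled

    @model_validator(mode="after")
    def _need_inputs_when_disabled(self):
        if not self.enabled and self.input_dir is None:
            raise ValueError(
                "phantom.input_dir is required when phantom.enabled is false"
            )
        return self

    @field_validator("noise_sigma")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("noise_sigma must be >= 0")
        return v


class ReconstructConfig(_Strict):
    use_b0: bool = True
    field_map: Optional[str] = None  # NIfTI path; phantom supplies one itself


class FitConfig(_Strict):
    method: str = "freq"  # "freq" (primary) or "oracle" (time-domain check)

    @field_validator("method")
    @classmethod
    def _known_method(cls, v):
        if v not in ("freq", "oracle"):
            raise ValueError("fit.method must be 'freq' or 'oracle'")
        return v


class SegmentationConfig(_Strict):
    threshold: float = 0.60
    displacements: str = "auto"  # "auto" (chemical shift) or "none"

    @field_validator("threshold")
    @classmethod
    def _in_unit(cls, v):
        if not 0 <= v < 1:
            raise ValueError("segmentation.threshold must be in [0, 1)")
        return v

    @field_validator("displacements")
    @classmethod
    def _known_mode(cls, v):
        if v not in ("auto", "none"):
            raise ValueError("segmentation.displacements must be 'auto' or 'none'")
        return v


class B1Config(_Strict):
    # floats, not ints: defaults skip validation and must hash identically
    # to the same config loaded back from YAML
    angles_deg: List[float] = [70.0, 80.0, 90.0, 100.0, 110.0, 120.0, 130.0,
                               140.0, 150.0, 160.0, 170.0, 180.0]
    input_image: Optional[str] = None  # 4D NIfTI, angle as 4th axis


class PipelineConfig(_Strict):
    """Top-level validated configuration for :func:`hpbrain.pipeline.run_pipeline`."""

    seed: int = 0
    output_dir: str = "run"
    protocol: ProtocolConfig = ProtocolConfig()
    basis: BasisConfig = BasisConfig()
    phantom: PhantomConfig = PhantomConfig()
    reconstruct: ReconstructConfig = ReconstructConfig()
    fit: FitConfig = FitConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    b1: B1Config = B1Config()

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v):
        if not 0 <= v <= MAX_SEED:
            raise ValueError(f"seed must be in [0, {MAX_SEED}]")
        return v

    @model_validator(mode="after")
    def _b0_needs_field_map(self):
        # The phantom stage carries its own field map; without it an external
        # one must be supplied for B0-corrected reconstruction.
        if self.reconstruct.use_b0 and not self.phantom.enabled \
                and self.reconstruct.field_map is None:
            raise ValueError(
                "reconstruct.field_map is required when reconstruct.use_b0 is "
                "true and no phantom stage supplies one"
            )
        return self

    def config_hash(self) -> str:
        """Stable hash of the full validated configuration."""
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)


def save_config(path, config: PipelineConfig) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=True))
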