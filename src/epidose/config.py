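"""Schema-validated run configuration for the end-to-end pipeline.

The YAML config mirrors :class:`epidose.analysis.MotionStudyConfig` but is
organised in sections (phantom, beam, acquisition, motion_set, analysis)
with a global seed and output directory.  Unknown keys are rejected before
any stage runs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .analysis import MotionStudyConfig

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Strict):
    separation_max: float = Field(16.0, gt=0, le=21.0)


class BeamSection(_Strict):
    field_size_x: float = Field(14.0, gt=0)
    field_size_y: float = Field(8.0, gt=0)
    wedge_min: float = Field(0.5, gt=0, le=1.0)
    calib_field_size: float = Field(26.0, gt=0)


class AcquisitionSection(_Strict):
    n_frames: int = Field(60, ge=1)
    frame_time: float = Field(0.43, gt=0)
    pixels: int = Field(256, ge=16)
    pixel_pitch: float = Field(0.1, gt=0)
    noise_scale: float = Field(0.005, ge=0)


class MotionSection(_Strict):
    amplitudes: list[float] = [0.5, 1.0, 1.5]
    frequencies: list[float] = [12.0, 15.0, 20.0]
    n_patient_traces: int = Field(2, ge=0)
    trace_duration: float = Field(60.0, gt=0)


class AnalysisSection(_Strict):
    gamma_criteria: list[list[float]] = [[5, 5], [3, 3], [2, 2], [1, 1]]
    diff_thresholds: list[float] = [5.0, 3.0, 2.0, 1.0]
    gamma_interp_factor: int = Field(10, ge=1)


class RunConfig(_Strict):
    """Validated top-level pipeline configuration."""

    phantom: PhantomSection = PhantomSection()
    beam: BeamSection = BeamSection()
    acquisition: AcquisitionSection = AcquisitionSection()
    motion_set: MotionSection = MotionSection()
    analysis: AnalysisSection = AnalysisSection()
    seed: int = 0
    out: str = "epidose_run"

    def to_study_config(self) -> MotionStudyConfig:
        return MotionStudyConfig(
            separation_max=self.phantom.separation_max,
            field_size_x=self.beam.field_size_x,
            field_size_y=self.beam.field_size_y,
            wedge_min=self.beam.wedge_min,
            calib_field_size=self.beam.calib_field_size,
            amplitudes=tuple(self.motion_set.amplitudes),
            frequencies=tuple(self.motion_set.frequencies),
            n_patient_traces=self.motion_set.n_patient_traces,
            trace_duration=self.motion_set.trace_duration,
            gamma_criteria=tuple((c[0], c[1]) for c in self.analysis.gamma_criteria),
            diff_thresholds=tuple(self.analysis.diff_thresholds),
            gamma_interp_factor=self.analysis.gamma_interp_factor,
            noise_scale=self.acquisition.noise_scale,
            n_frames=self.acquisition.n_frames,
            frame_time=self.acquisition.frame_time,
            pixels=self.acquisition.pixels,
            pixel_pitch=self.acquisition.pixel_pitch,
            seed=self.seed,
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)
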