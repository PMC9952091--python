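"""Validated run configuration for the pipeline stages.

Unknown keys are rejected so a typo in a YAML file fails loudly instead of
silently falling back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict

from . import synthetic


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RenderConfig(_Strict):
    pixel_size: float = 1.0       # µm/px
    background: float = 100.0
    nuclear_marker: float = 1000.0
    ktr_nucleus: float = 300.0
    noise_sd: float = 5.0
    poisson: bool = False


class SegmentationConfig(_Strict):
    nucleus_diameter: float = 12.0
    window_factor: float = 3.0
    offset_fraction: float = 0.25
    min_nucleus_area: float = 30.0
    min_cell_area: float = 100.0


class TrackingConfig(_Strict):
    d_gate: float = 30.0
    w_area: float = 1.0
    max_gap: int = 2
    mitosis_gate: float = 25.0
    area_tol: float = 0.35
    trim_k: int = 3


class OscillationConfig(_Strict):
    short_band: tuple[float, float] = (28.0, 60.0)
    long_band: tuple[float, float] = (92.0, 124.0)
    min_frames: int = 60
    max_gap: int = 2
    sweep_centers: Optional[list[float]] = None
    sweep_half_width: float = 16.0


class StatsConfig(_Strict):
    taus: tuple[float, ...] = (0.2, 0.5, 0.8)
    n_boot: int = 1000
    polar_bins: int = 16


class EventsConfig(_Strict):
    prominence: float = 0.1
    separation_min: float = 48.0
    smooth_frames: int = 3
    min_frames: int = 60
    q_low: float = 0.25
    q_high: float = 0.75


class VsiConfig(_Strict):
    h: float = 20.0
    sigma_nodes: float = 3.0
    aggregate_min: float = 20.0
    elimination_tol: float = 1.5


class RunConfig(_Strict):
    seed: int = 0
    workdir: str = "chemowave_out"
    one_based_frames: bool = False
    gradient_axis: tuple[float, float] = (1.0, 0.0)
    synthetic: dict = {}
    render: RenderConfig = RenderConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    tracking: TrackingConfig = TrackingConfig()
    oscillation: OscillationConfig = OscillationConfig()
    stats: StatsConfig = StatsConfig()
    events: EventsConfig = EventsConfig()
    vsi: VsiConfig = VsiConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        from .io import load_yaml
        return cls.model_validate(load_yaml(path))

    def synth_config(self) -> synthetic.SynthConfig:
        d = dict(self.synthetic)
        d.setdefault("rng_seed", self.seed)
        return synthetic.config_from_dict(d)

    def path(self, name: str) -> Path:
        return Path(self.workdir) / name
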