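"""Run configuration: the fixed constants of the analysis in one place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of one analysis run.

    The defaults encode the acquisition and analysis constants of the
    reference protocol: 20-min frame interval, 0.7-µm linking distance, upper
    threshold 255 (8-bit), σ = 1 px smoothing, duration bins 20–80 …
    340–400 min and kernel bandwidths 6 / 0.3 / 220 for per-focus intensity,
    area (µm²) and total signal respectively.
    """

    pixel_size: float = 0.1  # µm / pixel
    frame_interval: float = 20.0  # min
    max_link_distance: float = 0.7  # µm
    manual_threshold: float | None = None  # first-frame lower threshold
    threshold_factor: float | None = None  # alternative: pre-calibrated factor
    upper_threshold: float = 255.0
    smoothing_sigma: float = 1.0  # px
    min_focus_area_px: int = 4
    min_nucleus_area_px: int = 200
    register: bool = True
    duration_bin_edges: list[list[float]] = field(
        default_factory=lambda: [
            [20.0, 80.0],
            [100.0, 160.0],
            [180.0, 240.0],
            [260.0, 320.0],
            [340.0, 400.0],
        ]
    )
    kde_bandwidth_intensity: float = 6.0
    kde_bandwidth_area: float = 0.3
    kde_bandwidth_total: float = 220.0
    edu_fallback_cutoff: float | None = None
    write_plots: bool = True
    seed: int = 0
    input_stack: str | None = None
    input_channel_a: str | None = None
    input_channel_b: str | None = None
    input_edu: str | None = None
    output_dir: str = "focitrack_out"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.max_link_distance <= 0:
            raise ValueError("max_link_distance must be positive")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        for edge in self.duration_bin_edges:
            if len(edge) != 2 or edge[0] > edge[1]:
                raise ValueError(f"invalid duration bin {edge}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
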