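"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PointCloud", "StimulusRecord"]


@dataclass
class PointCloud:
    """An unordered set of 3D surface samples.

    coords       : (N, 3) float array, unit-sphere frame after normalization
    part_labels  : optional (N,) integer part assignment
    category     : category name (or None)
    instance_id  : provenance string
    """

    coords: np.ndarray
    part_labels: np.ndarray | None = None
    category: str | None = None
    instance_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if self.part_labels is not None:
            self.part_labels = np.asarray(self.part_labels, dtype=np.int64)
            if self.part_labels.shape != (len(self.coords),):
                raise ValueError(
                    f"part_labels length {self.part_labels.shape} does not match "
                    f"{len(self.coords)} points")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def copy(self) -> "PointCloud":
        return PointCloud(self.coords.copy(),
                          None if self.part_labels is None else self.part_labels.copy(),
                          self.category, self.instance_id)


@dataclass
class StimulusRecord:
    """A stimulus cloud plus the provenance needed to regenerate it."""

    cloud: PointCloud
    base_instance: str
    family: str                      # e.g. "density", "lego", "scramble"
    params: dict = field(default_factory=dict)
    seed: int | None = None
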