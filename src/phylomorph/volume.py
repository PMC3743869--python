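"""Voxel volumes with anisotropic physical spacing.

A ``VoxelVolume`` is a 3D boolean occupancy grid indexed ``(x, y, z)`` with
per-axis spacing in mm and a physical origin.  CT stacks of branching coral
colonies are typically anisotropic (e.g. 0.33 x 0.33 x 1.50 mm per voxel);
all geometry downstream is computed in mm, never in voxel counts.

I/O: multi-page TIFF stacks (one page per z slice, y rows, x columns) with a
YAML sidecar recording ``spacing`` and ``origin``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["VoxelVolume"]


@dataclass
class VoxelVolume:
    occupancy: np.ndarray  # bool, axes (x, y, z)
    spacing: tuple[float, float, float]  # mm per voxel along x, y, z
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm of voxel (0,0,0) center

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy).astype(bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def n_foreground(self) -> int:
        return int(self.occupancy.sum())

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel center(s) given index array (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def mm_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        """Nearest voxel index for physical position(s) in mm."""
        pos = np.asarray(pos, dtype=float)
        return np.rint((pos - np.asarray(self.origin)) / np.asarray(self.spacing)).astype(int)

    # ------------------------------- I/O ------------------------------
    def write_tiff(self, path: str | Path) -> None:
        """Write a z-stack TIFF plus a ``<stem>.spacing.yaml`` sidecar."""
        path = Path(path)
        # tifffile pages are (z, y, x)
        stack = np.transpose(self.occupancy.astype(np.uint8), (2, 1, 0))
        tifffile.imwrite(path, stack, photometric="minisblack")
        sidecar = path.with_suffix("").with_suffix(".spacing.yaml")
        with open(sidecar, "w") as fh:
            yaml.safe_dump({"spacing_mm": list(self.spacing), "origin_mm": list(self.origin)}, fh)

    @classmethod
    def read_tiff(cls, path: str | Path, spacing: tuple[float, float, float] | None = None) -> "VoxelVolume":
        """Read a z-stack TIFF; spacing from the sidecar unless given explicitly."""
        path = Path(path)
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        occ = np.transpose(stack > 0, (2, 1, 0))
        origin = (0.0, 0.0, 0.0)
        if spacing is None:
            sidecar = path.with_suffix("").with_suffix(".spacing.yaml")
            if not sidecar.exists():
                raise FileNotFoundError(
                    f"no spacing given and sidecar {sidecar.name} not found next to {path.name}"
                )
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh)
            spacing = tuple(meta["spacing_mm"])
            origin = tuple(meta.get("origin_mm", origin))
        return cls(occ, spacing, origin)
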