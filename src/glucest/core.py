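"""Shared image containers for CEST processing.

All images are 2D single-slice ``numpy`` arrays (rows x cols); a Z-spectrum
stack adds a trailing offset axis.  Offsets are in ppm relative to the water
resonance at 0 ppm.  Every container carries a boolean validity mask so that
voxels excluded by a processing step (boundary B0 estimates, out-of-domain
flip-angle ratios, zero S0) propagate as *absent*, never as silently wrong
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_float_image(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.ndim != 2:
        raise ValueError(f"{name} must be a 2D image, got shape {out.shape}")
    return out


@dataclass
class ZStack:
    """A saturated image series over a ppm offset grid.

    Parameters
    ----------
    data
        Intensity array, shape ``(rows, cols, n_offsets)``.  Non-negative.
    offsets
        Strictly increasing ppm grid, length ``n_offsets``.
    s0
        Unsaturated reference image, shape ``(rows, cols)``.  ``None`` for
        WASSR stacks, which are only ever minimised, not normalised.
    mask
        Boolean image of valid voxels; defaults to all-true.
    """

    data: np.ndarray
    offsets: np.ndarray
    s0: np.ndarray | None = None
    mask: np.ndarray | None = None
    offset_valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"ZStack data must be 3D, got shape {self.data.shape}")
        if self.offsets.ndim != 1 or self.offsets.size != self.data.shape[2]:
            raise ValueError("offsets must be 1D with length data.shape[2]")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if np.any(self.data < 0):
            raise ValueError("ZStack data must be non-negative")
        if self.s0 is not None:
            self.s0 = _as_float_image(self.s0, "s0")
            if self.s0.shape != self.shape:
                raise ValueError("s0 geometry does not match data")
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.shape:
                raise ValueError("mask geometry does not match data")
        if self.offset_valid is not None:
            self.offset_valid = np.asarray(self.offset_valid, dtype=bool)
            if self.offset_valid.shape != self.data.shape:
                raise ValueError("offset_valid must match data shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_offsets(self) -> int:
        return self.offsets.size

    def offset_index(self, ppm: float, atol: float = 1e-6) -> int:
        """Index of an on-grid offset; raises if ``ppm`` is not on the grid."""
        idx = int(np.argmin(np.abs(self.offsets - ppm)))
        if abs(self.offsets[idx] - ppm) > atol:
            raise ValueError(f"offset {ppm} ppm is not on the grid")
        return idx


@dataclass
class B0Map:
    """Per-voxel water-centre shift in ppm, from WASSR."""

    shift: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.shift = _as_float_image(self.shift, "shift")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.shift.shape:
            raise ValueError("B0Map mask geometry does not match shift")


@dataclass
class B1Map:
    """Per-voxel relative RF field (1 = nominal flip angle achieved)."""

    relative: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.relative = _as_float_image(self.relative, "relative")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.relative.shape:
            raise ValueError("B1Map mask geometry does not match relative")
        if np.any(self.relative[self.mask] <= 0):
            raise ValueError("relative B1 must be positive on the mask")


@dataclass
class GluCestMap:
    """GluCEST percentage image at +3.0 ppm with provenance of corrections."""

    value: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.value = _as_float_image(self.value, "value")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.value.shape:
            raise ValueError("GluCestMap mask geometry does not match value")
        if not np.all(np.isfinite(self.value[self.mask])):
            raise ValueError("GluCestMap values must be finite on the mask")


@dataclass
class RoiSummary:
    """Mean / SD of a parametric map over an ROI (sample SD, n-1)."""

    roi_label: str
    n_voxels: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("RoiSummary needs at least one voxel")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
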