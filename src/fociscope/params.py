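"""Parameter containers for simulation, segmentation, spot detection and gating.

All spatial quantities are voxel-based unless a unit suffix says otherwise
(``_um`` micrometres, ``_nm`` nanometres).  Axis order is z, y, x throughout,
matching the slice-major layout of the acquired stacks (30 slices of 3 um at
124 x 124 nm pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple


class ValidationError(ValueError):
    """Raised when a parameter set violates its documented invariants."""


MARKERS = ("gH2AX", "53BP1")
PHASES = ("G1", "SG2")


@dataclass(frozen=True)
class ConditionParams:
    """One experimental condition: cell line x marker x dose x time.

    ``lambda_g1`` and ``lambda_sg2`` are the mean foci per cell (Poisson
    rates) for EdU-negative (G1) and EdU-positive (S/G2) cells;
    ``frac_g1`` is the expected EdU-negative fraction of the population.
    """

    line_id: str = "hDF"
    marker: str = "gH2AX"
    dose_gy: float = 0.0
    time_h: float = 0.0
    lambda_g1: float = 1.13
    lambda_sg2: float = 29.9
    frac_g1: float = 0.872
    n_cells: int = 30

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValidationError(f"marker must be one of {MARKERS}, got {self.marker!r}")
        if self.dose_gy < 0 or self.time_h < 0:
            raise ValidationError("dose_gy and time_h must be non-negative")
        if self.lambda_g1 < 0 or self.lambda_sg2 < 0:
            raise ValidationError("foci rates must be non-negative")
        if not 0.0 <= self.frac_g1 <= 1.0:
            raise ValidationError("frac_g1 must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")


@dataclass(frozen=True)
class RenderParams:
    """Forward-model parameters for rendering synthetic acquisition fields.

    Defaults mirror the acquisition geometry of the study being emulated:
    30 slices of 3 um, 1392 x 1040 px fields, 124 x 124 nm pixels.  Intensities
    are 16-bit-class camera counts.  ``nucleus_radius_um`` bounds the common
    lateral scale of each nucleus; per-axis jitter of +/-5% is applied on top,
    giving a nuclear-volume CV of ~20% as seen in cultured fibroblasts.
    ``foci_min_sep_px`` enforces a hard-core point process for focus placement:
    two foci closer than the optical resolution would be one detectable spot,
    so ground-truth counts are counts of resolvable foci.
    """

    shape_zyx: Tuple[int, int, int] = (30, 1040, 1392)
    spacing_zyx: Tuple[float, float, float] = (3000.0, 124.0, 124.0)
    nucleus_radius_um: Tuple[float, float] = (4.5, 6.3)
    nucleus_axial_slices: Tuple[float, float] = (1.5, 2.5)
    nucleus_base_intensity: float = 100.0
    foci_amplitude: float = 200.0
    edu_neg_intensity: float = 20.0
    edu_pos_intensity: float = 400.0
    edu_level_cv: float = 0.10
    noise_sd: float = 5.0
    psf_sigma_px: float = 1.0
    foci_min_sep_px: float = 8.0
    foci_margin: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape_zyx) or any(s <= 0 for s in self.spacing_zyx):
            raise ValidationError("shape and spacing must be strictly positive")
        for name in ("nucleus_base_intensity", "foci_amplitude",
                     "edu_neg_intensity", "edu_pos_intensity", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.edu_pos_intensity <= self.edu_neg_intensity:
            raise ValidationError("edu_pos_intensity must exceed edu_neg_intensity")
        lo, hi = self.nucleus_radius_um
        if not (0 < lo <= hi):
            raise ValidationError("nucleus_radius_um must be an increasing positive range")
        if self.psf_sigma_px <= 0:
            raise ValidationError("psf_sigma_px must be positive")
        if not 0 < self.foci_margin <= 1:
            raise ValidationError("foci_margin must lie in (0, 1]")


@dataclass(frozen=True)
class SegmentationParams:
    """Nucleus segmentation: Gaussian preprocessing (sigma in lateral px),
    two-level Otsu feeding hysteresis, then minimum-size and border filters."""

    sigma_px: float = 1.0
    min_voxels: int = 2000
    exclude_border: bool = True
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.sigma_px < 0:
            raise ValidationError("sigma_px must be >= 0")
        if self.min_voxels < 1:
            raise ValidationError("min_voxels must be >= 1")
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")


@dataclass(frozen=True)
class FociParams:
    """Extended-maxima spot detector parameters.

    ``height_h`` is the spot height threshold in camera counts (the h of the
    h-maxima transform), ``max_spot_voxels`` the maximum voxel count of a
    maxima component.  Defaults follow the empirically set values of the
    original analysis: sigma 1, height 80, maximum size 800.
    """

    sigma_px: float = 1.0
    height_h: float = 80.0
    max_spot_voxels: int = 800

    def __post_init__(self) -> None:
        if self.height_h <= 0:
            raise ValidationError("height_h must be > 0")
        if self.max_spot_voxels < 1:
            raise ValidationError("max_spot_voxels must be >= 1")
        if self.sigma_px < 0:
            raise ValidationError("sigma_px must be >= 0")


@dataclass(frozen=True)
class GatingParams:
    """EdU gating: Otsu on linear-scale per-cell totals with ``n_bins`` bins."""

    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
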