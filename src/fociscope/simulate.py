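"""Synthetic 3D acquisition fields with known ground truth.

The generative model is deliberately simple but faithful to the summary
statistics it must reproduce: per-cell focus counts are Poisson with a
phase-specific rate, the cell-cycle phase is Bernoulli in the EdU-negative
fraction, nuclei are non-overlapping axis-aligned ellipsoids, and the EdU
channel is a two-level (negative/positive) fill with per-cell lognormal-free
Gaussian jitter.  Foci are rendered as in-plane Gaussian spots of
diffraction-class width; a hard-core minimum separation keeps every true
focus individually resolvable, because an unresolvable pair is one spot to
any counting method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .params import ConditionParams, RenderParams, ValidationError


class PlacementError(RuntimeError):
    """Raised when non-overlapping nuclei cannot be placed: field too crowded."""


@dataclass
class NucleusTruth:
    nucleus_id: int
    centroid_zyx: Tuple[float, float, float]
    semi_axes_zyx: Tuple[float, float, float]
    true_phase: str                      # "G1" or "SG2"
    true_foci_count: int
    true_foci_positions: np.ndarray      # (k, 3) int voxel coordinates, z-y-x
    true_edu_level: float

    def __post_init__(self) -> None:
        self.true_foci_positions = np.asarray(self.true_foci_positions,
                                              dtype=np.int64).reshape(-1, 3)
        if len(self.true_foci_positions) != self.true_foci_count:
            raise ValidationError("foci count does not match position list length")


@dataclass
class GroundTruth:
    """Simulator truth for one field: the quantities every downstream stage
    is later scored against."""

    nuclei: List[NucleusTruth]
    cond: ConditionParams
    render: RenderParams

    def __len__(self) -> int:
        return len(self.nuclei)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "nucleus_id": n.nucleus_id,
                "centroid_z": n.centroid_zyx[0],
                "centroid_y": n.centroid_zyx[1],
                "centroid_x": n.centroid_zyx[2],
                "semi_z": n.semi_axes_zyx[0],
                "semi_y": n.semi_axes_zyx[1],
                "semi_x": n.semi_axes_zyx[2],
                "true_phase": n.true_phase,
                "true_foci_count": n.true_foci_count,
                "true_edu_level": n.true_edu_level,
            }
            for n in self.nuclei
        ]
        return pd.DataFrame(rows)

    def foci_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.nuclei:
            for z, y, x in n.true_foci_positions:
                rows.append({"nucleus_id": n.nucleus_id, "z": int(z),
                             "y": int(y), "x": int(x)})
        return pd.DataFrame(rows, columns=["nucleus_id", "z", "y", "x"])


@dataclass
class ChannelStack:
    """Three co-registered intensity volumes (nuclear stain, foci marker, EdU)
    plus the voxel spacing in nm, z-y-x order."""

    nuclear: np.ndarray
    foci: np.ndarray
    edu: np.ndarray
    spacing_zyx: Tuple[float, float, float]
    metadata: Optional[ConditionParams] = None

    def __post_init__(self) -> None:
        shapes = {self.nuclear.shape, self.foci.shape, self.edu.shape}
        if len(shapes) != 1:
            raise ValidationError("channel volumes must share one shape")
        for name in ("nuclear", "foci", "edu"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)) or v.min() < 0:
                raise ValidationError(f"{name} channel must be finite and >= 0")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.nuclear.shape


def _draw_phases_and_counts(cond: ConditionParams, rng: np.random.Generator
                            ) -> Tuple[np.ndarray, np.ndarray]:
    g1 = rng.random(cond.n_cells) < cond.frac_g1
    rates = np.where(g1, cond.lambda_g1, cond.lambda_sg2)
    counts = rng.poisson(rates)
    return g1, counts


def sample_ground_truth(cond: ConditionParams, render: RenderParams,
                        seed: int) -> GroundTruth:
    """Draw per-nucleus truth (geometry, phase, focus count/positions, EdU
    level) for one field.

    Nuclei are placed by rejection sampling with a conservative ellipsoid
    separation test and may not touch the volume border.  Raises
    :class:`PlacementError` when the field is too crowded.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = render.shape_zyx
    px_um = render.spacing_zyx[1] / 1000.0  # lateral pixel size in um

    g1, counts = _draw_phases_and_counts(cond, rng)

    lo, hi = render.nucleus_radius_um
    scale_um = rng.uniform(lo, hi, cond.n_cells)
    semi_y = scale_um / px_um * rng.uniform(0.95, 1.05, cond.n_cells)
    semi_x = scale_um / px_um * rng.uniform(0.95, 1.05, cond.n_cells)
    az_lo, az_hi = render.nucleus_axial_slices
    # axial semi-axis tracks the lateral scale, clipped to the configured range
    semi_z = np.clip(scale_um * (az_hi / hi), az_lo, az_hi)

    needed = semi_z.max() * 2 + 2
    if nz < needed or ny < semi_y.max() * 2 + 2 or nx < semi_x.max() * 2 + 2:
        raise PlacementError(
            f"volume {render.shape_zyx} cannot hold a nucleus of semi-axes "
            f"({semi_z.max():.1f}, {semi_y.max():.1f}, {semi_x.max():.1f}); "
            "field too crowded")

    centers = np.empty((cond.n_cells, 3))
    axes = np.stack([semi_z, semi_y, semi_x], axis=1)
    margin = np.array([1.0, 4.0, 4.0])  # clearance between nuclei, voxels
    # sequential rejection sampling can wedge itself; restart on exhaustion
    for _restart in range(40):
        placed = 0
        tries = 0
        max_tries = 1000 * cond.n_cells
        while placed < cond.n_cells and tries < max_tries:
            tries += 1
            a = axes[placed] + 1.0  # keep one clear voxel to the border
            c = np.array([
                rng.uniform(a[0], nz - 1 - a[0]),
                rng.uniform(a[1], ny - 1 - a[1]),
                rng.uniform(a[2], nx - 1 - a[2]),
            ])
            if placed:
                d = centers[:placed] - c
                # disjoint if the centre offset lies outside an ellipsoid
                # bounding the Minkowski sum of the two margin-inflated
                # ellipsoids
                s = 2.0 * ((axes[:placed] + margin) ** 2 + (a + margin) ** 2)
                if np.any(np.sum(d * d / s, axis=1) < 1.0):
                    continue
            centers[placed] = c
            placed += 1
        if placed == cond.n_cells:
            break
    else:
        raise PlacementError(
            f"placed only {placed}/{cond.n_cells} nuclei; field too crowded")

    edu_lo, edu_hi = render.edu_neg_intensity, render.edu_pos_intensity
    nuclei: List[NucleusTruth] = []
    for i in range(cond.n_cells):
        level_mean = edu_lo if g1[i] else edu_hi
        level = max(1.0, level_mean * (1.0 + render.edu_level_cv * rng.standard_normal()))
        pos = _place_foci(int(counts[i]), centers[i], axes[i], rng, render)
        nuclei.append(NucleusTruth(
            nucleus_id=i + 1,
            centroid_zyx=tuple(centers[i]),
            semi_axes_zyx=tuple(axes[i]),
            true_phase="G1" if g1[i] else "SG2",
            true_foci_count=int(counts[i]),
            true_foci_positions=pos,
            true_edu_level=float(level),
        ))
    return GroundTruth(nuclei=nuclei, cond=cond, render=render)


def _place_foci(k: int, center: np.ndarray, axes: np.ndarray,
                rng: np.random.Generator, render: RenderParams) -> np.ndarray:
    """Hard-core placement of k foci inside the margin-scaled ellipsoid."""
    if k == 0:
        return np.empty((0, 3), dtype=np.int64)
    a = axes * render.foci_margin
    min_sep = render.foci_min_sep_px
    for _restart in range(20):
        pts: List[np.ndarray] = []
        tries = 0
        while len(pts) < k and tries < 4000:
            tries += 1
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            r = rng.random() ** (1.0 / 3.0)
            p = np.rint(center + u * r * a).astype(np.int64)
            # voxel rounding can nudge the point out; re-check the ellipsoid
            if np.sum(((p - center) / np.maximum(a, 1e-9)) ** 2) > 1.0:
                continue
            ok = True
            for q in pts:
                if abs(int(p[0]) - int(q[0])) <= 1:
                    if np.hypot(p[1] - q[1], p[2] - q[2]) < min_sep:
                        ok = False
                        break
            if ok:
                pts.append(p)
        if len(pts) == k:
            return np.asarray(pts, dtype=np.int64)
    raise PlacementError(
        f"could not place {k} foci with min separation {min_sep} px in a "
        f"nucleus of semi-axes {tuple(np.round(axes, 1))}")


def _ellipsoid_box(center: np.ndarray, axes: np.ndarray,
                   shape: Sequence[int]):
    lo = np.maximum(np.floor(center - axes).astype(int), 0)
    hi = np.minimum(np.ceil(center + axes).astype(int) + 1, np.asarray(shape))
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    r2 = (((zz - center[0]) / axes[0]) ** 2
          + ((yy - center[1]) / axes[1]) ** 2
          + ((xx - center[2]) / axes[2]) ** 2)
    sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    return sl, r2


def rasterize_truth(truth: GroundTruth) -> np.ndarray:
    """Integer label volume of the true nucleus ellipsoids (0 = background)."""
    labels = np.zeros(truth.render.shape_zyx, dtype=np.int32)
    for n in truth.nuclei:
        sl, r2 = _ellipsoid_box(np.asarray(n.centroid_zyx),
                                np.asarray(n.semi_axes_zyx),
                                truth.render.shape_zyx)
        labels[sl][r2 <= 1.0] = n.nucleus_id
    return labels


def render_stack(truth: GroundTruth, render: RenderParams, seed: int) -> ChannelStack:
    """Render the three channels for one field.

    Nuclear channel: base intensity with a mild radial chromatin gradient
    (brighter centre, dimmer periphery — flat nuclei are not what a stained
    nucleus looks like, and a flat fill would defeat any two-level threshold).
    Foci channel: in-plane Gaussian spots of peak ``foci_amplitude`` at the
    true positions on a dark background.  EdU channel: the per-nucleus level
    filling the ellipsoid.  Additive Gaussian read noise, clipped at zero.
    """
    shape = render.shape_zyx
    nuclear = np.zeros(shape, dtype=np.float32)
    edu = np.zeros(shape, dtype=np.float32)
    foci = np.zeros(shape, dtype=np.float32)

    for n in truth.nuclei:
        c = np.asarray(n.centroid_zyx)
        a = np.asarray(n.semi_axes_zyx)
        if np.any(np.floor(c - a) < -0.5) or np.any(np.ceil(c + a) > np.asarray(shape) - 0.5):
            raise ValidationError("nucleus extends beyond the render volume")
        sl, r2 = _ellipsoid_box(c, a, shape)
        inside = r2 <= 1.0
        # radial gradient: 1.3x base at the centre, 0.7x at the rim
        nuclear[sl][inside] += (render.nucleus_base_intensity
                                * (0.7 + 0.6 * (1.0 - r2[inside]))).astype(np.float32)
        edu[sl][inside] += np.float32(n.true_edu_level)

        sig = render.psf_sigma_px
        half = max(2, int(np.ceil(4 * sig)))
        for z, y, x in n.true_foci_positions:
            y0, y1 = max(0, y - half), min(shape[1], y + half + 1)
            x0, x1 = max(0, x - half), min(shape[2], x + half + 1)
            yy, xx = np.ogrid[y0:y1, x0:x1]
            spot = render.foci_amplitude * np.exp(
                -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sig * sig))
            foci[z, y0:y1, x0:x1] += spot.astype(np.float32)

    if render.noise_sd > 0:
        rng = np.random.default_rng(seed)
        for vol in (nuclear, foci, edu):
            vol += rng.normal(0.0, render.noise_sd, size=shape).astype(np.float32)
    np.clip(nuclear, 0, None, out=nuclear)
    np.clip(foci, 0, None, out=foci)
    np.clip(edu, 0, None, out=edu)
    return ChannelStack(nuclear=nuclear, foci=foci, edu=edu,
                        spacing_zyx=render.spacing_zyx, metadata=truth.cond)
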