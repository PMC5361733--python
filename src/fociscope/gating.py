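"""EdU image cytometry: per-nucleus total intensity and G1 vs S/G2 gating.

EdU (a thymidine analogue) is incorporated only during DNA replication, so
the summed EdU intensity over a nucleus is bimodal across a population:
EdU-negative cells are in G1, EdU-positive cells in S or G2.  The gate is an
Otsu threshold on the linear-scale per-cell totals, computed per virtual
slide (one threshold per sample, pooling its fields).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .params import ConditionParams, GatingParams, ValidationError
from .segment import DegenerateHistogramError, LabeledNuclei


@dataclass
class CellRecord:
    """One analysed nucleus: focus count, EdU total, inferred phase, provenance."""

    nucleus_id: int
    foci_count: int = 0
    edu_total: float = 0.0
    phase: str = "UNSET"
    voxels: int = 0
    condition: Optional[ConditionParams] = None
    field_id: int = 0
    slide_id: str = ""


@dataclass
class GateResult:
    threshold: float
    n_total: int
    n_neg: int
    n_pos: int
    frac_neg_percent: float
    histogram: Tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.condition
        rows.append({
            "slide_id": r.slide_id, "field_id": r.field_id,
            "nucleus_id": r.nucleus_id,
            "line_id": c.line_id if c else "", "marker": c.marker if c else "",
            "dose_gy": c.dose_gy if c else 0.0, "time_h": c.time_h if c else 0.0,
            "foci_count": r.foci_count, "edu_total": r.edu_total,
            "phase": r.phase, "voxels": r.voxels,
        })
    return pd.DataFrame(rows, columns=[
        "slide_id", "field_id", "nucleus_id", "line_id", "marker", "dose_gy",
        "time_h", "foci_count", "edu_total", "phase", "voxels"])


def frame_to_records(frame: pd.DataFrame) -> List[CellRecord]:
    records = []
    for row in frame.itertuples(index=False):
        cond = None
        line_id = getattr(row, "line_id", "")
        marker = getattr(row, "marker", "")
        if not pd.isna(line_id) and line_id and not pd.isna(marker) and marker:
            cond = ConditionParams(line_id=str(line_id), marker=str(marker),
                                   dose_gy=float(row.dose_gy),
                                   time_h=float(row.time_h))
        records.append(CellRecord(
            nucleus_id=int(row.nucleus_id), foci_count=int(row.foci_count),
            edu_total=float(row.edu_total), phase=str(row.phase),
            voxels=int(getattr(row, "voxels", 0)), condition=cond,
            field_id=int(getattr(row, "field_id", 0)),
            slide_id=str(getattr(row, "slide_id", ""))))
    return records


def edu_totals(edu_volume: np.ndarray, nuclei: LabeledNuclei) -> np.ndarray:
    """Summed EdU intensity over each nucleus mask, one value per nucleus."""
    edu_volume = np.asarray(edu_volume, dtype=np.float64)
    if edu_volume.shape != nuclei.labels.shape:
        raise ValidationError(
            f"edu volume shape {edu_volume.shape} != labels shape "
            f"{nuclei.labels.shape}")
    if nuclei.n_nuclei == 0:
        return np.zeros(0)
    return ndi.sum_labels(edu_volume, labels=nuclei.labels,
                          index=np.arange(1, nuclei.n_nuclei + 1))


def otsu_1d(values: Sequence[float], n_bins: int = 256) -> float:
    """Otsu threshold on a list of per-cell totals: the bin edge maximising
    the between-class variance of the ``n_bins`` linear-scale histogram,
    ties broken by the smallest threshold."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2 or np.unique(v).size < 2:
        raise DegenerateHistogramError("need >= 2 distinct values to gate")
    hist, edges = np.histogram(v, bins=n_bins)
    p = hist / hist.sum()
    centers = np.arange(n_bins, dtype=np.float64)
    P = np.cumsum(p)
    M = np.cumsum(p * centers)
    w0 = P[:-1]
    w1 = 1.0 - w0
    mu_t = M[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, M[:-1] / w0, 0.0)
        mu1 = np.where(w1 > 0, (mu_t - M[:-1]) / w1, 0.0)
    sb = np.where((w0 > 0) & (w1 > 0), w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    tol = 1e-9 * max(1.0, abs(sb.max()))
    k = int(np.argmax(sb >= sb.max() - tol))  # first maximum = smallest threshold
    return float(edges[k + 1])


def assign_phase(records: Sequence[CellRecord], threshold: float,
                 n_bins: int = 256) -> Tuple[List[CellRecord], GateResult]:
    """Split records at ``threshold``: phase G1 iff edu_total < threshold,
    else S/G2 (cells exactly at the threshold are EdU-positive)."""
    if len(records) == 0:
        raise ValidationError("cannot gate an empty record list")
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    out: List[CellRecord] = []
    n_neg = 0
    totals = np.array([r.edu_total for r in records])
    for r in records:
        phase = "G1" if r.edu_total < threshold else "SG2"
        n_neg += phase == "G1"
        out.append(CellRecord(**{**r.__dict__, "phase": phase}))
    hist, edges = np.histogram(totals, bins=n_bins)
    gate = GateResult(threshold=float(threshold), n_total=len(out),
                      n_neg=int(n_neg), n_pos=len(out) - int(n_neg),
                      frac_neg_percent=100.0 * n_neg / len(out),
                      histogram=(hist, edges))
    return out, gate


def gate_records(records: Sequence[CellRecord],
                 params: Optional[GatingParams] = None
                 ) -> Tuple[List[CellRecord], GateResult]:
    """Per-slide gate: Otsu threshold on the pooled totals, then assignment."""
    params = params or GatingParams()
    totals = [r.edu_total for r in records]
    thr = otsu_1d(totals, params.n_bins)
    return assign_phase(records, thr, params.n_bins)
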