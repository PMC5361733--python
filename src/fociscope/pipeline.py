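"""Orchestration: simulate -> segment -> count -> gate -> stats as one
reproducible run, with every intermediate written to disk.

A *slide* is one virtual sample (one condition); it holds several acquisition
*fields*, mirroring how hundreds of cells per slide are reached through many
microscope fields.  The EdU gate is computed per slide by pooling its fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .foci import detect_foci
from .gating import (CellRecord, GateResult, edu_totals, gate_records,
                     records_to_frame)
from .params import (ConditionParams, FociParams, GatingParams, RenderParams,
                     SegmentationParams)
from .segment import LabeledNuclei, segment_nuclei
from .simulate import ChannelStack, GroundTruth, render_stack, sample_ground_truth
from .stats import (anova_tukey, compare_two_groups, repair_time_course,
                    summaries_to_frame, summarize_foci, timecourse_to_frame,
                    TimeCourseGapError)

log = logging.getLogger("fociscope")


@dataclass
class SlideSpec:
    slide_id: str
    condition: ConditionParams
    n_fields: int = 1


@dataclass
class RunConfig:
    slides: List[SlideSpec]
    render: RenderParams = field(default_factory=RenderParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    foci: FociParams = field(default_factory=FociParams)
    gating: GatingParams = field(default_factory=GatingParams)
    seed: int = 0
    alpha: float = 0.05
    output: str = "run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, key):
            d = dict(raw.get(key) or {})
            for k, v in d.items():
                if isinstance(v, list):
                    d[k] = tuple(v)
            return klass(**d)

        slides = []
        for s in raw.get("slides", []):
            slides.append(SlideSpec(
                slide_id=str(s["slide_id"]),
                condition=ConditionParams(**(s.get("condition") or {})),
                n_fields=int(s.get("n_fields", 1))))
        return cls(slides=slides,
                   render=build(RenderParams, "render"),
                   segmentation=build(SegmentationParams, "segmentation"),
                   foci=build(FociParams, "foci"),
                   gating=build(GatingParams, "gating"),
                   seed=int(raw.get("seed", 0)),
                   alpha=float(raw.get("alpha", 0.05)),
                   output=str(raw.get("output", "run")))

    def to_dict(self) -> dict:
        def detuple(obj):
            if isinstance(obj, dict):
                return {k: detuple(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [detuple(v) for v in obj]
            return obj

        d = dataclasses.asdict(self)
        d["slides"] = [{"slide_id": s.slide_id,
                        "condition": dataclasses.asdict(s.condition),
                        "n_fields": s.n_fields} for s in self.slides]
        return detuple(d)


def field_seed(seed: int, slide_idx: int, field_idx: int) -> int:
    """Deterministic per-field child seed below 2**31."""
    ss = np.random.SeedSequence([seed, slide_idx, field_idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def analyze_field(stack: ChannelStack,
                  seg: Optional[SegmentationParams] = None,
                  foci_params: Optional[FociParams] = None
                  ) -> Tuple[List[CellRecord], LabeledNuclei]:
    """Segment one field and measure focus counts and EdU totals per nucleus.
    Phases are left UNSET (gating is a per-slide operation)."""
    nuclei = segment_nuclei(stack.nuclear, seg, stack.spacing_zyx)
    counts, _calls = detect_foci(stack.foci, nuclei, foci_params,
                                 stack.spacing_zyx)
    totals = edu_totals(stack.edu, nuclei)
    records = [CellRecord(nucleus_id=i + 1, foci_count=int(counts[i]),
                          edu_total=float(totals[i]),
                          voxels=int(nuclei.voxel_counts[i]),
                          condition=stack.metadata)
               for i in range(nuclei.n_nuclei)]
    return records, nuclei


def simulate_and_analyze_slide(cond: ConditionParams, render: RenderParams,
                               seed: int, n_fields: int,
                               seg: Optional[SegmentationParams] = None,
                               foci_params: Optional[FociParams] = None,
                               gating: Optional[GatingParams] = None,
                               gate: bool = True, slide_idx: int = 0,
                               count_spots: bool = True,
                               ) -> Tuple[List[CellRecord], List[GroundTruth],
                                          Optional[GateResult]]:
    """Generate ``n_fields`` fields of one condition and run the analysis
    stages in memory.  ``gate=False`` skips the per-slide EdU gate (useful
    for deliberately single-phase slides, where an Otsu split of a unimodal
    total distribution would be meaningless); phases then stay UNSET.
    ``count_spots=False`` skips focus rendering and counting for runs that
    only exercise the gating stage."""
    records: List[CellRecord] = []
    truths: List[GroundTruth] = []
    for f in range(n_fields):
        fseed = field_seed(seed, slide_idx, f)
        truth = sample_ground_truth(cond, render, fseed)
        stack = render_stack(truth, render, fseed + 1)
        if not count_spots:
            stack = ChannelStack(nuclear=stack.nuclear,
                                 foci=np.zeros_like(stack.foci),
                                 edu=stack.edu, spacing_zyx=stack.spacing_zyx,
                                 metadata=stack.metadata)
        recs, _ = analyze_field(stack, seg, foci_params)
        for r in recs:
            r.field_id = f
            r.slide_id = cond.line_id
        records.extend(recs)
        truths.append(truth)
    gate_result = None
    if gate and records:
        records, gate_result = gate_records(records, gating)
    return records, truths, gate_result


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full run and write cells.csv, summary.csv, tests.csv,
    tc.csv, gate.json and a manifest into the output directory.  Reruns with
    the same config and seed are byte-identical."""
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    all_records: List[CellRecord] = []
    gates: Dict[str, dict] = {}
    truth_counts: Dict[str, dict] = {}

    for si, slide in enumerate(config.slides):
        stage = f"slide {slide.slide_id}"
        try:
            records, truths, gate_result = simulate_and_analyze_slide(
                slide.condition, config.render, config.seed, slide.n_fields,
                config.segmentation, config.foci, config.gating,
                gate=True, slide_idx=si)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at {stage}: {exc}") from exc
        for r in records:
            r.slide_id = slide.slide_id
        all_records.extend(records)
        n_true = sum(len(t) for t in truths)
        truth_counts[slide.slide_id] = {
            "true_nuclei": n_true,
            "segmented": len(records),
        }
        if gate_result is not None:
            gates[slide.slide_id] = {
                "threshold": gate_result.threshold,
                "n_total": gate_result.n_total,
                "n_neg": gate_result.n_neg,
                "n_pos": gate_result.n_pos,
                "frac_neg_percent": gate_result.frac_neg_percent,
            }
        log.info("%s: %d/%d nuclei analysed", stage, len(records), n_true)

    cells = records_to_frame(all_records)
    fio.write_table(out / "cells.csv", cells)
    with open(out / "gate.json", "w", encoding="utf-8") as fh:
        json.dump(gates, fh, indent=2, sort_keys=True)

    if all_records:
        summaries = summarize_foci(all_records)
        fio.write_table(out / "summary.csv", summaries_to_frame(summaries))
        fio.write_table(out / "tests.csv", _group_tests(cells, config.alpha))
        try:
            tc = repair_time_course(summaries)
            fio.write_table(out / "tc.csv", timecourse_to_frame(tc))
        except TimeCourseGapError:
            fio.write_table(out / "tc.csv", timecourse_to_frame([]))
    else:
        fio.write_table(out / "summary.csv", summaries_to_frame([]))
        fio.write_table(out / "tests.csv", _group_tests(cells, config.alpha))
        fio.write_table(out / "tc.csv", timecourse_to_frame([]))

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "slides": truth_counts,
        "n_cells_total": len(all_records),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _group_tests(cells: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Per (marker, phase): compare focus counts across cell lines — ANOVA +
    Tukey for >= 3 lines, Student's t for exactly 2."""
    rows = []
    if cells.empty:
        return pd.DataFrame(rows, columns=["marker", "phase", "kind", "group_a",
                                           "group_b", "statistic", "p_value",
                                           "significant"])
    for (marker, phase), grp in cells.groupby(["marker", "phase"], sort=True):
        groups = {line: g["foci_count"].to_numpy(dtype=float)
                  for line, g in grp.groupby("line_id") if len(g) >= 2}
        if len(groups) >= 3:
            res = anova_tukey(groups, alpha=alpha)
            for a, b, p, sig in res.pairwise:
                rows.append({"marker": marker, "phase": phase,
                             "kind": "anova_tukey", "group_a": a, "group_b": b,
                             "statistic": res.statistic, "p_value": p,
                             "significant": sig})
        elif len(groups) == 2:
            (a, va), (b, vb) = groups.items()
            res = compare_two_groups(va, vb)
            rows.append({"marker": marker, "phase": phase, "kind": "t_test",
                         "group_a": a, "group_b": b,
                         "statistic": res.statistic, "p_value": res.p_value,
                         "significant": res.p_value < alpha})
    return pd.DataFrame(rows, columns=["marker", "phase", "kind", "group_a",
                                       "group_b", "statistic", "p_value",
                                       "significant"])
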