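"""End-to-end orchestration: preprocess -> threshold -> postprocess -> count.

``analyze_image`` is the pure in-memory pipeline; ``run_pipeline`` wraps it
with file input/output, logging and optional evaluation against a ground
truth file, for use by the command-line interface.  The analysis itself
contains no randomness: the same image and configuration always produce
byte-identical reports.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cclsc import EntropyConfig
from .image_io import read_image, write_image
from .metrics import EvalResult, evaluate, match_detections, true_negatives
from .postprocess import PostprocessConfig, denoise
from .preprocess import PreprocessConfig
from .quantify import QuantReport, quantify_image
from .segment import SegmentationResult, segment_image

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    input_path: str
    output_dir: str
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    connectivity: int = 8
    min_area: int = 0
    apply_on_enhanced: bool = False
    truth_path: str | None = None
    max_dist: float = 8.0
    save_intermediates: bool = False


@dataclass
class PipelineResult:
    """In-memory outputs of one run."""

    segmentation: SegmentationResult
    postprocessed_rgb: np.ndarray
    postprocessed_mask: np.ndarray
    report: QuantReport


def analyze_image(
    img: np.ndarray,
    pre_cfg: PreprocessConfig | None = None,
    ent_cfg: EntropyConfig | None = None,
    post_cfg: PostprocessConfig | None = None,
    connectivity: int = 8,
    min_area: int = 0,
    apply_on_enhanced: bool = False,
) -> PipelineResult:
    """Run the full analysis on an in-memory RGB image.

    The report's ``count_pre_postprocess`` holds the component count of the
    raw segmentation (before fill-holes/median), which the true-negative
    convention compares against the final count.
    """
    seg = segment_image(img, pre_cfg, ent_cfg, apply_on_enhanced=apply_on_enhanced)
    pre_report = quantify_image(seg.rgb, connectivity=connectivity, min_area=min_area)
    post_rgb, post_mask = denoise(seg.rgb, seg.mask, img, post_cfg)
    report = quantify_image(post_rgb, connectivity=connectivity, min_area=min_area)
    report.count_pre_postprocess = pre_report.count
    return PipelineResult(
        segmentation=seg,
        postprocessed_rgb=post_rgb,
        postprocessed_mask=post_mask,
        report=report,
    )


def evaluate_against_truth(
    result: PipelineResult, truth_centroids, max_dist: float
) -> EvalResult:
    """Confusion metrics of a run against ground-truth centroids."""
    detected = [o.centroid for o in result.report.objects]
    tp, fp, fn = match_detections(detected, truth_centroids, max_dist)
    tn = true_negatives(result.report.count_pre_postprocess, result.report.count)
    return evaluate(tp, fp, fn, tn)


def _write_phi_csv(path: Path, res) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "H_O", "H_B", "Phi"])
        for t in range(255):
            writer.writerow(
                [
                    t,
                    res.h_object_curve[t],
                    res.h_background_curve[t],
                    res.phi_curve[t],
                ]
            )


def _write_objects_csv(path: Path, report: QuantReport) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "centroid_row", "centroid_col", "area"])
        for o in report.objects:
            writer.writerow([o.label, o.centroid[0], o.centroid[1], o.area])


def load_truth_centroids(path) -> list:
    """Read ground-truth centroids from a JSON file ({"centroids": [[r,c],..]})."""
    with open(path) as fh:
        data = json.load(fh)
    return [tuple(c) for c in data["centroids"]]


def run_pipeline(cfg: RunConfig):
    """File-to-file pipeline run.

    Writes the segmented image, binary mask, thresholds, per-channel entropy
    curves and the quantification report into ``cfg.output_dir``; returns
    ``(PipelineResult, EvalResult | None)``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = read_image(cfg.input_path)

    t0 = time.perf_counter()
    result = analyze_image(
        img,
        pre_cfg=cfg.preprocess,
        ent_cfg=cfg.entropy,
        post_cfg=cfg.postprocess,
        connectivity=cfg.connectivity,
        min_area=cfg.min_area,
        apply_on_enhanced=cfg.apply_on_enhanced,
    )
    seg = result.segmentation
    logger.info(
        "segmented %s in %.2fs: thresholds (T_r=%d, T_g=%d, T_b=%d), %d nuclei",
        cfg.input_path,
        time.perf_counter() - t0,
        *seg.thresholds,
        result.report.count,
    )

    write_image(out / "R.png", result.postprocessed_rgb)
    write_image(out / "BW.png", result.postprocessed_mask * 255)
    with open(out / "thresholds.json", "w") as fh:
        json.dump(
            {"T_r": seg.thresholds.t_r, "T_g": seg.thresholds.t_g, "T_b": seg.thresholds.t_b},
            fh,
            indent=2,
        )
    for name, res in zip(("r", "g", "b"), seg.threshold_results):
        _write_phi_csv(out / f"phi_{name}.csv", res)
    _write_objects_csv(out / "objects.csv", result.report)

    eval_result = None
    if cfg.truth_path:
        truth = load_truth_centroids(cfg.truth_path)
        eval_result = evaluate_against_truth(result, truth, cfg.max_dist)

    report_payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "input": str(cfg.input_path),
        "thresholds": {
            "T_r": seg.thresholds.t_r,
            "T_g": seg.thresholds.t_g,
            "T_b": seg.thresholds.t_b,
        },
        **result.report.to_dict(),
    }
    if eval_result is not None:
        report_payload["evaluation"] = eval_result.to_dict()
    with open(out / "report.json", "w") as fh:
        json.dump(report_payload, fh, indent=2)

    if cfg.save_intermediates:
        write_image(out / "R_pre_postprocess.png", seg.rgb)
        for name, ch in zip(("r", "g", "b"), seg.preprocess.enhanced):
            write_image(out / f"K_{name}.png", ch)
        for name, m in zip(("r", "g", "b"), seg.channel_masks):
            write_image(out / f"B_{name}.png", m * 255)
        write_image(out / "tissue_mask.png", seg.preprocess.mask * 255)

    return result, eval_result
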