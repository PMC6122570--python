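"""End-to-end run: generate -> segment -> index -> calibrate -> evaluate.

Produces, under the run directory: the synthetic dataset (images, masks,
annotations, manifest), pairs.csv with the true index T and the area
indices A_within / A_whole per ROI, the fitted within-tumor calibration
model.json, the agreement report (CSV + JSON), and a log recording every
seed and parameter.  Re-running with the same config reproduces every
numeric output.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from .agreement import build_agreement_report
from .config import RunConfig
from .index import compute_area_index, fit_calibration
from .segmentation import load_default_precomputed, segment_roi
from .synth import generate_dataset

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("ki67area")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    config.to_yaml(out / "config.yaml")
    log.info("run start: seed=%d n_rois=%d out=%s", config.seed, config.n_rois, out)

    try:
        t0 = time.perf_counter()
        rois, manifest = generate_dataset(
            n_rois=config.n_rois,
            index_range=config.index_range,
            template=config.roi_template(),
            seed=config.seed,
            out_dir=out / "data",
            nontumor_frac_range=config.nontumor_frac_range,
        )
        log.info("stage=generate n_rois=%d elapsed=%.1fs",
                 len(rois), time.perf_counter() - t0)
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        raise PipelineError(f"generate stage failed: {exc}") from exc

    try:
        precomputed = load_default_precomputed()
        rows = []
        for roi_id, roi in zip(manifest["roi_id"], rois):
            t0 = time.perf_counter()
            masks = segment_roi(roi.image, tumor_mask=None,
                                precomputed=precomputed, config=config.segmentation)
            a_whole = compute_area_index(masks).value
            a_within = compute_area_index(masks, tumor_mask=roi.tumor_mask).value
            rows.append({"roi_id": roi_id, "T": roi.true_index,
                         "A_within": a_within, "A_whole": a_whole})
            log.info("stage=segment roi_id=%s threshold=%.3f precomputed=%s elapsed=%.2fs",
                     roi_id, masks.threshold_value, masks.used_precomputed,
                     time.perf_counter() - t0)
        pairs = pd.DataFrame(rows)
        pairs.to_csv(out / "pairs.csv", index=False)
    except Exception as exc:
        raise PipelineError(f"segment/index stage failed: {exc}") from exc

    try:
        model = fit_calibration(pairs[["A_within", "T"]], degree=1)
        model.to_json(out / "model.json")
        log.info("stage=calibrate c1=%.4f c2=%.4f rmse=%.3f r2=%.4f",
                 model.c1, model.c2, model.rmse, model.r_square)
        if config.n_rois < 10:
            log.warning("stage=calibrate n=%d is small; diagnostics unstable",
                        config.n_rois)
    except Exception as exc:
        raise PipelineError(f"calibrate stage failed: {exc}") from exc

    try:
        specs = dict(config.models)
        for col, spec in specs.items():
            degree = {"linear": 1, "quadratic": 2, "cubic": 3}.get(spec, spec)
            if degree is not None and len(pairs) <= degree + 1:
                log.warning("stage=evaluate n=%d too small for degree-%s fit "
                            "on %s; reporting raw statistics only",
                            len(pairs), degree, col)
                specs[col] = None
        report = build_agreement_report(pairs, specs)
        report.to_csv(out / "report.csv")
        report.to_json(out / "report.json")
        log.info("stage=evaluate rows=%d", len(report.table))
    except Exception as exc:
        raise PipelineError(f"evaluate stage failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
    return out
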