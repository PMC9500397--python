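"""End-to-end segmentation pipeline and batch evaluation.

Stage order: green channel → CLAHE → FOV mask (computed, unless an override
mask is supplied, e.g. the masks shipped with DRIVE) → masking → combined
symmetric+asymmetric B-COSFIRE response → top-hat → manual threshold →
connected-domain post-processing. Every intermediate is retained for
stepwise inspection; the whole path is deterministic for a fixed input and
configuration.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bcosfire, image_io, postprocess as pp, preprocess, segment
from .config import PipelineConfig
from .errors import ContractError
from .metrics import MetricsReport, evaluate
from .preprocess import ClaheParams

logger = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    """Final vessel map plus every intermediate of the pipeline."""

    final: np.ndarray
    fov: np.ndarray
    intermediates: dict[str, np.ndarray] = field(default_factory=dict)
    metrics: MetricsReport | None = None


def _rho_set(rho_max: float, rho_step: float) -> list[float]:
    n = int(math.floor(rho_max / rho_step + 1e-9))
    return [0.0] + [rho_step * (k + 1) for k in range(n)]


def build_filters(config: PipelineConfig) -> tuple[bcosfire.CosfireFilter, bcosfire.CosfireFilter | None]:
    """Configure the symmetric and (optionally) asymmetric filters."""
    common = dict(
        sigma0_prime=config["filter.sigma0_prime"],
        alpha=config["filter.alpha"],
        weight_sigma=config.weight_sigma(),
        t=config["filter.t"],
        dog_sign=config["dog.sign"],
    )
    width = config["filter.prototype_width"]

    def one(kind: str, sigma: float, rho_max: float, rho_step: float) -> bcosfire.CosfireFilter:
        size = max(101, 2 * int(math.ceil(rho_max)) + 41)
        size += 1 - size % 2
        proto = bcosfire.make_prototype(kind, width, size)
        return bcosfire.configure_filter(
            proto, sigma, _rho_set(rho_max, rho_step),
            config_threshold=config["filter.config_threshold"], kind=kind, **common,
        )

    f_sym = one("symmetric", config["filter.symmetric.sigma"],
                config["filter.symmetric.rho_max"], config["filter.symmetric.rho_step"])
    f_asym = None
    if config["filter.asymmetric.enabled"]:
        f_asym = one("asymmetric", config["filter.asymmetric.sigma"],
                     config["filter.asymmetric.rho_max"], config["filter.asymmetric.rho_step"])
    return f_sym, f_asym


def _log_stage(name: str, arr: np.ndarray, t0: float) -> None:
    logger.info("%-12s shape=%s range=[%.4g, %.4g] %.2fs",
                name, arr.shape, float(np.min(arr)), float(np.max(arr)), time.perf_counter() - t0)


def run_pipeline(
    img: np.ndarray,
    config: PipelineConfig | None = None,
    fov_override: np.ndarray | None = None,
    gold: np.ndarray | None = None,
    filters: tuple[bcosfire.CosfireFilter, bcosfire.CosfireFilter | None] | None = None,
) -> SegmentationResult:
    """Segment one color fundus image.

    ``fov_override`` takes precedence over the computed luminosity mask.
    If ``gold`` is given, FOV-restricted metrics are attached to the result.
    Pre-built ``filters`` may be passed to amortize configuration over a
    batch; they must match the config.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    green = preprocess.extract_green(img)
    _log_stage("green", green, t0)

    t0 = time.perf_counter()
    tiles = config["clahe.tiles"]
    enhanced = preprocess.clahe(
        green,
        ClaheParams(tiles, tiles, config["clahe.clip_limit"], config["clahe.n_bins"]),
    )
    _log_stage("clahe", enhanced, t0)

    t0 = time.perf_counter()
    if fov_override is not None:
        fov = np.asarray(fov_override, dtype=bool)
        if fov.shape != green.shape:
            raise ContractError("FOV override shape does not match the image")
    else:
        fov = preprocess.compute_fov_mask(
            img, method=config["fov.method"],
            fixed_threshold=config["fov.fixed_threshold"],
            erode_px=config["fov.erode_px"],
        )
    _log_stage("fov", fov, t0)

    masked = preprocess.apply_mask(enhanced, fov)

    # the filters respond to bright bars; fundus vessels are dark on bright,
    # so the filter input is the inverted masked image
    t0 = time.perf_counter()
    if filters is None:
        filters = build_filters(config)
    f_sym, f_asym = filters
    inverted = preprocess.apply_mask(1.0 - masked, fov)
    response = bcosfire.combined_vessel_response(
        inverted, f_sym, f_asym, config["filter.n_orientations"], fov=fov
    )
    _log_stage("bcosfire", response, t0)

    t0 = time.perf_counter()
    tophat = segment.top_hat(response, config["segment.se_size"])
    binary = segment.binarize(tophat, fov, config["segment.threshold"])
    _log_stage("binarize", binary, t0)

    t0 = time.perf_counter()
    params = pp.PostprocessParams(
        min_area=config["postprocess.min_area"],
        max_recovery_iters=config["postprocess.max_recovery_iters"],
    )
    final = pp.postprocess(binary, params)
    _log_stage("postprocess", final, t0)

    result = SegmentationResult(
        final=final,
        fov=fov,
        intermediates={
            "I": masked,
            "I1": response,
            "I2": tophat,
            "I3": binary,
        },
    )
    if gold is not None:
        eval_fov = fov if config["metrics.fov_only"] else np.ones_like(fov, dtype=bool)
        result.metrics = evaluate(final, gold, eval_fov)
    return result


# ---------------------------------------------------------------------------
# Batch evaluation
# ---------------------------------------------------------------------------

_SUMMARY_ROWS = ("average", "maximum", "minimum")


def _pair_by_stem(directory: Path) -> dict[str, Path]:
    files = {}
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in image_io.SUPPORTED_EXTENSIONS:
            files[p.stem] = p
    return files


def _report_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    numeric = ["se", "sp", "acc", "mcc"]
    summary = []
    for name, agg in zip(_SUMMARY_ROWS, ("mean", "max", "min")):
        entry = {"file": name, **{k: getattr(df[k], agg)() for k in numeric}}
        summary.append(entry)
    return pd.concat([df, pd.DataFrame(summary)], ignore_index=True)


def evaluate_predictions(
    pred_dir: str | Path, gold_dir: str | Path, fov_dir: str | Path | None = None
) -> pd.DataFrame:
    """Compare stored prediction maps against gold maps, paired by stem."""
    preds = _pair_by_stem(Path(pred_dir))
    golds = _pair_by_stem(Path(gold_dir))
    fovs = _pair_by_stem(Path(fov_dir)) if fov_dir else {}
    rows = []
    for stem, ppath in preds.items():
        if stem not in golds:
            logger.warning("no gold map for %s: skipped", stem)
            continue
        pred = image_io.read_binary_map(ppath)
        gold = image_io.read_binary_map(golds[stem])
        fov = image_io.read_binary_map(fovs[stem]) if stem in fovs else np.ones_like(gold)
        rep = evaluate(pred, gold, fov)
        rows.append({"file": stem, "tp": rep.counts.tp, "fp": rep.counts.fp,
                     "tn": rep.counts.tn, "fn": rep.counts.fn,
                     "se": rep.se, "sp": rep.sp, "acc": rep.acc, "mcc": rep.mcc})
    if not rows:
        raise ContractError("no prediction/gold pairs matched")
    return _report_frame(rows)


def evaluate_batch(
    image_dir: str | Path,
    gold_dir: str | Path,
    fov_dir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Segment every image in a directory and evaluate against gold maps.

    Images, gold maps and optional FOV masks are paired by filename stem.
    The report has one row per image plus average/maximum/minimum rows;
    dataset aggregates are unweighted means of per-image metrics.
    """
    config = config or PipelineConfig()
    images = _pair_by_stem(Path(image_dir))
    golds = _pair_by_stem(Path(gold_dir))
    fovs = _pair_by_stem(Path(fov_dir)) if fov_dir else {}
    filters = build_filters(config)
    rows = []
    for stem, ipath in images.items():
        if stem not in golds:
            logger.warning("no gold map for %s: skipped", stem)
            continue
        img = image_io.read_color_image(ipath)
        gold = image_io.read_binary_map(golds[stem])
        fov = image_io.read_binary_map(fovs[stem]) if stem in fovs else None
        res = run_pipeline(img, config, fov_override=fov, gold=gold, filters=filters)
        rep = res.metrics
        rows.append({"file": stem, "tp": rep.counts.tp, "fp": rep.counts.fp,
                     "tn": rep.counts.tn, "fn": rep.counts.fn,
                     "se": rep.se, "sp": rep.sp, "acc": rep.acc, "mcc": rep.mcc})
    if not rows:
        raise ContractError("no image/gold pairs matched")
    return _report_frame(rows)
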