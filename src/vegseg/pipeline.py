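"""Three-step analysis orchestration: mask, segment, evaluate.

``run_pipeline`` executes the full protocol on one scene: radiometric
scaling, 10-channel stack assembly, impervious masking on the whole
scene, per-engine segmentation of the pervious pixels (per 800x800 tile
when the scene exceeds the tile size), and -- when a truth label plane is
available -- class assignment, confusion matrices, accuracy metrics and
Gini channel importance. The Davies-Bouldin index is label-free and is
always computed.

A single global seed is fanned out to every stochastic stage through a
fixed counter scheme, so each engine can be re-run independently yet
reproducibly, and the returned manifest is sufficient to reproduce the
run bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .clustering import ClusterConfig, SegmentMap, secondary_class, segment
from .cnn_seg import CnnConfig, cnn_train_segment
from .evaluation import (assign_classes, confusion, davies_bouldin,
                         gini_importance, metrics)
from .indices import IndexParams, build_stack
from .masking import mask_impervious
from .raster_core import CLASS_NAMES, Raster, scale_dn, tile

logger = logging.getLogger("vegseg")

__all__ = ["PipelineConfig", "run_pipeline", "report"]

# sub-seed offsets for the counter-based seed fan-out
_SEED_MASK = 1
_SEED_ENGINE = {"kmeans": 2, "gmm": 3, "cnn": 4}
_SEED_IMPORTANCE = 5


@dataclass
class PipelineConfig:
    """Everything needed to run (and re-run) the three-step analysis."""

    engines: tuple[str, ...] = ("kmeans", "gmm", "cnn")
    cluster_config: ClusterConfig = field(default_factory=ClusterConfig)
    cnn_config: CnnConfig = field(default_factory=CnnConfig)
    index_params: IndexParams = field(default_factory=IndexParams)
    tile_size: int = 800
    seed: int = 0
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        for e in self.engines:
            if e not in ("kmeans", "gmm", "cnn"):
                raise ValueError(f"unknown engine {e!r}")


def _sub_seed(seed: int, offset: int) -> int:
    return (seed * 1009 + offset) % (2 ** 31 - 1)


def run_pipeline(raster: Raster, config: PipelineConfig,
                 truth: np.ndarray | None = None) -> dict:
    """Run mask -> segment -> evaluate on one scene.

    Parameters
    ----------
    raster : 4-band integer Raster (digital numbers).
    truth : optional co-registered class-label plane (-1 excluded);
        enables confusion/metrics/importance. DBI needs no labels and is
        always computed.

    Returns a manifest dict with per-stage results and timings; array
    artifacts (segment maps, soft memberships) are under ``"arrays"``.
    """
    manifest: dict = {
        "seed": config.seed,
        "engines": list(config.engines),
        "index_dialect": config.index_params.formula_dialect,
        "stages": {},
        "arrays": {},
        "failed_stage": None,
    }
    t0 = time.time()
    try:
        scaled = scale_dn(raster)
        stack = build_stack(scaled, config.index_params)
        manifest["stages"]["stack"] = {
            "channels": list(stack.raster.channel_names),
            "degenerate_counts": stack.degenerate_counts,
            "seconds": time.time() - t0,
        }

        t = time.time()
        pmask = mask_impervious(stack, seed=_sub_seed(config.seed, _SEED_MASK))
        manifest["stages"]["mask"] = {
            "kept_fraction": float(pmask.keep.mean()),
            "cluster_means": list(pmask.cluster_means),
            "inertia": pmask.inertia,
            "seed": pmask.seed,
            "seconds": time.time() - t,
        }
        manifest["arrays"]["pervious"] = pmask.keep

        h, w = raster.height, raster.width
        tiled = h > config.tile_size or w > config.tile_size

        for engine in config.engines:
            t = time.time()
            eng_seed = _sub_seed(config.seed, _SEED_ENGINE[engine])
            soft = None
            if engine == "cnn":
                cnn_cfg = CnnConfig(**{**asdict(config.cnn_config), "seed": eng_seed})
                segmap, trace = _run_tiled_cnn(stack, pmask.keep, cnn_cfg, config.tile_size) \
                    if tiled else cnn_train_segment(stack, pmask.keep, cnn_cfg)
                manifest["stages"][f"segment_{engine}"] = {
                    "n_updates": len(trace) if isinstance(trace, list) else None,
                    "final_labels": int(segmap.unique_labels().size),
                }
            else:
                cl_cfg = ClusterConfig(**{**asdict(config.cluster_config), "seed": eng_seed})
                result = segment(stack, pmask.keep, engine, cl_cfg)
                if engine == "gmm":
                    segmap, soft = result
                    manifest["arrays"][f"soft_{engine}"] = soft
                else:
                    segmap = result
                manifest["stages"][f"segment_{engine}"] = {
                    "n_labels": int(segmap.unique_labels().size),
                }
            manifest["arrays"][f"labels_{engine}"] = segmap
            manifest["stages"][f"segment_{engine}"]["seconds"] = time.time() - t

            # label-free validity
            valid = segmap.valid
            X = stack.values[valid]
            lab = segmap.labels[valid]
            if np.unique(lab).size >= 2:
                manifest["stages"][f"segment_{engine}"]["dbi"] = davies_bouldin(X, lab)

            if truth is not None:
                if engine == "cnn":
                    # variable label count: name each segment by its modal
                    # reference class (merging allowed), as in manual
                    # per-segment class assignment
                    from .evaluation import majority_mapping
                    matched = assign_classes(segmap,
                                             majority_mapping(segmap, truth))
                else:
                    matched = assign_classes(segmap, truth)
                manifest["arrays"][f"classes_{engine}"] = matched
                cm = confusion(matched, truth, n_classes=len(CLASS_NAMES))
                rep = metrics(cm)
                manifest["stages"][f"evaluate_{engine}"] = {
                    "confusion": cm.counts.tolist(),
                    "overall_accuracy": rep.overall_accuracy,
                    "recall": rep.recall,
                    "precision": rep.precision,
                    "f1": rep.f1,
                }
                imp = gini_importance(stack, matched,
                                      seed=_sub_seed(config.seed, _SEED_IMPORTANCE))
                manifest["stages"][f"evaluate_{engine}"]["importance"] = imp.coefficients
    except Exception as exc:
        stage = next(reversed(manifest["stages"]), "stack") if manifest["stages"] else "stack"
        manifest["failed_stage"] = {"after": stage, "error": str(exc)}
        raise
    manifest["total_seconds"] = time.time() - t0

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        serializable = {k: v for k, v in manifest.items() if k != "arrays"}
        (out / "manifest.json").write_text(json.dumps(serializable, indent=2))
    return manifest


def _run_tiled_cnn(stack, keep, cnn_cfg, tile_size):
    """Train the CNN per tile (large scenes) and stitch the label planes."""
    from .clustering import MASKED
    grid = tile(stack.raster, tile_size, tile_size)
    labels = np.full(keep.shape, MASKED, dtype=np.int64)
    traces = []
    offset = 0
    for t in grid:
        sub_keep = keep[t.row_off:t.row_off + t.raster.height,
                        t.col_off:t.col_off + t.raster.width]
        if not sub_keep.any():
            continue
        from .indices import ChannelStack
        sub_stack = ChannelStack(raster=t.raster, index_params=IndexParams())
        segmap, trace = cnn_train_segment(sub_stack, sub_keep, cnn_cfg)
        sub = segmap.labels.copy()
        sub[sub != MASKED] += offset  # keep tile label spaces disjoint
        labels[t.row_off:t.row_off + t.raster.height,
               t.col_off:t.col_off + t.raster.width] = sub
        offset = labels.max() + 1
        traces.append(trace)
    return SegmentMap(labels=labels), traces


def report(manifest: dict) -> dict:
    """Assemble summary tables (as column dicts) from a run manifest.

    Returns ``dbi`` (per-engine index + mean), ``accuracy`` (per-engine
    overall), ``per_class`` (recall/precision/F1 rows) and ``importance``
    (10 channel coefficients) tables; missing stages leave gaps flagged
    as None.
    """
    stages = manifest["stages"]
    engines = manifest["engines"]
    dbi_rows = {e: stages.get(f"segment_{e}", {}).get("dbi") for e in engines}
    present = [v for v in dbi_rows.values() if v is not None]
    dbi_rows["mean"] = float(np.mean(present)) if present else None
    acc = {e: stages.get(f"evaluate_{e}", {}).get("overall_accuracy") for e in engines}
    per_class = {}
    for e in engines:
        ev = stages.get(f"evaluate_{e}")
        if ev:
            per_class[e] = {cls: {"recall": ev["recall"][cls],
                                  "precision": ev["precision"][cls],
                                  "f1": ev["f1"][cls]}
                            for cls in ev["recall"]}
        else:
            per_class[e] = None
    importance = {e: stages.get(f"evaluate_{e}", {}).get("importance") for e in engines}
    return {"dbi": dbi_rows, "accuracy": acc, "per_class": per_class,
            "importance": importance}
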