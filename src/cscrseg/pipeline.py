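"""End-to-end segmentation pipeline and its ablation variants.

Variants (the ablation vocabulary used throughout):

* ``LR``        — decomposition on the raw angiography ROI, no use of the
                  fundus image (no vessel inpainting).
* ``LRM``       — the full baseline: multimodal vessel inpainting, then
                  decomposition (M for multimodal).
* ``LRM_to_R``  — region growing seeded by the baseline; the *grown*
                  regions alone form the output.
* ``LRM_plus_R``— the joint framework: union of the baseline mask and the
                  grown regions.

Every variant returns a :class:`~cscrseg.biomarkers.BiomarkerSet` restored
to full-image coordinates, plus a JSON-serializable report carrying the
configuration, per-stage timings and the region table for provenance.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from .biomarkers import BiomarkerSet, binarize_sparse_map, extract_regions, \
    restore_to_full_frame
from .config import RunConfig, T_GRID
from .io import ImagePair, ROIBox
from .lrsd import decompose_block
from .preprocessing import extract_roi, preprocess_fundus
from .region_growing import extract_seed, fuse, grow_all, region_grow
from .vessels import segment_and_inpaint

__all__ = ["PipelineStageError", "run_pipeline", "run_threshold_grid",
           "threshold_grid_masks", "save_report", "load_report", "VARIANTS"]

VARIANTS = ("LR", "LRM", "LRM_to_R", "LRM_plus_R")


class PipelineStageError(RuntimeError):
    """An error raised inside a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


def _staged(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - tag and re-raise
        raise PipelineStageError(stage, exc) from exc


def _decomposition_stage(pair: ImagePair, box: ROIBox, cfg: RunConfig,
                         multimodal: bool) -> dict:
    """Shared front half: ROI -> (optional inpainting) -> LRSD -> regions."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    box.validate_for(pair.shape, min_side=cfg.patch_size)
    I_a, fundus_block = _staged("roi_extraction", extract_roi, pair, box)
    timings["roi_extraction"] = time.perf_counter() - t0

    vessel_mask = None
    if multimodal:
        t0 = time.perf_counter()
        I_c = _staged("fundus_preprocessing", preprocess_fundus,
                      fundus_block, cfg.clahe_clip, cfg.clahe_tiles)
        G_P, vmask = _staged(
            "vessel_inpainting", segment_and_inpaint, I_a, I_c,
            sigma=cfg.log_sigma, half_size=cfg.log_half_size,
            min_area=cfg.vessel_min_area,
            dilate_radius=cfg.vessel_dilate_radius)
        vessel_mask = vmask.mask
        timings["vessel_inpainting"] = time.perf_counter() - t0
    else:
        G_P = I_a

    t0 = time.perf_counter()
    L_map, S_map, result = _staged("lrsd", decompose_block, G_P, cfg)
    timings["lrsd"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    candidate = _staged("binarization", binarize_sparse_map, S_map,
                        cfg.sparse_binarize_rule)
    bset = _staged("region_extraction", extract_regions, candidate,
                   cfg.biomarker_min_area, cfg.max_regions, box)
    for reg in bset.regions:
        reg.seed = extract_seed(reg, S_map, I_a).position
    timings["region_extraction"] = time.perf_counter() - t0

    return {"I_a": I_a, "G_P": G_P, "L_map": L_map, "S_map": S_map,
            "lrsd": result, "bset": bset, "vessel_mask": vessel_mask,
            "timings": timings}


def _rg_masks(stage: dict, cfg: RunConfig, T: float
              ) -> tuple[np.ndarray, np.ndarray]:
    """Grown-only mask and fused mask for one threshold."""
    bset: BiomarkerSet = stage["bset"]
    grown = grow_all(bset, stage["S_map"], stage["I_a"], T,
                     max_area_frac=cfg.rg_max_area_frac)
    rg_union = np.zeros(bset.S_P.shape, dtype=bool)
    for g in grown:
        rg_union |= g.R_pd
    fused = fuse(bset, grown)
    return rg_union, fused


def _finalize(mask_roi: np.ndarray, box: ROIBox, cfg: RunConfig,
              pair_shape: tuple[int, int]) -> BiomarkerSet:
    bset = extract_regions(mask_roi, cfg.biomarker_min_area,
                           cfg.max_regions, box)
    return restore_to_full_frame(bset, pair_shape)


def run_pipeline(pair: ImagePair, box: ROIBox,
                 config: RunConfig | None = None,
                 variant: str = "LRM_plus_R"
                 ) -> tuple[BiomarkerSet, dict]:
    """Run one ablation variant end to end.

    Returns the biomarker set (full-frame coordinates restored) and a
    JSON-serializable report.
    """
    cfg = config or RunConfig()
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; one of {VARIANTS}")
    stage = _decomposition_stage(pair, box, cfg, multimodal=variant != "LR")

    if variant in ("LR", "LRM"):
        final_roi = stage["bset"].S_P
    else:
        rg_union, fused = _staged("region_growing", _rg_masks, stage, cfg,
                                  cfg.threshold)
        final_roi = rg_union if variant == "LRM_to_R" else fused
    bset = _staged("restore", _finalize, final_roi, box, cfg, pair.shape)
    # carry the LRSD seeds through for provenance
    lrsd_seeds = [reg.seed for reg in stage["bset"].regions]

    report = {
        "variant": variant,
        "config": cfg.to_dict(),
        "box": list(box.astuple()),
        "threshold": cfg.threshold if variant in ("LRM_to_R", "LRM_plus_R")
        else None,
        "timings_s": {k: round(v, 4) for k, v in stage["timings"].items()},
        "lrsd": {
            "lambda": stage["lrsd"].lambda_used,
            "mu": stage["lrsd"].mu_used,
            "iterations": stage["lrsd"].iterations,
            "converged": bool(stage["lrsd"].converged),
        },
        "lrsd_seeds_roi": [list(s) for s in lrsd_seeds],
        "n_regions": len(bset),
        "regions": [_region_record(reg) for reg in bset.full_regions],
    }
    return bset, report


def _region_record(reg) -> dict:
    rr, cc = np.nonzero(reg.mask_roi)
    bbox = ([int(rr.min()), int(cc.min()), int(rr.max()) + 1,
             int(cc.max()) + 1] if rr.size else None)
    return {"label": reg.label, "area_px": reg.area_px,
            "centroid": [round(float(reg.centroid[0]), 2),
                         round(float(reg.centroid[1]), 2)],
            "seed": list(reg.seed) if reg.seed is not None else None,
            "bbox": bbox}


def run_threshold_grid(pair: ImagePair, box: ROIBox,
                       config: RunConfig | None = None,
                       T_grid: tuple[float, ...] = T_GRID,
                       variant: str = "LRM_plus_R"
                       ) -> dict[float, BiomarkerSet]:
    """Region growing over a threshold grid with the LRSD stage shared.

    The decomposition (and the seeds it provides) is computed once; only
    the growth/fusion step is repeated per threshold.
    """
    if not T_grid:
        raise ValueError("empty threshold grid")
    if variant not in ("LRM_to_R", "LRM_plus_R"):
        raise ValueError("threshold grid applies to the region-growing "
                         "variants only")
    cfg = config or RunConfig()
    stage = _decomposition_stage(pair, box, cfg, multimodal=True)
    out: dict[float, BiomarkerSet] = {}
    for T in T_grid:
        rg_union, fused = _rg_masks(stage, cfg, T)
        mask = rg_union if variant == "LRM_to_R" else fused
        out[T] = _finalize(mask, box, cfg, pair.shape)
    return out


def threshold_grid_masks(pair: ImagePair, box: ROIBox, cfg: RunConfig,
                         T_grid: tuple[float, ...] = T_GRID
                         ) -> dict[str, dict]:
    """Full-frame masks of all four variants over the grid (LRSD cached).

    The decomposition-only variants do not depend on T; their single mask
    is stored under the key ``None``.
    """
    lr_stage = _decomposition_stage(pair, box, cfg, multimodal=False)
    lrm_stage = _decomposition_stage(pair, box, cfg, multimodal=True)
    shape = pair.shape
    masks: dict[str, dict] = {
        "LR": {None: _finalize(lr_stage["bset"].S_P, box, cfg,
                               shape).full_mask},
        "LRM": {None: _finalize(lrm_stage["bset"].S_P, box, cfg,
                                shape).full_mask},
        "LRM_to_R": {}, "LRM_plus_R": {},
    }
    for T in T_grid:
        rg_union, fused = _rg_masks(lrm_stage, cfg, T)
        masks["LRM_to_R"][T] = _finalize(rg_union, box, cfg,
                                         shape).full_mask
        masks["LRM_plus_R"][T] = _finalize(fused, box, cfg, shape).full_mask
    return masks


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def load_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
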