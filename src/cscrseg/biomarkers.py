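"""Postprocessing of the sparse map into labeled biomarker regions and
restoration of the ROI-frame result to full-image coordinates.

The sparse map carries the hyperfluorescent leakage candidates; it is
binarized, cleaned of speckle by a minimum-area rule, and its 8-connected
components become the biomarker regions (largest first). Because the whole
computation happened inside the operator's ROI, the final step places the
binary result back at the box position so coordinates match the original
acquisition frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import ROIBox

__all__ = [
    "BiomarkerRegion",
    "BiomarkerSet",
    "binarize_sparse_map",
    "extract_regions",
    "restore_to_full_frame",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class BiomarkerRegion:
    label: int
    mask_roi: np.ndarray            # bool, ROI frame, single 8-conn component
    area_px: int
    centroid: tuple[float, float]   # (row, col), ROI frame
    seed: tuple[int, int] | None = None  # filled by the region-growing stage


@dataclass
class BiomarkerSet:
    """Labeled leakage regions plus their union mask S_P.

    ``full_mask`` (and full-frame centroids/seeds) exist only after
    :func:`restore_to_full_frame`.
    """

    regions: list[BiomarkerRegion]
    S_P: np.ndarray                 # bool union mask, ROI frame
    box: ROIBox | None = None
    full_mask: np.ndarray | None = None
    full_regions: list[BiomarkerRegion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)


def binarize_sparse_map(S_map: np.ndarray, rule: str = "adaptive"
                        ) -> np.ndarray:
    """Turn the non-negative sparse map into a binary candidate mask.

    rule "adaptive": threshold at mean + 2 std of the strictly positive
    entries (all-zero map -> empty mask). rule "nonzero": any strictly
    positive entry. The adaptive rule keeps only entries that stand out
    from the residual positive speckle the solver leaves behind.
    """
    S_map = np.asarray(S_map, dtype=np.float64)
    if S_map.size and S_map.min() < 0:
        raise ValueError("sparse map must be non-negative (clip upstream)")
    if rule == "nonzero":
        return S_map > 0
    if rule != "adaptive":
        raise ValueError(f"unknown binarization rule {rule!r}")
    pos = S_map[S_map > 0]
    if pos.size == 0:
        return np.zeros(S_map.shape, dtype=bool)
    thr = pos.mean() + 2.0 * pos.std()
    return S_map > thr


def extract_regions(mask: np.ndarray, min_area: int = 5,
                    max_regions: int | None = None,
                    box: ROIBox | None = None) -> BiomarkerSet:
    """Label the mask's 8-connected components into sorted biomarker regions.

    Components below ``min_area`` pixels are dropped; the survivors are
    sorted by area descending (ties broken by top-most, then left-most
    centroid), relabeled 1..K, and optionally capped at ``max_regions``.
    """
    mask = np.asarray(mask).astype(bool)
    labeled, n = ndimage.label(mask, structure=_EIGHT)
    entries = []
    for lab in range(1, n + 1):
        comp = labeled == lab
        area = int(comp.sum())
        if area < min_area:
            continue
        r, c = np.nonzero(comp)
        centroid = (float(r.mean()), float(c.mean()))
        entries.append((area, centroid, comp))
    entries.sort(key=lambda e: (-e[0], e[1][0], e[1][1]))
    if max_regions is not None:
        entries = entries[:max_regions]
    regions = [BiomarkerRegion(label=i + 1, mask_roi=comp, area_px=area,
                               centroid=centroid)
               for i, (area, centroid, comp) in enumerate(entries)]
    S_P = np.zeros(mask.shape, dtype=bool)
    for reg in regions:
        S_P |= reg.mask_roi
    return BiomarkerSet(regions=regions, S_P=S_P, box=box)


def restore_to_full_frame(bset: BiomarkerSet, image_shape: tuple[int, int]
                          ) -> BiomarkerSet:
    """Place S_P back at the box position in the original image frame."""
    if bset.box is None:
        raise ValueError("BiomarkerSet has no ROI box attached")
    box = bset.box
    h, w = image_shape
    if box.r1 > h or box.c1 > w:
        raise ValueError(f"box {box.astuple()} exceeds image shape {(h, w)}")
    if bset.S_P.shape != (box.height, box.width):
        raise ValueError("S_P shape does not match the box dimensions")
    full = np.zeros((h, w), dtype=bool)
    full[box.r0:box.r1, box.c0:box.c1] = bset.S_P
    off = np.array([box.r0, box.c0])
    full_regions = []
    for reg in bset.regions:
        fmask = np.zeros((h, w), dtype=bool)
        fmask[box.r0:box.r1, box.c0:box.c1] = reg.mask_roi
        seed = (tuple(int(v) for v in (np.array(reg.seed) + off))
                if reg.seed is not None else None)
        full_regions.append(replace(
            reg, mask_roi=fmask,
            centroid=(reg.centroid[0] + box.r0, reg.centroid[1] + box.c0),
            seed=seed))
    bset.full_mask = full
    bset.full_regions = full_regions
    return bset
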