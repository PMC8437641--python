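"""Synthetic multimodal fundus phantoms with pixel-level ground truth.

Clinical angiography/fundus pairs with ophthalmologist annotations are not
publicly available, so this module generates registered phantom pairs that
reproduce the statistical structure the segmentation pipeline relies on:

* a smooth *low-rank* background (a sum of a few separable intensity
  profiles, so its matrix rank is bounded by construction);
* curvilinear vessels, rendered *bright* in angiography and *dark* in the
  fundus green channel (the multimodal asymmetry the method exploits);
* compact hyperfluorescent leakage blobs (isotropic Gaussian bumps) present
  *only* in angiography — fluorescein leakage is invisible in a color
  photograph;
* i.i.d. Gaussian pixel noise in both modalities.

Ground truth for each blob is its half-maximum support, which for a
Gaussian bump of scale sigma is the disk of radius sigma*sqrt(2 ln 2).
Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import ImagePair, ROIBox, save_mask

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "phantom_batch",
    "roi_covering_blobs",
    "write_phantom",
]

_HALF_MAX_FACTOR = math.sqrt(2.0 * math.log(2.0))  # half-max radius / sigma


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom pair.

    ``n_blobs`` may be a fixed count or an inclusive (lo, hi) range sampled
    per phantom. ``background_smoothness`` scales the widths of the separable
    background profiles relative to the image side.
    """

    height: int = 512
    width: int = 512
    n_vessels: int = 6
    vessel_width_px: tuple[int, int] = (3, 7)
    vessel_contrast: float = 0.35
    n_blobs: int | tuple[int, int] = (2, 4)
    blob_sigma_px: tuple[float, float] = (6.0, 12.0)
    macular_radius_px: float = 60.0
    blob_peak_contrast: float = 0.45
    background_smoothness: float = 0.6
    noise_sigma: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        lo = self.n_blobs if isinstance(self.n_blobs, int) else self.n_blobs[0]
        if lo < 0:
            raise ValueError("n_blobs must be >= 0")
        if not (0.0 < self.blob_peak_contrast <= 1.0):
            raise ValueError("blob_peak_contrast must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        sig_hi = self.blob_sigma_px[1]
        if (2 * (math.ceil(3 * sig_hi) + self.macular_radius_px)
                >= min(self.height, self.width)):
            raise ValueError("macular disk plus 3-sigma blob margin does "
                             "not fit inside the image")


@dataclass
class PhantomTruth:
    """Pixel-level ground truth for one phantom."""

    blob_mask: np.ndarray                      # bool, half-max supports
    blob_centers: list[tuple[int, int]]        # (row, col) per blob
    blob_sigmas: list[float]
    vessel_mask: np.ndarray                    # bool
    background: np.ndarray                     # noiseless separable field
    blob_field: np.ndarray                     # noiseless leakage bumps


def _separable_background(h: int, w: int, smooth: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Sum of a constant and 3 separable Gaussian profiles; rank <= 4."""
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    acc = np.zeros((h, w))
    for _ in range(3):
        cr = rng.uniform(0.1, 0.9) * h
        cc = rng.uniform(0.1, 0.9) * w
        sr = smooth * h * rng.uniform(0.5, 1.0)
        sc = smooth * w * rng.uniform(0.5, 1.0)
        amp = rng.uniform(0.4, 1.0)
        acc = acc + amp * (np.exp(-0.5 * ((rows - cr) / sr) ** 2)
                           * np.exp(-0.5 * ((cols - cc) / sc) ** 2))
    rng_span = acc.max() - acc.min()
    if rng_span > 0:
        acc = (acc - acc.min()) / rng_span
    return 0.30 + 0.20 * acc          # values in [0.30, 0.50]


def _draw_vessels(h: int, w: int, spec: PhantomSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Random quadratic Bezier strokes stamped with per-vessel width."""
    mask = np.zeros((h, w), dtype=bool)
    n_samples = 2 * max(h, w)
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    for _ in range(spec.n_vessels):
        # endpoints on two distinct borders so strokes cross the field
        p0 = _border_point(h, w, rng)
        p2 = _border_point(h, w, rng)
        p1 = np.array([rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w])
        pts = ((1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2)
        width = rng.integers(spec.vessel_width_px[0],
                             spec.vessel_width_px[1] + 1)
        radius = max(width / 2.0, 0.5)
        rr = np.round(pts[:, 0]).astype(int)
        cc = np.round(pts[:, 1]).astype(int)
        stamp = np.zeros((h, w), dtype=bool)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        stamp[rr[ok], cc[ok]] = True
        # thicken the centerline to the sampled width
        stamp = ndimage.binary_dilation(
            stamp, structure=_disk(radius))
        mask |= stamp
    return mask


def _border_point(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    side = rng.integers(0, 4)
    u = rng.uniform(0.0, 1.0)
    if side == 0:
        return np.array([0.0, u * (w - 1)])
    if side == 1:
        return np.array([h - 1.0, u * (w - 1)])
    if side == 2:
        return np.array([u * (h - 1), 0.0])
    return np.array([u * (h - 1), w - 1.0])


def _disk(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    y, x = np.ogrid[-r:r + 1, -r:r + 1]
    return (y * y + x * x) <= radius * radius


def _place_blobs(spec: PhantomSpec, vessel_mask: np.ndarray,
                 rng: np.random.Generator
                 ) -> tuple[list[tuple[int, int]], list[float]]:
    """Rejection-sample blob centers inside a 'macular' disk: leakage points
    in CSCR cluster in the macula, so the centers are confined to a random
    disk of radius ``macular_radius_px``, kept inside a 3-sigma border
    margin, mutually separated (disjoint half-max supports), and when
    possible with the half-max disk clear of vessels — leakage sits in
    avascular tissue."""
    h, w = spec.height, spec.width
    if isinstance(spec.n_blobs, int):
        k = spec.n_blobs
    else:
        k = int(rng.integers(spec.n_blobs[0], spec.n_blobs[1] + 1))
    vessel_dist = ndimage.distance_transform_edt(
        ~ndimage.binary_dilation(vessel_mask, iterations=2))
    sig_hi = spec.blob_sigma_px[1]
    margin_hi = int(math.ceil(3.0 * sig_hi))
    rad = spec.macular_radius_px
    mr = rng.uniform(margin_hi + rad, h - margin_hi - rad)
    mc = rng.uniform(margin_hi + rad, w - margin_hi - rad)
    centers: list[tuple[int, int]] = []
    sigmas: list[float] = []
    for _ in range(k):
        sigma = float(rng.uniform(*spec.blob_sigma_px))
        margin = int(math.ceil(3.0 * sigma))
        placed = False
        for attempt in range(600):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            rho = rad * math.sqrt(rng.uniform(0.0, 1.0))
            r = int(round(mr + rho * math.sin(ang)))
            c = int(round(mc + rho * math.cos(ang)))
            if not (margin <= r < h - margin and margin <= c < w - margin):
                continue
            sep_ok = all(
                math.hypot(r - r0, c - c0) >= 1.6 * (sigma + s0)
                for (r0, c0), s0 in zip(centers, sigmas))
            clear = vessel_dist[r, c] >= _HALF_MAX_FACTOR * sigma + 2
            if sep_ok and (clear or attempt >= 450):
                centers.append((r, c))
                sigmas.append(sigma)
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place blobs; spec too crowded")
    return centers, sigmas


def generate_phantom(spec: PhantomSpec) -> tuple[ImagePair, PhantomTruth]:
    """Generate one registered phantom pair plus its ground truth."""
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.height, spec.width

    background = _separable_background(h, w, spec.background_smoothness, rng)
    vessel_mask = _draw_vessels(h, w, spec, rng)
    vessel_soft = ndimage.gaussian_filter(vessel_mask.astype(float), 1.0)

    centers, sigmas = _place_blobs(spec, vessel_mask, rng)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    blob_field = np.zeros((h, w))
    blob_mask = np.zeros((h, w), dtype=bool)
    for (r, c), sigma in zip(centers, sigmas):
        d2 = (rows - r) ** 2 + (cols - c) ** 2
        bump = spec.blob_peak_contrast * np.exp(-0.5 * d2 / sigma ** 2)
        blob_field += bump
        blob_mask |= bump > 0.5 * spec.blob_peak_contrast

    angio = background + spec.vessel_contrast * vessel_soft + blob_field
    green = background - 0.7 * spec.vessel_contrast * vessel_soft
    if spec.noise_sigma > 0:
        angio = angio + rng.normal(0.0, spec.noise_sigma, (h, w))
        green = green + rng.normal(0.0, spec.noise_sigma, (h, w))
    angio = np.clip(angio, 0.0, 1.0)
    green = np.clip(green, 0.0, 1.0)
    fundus = np.stack([
        np.clip(0.55 + 0.35 * background, 0.0, 1.0),  # reddish cast
        green,
        np.clip(0.15 * background, 0.0, 1.0),
    ], axis=-1)
    if spec.noise_sigma > 0:
        jitter = rng.normal(0.0, spec.noise_sigma, fundus.shape)
        jitter[..., 1] = 0.0            # green already carries its noise
        fundus = np.clip(fundus + jitter, 0.0, 1.0)

    pair = ImagePair(angiography=angio, color_fundus=fundus,
                     pixel_size_note="synthetic phantom")
    truth = PhantomTruth(blob_mask=blob_mask, blob_centers=centers,
                         blob_sigmas=sigmas, vessel_mask=vessel_mask,
                         background=background, blob_field=blob_field)
    return pair, truth


def phantom_batch(n: int, spec: PhantomSpec
                  ) -> list[tuple[ImagePair, PhantomTruth]]:
    """Generate ``n`` phantoms with seeds ``rng_seed .. rng_seed + n - 1``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for i in range(n):
        s = PhantomSpec(**{**asdict(spec), "rng_seed": spec.rng_seed + i})
        out.append(generate_phantom(s))
    return out


def roi_covering_blobs(truth: PhantomTruth, shape: tuple[int, int],
                       patch_size: int = 50, pad: int = 20,
                       min_side: int = 160) -> ROIBox:
    """A rectangular ROI enclosing every blob with margin — the phantom
    stand-in for the operator's manual box selection."""
    h, w = shape
    side = max(patch_size, min_side)
    if truth.blob_centers and truth.blob_mask.any():
        rr, cc = np.nonzero(truth.blob_mask)
        r0, r1 = int(rr.min()) - pad, int(rr.max()) + 1 + pad
        c0, c1 = int(cc.min()) - pad, int(cc.max()) + 1 + pad
    else:
        r0, r1 = (h - side) // 2, (h + side) // 2
        c0, c1 = (w - side) // 2, (w + side) // 2
    # grow to the minimum side, then clamp inside the frame
    r0, r1 = _grow_span(r0, r1, side, h)
    c0, c1 = _grow_span(c0, c1, side, w)
    return ROIBox(r0=r0, c0=c0, r1=r1, c1=c1)


def _grow_span(a: int, b: int, min_len: int, limit: int) -> tuple[int, int]:
    if b - a < min_len:
        mid = (a + b) // 2
        a, b = mid - min_len // 2, mid - min_len // 2 + min_len
    a = max(0, min(a, limit - min_len))
    b = min(limit, max(b, a + min_len))
    return a, b


def write_phantom(pair: ImagePair, truth: PhantomTruth, spec: PhantomSpec,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write the pair, truth masks and a JSON sidecar into ``out_dir``."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "angiography": out / "angiography.png",
        "color_fundus": out / "color_fundus.png",
        "blob_mask": out / "truth_blob_mask.png",
        "vessel_mask": out / "truth_vessel_mask.png",
        "sidecar": out / "phantom.json",
    }
    iio.imwrite(paths["angiography"],
                np.round(pair.angiography * 255).astype(np.uint8))
    iio.imwrite(paths["color_fundus"],
                np.round(pair.color_fundus * 255).astype(np.uint8))
    save_mask(truth.blob_mask, paths["blob_mask"])
    save_mask(truth.vessel_mask, paths["vessel_mask"])
    sidecar = {
        "spec": {**asdict(spec),
                 "n_blobs": list(spec.n_blobs)
                 if not isinstance(spec.n_blobs, int) else spec.n_blobs},
        "blob_centers": [list(c) for c in truth.blob_centers],
        "blob_sigmas": truth.blob_sigmas,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths
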