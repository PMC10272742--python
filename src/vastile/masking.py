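"""Tissue- and vascular-mask generation from raw stitched images.

The masking stage turns a raw immunofluorescence image into the two
binary inputs of the quantification pipeline:

* a **tissue mask** — contrast stretch, 3x3 mean smoothing, Huang fuzzy
  thresholding, disk-median filtering and small-particle removal; it is
  the normalisation denominator for all density read-outs and the gate
  that skips empty tiles;
* a **vascular mask** — despeckle, smooth, Gaussian convoluted
  background subtraction, multiplication by the tissue mask, then one of
  three histogram auto-thresholds (IsoData "default", Huang, Otsu).

Thresholding polarity is bright-foreground: pixels strictly greater than
the returned threshold are foreground (dark-field fluorescence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .io_tiling import BinaryMask, CalibratedImage

__all__ = [
    "MaskingParams",
    "histogram256",
    "auto_threshold",
    "make_tissue_mask",
    "gaussian_background_subtract",
    "make_vascular_mask",
    "overlay_validation",
]

logger = logging.getLogger(__name__)

THRESHOLD_METHODS = ("default", "huang", "otsu")


@dataclass
class MaskingParams:
    """User parameters of the masking stage (all lengths in µm).

    median_radius_um
        Disk radius for the median filter that closes small gaps in the
        thresholded tissue mask.
    min_particle_area_um2
        Connected components (8-connected) smaller than this area are
        removed from the tissue mask (e.g. ventricles, debris).
    background_radius_um
        Radius of the biggest object in the image; sets the Gaussian
        scale of the convoluted background subtraction.
    threshold_method
        Auto-threshold for the vascular mask: "default" (iterative
        IsoData), "huang" or "otsu".
    contrast_saturation
        Fraction of pixels saturated by the linear contrast stretch
        (total over both tails).
    sigma_factor
        σ_px = background_radius_um / (sigma_factor * calibration).
    """

    median_radius_um: float = 10.0
    min_particle_area_um2: float = 500.0
    background_radius_um: float = 50.0
    threshold_method: str = "huang"
    save_validation_image: bool = False
    contrast_saturation: float = 0.0035
    sigma_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.median_radius_um <= 0 or self.background_radius_um <= 0:
            raise ValueError("radii must be positive")
        if self.min_particle_area_um2 < 0:
            raise ValueError("min_particle_area_um2 must be nonnegative")
        if self.threshold_method not in THRESHOLD_METHODS:
            raise ValueError(f"threshold_method must be one of {THRESHOLD_METHODS}")


def histogram256(pixels: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of an 8-bit image."""
    return np.bincount(np.asarray(pixels, dtype=np.uint8).ravel(), minlength=256)


# ---------------------------------------------------------------------------
# histogram auto-thresholds
#
# All three methods return an integer cut point t in [0, 255]; pixels
# strictly greater than t are foreground.


def _otsu(hist: np.ndarray) -> int:
    h = hist.astype(np.float64)
    x = np.arange(256.0)
    w0 = np.cumsum(h)[:-1]          # class {0..t}, t = 0..254
    w1 = h.sum() - w0
    m0 = np.cumsum(h * x)[:-1]
    m1 = (h * x).sum() - m0
    valid = (w0 > 0) & (w1 > 0)
    var = np.full(255, -np.inf)
    var[valid] = w0[valid] * w1[valid] * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    return int(np.argmax(var))


def _huang(hist: np.ndarray) -> int:
    # Huang & Wang fuzzy-entropy minimisation: membership of a pixel with
    # value x is 1 / (1 + |x - mu_class| / C), C = occupied intensity span;
    # the threshold minimises the summed Shannon entropy of memberships.
    h = hist.astype(np.float64)
    nz = np.nonzero(h)[0]
    first, last = nz[0], nz[-1]
    if first == last:
        return int(first)
    C = float(last - first)
    x = np.arange(256.0)
    w = np.cumsum(h)
    m = np.cumsum(h * x)
    total_w, total_m = w[-1], m[-1]
    best_t, best_s = 0, np.inf
    for t in range(first, last):
        mu0 = m[t] / w[t]
        mu1 = (total_m - m[t]) / (total_w - w[t])
        mu = np.empty(256)
        mu[: t + 1] = 1.0 / (1.0 + np.abs(x[: t + 1] - mu0) / C)
        mu[t + 1 :] = 1.0 / (1.0 + np.abs(x[t + 1 :] - mu1) / C)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = -(mu * np.log(mu) + (1 - mu) * np.log(1 - mu))
        s[~np.isfinite(s)] = 0.0
        ent = float((h * s).sum())
        if ent < best_s:
            best_s, best_t = ent, t
    return int(best_t)


def _isodata(hist: np.ndarray) -> int:
    # Iterative mean-of-means fixed point: t_{k+1} = round of the average
    # of the two class means split at t_k.
    h = hist.astype(np.float64)
    x = np.arange(256.0)
    nz = np.nonzero(h)[0]
    if nz[0] == nz[-1]:
        return int(nz[0])
    t = int(round((h * x).sum() / h.sum()))
    for _ in range(256):
        lo, hi = h[: t + 1], h[t + 1 :]
        mu0 = (lo * x[: t + 1]).sum() / lo.sum() if lo.sum() > 0 else float(t)
        mu1 = (hi * x[t + 1 :]).sum() / hi.sum() if hi.sum() > 0 else float(t)
        t_new = int(round((mu0 + mu1) / 2.0))
        if t_new == t:
            break
        t = t_new
    return int(t)


def auto_threshold(histogram: np.ndarray, method: str = "default") -> int:
    """Compute an integer threshold in [0, 255] from a 256-bin histogram.

    ``otsu`` maximises the inter-class variance, ``huang`` minimises the
    Huang–Wang fuzzy entropy, ``default`` is the iterative IsoData
    mean-of-means fixed point.  Pixels strictly above the returned value
    are foreground.
    """
    hist = np.asarray(histogram)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be nonnegative")
    if hist.sum() == 0:
        raise ValueError("histogram is empty (all bins zero)")
    nz = np.nonzero(hist)[0]
    if len(nz) == 1:
        logger.info("degenerate single-bin histogram; threshold = %d", nz[0])
        return int(nz[0])
    if method == "otsu":
        return _otsu(hist)
    if method == "huang":
        return _huang(hist)
    if method == "default":
        return _isodata(hist)
    raise ValueError(f"unknown threshold method {method!r}")


# ---------------------------------------------------------------------------
# tissue mask


def _contrast_stretch(pixels: np.ndarray, saturation: float) -> np.ndarray:
    p = pixels.astype(np.float64)
    lo = np.percentile(p, 100.0 * saturation / 2.0)
    hi = np.percentile(p, 100.0 * (1.0 - saturation / 2.0))
    if hi <= lo:
        return pixels.copy()
    out = np.clip((p - lo) * (255.0 / (hi - lo)), 0, 255)
    return np.round(out).astype(np.uint8)


def make_tissue_mask(image: CalibratedImage, params: MaskingParams) -> BinaryMask:
    """Segment tissue from background in a raw stitched image.

    Steps, in order: percentile contrast stretch; 3x3 mean filter; Huang
    fuzzy threshold; disk-median filter of radius ``median_radius_um``;
    removal of 8-connected components below ``min_particle_area_um2``.
    An all-background result is legal (empty tissue).
    """
    cal = image.calibration_um_per_px
    stretched = _contrast_stretch(image.pixels, params.contrast_saturation)
    smoothed = ndimage.uniform_filter(stretched.astype(np.float64), size=3, mode="nearest")
    smoothed = np.round(np.clip(smoothed, 0, 255)).astype(np.uint8)
    t = auto_threshold(histogram256(smoothed), "huang")
    binary = smoothed > t
    r_px = max(1, round(params.median_radius_um / cal))
    footprint = disk(r_px)
    binary = ndimage.median_filter(binary.astype(np.uint8), footprint=footprint, mode="constant") > 0
    min_px = int(np.ceil(params.min_particle_area_um2 / cal**2))
    if min_px > 1:
        lab, n = ndimage.label(binary, structure=np.ones((3, 3)))
        if n:
            areas = np.bincount(lab.ravel(), minlength=n + 1)
            small = areas < min_px  # strictly below the lower range
            small[0] = False
            binary[small[lab]] = False
    return BinaryMask(binary, cal, semantics="tissue", name=image.name)


def gaussian_background_subtract(
    image: CalibratedImage, background_radius_um: float, sigma_factor: float = 2.0
) -> CalibratedImage:
    """Remove slowly varying background by subtracting a Gaussian blur.

    A convoluted copy of the input (Gaussian, σ_px derived from
    ``background_radius_um``) is subtracted from it; negative residuals
    are clamped to zero.  The radius should be based on the radius of
    the biggest object so the blur scale exceeds every vessel width.
    """
    if background_radius_um <= 0:
        raise ValueError("background_radius_um must be positive")
    sigma = background_radius_um / (sigma_factor * image.calibration_um_per_px)
    if sigma < 1.0:
        logger.warning("background radius < 1 px after conversion; flooring σ at 1 px")
        sigma = 1.0
    p = image.pixels.astype(np.float64)
    blurred = ndimage.gaussian_filter(p, sigma=sigma, mode="nearest")
    out = np.clip(p - blurred, 0, 255)
    return CalibratedImage(np.round(out).astype(np.uint8), image.calibration_um_per_px, name=image.name)


def make_vascular_mask(
    image: CalibratedImage, tissue: BinaryMask, params: MaskingParams
) -> BinaryMask:
    """Segment the vasculature inside the tissue mask.

    Steps, in order: 3x3 median despeckle; 3x3 mean smooth; Gaussian
    background subtraction; pixel-wise multiplication by the tissue mask
    (zeroing everything outside tissue); auto-threshold with
    ``params.threshold_method``.  The result is by construction a subset
    of the tissue mask.
    """
    if image.shape != tissue.shape:
        raise ValueError(f"image {image.shape} and tissue mask {tissue.shape} differ in shape")
    if abs(image.calibration_um_per_px - tissue.calibration_um_per_px) > 1e-9:
        raise ValueError("image and tissue mask calibrations differ")
    despeckled = ndimage.median_filter(image.pixels, size=3, mode="nearest")
    smoothed = ndimage.uniform_filter(despeckled.astype(np.float64), size=3, mode="nearest")
    smoothed = CalibratedImage(
        np.round(np.clip(smoothed, 0, 255)).astype(np.uint8), image.calibration_um_per_px
    )
    subtracted = gaussian_background_subtract(
        smoothed, params.background_radius_um, params.sigma_factor
    )
    gated = np.where(tissue.pixels, subtracted.pixels, 0).astype(np.uint8)
    t = auto_threshold(histogram256(gated), params.threshold_method)
    vascular = gated > t
    return BinaryMask(vascular, image.calibration_um_per_px, semantics="vascular", name=image.name)


def overlay_validation(
    image: CalibratedImage, mask: BinaryMask, color: tuple[int, int, int] = (255, 0, 255)
) -> np.ndarray:
    """Superimpose the mask perimeter onto the image for visual QC.

    Returns an (H, W, 3) uint8 RGB array: the grayscale image in all
    channels with the 1-px mask boundary painted in ``color``.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    rgb = np.repeat(image.pixels[:, :, None], 3, axis=2).copy()
    if mask.pixels.any():
        eroded = ndimage.binary_erosion(mask.pixels, structure=np.ones((3, 3)), border_value=0)
        perimeter = mask.pixels & ~eroded
        rgb[perimeter] = color
    return rgb
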