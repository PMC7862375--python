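"""Angiogram binarization operators.

The retinal slabs (SVC, DCC) are binarized by the dual-branch chain used in
quantitative OCTA work: a white top-hat (disk, radius 12 px on the 1024
grid) feeds two branches — (a) single-scale Frangi vesselness followed by
Huang fuzzy-entropy global thresholding, and (b) local median thresholding
(disk, radius 15 px) — and the final flow map keeps only pixels present in
both branches.

The choriocapillaris is binarized by a global threshold set one standard
deviation below the pooled mean intensity of a normative database of young
healthy CC angiograms; pixels below threshold are flow deficits.

Large superficial vessels are masked by smoothing the SVC with a 15x15 px
Gaussian window and thresholding the normalized intensity at 0.4; the mask
excludes those pixels from every slab's metrics downstream.

Pixel-unit defaults refer to the 1024-px / 6-mm grid and are rescaled with
the working grid so the physical operators are resolution-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import frangi, rank
from skimage.morphology import dilation, disk, white_tophat

from .io import EnFaceImage

__all__ = [
    "BinarizationParams",
    "BinarizedMap",
    "NormalCCDatabase",
    "top_hat",
    "hessian_vesselness",
    "huang_threshold",
    "local_median_binarize",
    "plexus_flow",
    "binarize_plexus",
    "cc_threshold_from_normals",
    "binarize_cc",
    "large_vessel_mask",
]

_REF_GRID = 1024  # grid on which the pixel-unit defaults are defined


@dataclass
class BinarizationParams:
    """Operator parameters, in pixels of the working grid."""

    tophat_radius_px: int = 12
    vesselness_sigma_px: float = 2.0
    median_radius_px: int = 15
    lv_gaussian_window_px: float = 15.0
    lv_threshold: float = 0.4
    cc_sd_multiplier: float = 1.0

    @classmethod
    def for_grid(cls, n_px: int) -> "BinarizationParams":
        """Defaults rescaled from the 1024-px reference grid, so the
        operators act at the same physical scale on any grid."""
        f = n_px / _REF_GRID
        return cls(
            tophat_radius_px=max(1, round(12 * f)),
            vesselness_sigma_px=max(0.8, 2.0 * f),
            median_radius_px=max(2, round(15 * f)),
            lv_gaussian_window_px=max(3.0, 15.0 * f),
        )


@dataclass
class BinarizedMap:
    """Binary flow map plus exclusion and validity masks.

    ``flow`` marks vessel/flow pixels (for the CC the deficit map is its
    complement); ``vessel_mask`` marks excluded large-vessel pixels;
    ``valid`` marks pixels inside the registered field.
    """

    flow: np.ndarray
    vessel_mask: np.ndarray
    valid: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        if not (self.flow.shape == self.vessel_mask.shape == self.valid.shape):
            raise ValueError("flow / vessel_mask / valid shapes differ")
        # the exclusion mask is only meaningful inside the valid field
        self.vessel_mask = self.vessel_mask & self.valid

    @property
    def analyzable(self) -> np.ndarray:
        return self.valid & ~self.vessel_mask


@dataclass
class NormalCCDatabase:
    """Normative CC angiograms of young healthy subjects."""

    images: list

    def __post_init__(self) -> None:
        if len(self.images) < 2:
            raise ValueError("a normative database needs at least 2 images")


# ---------------------------------------------------------------------------
# primitive operators


def top_hat(img: np.ndarray, radius_px: int = 12) -> np.ndarray:
    """White top-hat with a disk structuring element: the image minus its
    morphological opening; flattens background, keeps capillary-scale
    bright structure. Output is non-negative."""
    return white_tophat(np.asarray(img, dtype=np.float64), disk(radius_px))


def hessian_vesselness(img: np.ndarray, sigma_px: float = 2.0) -> np.ndarray:
    """Single-scale Frangi vesselness (bright tubes on dark background),
    rescaled to [0, 1]; a constant image maps to zeros.

    Rescaling saturates at the 95th percentile of the positive responses
    rather than the maximum: a handful of very bright arterioles or
    venules would otherwise compress the capillary response range and
    destabilize the downstream global threshold.
    """
    img = np.asarray(img, dtype=np.float64)
    v = frangi(img, sigmas=[sigma_px], black_ridges=False)
    pos = v[v > 0]
    if pos.size == 0:
        return np.zeros_like(v)
    return np.clip(v / np.percentile(pos, 95), 0.0, 1.0)


def _quantize_u8(img: np.ndarray) -> np.ndarray:
    """Map intensities to the 8-bit histogram used by the global threshold.

    Float input in [0, 1] is scaled by 255; integer input is used as-is
    (so thresholds are expressed in native gray levels).
    """
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(np.int64)
    return np.clip(np.round(img * 255), 0, 255).astype(np.int64)


def huang_threshold(img: np.ndarray) -> int:
    """Huang-Wang fuzzy-entropy global threshold on the 8-bit histogram.

    For each candidate level t, pixels are given fuzzy memberships
    mu(g) = 1 / (1 + |g - m| / C) to their class (m is the mean gray level
    of the class the pixel falls in at t; C the gray-level range), and the
    Shannon fuzzy entropy  sum h(g) * S(mu(g))  with
    S(u) = -u ln u - (1-u) ln(1-u)  is accumulated over the histogram.
    The threshold is the level minimizing the entropy; ties take the
    lowest level. A pixel with gray level <= t belongs to the background
    class.

    Raises ValueError on a single-valued histogram (no threshold exists).
    """
    g = _quantize_u8(img)
    gmin, gmax = int(g.min()), int(g.max())
    if gmin == gmax:
        raise ValueError("cannot threshold a single-valued image")
    levels = np.arange(gmin, gmax + 1)
    hist = np.bincount((g - gmin).ravel(), minlength=levels.size).astype(np.float64)
    c = float(gmax - gmin)
    w = hist * levels                      # weighted levels
    cum_h = np.cumsum(hist)
    cum_w = np.cumsum(w)
    tot_h, tot_w = cum_h[-1], cum_w[-1]

    best_t, best_s = None, np.inf
    # candidates t with both classes nonempty
    for i in range(levels.size - 1):
        n0, n1 = cum_h[i], tot_h - cum_h[i]
        if n0 == 0 or n1 == 0:
            continue
        m0 = cum_w[i] / n0
        m1 = (tot_w - cum_w[i]) / n1
        mu = np.empty_like(levels, dtype=np.float64)
        mu[: i + 1] = 1.0 / (1.0 + np.abs(levels[: i + 1] - m0) / c)
        mu[i + 1:] = 1.0 / (1.0 + np.abs(levels[i + 1:] - m1) / c)
        with np.errstate(divide="ignore", invalid="ignore"):
            s_terms = -mu * np.log(mu) - (1 - mu) * np.log(1 - mu)
        s_terms[~np.isfinite(s_terms)] = 0.0   # mu == 1 contributes zero
        s = float(np.dot(hist, s_terms))
        if s < best_s - 1e-12:
            best_s, best_t = s, int(levels[i])
    return best_t


def local_median_binarize(img: np.ndarray, radius_px: int = 15) -> np.ndarray:
    """Local median thresholding: a pixel is foreground iff its value
    strictly exceeds the median of its disk neighborhood (reflection
    padding at the borders).

    The comparison happens on the 8-bit quantized image (the histogram
    granularity global thresholds use as well), which admits a fast
    sliding-histogram median.
    """
    g = _quantize_u8(img)
    if g.min() < 0 or g.max() > 255:
        raise ValueError("local median expects intensities quantizable to 8 bit")
    g8 = g.astype(np.uint8)
    padded = np.pad(g8, radius_px, mode="reflect")
    med = rank.median(padded, disk(radius_px))[
        radius_px:-radius_px, radius_px:-radius_px]
    return g8 > med


# ---------------------------------------------------------------------------
# slab-level operators


def plexus_flow(pixels: np.ndarray, params: BinarizationParams) -> np.ndarray:
    """Dual-branch flow segmentation of a retinal-slab pixel grid.

    Both branches consume the top-hat output; the result is the pixelwise
    AND of the Frangi->Huang branch and the local-median branch.
    """
    th = top_hat(pixels, params.tophat_radius_px)
    vess = hessian_vesselness(th, params.vesselness_sigma_px)
    t = huang_threshold(vess)
    branch_hessian = _quantize_u8(vess) > t
    branch_median = local_median_binarize(th, params.median_radius_px)
    return branch_hessian & branch_median


def binarize_plexus(
    img: EnFaceImage,
    params: BinarizationParams | None = None,
    vessel_mask: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> BinarizedMap:
    """Dual-branch SVC/DCC binarization (see :func:`plexus_flow`)."""
    if params is None:
        params = BinarizationParams.for_grid(img.n_px)
    flow = plexus_flow(img.pixels, params)
    n = img.n_px
    if valid is None:
        valid = np.ones((n, n), dtype=bool)
    if vessel_mask is None:
        vessel_mask = np.zeros((n, n), dtype=bool)
    return BinarizedMap(flow=flow & valid, vessel_mask=vessel_mask,
                        valid=valid, modality=img.modality)


def cc_threshold_from_normals(
    db: NormalCCDatabase, sd_multiplier: float = 1.0, pooling: str = "pixel"
) -> float:
    """Global CC flow threshold from a normative database.

    ``pixel`` pooling (default): mean and SD over all pixels of all normal
    images pooled together; ``image`` pooling: mean and SD computed per
    image, then averaged. Threshold = mean - sd_multiplier * SD; pixels
    below it count as flow deficits.
    """
    if pooling == "pixel":
        pool = np.concatenate([np.ravel(im.pixels) for im in db.images])
        sd = float(pool.std())
        thr = float(pool.mean() - sd_multiplier * sd)
    elif pooling == "image":
        means = np.array([im.pixels.mean() for im in db.images])
        sds = np.array([im.pixels.std() for im in db.images])
        sd = float(sds.mean())
        thr = float(means.mean() - sd_multiplier * sd)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    if sd > 1e-12:
        lo = min(float(np.min(im.pixels)) for im in db.images)
        hi = max(float(np.max(im.pixels)) for im in db.images)
        if not lo < thr < hi:
            raise ValueError(
                f"normative threshold {thr:.4f} outside observed range "
                f"({lo:.4f}, {hi:.4f})")
    return thr


def binarize_cc(
    img: EnFaceImage,
    threshold: float,
    vessel_mask: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> BinarizedMap:
    """Global-threshold CC binarization: flow where intensity >= threshold;
    the flow-deficit fraction downstream is 1 - flow fraction."""
    n = img.n_px
    if valid is None:
        valid = np.ones((n, n), dtype=bool)
    if vessel_mask is None:
        vessel_mask = np.zeros((n, n), dtype=bool)
    flow = (img.pixels >= threshold) & valid
    return BinarizedMap(flow=flow, vessel_mask=vessel_mask, valid=valid,
                        modality=img.modality)


def large_vessel_mask(
    svc: EnFaceImage, params: BinarizationParams | None = None
) -> np.ndarray:
    """Large-vessel exclusion mask from the SVC slab.

    Gaussian smoothing with a WxW window (sigma = W/4, so +-2 sigma spans
    the window), absolute threshold on the normalized intensity, then a
    1 px dilation to cover vessel edges. The same mask excludes pixels in
    all three slabs.
    """
    if params is None:
        params = BinarizationParams.for_grid(svc.n_px)
    sigma = params.lv_gaussian_window_px / 4.0
    smoothed = ndimage.gaussian_filter(svc.pixels, sigma)
    mask = smoothed > params.lv_threshold
    return dilation(mask, disk(1))
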