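"""Angiogram-to-NIR-FAF registration using the superficial vessels.

The large superficial vessels are the only structure visible in both the
SVC angiogram and the NIR-FAF image, so both images are ridge-enhanced at
the large-vessel scale and a similarity transform (translation, rotation,
isotropic scale) is estimated by maximizing normalized cross-correlation
over a coarse-to-fine grid search. The transform estimated on the SVC is
then applied identically to all three slabs: the acquisition is one
volume, so the set moves as a whole.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import frangi

from .io import AngiogramSet, EnFaceImage

__all__ = [
    "SimilarityTransform",
    "RegistrationError",
    "vessel_enhance",
    "estimate_transform",
    "apply_transform",
    "apply_transform_image",
]

ROTATION_BOUNDS_DEG = (-10.0, 10.0)
SCALE_BOUNDS = (0.8, 1.25)

# fixed Frangi structure-sensitivity: with gamma pinned to the intensity
# scale (instead of skimage's per-image adaptive default) weak noise ridges
# produce weak responses in absolute terms
_ENHANCE_GAMMA = 0.02
# responses are divided by max(peak, floor), so structure-free images are
# not stretched to full range
_ENHANCE_FLOOR = 1.0


class RegistrationError(RuntimeError):
    """Raised when no acceptable correlation peak is found."""


@dataclass(frozen=True)
class SimilarityTransform:
    """Similarity transform carrying moving-frame (angiogram) coordinates
    into the fixed frame (NIR-FAF), rotation/scale about the grid center:

    ``x_fixed = scale * R(rotation) @ (x_mov - c) + c + (dx, dy)``
    """

    dx_px: float = 0.0
    dy_px: float = 0.0
    rotation_deg: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (ROTATION_BOUNDS_DEG[0] <= self.rotation_deg <= ROTATION_BOUNDS_DEG[1]):
            raise ValueError(
                f"rotation {self.rotation_deg} deg outside search bounds "
                f"{ROTATION_BOUNDS_DEG}")
        if not (SCALE_BOUNDS[0] <= self.scale <= SCALE_BOUNDS[1]):
            raise ValueError(f"scale {self.scale} outside search bounds {SCALE_BOUNDS}")

    @property
    def is_identity(self) -> bool:
        return (self.dx_px, self.dy_px, self.rotation_deg, self.scale) == (0, 0, 0, 1)

    def inverse(self) -> "SimilarityTransform":
        th = np.deg2rad(self.rotation_deg)
        R_inv = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        t_inv = -(R_inv @ np.array([self.dx_px, self.dy_px])) / self.scale
        return SimilarityTransform(float(t_inv[0]), float(t_inv[1]),
                                   -self.rotation_deg, 1.0 / self.scale)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SimilarityTransform":
        return cls(**json.loads(s))


def vessel_enhance(img: EnFaceImage | np.ndarray,
                   sigma_px: float | None = None) -> np.ndarray:
    """Ridge-enhance large vessels for landmark registration.

    Single-scale Frangi vesselness at sigma matched to >= 50 um vessels
    (default: half the large-vessel width, ~6 px on the 1024 grid for a
    6 mm scan). Output in [0, 1], normalized by ``max(peak, floor)`` with
    an absolute floor so structure-free images are not amplified.
    """
    black_ridges = False
    if isinstance(img, EnFaceImage):
        pixels = img.pixels
        # vessels are dark silhouettes on NIR-FAF, bright flow on OCTA
        black_ridges = img.modality == "NIRFAF"
        if sigma_px is None:
            sigma_px = max(1.5, 35.0 / img.scale_um_per_px)
    else:
        pixels = np.asarray(img, dtype=np.float64)
        if sigma_px is None:
            sigma_px = 6.0
    if np.ptp(pixels) == 0:
        return np.zeros_like(pixels)
    v = frangi(pixels, sigmas=[sigma_px], black_ridges=black_ridges,
               gamma=_ENHANCE_GAMMA)
    return np.clip(v / max(v.max(), _ENHANCE_FLOOR), 0.0, 1.0)


def _warp(pixels: np.ndarray, t: SimilarityTransform, order: int = 1,
          cval: float = 0.0) -> np.ndarray:
    """Resample a moving image into the fixed frame: out(x) = img(T^-1 x)."""
    if t.is_identity:
        return pixels.copy()
    n = pixels.shape[0]
    c = (n - 1) / 2.0
    inv = t.inverse()
    th = np.deg2rad(inv.rotation_deg)
    # scipy works in (row, col) = (y, x); matrix maps output coords to input
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    M = inv.scale * np.array([[R[1, 1], R[1, 0]], [R[0, 1], R[0, 0]]])
    offset = np.array([c + inv.dy_px, c + inv.dx_px]) - M @ np.array([c, c])
    return ndimage.affine_transform(pixels, M, offset=offset, order=order,
                                    mode="constant", cval=cval)


def _best_shift(fixed: np.ndarray, moving: np.ndarray,
                max_shift: int) -> tuple[float, float, float]:
    """FFT cross-correlation of zero-mean images; returns (dx, dy, score)
    with sub-pixel refinement by parabolic interpolation of the peak."""
    f = fixed - fixed.mean()
    m = moving - moving.mean()
    F = np.fft.rfft2(f)
    M = np.fft.rfft2(m)
    corr = np.fft.irfft2(F * np.conj(M), s=f.shape)
    corr = np.fft.fftshift(corr)
    n = f.shape[0]
    c = n // 2
    window = corr[c - max_shift:c + max_shift + 1, c - max_shift:c + max_shift + 1]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    peak = window[iy, ix]

    def _parab(fm, f0, fp):
        d = fm - 2 * f0 + fp
        return 0.0 if d == 0 else 0.5 * (fm - fp) / d

    dy_sub = dx_sub = 0.0
    if 0 < iy < window.shape[0] - 1:
        dy_sub = _parab(window[iy - 1, ix], peak, window[iy + 1, ix])
    if 0 < ix < window.shape[1] - 1:
        dx_sub = _parab(window[iy, ix - 1], peak, window[iy, ix + 1])
    norm = np.sqrt((f * f).sum() * (m * m).sum())
    score = float(peak / norm) if norm > 0 else 0.0
    return (ix - max_shift + dx_sub, iy - max_shift + dy_sub, score)


def estimate_transform(
    moving: EnFaceImage,
    fixed: EnFaceImage,
    max_shift_px: int | None = None,
    ncc_floor: float = 0.2,
    enhance: bool = True,
) -> SimilarityTransform:
    """Estimate the similarity transform aligning ``moving`` (SVC) to
    ``fixed`` (NIR-FAF) by NCC grid search on vessel-enhanced images.

    Coarse-to-fine over rotation and scale within the search bounds;
    translation by FFT cross-correlation with sub-pixel refinement at each
    node. Raises RegistrationError when the best correlation stays below
    ``ncc_floor``.
    """
    mov = vessel_enhance(moving) if enhance else np.asarray(moving.pixels, float)
    fix = vessel_enhance(fixed) if enhance else np.asarray(fixed.pixels, float)
    n = fix.shape[0]
    if max_shift_px is None:
        max_shift_px = n // 8

    def evaluate(rot: float, scale: float):
        warped = _warp(mov, SimilarityTransform(0.0, 0.0, rot, scale))
        dx, dy, score = _best_shift(fix, warped, max_shift_px)
        return score, SimilarityTransform(dx, dy, rot, scale)

    best_score, best_t = -np.inf, None
    for rot in np.arange(ROTATION_BOUNDS_DEG[0], ROTATION_BOUNDS_DEG[1] + 1e-9, 2.0):
        for scale in np.arange(SCALE_BOUNDS[0], SCALE_BOUNDS[1] + 1e-9, 0.05):
            score, t = evaluate(float(np.clip(rot, *ROTATION_BOUNDS_DEG)),
                                float(np.clip(scale, *SCALE_BOUNDS)))
            if score > best_score:
                best_score, best_t = score, t

    # two refinement passes around the incumbent
    for rot_step, scale_step in ((0.5, 0.0125), (0.1, 0.0025)):
        rots = best_t.rotation_deg + rot_step * np.arange(-3, 4)
        scales = best_t.scale + scale_step * np.arange(-3, 4)
        for rot in rots:
            rot = float(np.clip(rot, *ROTATION_BOUNDS_DEG))
            for scale in scales:
                scale = float(np.clip(scale, *SCALE_BOUNDS))
                score, t = evaluate(rot, scale)
                if score > best_score:
                    best_score, best_t = score, t

    if best_score < ncc_floor:
        raise RegistrationError(
            f"registration failed: best NCC {best_score:.3f} below floor {ncc_floor}")
    return best_t


def apply_transform_image(img: EnFaceImage, t: SimilarityTransform
                          ) -> tuple[EnFaceImage, np.ndarray]:
    """Resample one image into the fixed frame (bilinear); returns the
    warped image and the validity mask (False where the sample fell
    outside the acquired field, never silently zero-filled)."""
    warped = _warp(img.pixels, t, order=1)
    inside = _warp(np.ones_like(img.pixels), t, order=0) > 0.5
    return img.with_pixels(warped), inside


def apply_transform(angio: AngiogramSet, t: SimilarityTransform
                    ) -> tuple[AngiogramSet, np.ndarray]:
    """Resample all three slabs into the NIR-FAF frame with one shared
    transform and interpolation; returns the warped set and the common
    validity mask."""
    svc, valid = apply_transform_image(angio.svc, t)
    dcc, _ = apply_transform_image(angio.dcc, t)
    cc, _ = apply_transform_image(angio.cc, t)
    return AngiogramSet(svc=svc, dcc=dcc, cc=cc,
                        signal_strength=angio.signal_strength), valid
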