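"""Synthetic paired NIR-FAF + angiogram cases with known ground truth.

The generator emulates the structures the quantitative pipeline measures in
retinitis pigmentosa maculae:

* a bright preserved-autofluorescence area (APA) with a sharp intensity
  drop at its elliptical border, optionally with a hyperautofluorescent
  ring just inside the border;
* capillary-scale flow texture in the retinal slabs (SVC, DCC) whose
  vessel-area fraction differs inside vs outside the APA by a configurable
  amount per slab;
* choriocapillaris speckle with contiguous dark flow-deficit patches at a
  configurable area fraction per region;
* thick bright superficial vessels crossing the field (identical in a
  patient and its matched control);
* a known similarity misalignment between the angiogram frame and the
  NIR-FAF frame.

Density targets are enforced against an emitted per-pixel ground-truth
label map (exact pixel-count trimming per region), never against the
pipeline's own binarization. Matched controls use the inside-APA density
everywhere. All randomness derives from a single integer seed; identical
seed and parameters give bit-identical images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.morphology import dilation, disk, skeletonize

from .io import AngiogramSet, EnFaceImage, write_image

__all__ = [
    "SyntheticCaseParams",
    "GroundTruth",
    "SyntheticCase",
    "generate_vessel_texture",
    "generate_cc_texture",
    "generate_nirfaf",
    "generate_case",
    "make_normal_cc_database",
    "write_case",
    "write_cohort",
]

DIRECTIONS = ("superior", "inferior", "temporal")

# appearance constants (arbitrary units on the normalized [0,1] scale);
# chosen once so the standard binarization chain resolves the texture
_BG = 0.08           # angiogram background level
# capillary signal above background; the SVC runs dimmer so that only its
# genuinely large vessels survive the 15x15 Gaussian smoothing + 0.4
# absolute threshold of the exclusion mask (mirrors the real-data contrast
# gap between capillaries and arterioles/venules in the superficial slab)
_CAP_AMP = {"SVC": 0.35, "DCC": 0.55}
_LV_LEVEL = 0.95     # large superficial vessel level
_LV_WIDTH_FRAC = 12 / 1024   # large-vessel stroke width as fraction of grid
_LV_SHADOW = 0.55    # fractional NIR-FAF signal loss under a large vessel
_CC_FLOW_MEAN = 0.62
_CC_FLOW_SD = 0.07
_CC_DEFICIT_LEVEL = 0.22

# deterministic child-stream ids
_STREAM = {"web": 1, "keep": 2, "noise": 3, "cc": 4, "cckeep": 5, "lv": 6,
           "nirfaf": 7, "ctrl_noise": 8}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM[stream], extra])


@dataclass
class SyntheticCaseParams:
    """Ground-truth parameters of one synthetic patient/control pair.

    Densities are vessel-area fractions (retinal slabs) or flow-deficit
    area fractions (CC) in [0, 1]; geometry is in millimetres on the scan;
    ``misalignment`` is the similarity transform (dx_px, dy_px,
    rotation_deg, scale) carrying the angiogram frame into the NIR-FAF
    frame.
    """

    image_size_px: int = 1024
    scan_width_mm: float = 6.0
    # ellipse semi-axes (x: temporal-nasal, y: vertical) and center offset
    # from the fovea, all in mm; None means no APA at all
    apa_semi_axes_mm: tuple[float, float] | None = (1.5, 1.0)
    apa_center_offset_mm: tuple[float, float] = (0.0, 0.0)
    vd_inside: dict = field(default_factory=lambda: {"SVC": 0.40, "DCC": 0.42})
    vd_outside: dict = field(default_factory=lambda: {"SVC": 0.37, "DCC": 0.12})
    fd_inside: float = 0.06
    fd_outside: float = 0.11
    large_vessel_count: int = 6
    nirfaf_high: float = 0.75
    nirfaf_low: float = 0.20
    ring_gain: float = 1.0
    ring_width_mm: float = 0.15
    noise_sd: float = 0.03
    misalignment: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 1.0)
    temporal_side: str = "left"
    fovea_xy_px: tuple[float, float] | None = None  # default: grid center
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size_px < 128:
            raise ValueError("image_size_px must be >= 128")
        for dct in (self.vd_inside, self.vd_outside):
            for slab, v in dct.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"vd[{slab}]={v} outside [0,1]")
        for v in (self.fd_inside, self.fd_outside):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fd={v} outside [0,1]")
        if self.temporal_side not in ("left", "right"):
            raise ValueError("temporal_side must be 'left'|'right'")
        if self.apa_semi_axes_mm is not None:
            a, b = self.apa_semi_axes_mm
            if a <= 0 or b <= 0:
                raise ValueError("APA semi-axes must be positive")

    @property
    def scale_um_per_px(self) -> float:
        return 1000.0 * self.scan_width_mm / self.image_size_px

    @property
    def fovea(self) -> tuple[float, float]:
        if self.fovea_xy_px is not None:
            return self.fovea_xy_px
        c = (self.image_size_px - 1) / 2.0
        return (c, c)

    def direction_unit(self, direction: str) -> tuple[float, float]:
        """Unit vector (x, y) of a sampling direction in image coordinates."""
        if direction == "superior":
            return (0.0, -1.0)
        if direction == "inferior":
            return (0.0, 1.0)
        if direction == "temporal":
            return (-1.0, 0.0) if self.temporal_side == "left" else (1.0, 0.0)
        raise ValueError(f"unknown direction {direction!r}")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    apa_present: bool
    apa_mask: np.ndarray | None            # bool grid in the NIR-FAF frame
    edge_distance_mm: dict                 # direction -> float (if present)
    true_vd: dict                          # slab -> {"inside": v, "outside": v}
    true_fd: dict                          # {"inside": f, "outside": f}
    applied_transform: tuple[float, float, float, float]
    seed: int
    vessel_labels: dict = field(default_factory=dict)   # slab -> bool grid
    cc_deficit_label: np.ndarray | None = None
    large_vessel_label: np.ndarray | None = None
    control_vessel_labels: dict = field(default_factory=dict)
    control_cc_deficit_label: np.ndarray | None = None


@dataclass
class SyntheticCase:
    patient: AngiogramSet
    patient_nirfaf: EnFaceImage
    control: AngiogramSet
    control_nirfaf: EnFaceImage
    truth: GroundTruth


# ---------------------------------------------------------------------------
# geometry


def apa_mask_grid(params: SyntheticCaseParams) -> np.ndarray | None:
    """Boolean APA ellipse on the pixel grid (NIR-FAF frame)."""
    if params.apa_semi_axes_mm is None:
        return None
    n = params.image_size_px
    mm = params.scale_um_per_px / 1000.0
    fx, fy = params.fovea
    cx = fx * mm + params.apa_center_offset_mm[0]
    cy = fy * mm + params.apa_center_offset_mm[1]
    a, b = params.apa_semi_axes_mm
    yy, xx = np.mgrid[0:n, 0:n]
    x_mm = xx * mm
    y_mm = yy * mm
    return ((x_mm - cx) / a) ** 2 + ((y_mm - cy) / b) ** 2 <= 1.0


def edge_distances(params: SyntheticCaseParams) -> dict:
    """Distance (mm) from the fovea to the APA border along each direction.

    Solves the ray-ellipse intersection analytically and keeps the
    outermost positive crossing.
    """
    if params.apa_semi_axes_mm is None:
        return {}
    a, b = params.apa_semi_axes_mm
    ox, oy = params.apa_center_offset_mm
    out = {}
    for direction in DIRECTIONS:
        ux, uy = params.direction_unit(direction)
        # ray p(t) = fovea + t*u; ellipse centered at fovea + offset
        dx, dy = -ox, -oy
        A = (ux / a) ** 2 + (uy / b) ** 2
        B = 2 * (dx * ux / a**2 + dy * uy / b**2)
        C = (dx / a) ** 2 + (dy / b) ** 2 - 1.0
        disc = B * B - 4 * A * C
        if disc < 0:
            continue  # ray never crosses the border (fovea outside APA)
        t = (-B + np.sqrt(disc)) / (2 * A)
        if t > 0:
            out[direction] = float(t)
    return out


# ---------------------------------------------------------------------------
# texture primitives


def _smooth_noise(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _capillary_web(rng: np.random.Generator, n: int) -> np.ndarray:
    """Dense curvilinear capillary bed: skeletonized band-pass noise at
    three spatial scales, dilated to capillary width (~18 um), overlaid so
    the web fraction exceeds any realistic density target while individual
    capillaries stay thin and tubular."""
    web = np.zeros((n, n), dtype=bool)
    for sigma in (2.0 * n / 1024, 3.0 * n / 1024, 4.5 * n / 1024):
        f = _smooth_noise(rng, n, max(sigma, 1.0))
        sk = skeletonize(f > np.quantile(f, 0.45))
        web |= dilation(sk, disk(1))
    return web


def _trim_to_targets(web: np.ndarray, keep_field: np.ndarray,
                     region_mask: np.ndarray | None,
                     inside_target: float, outside_target: float) -> np.ndarray:
    """Keep exactly the target number of web pixels per region, ranked by a
    smooth keep-field so removal happens in contiguous patches."""
    n2 = web.size
    label = np.zeros_like(web)
    if region_mask is None:
        regions = [(np.ones_like(web), inside_target)]
    else:
        regions = [(region_mask, inside_target), (~region_mask, outside_target)]
    for mask, target in regions:
        region_n = int(mask.sum())
        if region_n == 0:
            continue
        k = int(round(target * region_n))
        cand = web & mask
        n_cand = int(cand.sum())
        if k > n_cand:
            raise ValueError(
                f"unreachable density target {target:.3f}: web supplies only "
                f"{n_cand / region_n:.3f} of the region"
            )
        if k == 0:
            continue
        vals = keep_field[cand]
        cutoff = np.partition(vals, n_cand - k)[n_cand - k]
        keep = cand & (keep_field >= cutoff)
        # resolve ties at the cutoff to hit the count exactly
        excess = int(keep.sum()) - k
        if excess > 0:
            tie = keep & (keep_field == cutoff)
            idx = np.flatnonzero(tie.ravel())[:excess]
            keep.ravel()[idx] = False
        label |= keep
    return label


def _large_vessels(params: SyntheticCaseParams) -> np.ndarray:
    """Thick bright curvilinear vessels crossing the field (bool label)."""
    n = params.image_size_px
    rng = _rng(params.seed, "lv")
    canvas = np.zeros((n, n), dtype=bool)
    width = max(2, round(_LV_WIDTH_FRAC * n))
    t = np.linspace(0.0, 1.0, 4 * n)
    for _ in range(params.large_vessel_count):
        vertical = rng.random() < 0.5
        c0 = rng.uniform(0.1, 0.9) * n
        c1 = rng.uniform(0.1, 0.9) * n
        amp = rng.uniform(0.03, 0.10) * n
        phase = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(1.0, 2.5)
        along = t * (n - 1)
        across = c0 + (c1 - c0) * t + amp * np.sin(2 * np.pi * freq * t + phase)
        across = np.clip(across, 0, n - 1)
        if vertical:
            rr, cc = along.astype(int), across.astype(int)
        else:
            rr, cc = across.astype(int), along.astype(int)
        canvas[rr, cc] = True
    return dilation(canvas, disk(width // 2))


# ---------------------------------------------------------------------------
# public generators


def generate_vessel_texture(
    params: SyntheticCaseParams,
    slab: str,
    region_mask: np.ndarray | None,
    *,
    vd_inside: float | None = None,
    vd_outside: float | None = None,
    role: str = "patient",
    with_large_vessels: bool | None = None,
) -> tuple[EnFaceImage, np.ndarray]:
    """Retinal-slab angiogram texture hitting per-region density targets.

    Returns the grayscale image and the boolean capillary label map; the
    label-map vessel fraction per region equals the target to within one
    pixel. The SVC additionally carries the shared large-vessel strokes.
    """
    n = params.image_size_px
    if vd_inside is None:
        vd_inside = params.vd_inside[slab]
    if vd_outside is None:
        vd_outside = params.vd_outside[slab]
    slab_extra = {"SVC": 0, "DCC": 1}[slab] + (100 if role == "control" else 0)
    web = _capillary_web(_rng(params.seed, "web", slab_extra), n)
    keep = _smooth_noise(_rng(params.seed, "keep", slab_extra), n, 8.0 * n / 1024)
    label = _trim_to_targets(web, keep, region_mask, vd_inside, vd_outside)

    img = np.full((n, n), _BG)
    img += _CAP_AMP[slab] * ndimage.gaussian_filter(label.astype(float), 0.8 * n / 1024)
    if with_large_vessels is None:
        with_large_vessels = slab == "SVC"
    if with_large_vessels:
        lv = _large_vessels(params)
        img = np.maximum(img, np.where(lv, _LV_LEVEL, 0.0))
    img += params.noise_sd * _rng(params.seed, "noise", slab_extra).standard_normal((n, n))
    img = np.clip(img, 0.0, 1.0)
    en = EnFaceImage(img, params.scale_um_per_px, params.fovea, slab,
                     temporal_side=params.temporal_side, role=role)
    return en, label


def generate_cc_texture(
    params: SyntheticCaseParams,
    region_mask: np.ndarray | None,
    *,
    fd_inside: float | None = None,
    fd_outside: float | None = None,
    role: str = "patient",
) -> tuple[EnFaceImage, np.ndarray]:
    """Choriocapillaris speckle with contiguous dark flow-deficit patches.

    The boolean deficit label map hits the per-region deficit fraction to
    within one pixel.
    """
    n = params.image_size_px
    if fd_inside is None:
        fd_inside = params.fd_inside
    if fd_outside is None:
        fd_outside = params.fd_outside
    extra = 200 if role == "control" else 0
    speckle = _CC_FLOW_MEAN + _CC_FLOW_SD * _smooth_noise(
        _rng(params.seed, "cc", extra), n, 1.2 * n / 1024)
    patch_field = _smooth_noise(_rng(params.seed, "cckeep", extra), n, 4.0 * n / 1024)
    # deficits occupy the lowest-ranked patch-field pixels per region;
    # reuse the trimming machinery on the negated field
    deficit = _trim_to_targets(np.ones((n, n), dtype=bool), -patch_field,
                               region_mask, fd_inside, fd_outside)
    m = ndimage.gaussian_filter(deficit.astype(float), 0.6 * n / 1024)
    img = speckle * (1 - m) + _CC_DEFICIT_LEVEL * m
    img += params.noise_sd * _rng(params.seed, "noise", 2 + extra).standard_normal((n, n))
    img = np.clip(img, 0.0, 1.0)
    en = EnFaceImage(img, params.scale_um_per_px, params.fovea, "CC",
                     temporal_side=params.temporal_side, role=role)
    return en, deficit


def generate_nirfaf(params: SyntheticCaseParams) -> tuple[EnFaceImage, GroundTruth]:
    """NIR-FAF image: bright APA, dark surround, sharp (1 px) border,
    optional hyperautofluorescent ring just inside the border."""
    n = params.image_size_px
    mask = apa_mask_grid(params)
    if mask is None:
        img = np.full((n, n), params.nirfaf_low)
        truth = GroundTruth(False, None, {}, {}, {}, params.misalignment, params.seed)
    else:
        img = np.where(mask, params.nirfaf_high, params.nirfaf_low)
        if params.ring_gain > 1.0:
            ring_px = max(1, round(params.ring_width_mm * 1000 / params.scale_um_per_px))
            inner = ndimage.binary_erosion(mask, disk(ring_px))
            ring = mask & ~inner
            img = np.where(ring, np.minimum(params.nirfaf_high * params.ring_gain, 1.0), img)
        truth = GroundTruth(True, mask, edge_distances(params), {}, {},
                            params.misalignment, params.seed)
    # retinal vessels block the RPE autofluorescence signal and appear as
    # dark silhouettes: the shared landmark structure for registration
    if params.large_vessel_count > 0:
        shadow = ndimage.gaussian_filter(
            _large_vessels(params).astype(float), 0.8 * n / 1024)
        img = img * (1.0 - _LV_SHADOW * np.clip(shadow, 0.0, 1.0))
    if params.noise_sd > 0:
        img = img + params.noise_sd * _rng(params.seed, "nirfaf").standard_normal((n, n))
    img = np.clip(img, 0.0, 1.0)
    en = EnFaceImage(img, params.scale_um_per_px, params.fovea, "NIRFAF",
                     temporal_side=params.temporal_side)
    return en, truth


def _misalign(pixels: np.ndarray, t: tuple[float, float, float, float]) -> np.ndarray:
    """Resample an aligned scene into the misaligned angiogram frame.

    ``t = (dx, dy, rot_deg, scale)`` maps angiogram coordinates to scene
    (NIR-FAF) coordinates about the image center; the acquired angiogram
    is the scene sampled at those mapped positions.
    """
    dx, dy, rot_deg, scale = t
    if (dx, dy, rot_deg, scale) == (0.0, 0.0, 0.0, 1.0):
        return pixels.copy()
    n = pixels.shape[0]
    c = (n - 1) / 2.0
    th = np.deg2rad(rot_deg)
    # (row, col) = (y, x) ordering for scipy.ndimage
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    M = scale * np.array([[R[1, 1], R[1, 0]], [R[0, 1], R[0, 0]]])  # yx-ordered
    offset = np.array([c + dy, c + dx]) - M @ np.array([c, c])
    return ndimage.affine_transform(pixels, M, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def generate_case(params: SyntheticCaseParams, subject_id: str = "case") -> SyntheticCase:
    """One patient (APA deficit + misalignment) and its matched control.

    The control shares the large-vessel anatomy and uses the inside-APA
    densities everywhere (no deficit, uniform-high NIR-FAF); patient
    angiograms are resampled through the misalignment transform relative
    to the NIR-FAF frame.
    """
    region = apa_mask_grid(params)
    nirfaf, truth = generate_nirfaf(params)
    nirfaf.subject_id = subject_id

    slabs = {}
    for slab in ("SVC", "DCC"):
        img, label = generate_vessel_texture(params, slab, region)
        truth.vessel_labels[slab] = label
        slabs[slab] = img
    cc_img, cc_label = generate_cc_texture(params, region)
    truth.cc_deficit_label = cc_label
    truth.large_vessel_label = _large_vessels(params)
    truth.true_vd = {
        slab: {"inside": params.vd_inside[slab], "outside": params.vd_outside[slab]}
        for slab in ("SVC", "DCC")
    }
    truth.true_fd = {"inside": params.fd_inside, "outside": params.fd_outside}

    def _as_set(imgs: dict, sid: str, role: str) -> AngiogramSet:
        out = {}
        for slab, im in imgs.items():
            im = EnFaceImage(im.pixels, params.scale_um_per_px, params.fovea, slab,
                             temporal_side=params.temporal_side,
                             subject_id=sid, role=role)
            out[slab] = im
        return AngiogramSet(svc=out["SVC"], dcc=out["DCC"], cc=out["CC"])

    patient_imgs = {"SVC": slabs["SVC"], "DCC": slabs["DCC"], "CC": cc_img}
    for slab in patient_imgs:
        patient_imgs[slab] = patient_imgs[slab].with_pixels(
            _misalign(patient_imgs[slab].pixels, params.misalignment))
    patient = _as_set(patient_imgs, subject_id, "patient")

    ctrl_imgs = {}
    for slab in ("SVC", "DCC"):
        # equal targets on the patient's region split: the control image is
        # homogeneous, but region-wise trimming pins the label fraction in
        # each region exactly (a global trim would let the within-region
        # fraction wander by the keep-field fluctuation)
        img, label = generate_vessel_texture(
            params, slab, region, vd_inside=params.vd_inside[slab],
            vd_outside=params.vd_inside[slab], role="control")
        truth.control_vessel_labels[slab] = label
        ctrl_imgs[slab] = img
    cimg, clabel = generate_cc_texture(params, region, fd_inside=params.fd_inside,
                                       fd_outside=params.fd_inside, role="control")
    truth.control_cc_deficit_label = clabel
    ctrl_imgs["CC"] = cimg
    control_id = f"{subject_id}-ctrl"
    control = _as_set(ctrl_imgs, control_id, "control")

    n = params.image_size_px
    ctrl_nirfaf_px = np.full((n, n), params.nirfaf_high)
    if params.large_vessel_count > 0:
        shadow = ndimage.gaussian_filter(
            _large_vessels(params).astype(float), 0.8 * n / 1024)
        ctrl_nirfaf_px *= 1.0 - _LV_SHADOW * np.clip(shadow, 0.0, 1.0)
    ctrl_nirfaf_px = np.clip(
        ctrl_nirfaf_px
        + params.noise_sd * _rng(params.seed, "ctrl_noise").standard_normal((n, n)),
        0.0, 1.0)
    control_nirfaf = EnFaceImage(ctrl_nirfaf_px, params.scale_um_per_px, params.fovea,
                                 "NIRFAF", temporal_side=params.temporal_side,
                                 subject_id=control_id, role="control")
    return SyntheticCase(patient, nirfaf, control, control_nirfaf, truth)


def make_normal_cc_database(
    params: SyntheticCaseParams, n_subjects: int = 20, fd: float | None = None
) -> list[EnFaceImage]:
    """CC angiograms of a young healthy normative cohort (uniform
    physiologic deficit fraction, one seed per subject)."""
    if fd is None:
        fd = params.fd_inside
    out = []
    for i in range(n_subjects):
        p = SyntheticCaseParams(**{**params.__dict__,
                                   "seed": int(params.seed) * 1000 + 500 + i})
        img, _ = generate_cc_texture(p, None, fd_inside=fd, fd_outside=fd,
                                     role="control")
        img.subject_id = f"normal-{i:02d}"
        out.append(img)
    return out


# ---------------------------------------------------------------------------
# on-disk cohort layout


def write_case(case: SyntheticCase, out_dir: str | Path) -> list[dict]:
    """Write one case's eight images + sidecars + ground truth; returns the
    two manifest rows."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for angio, nirfaf, role in ((case.patient, case.patient_nirfaf, "patient"),
                                (case.control, case.control_nirfaf, "control")):
        sid = angio.subject_id
        row = {"subject_id": sid, "role": role,
               "control_id": case.control.subject_id if role == "patient" else ""}
        for key, img in {**angio.slabs(), "NIRFAF": nirfaf}.items():
            fname = f"{sid}_{key.lower()}.tiff"
            write_image(img, out_dir / fname)
            row[{"SVC": "svc_path", "DCC": "dcc_path", "CC": "cc_path",
                 "NIRFAF": "nirfaf_path"}[key]] = fname
        rows.append(row)
    t = case.truth
    gt = {
        "apa_present": t.apa_present,
        "edge_distance_mm": t.edge_distance_mm,
        "true_vd": t.true_vd,
        "true_fd": t.true_fd,
        "applied_transform": list(t.applied_transform),
        "seed": t.seed,
    }
    sid = case.patient.subject_id
    (out_dir / f"{sid}_truth.json").write_text(json.dumps(gt, indent=1))
    if t.apa_mask is not None:
        tifffile.imwrite(out_dir / f"{sid}_apa_mask.tiff",
                         t.apa_mask.astype(np.uint8) * 255)
    for slab, label in t.vessel_labels.items():
        tifffile.imwrite(out_dir / f"{sid}_{slab.lower()}_label.tiff",
                         label.astype(np.uint8) * 255)
    if t.cc_deficit_label is not None:
        tifffile.imwrite(out_dir / f"{sid}_cc_label.tiff",
                         t.cc_deficit_label.astype(np.uint8) * 255)
    return rows


def write_cohort(base_params: SyntheticCaseParams, n_cases: int,
                 out_dir: str | Path, seed: int | None = None) -> Path:
    """Generate ``n_cases`` patient-control pairs sharing one parameter set
    (distinct seeds) and write the cohort manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = base_params.seed if seed is None else seed
    rows = []
    for i in range(n_cases):
        p = SyntheticCaseParams(**{**base_params.__dict__, "seed": seed + i})
        case = generate_case(p, subject_id=f"P{i:03d}")
        rows.extend(write_case(case, out_dir))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"
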