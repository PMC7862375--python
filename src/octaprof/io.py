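"""Image and metadata I/O.

Canonical in-memory containers for en-face acquisitions (``EnFaceImage``,
``AngiogramSet``), TIFF/PNG readers and writers with JSON sidecars, and
cohort-manifest validation.

Conventions used throughout the package (stated once, here):

* pixel coordinates are 0-based, ``x`` rightward, ``y`` downward, origin at
  the top-left pixel; rectangles are half-open;
* intensities are normalized to ``[0, 1]`` by dividing by the *dtype*
  maximum (not the per-image maximum), so absolute thresholds such as 0.4
  mean the same thing in every image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

MODALITIES = ("SVC", "DCC", "CC", "NIRFAF")

__all__ = [
    "EnFaceImage",
    "AngiogramSet",
    "LoadError",
    "read_image",
    "write_image",
    "load_subject",
    "quality_gate",
    "validate_manifest",
]


class LoadError(ValueError):
    """Raised when an image, sidecar or manifest cannot be validated."""


@dataclass
class EnFaceImage:
    """One grayscale en-face acquisition plus its physical geometry.

    Parameters
    ----------
    pixels : ndarray
        Square 2-D float array of normalized intensities in ``[0, 1]``.
    scale_um_per_px : float
        Physical scale; a 6-mm field on a 1024 grid gives 5.859 um/px.
    fovea_xy_px : tuple of float
        Fovea center, ``(x, y)`` in pixel coordinates.
    modality : str
        One of ``SVC``, ``DCC``, ``CC``, ``NIRFAF``.
    temporal_side : str
        ``"left"`` or ``"right"``: the image side toward the temporal
        retina (explicit, never inferred from laterality).
    """

    pixels: np.ndarray
    scale_um_per_px: float
    fovea_xy_px: tuple[float, float]
    modality: str
    temporal_side: str = "right"
    eye: str = "OD"
    subject_id: str = ""
    role: str = "patient"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise LoadError(
                f"expected a square 2-D image, got shape {self.pixels.shape}"
            )
        if not self.scale_um_per_px > 0:
            raise LoadError("scale_um_per_px must be positive")
        if self.modality not in MODALITIES:
            raise LoadError(f"unknown modality {self.modality!r}")
        if self.temporal_side not in ("left", "right"):
            raise LoadError(f"temporal_side must be 'left'|'right', got {self.temporal_side!r}")
        n = self.pixels.shape[0]
        fx, fy = self.fovea_xy_px
        if not (0 <= fx < n and 0 <= fy < n):
            raise LoadError(f"fovea {self.fovea_xy_px} outside {n}x{n} grid")

    @property
    def n_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_mm(self) -> float:
        return self.n_px * self.scale_um_per_px / 1000.0

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceImage":
        return replace(self, pixels=pixels)


@dataclass
class AngiogramSet:
    """The three co-acquired angiographic slabs of one eye."""

    svc: EnFaceImage
    dcc: EnFaceImage
    cc: EnFaceImage
    signal_strength: int | None = None

    def __post_init__(self) -> None:
        ims = (self.svc, self.dcc, self.cc)
        shapes = {im.pixels.shape for im in ims}
        if len(shapes) != 1:
            raise LoadError(f"slab grid sizes differ: {sorted(shapes)}")
        scales = {round(im.scale_um_per_px, 6) for im in ims}
        if len(scales) != 1:
            raise LoadError(f"slab scales differ: {sorted(scales)}")
        subjects = {im.subject_id for im in ims}
        if len(subjects) != 1:
            raise LoadError(f"slab subject ids differ: {sorted(subjects)}")

    @property
    def subject_id(self) -> str:
        return self.svc.subject_id

    def slabs(self) -> dict[str, EnFaceImage]:
        return {"SVC": self.svc, "DCC": self.dcc, "CC": self.cc}


# ---------------------------------------------------------------------------
# file round-trips


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(".json")


def write_image(img: EnFaceImage, path: str | Path, dtype: str = "uint16") -> Path:
    """Write an image as grayscale TIFF/PNG plus its JSON sidecar.

    Normalized intensities are expanded to the integer dtype range; the
    16-bit round-trip is lossless to within half a quantization step.
    """
    path = Path(path)
    info = np.iinfo(np.dtype(dtype))
    raw = np.clip(np.round(img.pixels * info.max), 0, info.max).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, raw)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, raw)
    else:
        raise LoadError(f"unsupported image format {path.suffix!r}")
    sidecar = {
        "scale_um_per_px": img.scale_um_per_px,
        "fovea_xy_px": list(img.fovea_xy_px),
        "eye": img.eye,
        "temporal_side": img.temporal_side,
        "modality": img.modality,
        "subject_id": img.subject_id,
        "role": img.role,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


_REQUIRED_SIDECAR = ("scale_um_per_px", "fovea_xy_px", "modality")


def read_image(path: str | Path) -> EnFaceImage:
    """Read a grayscale TIFF/PNG with its JSON sidecar into an EnFaceImage."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"image file not found: {path}")
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise LoadError(f"sidecar not found: {sc_path}")
    meta = json.loads(sc_path.read_text())
    for key in _REQUIRED_SIDECAR:
        if key not in meta:
            raise LoadError(f"sidecar {sc_path} missing required field {key!r}")
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(path)
    else:
        raw = iio.imread(path)
    raw = np.asarray(raw)
    if raw.ndim == 3:  # grayscale stored with a channel axis
        raw = raw[..., 0]
    if not np.issubdtype(raw.dtype, np.integer):
        raise LoadError(f"expected integer grayscale pixels, got {raw.dtype}")
    pixels = raw.astype(np.float64) / np.iinfo(raw.dtype).max
    return EnFaceImage(
        pixels=pixels,
        scale_um_per_px=float(meta["scale_um_per_px"]),
        fovea_xy_px=tuple(float(v) for v in meta["fovea_xy_px"]),
        modality=meta["modality"],
        temporal_side=meta.get("temporal_side", "right"),
        eye=meta.get("eye", "OD"),
        subject_id=meta.get("subject_id", ""),
        role=meta.get("role", "patient"),
    )


# ---------------------------------------------------------------------------
# subjects and manifests


def load_subject(manifest_row: dict | pd.Series, root: str | Path = ".") -> tuple[AngiogramSet, EnFaceImage]:
    """Load the three angiograms and the NIR-FAF image of one subject.

    ``manifest_row`` must carry file paths under keys ``svc_path``,
    ``dcc_path``, ``cc_path``, ``nirfaf_path`` (relative to ``root``).
    """
    root = Path(root)
    imgs = {}
    for key in ("svc_path", "dcc_path", "cc_path", "nirfaf_path"):
        if key not in manifest_row or not str(manifest_row[key]):
            raise LoadError(f"manifest row missing {key!r}")
        imgs[key] = read_image(root / str(manifest_row[key]))
    ssi = manifest_row.get("signal_strength") if hasattr(manifest_row, "get") else None
    if ssi is not None and not pd.isna(ssi):
        ssi = int(ssi)
    else:
        ssi = None
    aset = AngiogramSet(svc=imgs["svc_path"], dcc=imgs["dcc_path"], cc=imgs["cc_path"],
                        signal_strength=ssi)
    nirfaf = imgs["nirfaf_path"]
    if nirfaf.modality != "NIRFAF":
        raise LoadError(f"nirfaf_path points at modality {nirfaf.modality!r}")
    if nirfaf.pixels.shape != aset.svc.pixels.shape:
        raise LoadError("NIR-FAF grid size differs from angiogram grid")
    return aset, nirfaf


def quality_gate(angio: AngiogramSet, min_ssi: int = 7) -> bool:
    """Scan-quality gate on the device signal-strength index.

    Acquisitions are retained only for SSI strictly greater than
    ``min_ssi`` (default ``> 7/10``). A set without a recorded SSI passes
    (synthetic data carries none); callers may warn.
    """
    if angio.signal_strength is None:
        return True
    return angio.signal_strength > min_ssi


_MANIFEST_COLUMNS = (
    "subject_id", "control_id", "role",
    "svc_path", "dcc_path", "cc_path", "nirfaf_path",
)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort manifest: every patient row needs a control row.

    Returns the manifest indexed by subject_id. Raises LoadError on
    missing columns, duplicate subjects, or unpaired patients.
    """
    missing = [c for c in _MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise LoadError(f"manifest missing columns: {missing}")
    if manifest["subject_id"].duplicated().any():
        dupes = manifest.loc[manifest["subject_id"].duplicated(), "subject_id"].tolist()
        raise LoadError(f"duplicate subject ids in manifest: {dupes}")
    by_id = manifest.set_index("subject_id", drop=False)
    patients = by_id[by_id["role"] == "patient"]
    for sid, row in patients.iterrows():
        cid = row["control_id"]
        if pd.isna(cid) or cid not in by_id.index:
            raise LoadError(f"patient {sid!r} has no control pairing (control_id={cid!r})")
        if by_id.loc[cid, "role"] != "control":
            raise LoadError(f"control_id {cid!r} of patient {sid!r} is not a control row")
    return by_id
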