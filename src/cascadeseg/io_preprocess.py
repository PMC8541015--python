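"""CT volume I/O and slice preprocessing.

Raw scanner values are converted to Hounsfield units (HU) with the scanner's
affine calibration, HU = pixel * slope + intercept, then clipped to a
tissue-relevant window and lightly denoised with a Gaussian filter.  Axial
slices whose label masks contain no liver or tumor pixels are dropped from
training sets, and slice/mask pairs can be exported as 8-bit PNG pairs.

Defaults: window (-200, +250) HU — a standard liver window covering
parenchyma and hypodense lesions while suppressing air and most bone — and
Gaussian sigma 1.0 px (truncated at 3 sigma, reflective borders).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

DEFAULT_WINDOW: tuple[float, float] = (-200.0, 250.0)
DEFAULT_SIGMA: float = 1.0

BACKGROUND, LIVER, TUMOR = 0, 1, 2


@dataclass
class CTVolume:
    """Raw scanner voxel grid (Z x H x W) with HU calibration metadata."""

    voxels: np.ndarray
    slope: float
    intercept: float
    case_id: str = "case"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a Z x H x W array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError(f"non-finite voxel values in case {self.case_id}")


@dataclass
class HUSlice:
    """One axial slice in Hounsfield units, with the window applied to it."""

    pixels: np.ndarray
    window: tuple[float, float] = DEFAULT_WINDOW
    case_id: str = "case"
    slice_index: int = 0


@dataclass
class LabelMask:
    """Per-pixel labels: 0 background, 1 liver, 2 tumor."""

    labels: np.ndarray
    case_id: str = "case"
    slice_index: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        bad = set(np.unique(self.labels)) - {BACKGROUND, LIVER, TUMOR}
        if bad:
            raise ValueError(f"labels outside {{0,1,2}}: {sorted(bad)}")


def to_hounsfield(volume: CTVolume) -> np.ndarray:
    """Convert raw scanner values to HU via the affine calibration."""
    if volume.slope is None or volume.intercept is None:
        raise ValueError(f"case {volume.case_id}: slope/intercept not set")
    if volume.slope == 0:
        raise ValueError(f"case {volume.case_id}: slope must be nonzero")
    return volume.voxels.astype(np.float64) * volume.slope + volume.intercept


def window_hu(hu: np.ndarray, low: float = DEFAULT_WINDOW[0],
              high: float = DEFAULT_WINDOW[1]) -> np.ndarray:
    """Clip HU values to [low, high]."""
    if low >= high:
        raise ValueError(f"window low ({low}) must be < high ({high})")
    return np.clip(hu, low, high)


def gaussian_smooth(slc: HUSlice | np.ndarray, sigma: float = DEFAULT_SIGMA):
    """Gaussian denoising; sigma = 0 is the identity. Reflective borders."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    pixels = slc.pixels if isinstance(slc, HUSlice) else np.asarray(slc)
    if sigma == 0:
        out = pixels
    else:
        out = gaussian_filter(pixels.astype(np.float64), sigma=sigma,
                              mode="reflect", truncate=3.0)
    if isinstance(slc, HUSlice):
        return HUSlice(out, slc.window, slc.case_id, slc.slice_index)
    return out


def drop_empty_slices(slices: list, masks: list) -> tuple[list, list]:
    """Keep only pairs whose mask has at least one liver/tumor pixel."""
    if len(slices) != len(masks):
        raise ValueError(f"{len(slices)} slices but {len(masks)} masks")
    kept_s, kept_m = [], []
    for s, m in zip(slices, masks):
        labels = m.labels if isinstance(m, LabelMask) else np.asarray(m)
        if np.any(labels > 0):
            kept_s.append(s)
            kept_m.append(m)
    return kept_s, kept_m


def normalize01(pixels: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Map the window range linearly onto [0, 1]."""
    low, high = window
    return (np.clip(pixels, low, high) - low) / (high - low)


def export_png(slc: HUSlice, mask: LabelMask, out_dir: str | Path) -> tuple[Path, Path]:
    """Write an 8-bit intensity PNG and a raw-label mask PNG pair.

    The window range maps linearly to [0, 255]; mask PNGs store the labels
    verbatim so a read round-trips exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{slc.case_id}_{slc.slice_index:04d}"
    img8 = np.round(normalize01(slc.pixels, slc.window) * 255).astype(np.uint8)
    img_path = out_dir / f"{stem}_img.png"
    mask_path = out_dir / f"{stem}_mask.png"
    Image.fromarray(img8).save(img_path)
    Image.fromarray(mask.labels.astype(np.uint8)).save(mask_path)
    return img_path, mask_path


def read_png_pair(img_path: str | Path, mask_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an exported pair back as (image in [0,1], integer mask)."""
    img = np.asarray(Image.open(img_path), dtype=np.float32) / 255.0
    mask = np.asarray(Image.open(mask_path), dtype=np.uint8)
    return img, mask


def load_nifti_volume(image_path: str | Path, case_id: str | None = None,
                      slope: float = 1.0, intercept: float = 0.0) -> CTVolume:
    """Load a NIfTI image as a CTVolume.

    Slices are taken along the last stored axis (LiTS convention); no
    reorientation is attempted.  nibabel applies any scl_slope/scl_inter
    stored in the header, so the default calibration here is the identity.
    """
    import nibabel as nib

    image_path = Path(image_path)
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj)
    vox = np.moveaxis(data, -1, 0)  # (Z, H, W)
    name = case_id or image_path.name.split(".")[0]
    return CTVolume(vox, slope=slope, intercept=intercept, case_id=name)


def load_nifti_labels(label_path: str | Path) -> np.ndarray:
    import nibabel as nib

    lab = np.asanyarray(nib.load(str(label_path)).dataobj)
    return np.moveaxis(np.rint(lab).astype(np.uint8), -1, 0)


@dataclass
class PreprocessConfig:
    window: tuple[float, float] = DEFAULT_WINDOW
    sigma: float = DEFAULT_SIGMA
    drop_empty: bool = True


def preprocess_volume(volume: CTVolume, labels: np.ndarray,
                      cfg: PreprocessConfig = PreprocessConfig()
                      ) -> tuple[list[HUSlice], list[LabelMask]]:
    """HU conversion -> windowing -> Gaussian smoothing -> empty-slice filter."""
    hu = to_hounsfield(volume)
    slices, masks = [], []
    for z in range(hu.shape[0]):
        win = window_hu(hu[z], *cfg.window)
        slc = HUSlice(win, cfg.window, volume.case_id, z)
        slc = gaussian_smooth(slc, cfg.sigma)
        # re-window: smoothing can ring just past the clip bounds
        slc.pixels = window_hu(slc.pixels, *cfg.window)
        slices.append(slc)
        masks.append(LabelMask(labels[z], volume.case_id, z))
    if cfg.drop_empty:
        slices, masks = drop_empty_slices(slices, masks)
    return slices, masks
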