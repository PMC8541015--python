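"""Synthetic abdominal CT phantoms with liver and tumor labels.

Each phantom slice carries one noisy-edged elliptical "liver" (label 1) on a
darker cluttered background, with zero or more hypodense disk "tumors"
(label 2) strictly inside the liver.  Raw voxel values are stored on the
scanner scale ((HU - intercept) / slope) so the phantoms exercise the same
HU-calibration path as real data.

Lesion patterns follow the clinical stratification used for evaluation:
``large``   one tumor occupying > 10% of the liver region's pixels,
``small``   one tumor at or below that ratio,
``multiple``  at least two disjoint lesions,
``none``    no tumor.
The ratio's denominator counts the whole liver region (labels 1 and 2
together), since lesions lie anatomically within the liver.

Default tissue attenuations: liver 60 +/- 10 HU, tumor 30 +/- 8 HU,
background -100 HU, plus 15 HU global acquisition noise — a plausible
portal-venous-phase contrast ordering with hypodense lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_preprocess import (CTVolume, HUSlice, LabelMask, PreprocessConfig,
                            export_png, normalize01, preprocess_volume,
                            to_hounsfield, window_hu)

PATTERNS = ("large", "small", "multiple", "none")
LARGE_TUMOR_RATIO = 0.10  # tumor/liver pixel-ratio threshold for "large"


class GenerationError(RuntimeError):
    """Raised when a phantom cannot satisfy its spec after bounded retries."""


@dataclass(frozen=True)
class PhantomSpec:
    image_side: int = 512
    liver_hu_mean: float = 60.0
    liver_hu_sd: float = 10.0
    tumor_hu_mean: float = 30.0
    tumor_hu_sd: float = 8.0
    background_hu_mean: float = -100.0
    noise_sd: float = 15.0
    n_tumors: int = 1
    tumor_radius_range: tuple[float, float] | None = None
    liver_axes_range: tuple[float, float] | None = None
    slope: float = 1.0
    intercept: float = -1024.0
    pattern: str = "small"

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        if self.image_side < 16:
            raise ValueError("image_side too small")

    @property
    def axes_range(self) -> tuple[float, float]:
        if self.liver_axes_range is not None:
            return self.liver_axes_range
        return (0.22 * self.image_side, 0.34 * self.image_side)

    @property
    def radius_range(self) -> tuple[float, float]:
        if self.tumor_radius_range is not None:
            return self.tumor_radius_range
        return (0.04 * self.image_side, 0.10 * self.image_side)


def _liver_mask(rng: np.random.Generator, side: int,
                axes_range: tuple[float, float]) -> np.ndarray:
    """Noisy-edged ellipse roughly centred in the frame."""
    a = rng.uniform(*axes_range)
    b = rng.uniform(*axes_range)
    cy = side / 2 + rng.uniform(-0.05, 0.05) * side
    cx = side / 2 + rng.uniform(-0.05, 0.05) * side
    angle = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:side, 0:side]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    theta = np.arctan2(v, u)
    rho = 1.0
    for k in (3, 5, 8):
        rho = rho + rng.uniform(0.0, 0.04) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    return (u / a) ** 2 + (v / b) ** 2 <= rho ** 2


def _disk(side: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def _place_tumor(rng: np.random.Generator, liver: np.ndarray, r: float,
                 forbidden: np.ndarray, tries: int = 60) -> np.ndarray | None:
    """A disk of radius r strictly inside the liver, clear of `forbidden`."""
    # centres must keep the whole disk (plus a 1 px margin) inside the liver
    interior = ndimage.binary_erosion(liver, iterations=max(1, int(np.ceil(r)) + 1))
    ys, xs = np.nonzero(interior)
    if ys.size == 0:
        return None
    for _ in range(tries):
        i = rng.integers(ys.size)
        disk = _disk(liver.shape[0], ys[i], xs[i], r)
        # keep lesions disjoint so component counting is unambiguous
        if not np.any(ndimage.binary_dilation(disk) & forbidden):
            return disk
    return None


def _target_area_fraction(rng: np.random.Generator, pattern: str) -> float:
    if pattern == "large":
        return rng.uniform(0.13, 0.22)
    return rng.uniform(0.02, 0.07)


def _paint(rng: np.random.Generator, spec: PhantomSpec,
           mask: np.ndarray) -> np.ndarray:
    """Raw voxel slice from a label mask."""
    side = spec.image_side
    hu = np.full((side, side), spec.background_hu_mean, dtype=np.float64)
    # low-frequency background clutter (other organs / table)
    clutter = ndimage.gaussian_filter(rng.standard_normal((side, side)),
                                      sigma=side / 12) * 120.0
    hu += np.where(mask == 0, clutter, 0.0)
    liver_px = mask == 1
    tumor_px = mask == 2
    hu[liver_px] = spec.liver_hu_mean + spec.liver_hu_sd * rng.standard_normal(liver_px.sum())
    hu[tumor_px] = spec.tumor_hu_mean + spec.tumor_hu_sd * rng.standard_normal(tumor_px.sum())
    hu += spec.noise_sd * rng.standard_normal((side, side))
    return (hu - spec.intercept) / spec.slope


def generate_slice(spec: PhantomSpec, seed) -> tuple[CTVolume, LabelMask]:
    """Generate one labelled phantom slice; identical seed, identical output."""
    rng = np.random.default_rng(seed)
    max_attempts = 50
    for _ in range(max_attempts):
        liver = _liver_mask(rng, spec.image_side, spec.axes_range)
        area = liver.sum()
        if area < 0.05 * spec.image_side ** 2:
            continue
        mask = np.where(liver, 1, 0).astype(np.uint8)
        if spec.pattern == "none":
            n_wanted = 0
        elif spec.pattern == "multiple":
            n_wanted = int(rng.integers(2, 5))
        else:
            n_wanted = 1
        placed = np.zeros_like(liver)
        ok = True
        for _t in range(n_wanted):
            if spec.pattern == "multiple":
                frac = rng.uniform(0.01, 0.05)
            else:
                frac = _target_area_fraction(rng, spec.pattern)
            r = float(np.sqrt(frac * area / np.pi))
            r = max(r, 1.5)
            disk = _place_tumor(rng, liver, r, placed)
            if disk is None:
                ok = False
                break
            placed |= disk
        if not ok:
            continue
        mask[placed] = 2
        if classify_pattern(mask) != spec.pattern:
            continue
        raw = _paint(rng, spec, mask)
        vol = CTVolume(raw[None], slope=spec.slope, intercept=spec.intercept)
        return vol, LabelMask(mask)
    raise GenerationError(
        f"could not realise pattern {spec.pattern!r} in {max_attempts} attempts")


def classify_pattern(mask, threshold: float = LARGE_TUMOR_RATIO) -> str:
    """Classify a label mask's lesion pattern.

    ``none`` without tumor pixels; ``multiple`` with >= 2 disjoint lesion
    components (8-connectivity in 2-D, 26 in 3-D); otherwise ``large`` when
    tumor pixels exceed `threshold` of the liver region (labels 1 and 2),
    else ``small``.
    """
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    if labels.ndim not in (2, 3):
        raise ValueError("mask must be 2-D or a 3-D stack")
    tumor = labels == 2
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        return "none"
    liver_region = int((labels >= 1).sum())
    if liver_region == n_tumor and not np.any(labels == 1):
        raise ValueError("degenerate mask: tumor pixels without any liver")
    structure = np.ones((3,) * labels.ndim, dtype=bool)
    _, n_comp = ndimage.label(tumor, structure=structure)
    if n_comp >= 2:
        return "multiple"
    return "large" if n_tumor / liver_region > threshold else "small"


def tumor_ratio(mask) -> float:
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    liver_region = int((labels >= 1).sum())
    return float((labels == 2).sum() / liver_region) if liver_region else 0.0


def _pattern_counts(n_cases: int, pattern_mix: dict[str, float]) -> list[str]:
    """Largest-remainder apportionment of patterns over n_cases."""
    total = sum(pattern_mix.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"pattern_mix must sum to 1, got {total}")
    items = [(p, f * n_cases) for p, f in pattern_mix.items() if f > 0]
    counts = {p: int(np.floor(q)) for p, q in items}
    short = n_cases - sum(counts.values())
    for p, q in sorted(items, key=lambda kv: kv[1] - np.floor(kv[1]), reverse=True)[:short]:
        counts[p] += 1
    out: list[str] = []
    for p, c in counts.items():
        out.extend([p] * c)
    return out


def generate_arrays(n_cases: int, pattern_mix: dict[str, float],
                    spec: PhantomSpec, seed: int,
                    preprocess: PreprocessConfig = PreprocessConfig()
                    ) -> tuple[list[np.ndarray], list[np.ndarray], list[str]]:
    """In-memory dataset: preprocessed images in [0,1], masks, pattern labels."""
    assignments = _pattern_counts(n_cases, pattern_mix)
    children = np.random.SeedSequence(seed).spawn(n_cases)
    images, masks, patterns = [], [], []
    for pat, ss in zip(assignments, children):
        vol, mask = generate_slice(replace(spec, pattern=pat), ss)
        slices, ms = preprocess_volume(vol, mask.labels[None], preprocess)
        img = normalize01(slices[0].pixels, preprocess.window)
        images.append(img.astype(np.float32))
        masks.append(ms[0].labels)
        patterns.append(pat)
    return images, masks, patterns


def generate_dataset(n_cases: int, pattern_mix: dict[str, float],
                     spec: PhantomSpec, seed: int, out_dir: str | Path,
                     preprocess: PreprocessConfig = PreprocessConfig()
                     ) -> pd.DataFrame:
    """Write PNG slice/mask pairs plus a TSV manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assignments = _pattern_counts(n_cases, pattern_mix)
    children = np.random.SeedSequence(seed).spawn(n_cases)
    rows = []
    for i, (pat, ss) in enumerate(zip(assignments, children)):
        vol, mask = generate_slice(replace(spec, pattern=pat), ss)
        case = f"phantom{i:04d}"
        hu = window_hu(to_hounsfield(vol)[0], *preprocess.window)
        slc = HUSlice(hu, preprocess.window, case_id=case, slice_index=0)
        lm = LabelMask(mask.labels, case_id=case, slice_index=0)
        export_png(slc, lm, out_dir)
        structure = np.ones((3, 3), dtype=bool)
        _, n_comp = ndimage.label(mask.labels == 2, structure=structure)
        rows.append({"case": case, "slice": 0, "pattern": pat,
                     "tumor_count": int(n_comp),
                     "tumor_ratio": round(tumor_ratio(mask), 6)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
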