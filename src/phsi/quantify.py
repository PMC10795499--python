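"""Texture contrast, masked ROI spectral summaries, and per-band tests.

Contrast is the gray-level co-occurrence (GLCM) contrast of a [0, 1]
image: quantize to ``n_levels`` uniform bins, pool co-occurrence counts of
all configured neighbor offsets into one probability matrix p, and return

    contrast = sum_{i,j} ((i - j) / (n_levels - 1))^2 * p(i, j)

The level-difference normalization puts full-range images in [0, 1]:
a constant image scores 0, a two-level checkerboard against a single
horizontal offset scores 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .polarization import SpectralAxis, StokesCube
from .visualize import RGBImage

logger = logging.getLogger("phsi")

__all__ = [
    "GLCMConfig",
    "ROIMask",
    "SpectralSummary",
    "BandTestResult",
    "glcm_contrast",
    "rgb_to_gray",
    "extract_roi_spectra",
    "per_band_ttest",
]

#: the four standard neighbor displacements (row, col)
DEFAULT_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))

ROI_LABELS = ("collagen", "normal_cell", "tumor_cell", "other")


@dataclass(frozen=True)
class GLCMConfig:
    """Gray-level co-occurrence setup.

    ``directions`` lists the pixel displacements whose co-occurrence
    counts are pooled; with ``symmetric`` each pair is counted in both
    orders, making the contrast invariant to gray-level inversion.
    """

    n_levels: int = 8
    directions: tuple[tuple[int, int], ...] = DEFAULT_DIRECTIONS
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not self.directions:
            raise ValueError("at least one direction is required")
        for d in self.directions:
            if d == (0, 0):
                raise ValueError("offsets must be nonzero")


def _quantize(image: np.ndarray, n_levels: int) -> np.ndarray:
    return np.minimum((image * n_levels).astype(int), n_levels - 1)


def glcm_contrast(image: np.ndarray, config: GLCMConfig | None = None) -> float:
    """GLCM contrast of a single-channel image with values in [0, 1]."""
    config = config or GLCMConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("contrast expects a single-channel 2-D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite-valued")
    if img.min() < -1e-9 or img.max() > 1.0 + 1e-9:
        raise ValueError("image values must lie in [0, 1]")
    img = np.clip(img, 0.0, 1.0)

    levels = config.n_levels
    q = _quantize(img, levels)
    rows, cols = q.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    any_pairs = False
    for dr, dc in config.directions:
        r0, r1 = max(0, -dr), rows - max(0, dr)
        c0, c1 = max(0, -dc), cols - max(0, dc)
        if r1 <= r0 or c1 <= c0:
            continue
        any_pairs = True
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        np.add.at(counts, (a, b), 1)
    if not any_pairs:
        raise ValueError("image is smaller than every configured offset")
    if config.symmetric:
        counts = counts + counts.T
    p = counts / counts.sum()
    i, j = np.indices((levels, levels))
    diff = (i - j) / (levels - 1)
    return float(np.sum(diff * diff * p))


def rgb_to_gray(
    image: RGBImage | np.ndarray,
    weights: Sequence[float] = (0.2126, 0.7152, 0.0722),
) -> np.ndarray:
    """Luminance-weighted grayscale of an RGB image, output in [0, 1]."""
    pixels = image.pixels if isinstance(image, RGBImage) else np.asarray(image, float)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (rows, cols, 3)")
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be three nonnegative values")
    w = w / w.sum()
    return np.clip(pixels @ w, 0.0, 1.0)


@dataclass
class ROIMask:
    """Binary region-of-interest mask with a semantic label."""

    mask: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        self.mask = m.astype(bool)
        if not self.mask.any():
            raise ValueError("ROI mask has no true pixels")
        if self.label not in ROI_LABELS:
            raise ValueError(f"label must be one of {ROI_LABELS}")


@dataclass
class SpectralSummary:
    """Per-band mean and (population) std of one parameter over an ROI."""

    wavelengths_nm: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    n_pixels: np.ndarray
    parameter: str
    label: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths_nm,
                "mean": self.mean,
                "std": self.std,
                "n_pixels": self.n_pixels,
            }
        )


def extract_roi_spectra(
    cube: StokesCube, mask: ROIMask | np.ndarray, parameter: str = "S0"
) -> SpectralSummary:
    """Mean/std spectrum of one Stokes parameter over a binary ROI.

    Normalization-masked (invalid) pixels are excluded band-wise; the
    standard deviation is the population form (divide by n).  An ROI with
    no valid pixel at all is rejected.
    """
    roi = mask if isinstance(mask, ROIMask) else ROIMask(np.asarray(mask), "other")
    if roi.mask.shape != cube.shape[:2]:
        raise ValueError(
            f"mask shape {roi.mask.shape} != cube spatial shape {cube.shape[:2]}"
        )
    data = cube.parameter(parameter)
    effective = roi.mask[:, :, None] & cube.valid_mask() & np.isfinite(data)
    n_pixels = effective.sum(axis=(0, 1))
    if n_pixels.max() == 0:
        raise ValueError("ROI mask is empty after intersecting valid pixels")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(effective, data, 0.0)
        n_safe = np.maximum(n_pixels, 1)
        mean = vals.sum(axis=(0, 1)) / n_safe
        dev2 = np.where(effective, (data - mean[None, None, :]) ** 2, 0.0)
        std = np.sqrt(dev2.sum(axis=(0, 1)) / n_safe)
        mean = np.where(n_pixels > 0, mean, np.nan)
        std = np.where(n_pixels > 0, std, np.nan)
    return SpectralSummary(
        wavelengths_nm=cube.axis.as_array(),
        mean=mean,
        std=std,
        n_pixels=n_pixels,
        parameter=parameter.upper(),
        label=roi.label,
    )


@dataclass
class BandTestResult:
    """Per-band two-sample comparison between two groups of mean spectra."""

    wavelengths_nm: np.ndarray | None
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray | None
    n_a: int
    n_b: int
    variant: str

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t, "p": self.p}
        if self.wavelengths_nm is not None:
            data = {"wavelength_nm": self.wavelengths_nm, **data}
        if self.q is not None:
            data["q_bh"] = self.q
        return pd.DataFrame(data)


def _as_spectrum(obj) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(obj, SpectralSummary):
        return np.asarray(obj.mean, float), np.asarray(obj.wavelengths_nm, float)
    return np.asarray(obj, dtype=float), None


def per_band_ttest(
    group_a: Sequence,
    group_b: Sequence,
    variant: str = "welch",
    fdr: bool = False,
) -> BandTestResult:
    """Two-sample t test at every band between two groups of ROI spectra.

    Each group element is a per-ROI average spectrum (array of per-band
    means, or a SpectralSummary).  ``variant`` is ``'welch'`` (unequal
    variances, default) or ``'student'`` (pooled).  Raw p values are
    reported; ``fdr=True`` adds a Benjamini-Hochberg-adjusted column.
    Bands where both groups have zero variance get t = 0, p = 1.
    """
    if variant not in {"welch", "student"}:
        raise ValueError("variant must be 'welch' or 'student'")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two spectra")

    wavelengths = None
    stacks = []
    for group in (group_a, group_b):
        arrs = []
        for item in group:
            spec, wl = _as_spectrum(item)
            if wl is not None:
                if wavelengths is None:
                    wavelengths = wl
                elif not np.allclose(wavelengths, wl):
                    raise ValueError("spectra are on different band grids")
            arrs.append(spec)
        stacks.append(np.stack(arrs, axis=0))
    a, b = stacks
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups have different numbers of bands")

    import warnings

    with warnings.catch_warnings():
        # zero-variance bands are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=0, equal_var=(variant == "student"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    if degenerate.any():
        logger.info(
            "per_band_ttest: %d band(s) have zero variance in both groups; "
            "p reported as 1", int(degenerate.sum())
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)

    q = None
    if fdr:
        q = stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")
    return BandTestResult(
        wavelengths_nm=wavelengths,
        t=t,
        p=np.clip(p, 0.0, 1.0),
        q=q,
        n_a=a.shape[0],
        n_b=b.shape[0],
        variant=variant,
    )
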