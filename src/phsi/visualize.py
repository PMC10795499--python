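"""Synthetic-RGB rendering of hyperspectral Stokes cubes.

Each output channel is a per-pixel weighted sum of the bands with a
nonnegative spectral response curve (R, G, B) that sums to one, so channel
values are convex combinations of (scaled) band values.  Signed parameter
cubes (S1, S2, S3) are first mapped into [0, 1]; the mapping mode and its
scale are recorded in the image provenance.

The default curves are parametric raised-cosine lobes peaking near 610 nm
(R), 540 nm (G) and 470 nm (B) — a qualitative stand-in for a camera /
human-eye response, fully overridable from a CSV.  No colorimetric
accuracy is claimed; the S0 rendering is an H&E-like analog only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .polarization import SpectralAxis, StokesCube

logger = logging.getLogger("phsi")

__all__ = [
    "ResponseCurves",
    "RGBImage",
    "default_response_curves",
    "load_response_curves",
    "synthesize_rgb",
    "render_stokes",
]

SCALING_MODES = ("symmetric", "minmax", "identity")

#: default scaling per Stokes parameter: total intensity is rendered on its
#: own (divided by its max), signed parameters symmetrically about zero
DEFAULT_PARAM_SCALING = {"S0": "identity", "S1": "symmetric",
                         "S2": "symmetric", "S3": "symmetric"}


@dataclass
class ResponseCurves:
    """Per-band R/G/B weights over a spectral axis.

    Weights must be nonnegative; each curve is normalized to unit sum on
    construction (a curve of all zeros is rejected).
    """

    r_weights: np.ndarray
    g_weights: np.ndarray
    b_weights: np.ndarray
    axis: SpectralAxis

    def __post_init__(self) -> None:
        for name in ("r_weights", "g_weights", "b_weights"):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.shape != (self.axis.n_bands,):
                raise ValueError(f"{name} length {w.size} != n_bands {self.axis.n_bands}")
            if np.any(w < 0):
                raise ValueError(f"{name} has negative weights")
            total = w.sum()
            if total <= 0:
                raise ValueError(f"{name} sums to zero")
            setattr(self, name, w / total)

    def as_matrix(self) -> np.ndarray:
        """(n_bands, 3) weight matrix in R, G, B column order."""
        return np.stack([self.r_weights, self.g_weights, self.b_weights], axis=1)


def _raised_cosine(wl: np.ndarray, peak: float, half_width: float) -> np.ndarray:
    x = np.clip((wl - peak) / half_width, -1.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * x)) * (np.abs((wl - peak) / half_width) <= 1.0)


def default_response_curves(axis: SpectralAxis) -> ResponseCurves:
    """Built-in smooth unimodal curves peaking near 610/540/470 nm."""
    wl = axis.as_array()
    return ResponseCurves(
        r_weights=_raised_cosine(wl, 610.0, 90.0),
        g_weights=_raised_cosine(wl, 540.0, 90.0),
        b_weights=_raised_cosine(wl, 470.0, 90.0),
        axis=axis,
    )


def load_response_curves(path: str, axis: SpectralAxis) -> ResponseCurves:
    """Read curves from CSV columns wavelength_nm, r, g, b.

    Values are linearly interpolated onto the target axis (zero outside
    the tabulated range); negative weights are rejected.
    """
    table = pd.read_csv(path)
    required = {"wavelength_nm", "r", "g", "b"}
    if not required.issubset(table.columns):
        raise ValueError(f"response-curve CSV must have columns {sorted(required)}")
    if (table[["r", "g", "b"]].to_numpy() < 0).any():
        raise ValueError("response-curve CSV contains negative weights")
    table = table.sort_values("wavelength_nm")
    wl = axis.as_array()
    interp = {
        c: np.interp(wl, table["wavelength_nm"], table[c], left=0.0, right=0.0)
        for c in ("r", "g", "b")
    }
    return ResponseCurves(interp["r"], interp["g"], interp["b"], axis)


@dataclass
class RGBImage:
    """(rows, cols, 3) float image in [0, 1] plus rendering provenance."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("RGBImage pixels must be (rows, cols, 3)")
        self.pixels = p
        if not self.provenance:
            raise ValueError("RGBImage provenance must be populated")

    def to_uint8(self) -> np.ndarray:
        return np.round(np.clip(self.pixels, 0.0, 1.0) * 255).astype(np.uint8)


def _scale_cube(cube: np.ndarray, scaling: str, scale: float | None) -> tuple[np.ndarray, float | None]:
    """Map a (possibly signed) cube into nonnegative display range."""
    if scaling == "identity":
        return cube, None
    if scaling == "symmetric":
        a = float(np.nanmax(np.abs(cube))) if scale is None else float(scale)
        if a == 0.0:
            return np.full_like(cube, 0.5), 0.0
        return (cube / a + 1.0) / 2.0, a
    if scaling == "minmax":
        lo = float(np.nanmin(cube))
        hi = float(np.nanmax(cube)) if scale is None else float(scale)
        if hi == lo:
            return np.zeros_like(cube), hi
        return (cube - lo) / (hi - lo), hi
    raise ValueError(f"unknown scaling mode {scaling!r}; choose from {SCALING_MODES}")


def synthesize_rgb(
    cube: np.ndarray,
    curves: ResponseCurves,
    scaling: str = "symmetric",
    parameter: str = "",
    scale: float | None = None,
    clip: bool = True,
) -> RGBImage:
    """Weight a single Stokes-parameter cube into an RGB image.

    Parameters
    ----------
    cube : ndarray, (rows, cols, bands)
        One Stokes parameter.  NaN pixels (normalization-masked) render
        as the value that zero maps to under the scaling mode.
    curves : ResponseCurves
        Per-band channel weights (band count must match).
    scaling : {'symmetric', 'minmax', 'identity'}
        How signed values reach [0, 1] before weighting: ``symmetric``
        maps [-a, a] -> [0, 1] with a = max |value| (zero -> 0.5),
        ``minmax`` stretches [min, max], ``identity`` leaves values as-is.
    scale : float, optional
        Explicit scale ``a`` (symmetric) or max (minmax); makes the
        rendering independent of the data — e.g. stable under cropping.
    clip : bool
        Clip the result to [0, 1] (default).  Disable for linearity
        analysis.
    """
    c = np.asarray(cube, dtype=float)
    if c.ndim != 3:
        raise ValueError("cube must be (rows, cols, bands)")
    if c.shape[2] != curves.axis.n_bands:
        raise ValueError(
            f"cube has {c.shape[2]} bands but curves expect {curves.axis.n_bands}"
        )
    if np.all(np.isnan(c)):
        raise ValueError("cube contains no finite values")
    mapped, used_scale = _scale_cube(c, scaling, scale)
    # masked pixels take the image of zero under the current mapping
    fill = _scale_cube(np.zeros((1, 1, 1)), scaling, used_scale)[0].item()
    mapped = np.where(np.isnan(mapped), fill, mapped)
    channels = mapped @ curves.as_matrix()
    if clip:
        channels = np.clip(channels, 0.0, 1.0)
    return RGBImage(
        channels,
        provenance={"parameter": parameter or "unknown", "scaling": scaling,
                    "scale": used_scale},
    )


def render_stokes(
    cube: StokesCube,
    curves: ResponseCurves | None = None,
    scaling_overrides: dict[str, str] | None = None,
) -> dict[str, RGBImage]:
    """Render all four Stokes parameters with their default scaling modes.

    S0 is divided by its maximum and rendered with identity scaling;
    S1..S3 use symmetric scaling about zero.  Returns a dict keyed
    'S0'..'S3'.
    """
    curves = curves or default_response_curves(cube.axis)
    modes = dict(DEFAULT_PARAM_SCALING)
    if scaling_overrides:
        modes.update(scaling_overrides)
    out: dict[str, RGBImage] = {}
    for par in ("S0", "S1", "S2", "S3"):
        data = cube.parameter(par)
        mode = modes[par]
        if par == "S0" and mode == "identity":
            peak = float(np.nanmax(np.abs(data)))
            data = data / peak if peak > 0 else data
        out[par] = synthesize_rgb(data, curves, scaling=mode, parameter=par)
    return out
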