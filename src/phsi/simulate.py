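"""Synthetic scene generation and virtual acquisition.

Stands in for the microscope hardware: a scene is a per-pixel (optionally
per-band) field of 4x4 Mueller matrices; acquisition propagates
generator-polarized halogen light through the scene and the four analyzer
states and adds seeded detector noise.

Phantoms
--------
* quarter-wave-plate target — uniform retarder, the calibration standard;
* birefringent fiber field — collagen analog: anti-aliased capsule-shaped
  fibers whose fast axis follows the fiber direction, on a neutral
  absorbing background;
* absorbing cell field — H&E analog: nucleus/cytoplasm disks with
  wavelength-dependent transmittance and a small residual nuclear
  retardance, optionally fragmented into disjoint lobes.

Phantom optical constants are illustrative, not tissue-calibrated: the
paper trail for real collagen/cell retardance and dye spectra lives in
histology, not in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .polarization import (
    CANONICAL_STATES,
    AnalyzerState,
    ElementImageSet,
    SpectralAxis,
    analyzer_mueller,
    mueller_linear_polarizer,
    mueller_retarder,
)

logger = logging.getLogger("phsi")

__all__ = [
    "Scene",
    "IlluminationSpec",
    "NoiseSpec",
    "FiberPhantomParams",
    "CellPhantomParams",
    "halogen_spectrum",
    "clear_scene",
    "make_qwp_scene",
    "make_fiber_scene",
    "make_cell_scene",
    "simulate_acquisition",
]


def halogen_spectrum(axis: SpectralAxis) -> np.ndarray:
    """Smooth broad halogen-like source spectrum, peak normalized to 1.

    The exact shape is arbitrary (it cancels in all S0-normalized
    quantities); a wide Gaussian peaking toward the red mimics a tungsten
    halogen lamp over 470-750 nm.
    """
    wl = axis.as_array()
    return np.exp(-0.5 * ((wl - 640.0) / 180.0) ** 2)


@dataclass
class IlluminationSpec:
    """Source spectrum plus generator polarizer axis (45 deg by default)."""

    source_spectrum: np.ndarray | None = None
    generator_axis_deg: float = 45.0

    def spectrum(self, axis: SpectralAxis) -> np.ndarray:
        if self.source_spectrum is None:
            return halogen_spectrum(axis)
        spec = np.asarray(self.source_spectrum, dtype=float)
        if spec.shape != (axis.n_bands,):
            raise ValueError(
                f"source spectrum length {spec.size} != n_bands {axis.n_bands}"
            )
        if np.any(spec < 0):
            raise ValueError("source spectrum must be nonnegative")
        return spec


@dataclass
class NoiseSpec:
    """Detector noise model; identical spec + seed reproduce exactly.

    ``poisson_gaussian`` draws shot noise at ``photon_scale`` expected
    counts per unit intensity, then adds Gaussian read noise of std
    ``read_sigma`` (intensity units).  ``gaussian`` adds read noise only.
    """

    model: str = "poisson_gaussian"
    read_sigma: float = 1e-3
    photon_scale: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in {"none", "gaussian", "poisson_gaussian"}:
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.read_sigma < 0 or self.photon_scale <= 0:
            raise ValueError("read_sigma must be >= 0 and photon_scale > 0")

    def apply(self, intensity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.model == "none":
            return intensity.copy()
        out = intensity.astype(float)
        if self.model == "poisson_gaussian":
            counts = rng.poisson(np.clip(out, 0.0, None) * self.photon_scale)
            out = counts / self.photon_scale
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, size=out.shape)
        return out


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """A spatial (x spectral) field of Mueller matrices describing a sample.

    ``mueller_field`` is (rows, cols, 4, 4) for achromatic samples or
    (rows, cols, n_bands, 4, 4) for dispersive/absorbing ones.
    """

    mueller_field: np.ndarray
    axis: SpectralAxis
    description: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mueller_field, dtype=float)
        if m.ndim not in (4, 5) or m.shape[-2:] != (4, 4):
            raise ValueError("mueller_field must be (rows, cols[, bands], 4, 4)")
        if m.ndim == 5 and m.shape[2] != self.axis.n_bands:
            raise ValueError(
                f"mueller_field has {m.shape[2]} bands, axis has {self.axis.n_bands}"
            )
        if np.any(m[..., 0, 0] < 0):
            raise ValueError("passive elements need m[0,0] >= 0")
        self.mueller_field = m

    @property
    def per_band(self) -> bool:
        return self.mueller_field.ndim == 5

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.mueller_field.shape[:2]

    def field_per_band(self) -> np.ndarray:
        """The field broadcast to (rows, cols, n_bands, 4, 4)."""
        if self.per_band:
            return self.mueller_field
        return np.broadcast_to(
            self.mueller_field[:, :, None, :, :],
            self.spatial_shape + (self.axis.n_bands, 4, 4),
        )

    def max_passivity_excess(self, n_samples: int = 200, seed: int = 0) -> float:
        """Worst relative excess of output polarized power over S0^2.

        Applies every matrix to ``n_samples`` random fully/partially
        polarized unit-S0 Stokes vectors; passive scenes return <= ~1e-12.
        """
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        dop = rng.uniform(0.0, 1.0, size=(n_samples, 1))
        stokes = np.concatenate([np.ones((n_samples, 1)), dop * v], axis=1)
        m = self.mueller_field.reshape(-1, 4, 4)
        out = np.einsum("mij,nj->mni", m, stokes)
        s0 = out[..., 0]
        pol2 = np.sum(out[..., 1:] ** 2, axis=-1)
        return float(np.max(pol2 - s0**2))


def clear_scene(shape: tuple[int, int], axis: SpectralAxis) -> Scene:
    """Empty field of view: identity Mueller matrix at every pixel."""
    rows, cols = shape
    m = np.zeros((rows, cols, 4, 4))
    m[..., range(4), range(4)] = 1.0
    return Scene(m, axis, description="clear (identity) scene")


def make_qwp_scene(
    fast_axis_deg: float, shape: tuple[int, int], axis: SpectralAxis
) -> Scene:
    """Uniform quarter-wave-plate calibration target (achromatic)."""
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError("scene shape must be positive")
    m = mueller_retarder(fast_axis_deg, np.pi / 2.0)
    field = np.broadcast_to(m, (rows, cols, 4, 4)).copy()
    return Scene(field, axis, description=f"QWP target, fast axis {fast_axis_deg} deg")


# ---------------------------------------------------------------------------
# tissue phantoms
# ---------------------------------------------------------------------------

@dataclass
class FiberPhantomParams:
    """Birefringent fiber (collagen analog) phantom parameters.

    Transmittances are scalars or per-band arrays in [0, 1]; matched
    background/fiber transmittance makes the fibers invisible in S0 while
    their retardance still imprints on S1..S3.  ``density='sparse'``
    quarters the fiber count.
    """

    n_fibers: int = 12
    retardance_max_rad: float = 0.6
    fiber_width_px: float = 3.0
    length_px: float = 40.0
    background_transmittance: float | np.ndarray = 0.9
    fiber_transmittance: float | np.ndarray = 0.9
    density: str = "dense"
    preferred_orientation_deg: float | None = None
    orientation_jitter_deg: float = 15.0

    def __post_init__(self) -> None:
        if self.retardance_max_rad < 0:
            raise ValueError("retardance_max_rad must be >= 0")
        for name in ("background_transmittance", "fiber_transmittance"):
            t = np.asarray(getattr(self, name), dtype=float)
            if np.any(t < 0) or np.any(t > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.density not in {"dense", "sparse"}:
            raise ValueError("density must be 'dense' or 'sparse'")

    @property
    def effective_n_fibers(self) -> int:
        if self.density == "sparse":
            return max(1, self.n_fibers // 4)
        return self.n_fibers


def _capsule_coverage(
    rows: int, cols: int, p0: np.ndarray, p1: np.ndarray, width: float
) -> np.ndarray:
    """Anti-aliased coverage in [0,1] of a capsule (segment + radius)."""
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    d = p1 - p0
    seg2 = float(d @ d)
    if seg2 == 0.0:
        t = np.zeros((rows, cols))
    else:
        t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / seg2
        t = np.clip(t, 0.0, 1.0)
    nr = p0[0] + t * d[0]
    nc = p0[1] + t * d[1]
    dist = np.hypot(rr - nr, cc - nc)
    # 1 px linear edge ramp around the nominal half-width
    return np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0)


def _transmittance_field(
    t_bg: np.ndarray, t_fg: np.ndarray, coverage: np.ndarray, axis: SpectralAxis
) -> np.ndarray:
    """Blend background/foreground transmittance; (rows, cols, bands)."""
    t_bg = np.broadcast_to(np.atleast_1d(t_bg), (axis.n_bands,))
    t_fg = np.broadcast_to(np.atleast_1d(t_fg), (axis.n_bands,))
    cov = coverage[:, :, None]
    return (1.0 - cov) * t_bg + cov * t_fg


def make_fiber_scene(
    params: FiberPhantomParams,
    shape: tuple[int, int],
    axis: SpectralAxis,
    seed: int = 0,
) -> Scene:
    """Random field of birefringent capsule fibers on a neutral background.

    Each fiber is an attenuating linear retarder whose fast axis follows
    the fiber direction; retardance ramps with the anti-aliased coverage
    up to ``retardance_max_rad``.  Fibers reaching past the image edge are
    clipped, not rejected.  Identical (params, shape, axis, seed) always
    reproduce the same scene.
    """
    rows, cols = shape
    rng = np.random.default_rng(seed)
    coverage = np.zeros((rows, cols))
    orientation = np.zeros((rows, cols))

    for _ in range(params.effective_n_fibers):
        center = rng.uniform([0, 0], [rows, cols])
        if params.preferred_orientation_deg is None:
            theta = rng.uniform(0.0, 180.0)
        else:
            theta = params.preferred_orientation_deg + rng.normal(
                0.0, params.orientation_jitter_deg
            )
        length = params.length_px * rng.uniform(0.6, 1.4)
        # image rows grow downward, so a +theta polarization axis runs
        # along (-sin theta, +cos theta) in (row, col) pixel steps
        d = 0.5 * length * np.array([-np.sin(np.deg2rad(theta)), np.cos(np.deg2rad(theta))])
        cov = _capsule_coverage(rows, cols, center - d, center + d, params.fiber_width_px)
        stronger = cov > coverage
        orientation = np.where(stronger, theta, orientation)
        coverage = np.maximum(coverage, cov)

    retardance = params.retardance_max_rad * coverage
    ret = mueller_retarder(orientation, retardance)  # (rows, cols, 4, 4)
    trans = _transmittance_field(
        np.asarray(params.background_transmittance, dtype=float),
        np.asarray(params.fiber_transmittance, dtype=float),
        coverage,
        axis,
    )
    achromatic = np.allclose(trans, trans[:, :, :1])
    if achromatic:
        field = trans[:, :, 0, None, None] * ret
    else:
        field = trans[:, :, :, None, None] * ret[:, :, None, :, :]
    return Scene(field, axis, description=f"fiber phantom ({params.density}), seed {seed}")


@dataclass
class CellPhantomParams:
    """Absorbing cell (H&E analog) phantom parameters.

    Absorbance spectra are per-band attenuations in [0, 1] with a stated
    peak; defaults peak near 550 nm (hematoxylin-like).  ``fragmentation``
    splits each nucleus into disjoint lobes.
    """

    n_cells: int = 8
    nucleus_radius_px: float = 4.0
    cytoplasm_radius_px: float = 9.0
    nucleus_absorbance_spectrum: np.ndarray | None = None
    cytoplasm_absorbance_spectrum: np.ndarray | None = None
    absorption_peak_nm: float = 550.0
    nucleus_retardance_rad: float = 0.05
    nucleus_orientation_deg: float | None = None  # None -> random per cell
    fragmentation: bool = False

    def absorbances(self, axis: SpectralAxis) -> tuple[np.ndarray, np.ndarray]:
        wl = axis.as_array()
        lobe = np.exp(-0.5 * ((wl - self.absorption_peak_nm) / 60.0) ** 2)
        nuc = (
            np.asarray(self.nucleus_absorbance_spectrum, dtype=float)
            if self.nucleus_absorbance_spectrum is not None
            else 0.7 * lobe
        )
        cyt = (
            np.asarray(self.cytoplasm_absorbance_spectrum, dtype=float)
            if self.cytoplasm_absorbance_spectrum is not None
            else 0.3 * lobe
        )
        for name, a in (("nucleus", nuc), ("cytoplasm", cyt)):
            if a.shape != (axis.n_bands,):
                raise ValueError(f"{name} absorbance length != n_bands")
            if np.any(a < 0) or np.any(a > 1):
                raise ValueError(f"{name} absorbance must lie in [0, 1]")
        return nuc, cyt


def _disk_coverage(rows: int, cols: int, center: np.ndarray, radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    dist = np.hypot(rr - center[0], cc - center[1])
    return np.clip(radius + 0.5 - dist, 0.0, 1.0)


def make_cell_scene(
    params: CellPhantomParams,
    shape: tuple[int, int],
    axis: SpectralAxis,
    seed: int = 0,
) -> Scene:
    """Random field of absorbing cells with small nuclear retardance."""
    rows, cols = shape
    rng = np.random.default_rng(seed)
    nuc_abs, cyt_abs = params.absorbances(axis)

    nuc_cov = np.zeros((rows, cols))
    cyt_cov = np.zeros((rows, cols))
    nuc_orient = np.zeros((rows, cols))

    for _ in range(params.n_cells):
        center = rng.uniform([0, 0], [rows, cols])
        cyt_cov = np.maximum(
            cyt_cov, _disk_coverage(rows, cols, center, params.cytoplasm_radius_px)
        )
        if params.nucleus_orientation_deg is None:
            theta = rng.uniform(0.0, 180.0)
        else:
            theta = params.nucleus_orientation_deg
        if params.fragmentation:
            n_lobes = rng.integers(2, 5)
            lobe_r = params.nucleus_radius_px / 1.8
            for _ in range(n_lobes):
                off = rng.uniform(-1.0, 1.0, size=2) * params.nucleus_radius_px * 1.6
                cov = _disk_coverage(rows, cols, center + off, lobe_r)
                nuc_orient = np.where(cov > nuc_cov, theta, nuc_orient)
                nuc_cov = np.maximum(nuc_cov, cov)
        else:
            cov = _disk_coverage(rows, cols, center, params.nucleus_radius_px)
            nuc_orient = np.where(cov > nuc_cov, theta, nuc_orient)
            nuc_cov = np.maximum(nuc_cov, cov)

    # per-pixel, per-band transmittance: cytoplasm absorbs where covered,
    # nucleus absorbs on top of it
    trans = (1.0 - cyt_cov[:, :, None] * cyt_abs) * (1.0 - nuc_cov[:, :, None] * nuc_abs)
    ret = mueller_retarder(nuc_orient, params.nucleus_retardance_rad * nuc_cov)
    field = trans[:, :, :, None, None] * ret[:, :, None, :, :]
    return Scene(field, axis, description=f"cell phantom, seed {seed}")


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------

def generator_stokes(illum: IlluminationSpec, axis: SpectralAxis) -> np.ndarray:
    """Per-band Stokes vector delivered to the sample, shape (n_bands, 4)."""
    gen = mueller_linear_polarizer(illum.generator_axis_deg)
    unpolarized = np.array([1.0, 0.0, 0.0, 0.0])
    base = gen @ unpolarized
    return illum.spectrum(axis)[:, None] * base


def sample_exit_stokes(scene: Scene, illum: IlluminationSpec | None = None) -> np.ndarray:
    """Noiseless Stokes field after the sample, (rows, cols, bands, 4).

    This is the oracle the element-image reconstruction must recover.
    """
    illum = illum or IlluminationSpec()
    s_in = generator_stokes(illum, scene.axis)
    if scene.per_band:
        return np.einsum("rcbij,bj->rcbi", scene.mueller_field, s_in)
    return np.einsum("rcij,bj->rcbi", scene.mueller_field, s_in)


def simulate_acquisition(
    scene: Scene,
    illum: IlluminationSpec | None = None,
    states: Sequence[AnalyzerState] = CANONICAL_STATES,
    noise: NoiseSpec | None = None,
) -> ElementImageSet:
    """Virtual acquisition of the four element-image cubes.

    Per pixel, band and analyzer state the ideal intensity is the S0
    component of analyzer_chain @ M_scene @ S_generator; noise (if any) is
    applied afterwards, one stream per acquisition in the fixed state
    order (ih, iv, i45, irc).
    """
    if len(states) != 4:
        raise ValueError("exactly four analyzer states are required")
    illum = illum or IlluminationSpec()
    exit_field = sample_exit_stokes(scene, illum)

    rng = None
    if noise is not None and noise.model != "none":
        rng = np.random.default_rng(noise.seed)

    cubes = []
    for state in states:
        row = analyzer_mueller(state)[0]
        ideal = exit_field @ row
        if noise is None or noise.model == "none":
            cubes.append(ideal)
        else:
            cubes.append(noise.apply(ideal, rng))
    return ElementImageSet(cubes[0], cubes[1], cubes[2], cubes[3], scene.axis)
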