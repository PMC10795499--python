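"""Mueller/Stokes algebra for the dual-LCVR full-Stokes analyzer.

The instrument model is a polarization state generator (linear polarizer,
transmission axis 45 deg by default) ahead of the sample, and an analyzer
behind it consisting of LCVR 1 (fast axis 0 deg, retardance delta1),
LCVR 2 (fast axis 45 deg, retardance delta2) and a linear polarizer at
0 deg. Four analyzer states produce the element images Ih, Iv, I45, Irc,
from which the Stokes parameters are reconstructed per pixel and band::

    S0 = Ih + Iv
    S1 = Ih - Iv
    S2 = 2*I45 - (Ih + Iv)
    S3 = 2*Irc - (Ih + Iv)

Sign convention
---------------
Linear retarders use the standard textbook Mueller matrix (for fast axis
``t`` and retardance ``d``, the S3 row is ``[0, s*sin d, -c*sin d, cos d]``
with ``c = cos 2t``, ``s = sin 2t``).  Under this convention a quarter-wave
plate at fast-axis angle theta turns +45 deg linear light into
``(1, sin2t*cos2t, sin^2 2t, -cos2t)``, and the right-circular analyzer
state must be ``(delta1, delta2) = (0, -pi/2)`` so that
``Irc = (S0 + S3)/2`` and the reconstruction above returns the true
sample-exit S3.  With the opposite choice ``delta2 = +pi/2`` the
reconstructed S3 flips sign and the quarter-wave calibration curves come
out as ``+cos2t`` instead of ``-cos2t``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger("phsi")

__all__ = [
    "SpectralAxis",
    "AnalyzerState",
    "STATE_H",
    "STATE_V",
    "STATE_P45",
    "STATE_RC",
    "CANONICAL_STATES",
    "ElementImageSet",
    "StokesCube",
    "mueller_linear_polarizer",
    "mueller_retarder",
    "mueller_rotator",
    "analyzer_mueller",
    "analyzer_intensity",
    "compute_stokes",
    "normalize_stokes",
    "count_physicality_violations",
]

# physicality slack used when counting noise-induced violations
_PHYS_TOL = 1e-12


# ---------------------------------------------------------------------------
# spectral axis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralAxis:
    """Band-center wavelengths of a hyperspectral cube, in nanometres.

    Wavelengths must be strictly increasing.  The full instrument axis is
    470-750 nm in 97 bands (:meth:`default`); :meth:`test_scale` gives a
    coarse 21-band axis over the same range for fast simulation work.
    """

    wavelengths_nm: tuple[float, ...]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("SpectralAxis needs a non-empty 1-D wavelength list")
        if not np.all(np.isfinite(wl)):
            raise ValueError("SpectralAxis wavelengths must be finite")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("SpectralAxis wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", tuple(float(w) for w in wl))

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths_nm)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.wavelengths_nm, dtype=float)

    @classmethod
    def default(cls) -> "SpectralAxis":
        """Full instrument axis: 470-750 nm, 97 bands."""
        return cls(tuple(np.linspace(470.0, 750.0, 97)))

    @classmethod
    def test_scale(cls) -> "SpectralAxis":
        """Coarse axis for simulation work: 470-750 nm step 14 (21 bands)."""
        return cls(tuple(np.arange(470.0, 750.0 + 1e-9, 14.0)))

    def nearest_band(self, wavelength_nm: float) -> tuple[int, float]:
        """Index and center of the band closest to ``wavelength_nm``.

        Logs a warning when the requested wavelength is not an exact band
        center (it is snapped, never interpolated).
        """
        wl = self.as_array()
        idx = int(np.argmin(np.abs(wl - wavelength_nm)))
        snapped = float(wl[idx])
        if abs(snapped - wavelength_nm) > 1e-6:
            logger.warning(
                "wavelength %.6g nm snapped to nearest band center %.6g nm",
                wavelength_nm,
                snapped,
            )
        return idx, snapped


# ---------------------------------------------------------------------------
# Mueller matrices
# ---------------------------------------------------------------------------

def mueller_rotator(angle_deg: float | np.ndarray) -> np.ndarray:
    """Mueller rotation matrix R(angle) used to rotate element frames."""
    a = 2.0 * np.deg2rad(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (4, 4))
    out[..., 0, 0] = 1.0
    out[..., 3, 3] = 1.0
    out[..., 1, 1] = c
    out[..., 1, 2] = s
    out[..., 2, 1] = -s
    out[..., 2, 2] = c
    return out


def mueller_linear_polarizer(transmission_axis_deg: float | np.ndarray) -> np.ndarray:
    """Ideal linear polarizer Mueller matrix.

    Parameters
    ----------
    transmission_axis_deg : float or array
        Transmission-axis angle in degrees, measured from horizontal.
        Array input broadcasts to a stack of matrices.

    Returns
    -------
    ndarray, shape (..., 4, 4)
    """
    a = 2.0 * np.deg2rad(np.asarray(transmission_axis_deg, dtype=float))
    if not np.all(np.isfinite(a)):
        raise ValueError("polarizer angle must be finite")
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (4, 4))
    out[..., 0, 0] = 1.0
    out[..., 0, 1] = c
    out[..., 0, 2] = s
    out[..., 1, 0] = c
    out[..., 1, 1] = c * c
    out[..., 1, 2] = c * s
    out[..., 2, 0] = s
    out[..., 2, 1] = c * s
    out[..., 2, 2] = s * s
    return 0.5 * out


def mueller_retarder(
    fast_axis_deg: float | np.ndarray, retardance_rad: float | np.ndarray
) -> np.ndarray:
    """Ideal linear retarder Mueller matrix (standard sign convention).

    Parameters
    ----------
    fast_axis_deg : float or array
        Fast-axis angle in degrees from horizontal.
    retardance_rad : float or array
        Phase retardance in radians. Zero gives the identity.

    Returns
    -------
    ndarray, shape (..., 4, 4)
        Broadcast over the inputs; preserves S0 and the degree of
        polarization.
    """
    t = np.asarray(fast_axis_deg, dtype=float)
    d = np.asarray(retardance_rad, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(d))):
        raise ValueError("retarder parameters must be finite")
    t, d = np.broadcast_arrays(2.0 * np.deg2rad(t), d)
    c, s = np.cos(t), np.sin(t)
    cd, sd = np.cos(d), np.sin(d)
    out = np.zeros(np.shape(c) + (4, 4))
    out[..., 0, 0] = 1.0
    out[..., 1, 1] = c * c + s * s * cd
    out[..., 1, 2] = c * s * (1.0 - cd)
    out[..., 1, 3] = -s * sd
    out[..., 2, 1] = c * s * (1.0 - cd)
    out[..., 2, 2] = s * s + c * c * cd
    out[..., 2, 3] = c * sd
    out[..., 3, 1] = s * sd
    out[..., 3, 2] = -c * sd
    out[..., 3, 3] = cd
    return out


# ---------------------------------------------------------------------------
# analyzer states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyzerState:
    """One analyzer configuration: LCVR retardances (delta1, delta2) in rad."""

    name: str
    delta1: float
    delta2: float


STATE_H = AnalyzerState("H", 0.0, 0.0)
STATE_V = AnalyzerState("V", 0.0, np.pi)
STATE_P45 = AnalyzerState("P45", np.pi / 2.0, np.pi / 2.0)
# delta2 = -pi/2 so that Irc = (S0 + S3)/2; see module docstring.
STATE_RC = AnalyzerState("RC", 0.0, -np.pi / 2.0)

CANONICAL_STATES: tuple[AnalyzerState, ...] = (STATE_H, STATE_V, STATE_P45, STATE_RC)


def analyzer_mueller(state: AnalyzerState) -> np.ndarray:
    """Composed analyzer Mueller matrix P(0) @ LCVR2(45, d2) @ LCVR1(0, d1)."""
    return (
        mueller_linear_polarizer(0.0)
        @ mueller_retarder(45.0, state.delta2)
        @ mueller_retarder(0.0, state.delta1)
    )


def analyzer_intensity(state: AnalyzerState, s_in: np.ndarray) -> np.ndarray:
    """Detected intensity for Stokes input(s) through one analyzer state.

    ``s_in`` has shape (..., 4); the result drops the last axis.  The
    intensity is the S0 component of the composed analyzer chain applied
    to the input, i.e. for the canonical states::

        I = (S0 + S1*cos d2 + S2*sin d1*sin d2 - S3*cos d1*sin d2) / 2
    """
    s = np.asarray(s_in, dtype=float)
    if s.shape[-1] != 4:
        raise ValueError("Stokes input must have length 4 on the last axis")
    row = analyzer_mueller(state)[0]
    return s @ row


# ---------------------------------------------------------------------------
# data cubes
# ---------------------------------------------------------------------------

def _check_cube(arr: np.ndarray, name: str, axis: SpectralAxis) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 3:
        raise ValueError(f"cube '{name}' must be rows x cols x bands, got ndim={a.ndim}")
    if a.shape[2] != axis.n_bands:
        raise ValueError(
            f"cube '{name}' has {a.shape[2]} bands but the spectral axis has "
            f"{axis.n_bands}"
        )
    return a


@dataclass
class ElementImageSet:
    """The four analyzer element-image cubes sharing one FOV and axis.

    Cubes are (rows, cols, bands) with row 0 at the top of the image.
    """

    ih: np.ndarray
    iv: np.ndarray
    i45: np.ndarray
    irc: np.ndarray
    axis: SpectralAxis

    def __post_init__(self) -> None:
        self.ih = _check_cube(self.ih, "ih", self.axis)
        ref = self.ih.shape
        for name in ("iv", "i45", "irc"):
            arr = _check_cube(getattr(self, name), name, self.axis)
            if arr.shape != ref:
                raise ValueError(
                    f"cube '{name}' has shape {arr.shape}, expected {ref} to match 'ih'"
                )
            setattr(self, name, arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ih.shape

    def scaled(self, factor: float) -> "ElementImageSet":
        return ElementImageSet(
            self.ih * factor, self.iv * factor, self.i45 * factor, self.irc * factor,
            self.axis,
        )


@dataclass
class StokesCube:
    """Four co-registered Stokes parameter cubes S0..S3.

    ``normalized`` marks S0-normalized data: s1..s3 are dimensionless
    ratios, s0 is 1 where defined, and ``valid`` flags pixels whose S0 was
    large enough to divide by (invalid pixels hold NaN and are excluded
    from downstream statistics).
    """

    s0: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    s3: np.ndarray
    axis: SpectralAxis
    normalized: bool = False
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s0 = _check_cube(self.s0, "s0", self.axis)
        ref = self.s0.shape
        for name in ("s1", "s2", "s3"):
            arr = _check_cube(getattr(self, name), name, self.axis)
            if arr.shape != ref:
                raise ValueError(
                    f"cube '{name}' has shape {arr.shape}, expected {ref} to match 's0'"
                )
            setattr(self, name, arr)
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != ref:
                raise ValueError("valid mask shape must match the Stokes cubes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.s0.shape

    def parameter(self, name: str) -> np.ndarray:
        """Return one parameter cube by id ('S0'..'S3', case-insensitive)."""
        key = name.lower()
        if key not in {"s0", "s1", "s2", "s3"}:
            raise ValueError(f"unknown Stokes parameter {name!r}")
        return getattr(self, key)

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.shape, dtype=bool)
        return self.valid


def compute_stokes(images: ElementImageSet) -> StokesCube:
    """Reconstruct the (un-normalized) Stokes cube from four element images.

    Per pixel and band: ``s0 = ih + iv``, ``s1 = ih - iv``,
    ``s2 = 2*i45 - (ih + iv)``, ``s3 = 2*irc - (ih + iv)``.
    Physicality violations (s1^2+s2^2+s3^2 > s0^2, possible under noise)
    are retained and logged, never clipped.
    """
    s0 = images.ih + images.iv
    cube = StokesCube(
        s0=s0,
        s1=images.ih - images.iv,
        s2=2.0 * images.i45 - s0,
        s3=2.0 * images.irc - s0,
        axis=images.axis,
        normalized=False,
    )
    n_bad = count_physicality_violations(cube)
    if n_bad:
        logger.info(
            "compute_stokes: %d of %d pixel-bands violate s1^2+s2^2+s3^2 <= s0^2 "
            "(retained, not clipped)",
            n_bad,
            cube.s0.size,
        )
    return cube


def count_physicality_violations(cube: StokesCube, tol: float = _PHYS_TOL) -> int:
    """Count pixel-bands with polarized power exceeding total intensity."""
    pol2 = cube.s1**2 + cube.s2**2 + cube.s3**2
    return int(np.sum(pol2 > cube.s0**2 * (1.0 + tol)))


def normalize_stokes(cube: StokesCube, epsilon: float | None = None) -> StokesCube:
    """Divide s1..s3 by s0, masking pixels with |s0| below ``epsilon``.

    ``epsilon`` defaults to 1e-9 times the largest |s0| in the cube.
    Invalid pixels are set to NaN and flagged False in ``valid`` so they
    propagate as missing values rather than infinities or zeros.
    """
    if cube.normalized:
        raise ValueError("cube is already normalized")
    if epsilon is None:
        peak = float(np.nanmax(np.abs(cube.s0))) if cube.s0.size else 0.0
        epsilon = 1e-9 * peak
    valid = np.abs(cube.s0) > epsilon
    n_invalid = int(valid.size - np.count_nonzero(valid))
    if n_invalid:
        logger.info("normalize_stokes: %d pixel-bands masked (|s0| <= %.3g)",
                    n_invalid, epsilon)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = {}
        for name in ("s1", "s2", "s3"):
            arr = np.where(valid, getattr(cube, name) / cube.s0, np.nan)
            out[name] = arr
    s0 = np.where(valid, 1.0, np.nan)
    return StokesCube(
        s0=s0, s1=out["s1"], s2=out["s2"], s3=out["s3"],
        axis=cube.axis, normalized=True, valid=valid,
    )
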