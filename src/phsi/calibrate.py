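"""Quarter-wave-plate sweep calibration of the full-Stokes analyzer.

A quarter-wave plate between the 45-deg generator and the analyzer is
rotated through known fast-axis positions theta; the normalized Stokes
parameters of the light it delivers are analytically::

    s1(theta) = sin(2 theta) cos(2 theta)
    s2(theta) = sin(2 theta) sin(2 theta)
    s3(theta) = -cos(2 theta)

At each position the four element cubes are acquired, reconstructed,
normalized and spatially averaged (the target is uniform), and agreement
with the analytic curves is summarized by the root-mean-square error per
Stokes parameter at a handful of reporting wavelengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .polarization import ElementImageSet, SpectralAxis, compute_stokes, normalize_stokes
from .simulate import IlluminationSpec, NoiseSpec, make_qwp_scene, simulate_acquisition

logger = logging.getLogger("phsi")

__all__ = [
    "CalibrationProtocol",
    "CalibrationResult",
    "theoretical_qwp_stokes",
    "rmse",
    "run_calibration",
    "simulate_qwp_sweep",
]

_PARAMS = ("S1", "S2", "S3")


def theoretical_qwp_stokes(theta_deg: float | np.ndarray) -> np.ndarray:
    """Analytic normalized (s1, s2, s3) behind a QWP at fast axis theta.

    Vectorized: scalar input returns shape (3,), array input (..., 3).
    """
    t = 2.0 * np.deg2rad(np.asarray(theta_deg, dtype=float))
    s1 = np.sin(t) * np.cos(t)
    s2 = np.sin(t) * np.sin(t)
    s3 = -np.cos(t)
    return np.stack([s1, s2, s3], axis=-1)


def rmse(experimental: Sequence[float], theoretical: Sequence[float]) -> float:
    """Root-mean-square error between two equal-length curves.

    sqrt( (1/N) * sum_n (exp_n - theory_n)^2 ); symmetric in its
    arguments and invariant to reordering applied to both.
    """
    e = np.asarray(experimental, dtype=float)
    t = np.asarray(theoretical, dtype=float)
    if e.shape != t.shape or e.ndim != 1 or e.size < 1:
        raise ValueError(
            f"rmse needs two equal-length 1-D sequences, got {e.shape} and {t.shape}"
        )
    return float(np.sqrt(np.mean((e - t) ** 2)))


@dataclass(frozen=True)
class CalibrationProtocol:
    """QWP sweep layout: fast-axis angles and reporting wavelengths."""

    angles_deg: tuple[float, ...] = tuple(float(a) for a in range(0, 181, 10))
    wavelengths_nm: tuple[float, ...] = (470.0, 525.0, 626.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        if a.size < 2:
            raise ValueError("protocol needs at least two angles")
        if np.any(a < 0) or np.any(a > 180):
            raise ValueError("protocol angles must lie in [0, 180] deg")
        if len(self.wavelengths_nm) < 1:
            raise ValueError("protocol needs at least one reporting wavelength")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)


@dataclass
class CalibrationResult:
    """Experimental vs. theoretical normalized Stokes curves and RMSE.

    ``experimental`` is (n_wavelengths, 3, n_angles) for (S1, S2, S3);
    ``theoretical`` is (3, n_angles) (the QWP curves are achromatic);
    ``rmse`` is (n_wavelengths, 3).
    """

    angles_deg: np.ndarray
    wavelengths_nm: np.ndarray          # snapped band centers
    requested_wavelengths_nm: np.ndarray
    band_indices: np.ndarray
    experimental: np.ndarray
    theoretical: np.ndarray
    rmse: np.ndarray

    def rmse_frame(self) -> pd.DataFrame:
        """RMSE table: one row per wavelength, one column per parameter."""
        return pd.DataFrame(
            self.rmse, columns=list(_PARAMS),
            index=pd.Index(self.wavelengths_nm, name="wavelength_nm"),
        )

    def curves_frame(self) -> pd.DataFrame:
        """Long-format table of experimental and theoretical curves."""
        rows = []
        for wi, wl in enumerate(self.wavelengths_nm):
            for pi, par in enumerate(_PARAMS):
                for ai, ang in enumerate(self.angles_deg):
                    rows.append(
                        {
                            "wavelength_nm": wl,
                            "parameter": par,
                            "angle_deg": ang,
                            "experimental": self.experimental[wi, pi, ai],
                            "theoretical": self.theoretical[pi, ai],
                        }
                    )
        return pd.DataFrame(rows)

    @property
    def max_rmse(self) -> float:
        return float(np.max(self.rmse))


def run_calibration(
    sweep: Mapping[float, ElementImageSet],
    protocol: CalibrationProtocol | None = None,
) -> CalibrationResult:
    """Reduce a QWP sweep to curves and RMSE per wavelength and parameter.

    ``sweep`` maps fast-axis angle (deg) to the ElementImageSet acquired
    there; every protocol angle must be present.  For each angle the
    Stokes cube is reconstructed, S0-normalized, and averaged over valid
    pixels (the calibration target is spatially uniform).
    """
    protocol = protocol or CalibrationProtocol()
    missing = [a for a in protocol.angles_deg if a not in sweep]
    if missing:
        raise ValueError(f"sweep is missing protocol angle(s): {missing}")

    axis: SpectralAxis | None = None
    curves = []  # per angle: (n_bands, 3) spatial means of s1, s2, s3
    for angle in protocol.angles_deg:
        images = sweep[angle]
        if axis is None:
            axis = images.axis
        elif images.axis != axis:
            raise ValueError(f"sweep angle {angle} has a different spectral axis")
        norm = normalize_stokes(compute_stokes(images))
        stacked = np.stack([norm.s1, norm.s2, norm.s3], axis=-1)
        curves.append(np.nanmean(stacked, axis=(0, 1)))
    assert axis is not None
    curves_arr = np.stack(curves, axis=0)  # (n_angles, n_bands, 3)

    band_indices = []
    snapped = []
    for wl in protocol.wavelengths_nm:
        idx, snap = axis.nearest_band(wl)
        band_indices.append(idx)
        snapped.append(snap)

    theory = theoretical_qwp_stokes(np.asarray(protocol.angles_deg)).T  # (3, N)
    experimental = np.empty((len(band_indices), 3, protocol.n_angles))
    rmse_table = np.empty((len(band_indices), 3))
    for wi, bi in enumerate(band_indices):
        for pi in range(3):
            exp_curve = curves_arr[:, bi, pi]
            experimental[wi, pi] = exp_curve
            rmse_table[wi, pi] = rmse(exp_curve, theory[pi])

    return CalibrationResult(
        angles_deg=np.asarray(protocol.angles_deg, dtype=float),
        wavelengths_nm=np.asarray(snapped, dtype=float),
        requested_wavelengths_nm=np.asarray(protocol.wavelengths_nm, dtype=float),
        band_indices=np.asarray(band_indices),
        experimental=experimental,
        theoretical=theory,
        rmse=rmse_table,
    )


def simulate_qwp_sweep(
    protocol: CalibrationProtocol | None = None,
    shape: tuple[int, int] = (64, 64),
    axis: SpectralAxis | None = None,
    illum: IlluminationSpec | None = None,
    noise: NoiseSpec | None = None,
    angle_offset_deg: float = 0.0,
) -> dict[float, ElementImageSet]:
    """Simulate the full QWP calibration sweep.

    ``angle_offset_deg`` misaligns every plate position (useful for
    studying systematic errors).  When noise is requested, each angle gets
    an independent substream derived from ``noise.seed`` so the sweep as a
    whole is reproducible from one seed.
    """
    protocol = protocol or CalibrationProtocol()
    axis = axis or SpectralAxis.test_scale()
    sweep: dict[float, ElementImageSet] = {}
    if noise is not None and noise.model != "none":
        child_seeds = [
            int(s) & 0x7FFFFFFF
            for s in np.random.SeedSequence(noise.seed).generate_state(protocol.n_angles)
        ]
    else:
        child_seeds = [0] * protocol.n_angles
    for angle, sub_seed in zip(protocol.angles_deg, child_seeds):
        scene = make_qwp_scene(angle + angle_offset_deg, shape, axis)
        angle_noise = None
        if noise is not None and noise.model != "none":
            angle_noise = NoiseSpec(
                model=noise.model,
                read_sigma=noise.read_sigma,
                photon_scale=noise.photon_scale,
                seed=sub_seed,
            )
        sweep[angle] = simulate_acquisition(scene, illum=illum, noise=angle_noise)
    return sweep


def plot_calibration(result: CalibrationResult, path: str, wavelength_nm: float | None = None):
    """Scatter of experimental values over the theoretical curves (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if wavelength_nm is None:
        wi = 0
    else:
        wi = int(np.argmin(np.abs(result.wavelengths_nm - wavelength_nm)))
    fine = np.linspace(result.angles_deg.min(), result.angles_deg.max(), 361)
    theory_fine = theoretical_qwp_stokes(fine)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharey=True)
    for pi, (ax, par) in enumerate(zip(axes, _PARAMS)):
        ax.plot(fine, theory_fine[:, pi], "-", label="theory")
        ax.plot(result.angles_deg, result.experimental[wi, pi], "o", ms=4,
                label="experimental")
        ax.set_title(f"{par} (RMSE {result.rmse[wi, pi]:.3g})")
        ax.set_xlabel("QWP fast axis (deg)")
    axes[0].set_ylabel(f"normalized Stokes @ {result.wavelengths_nm[wi]:.0f} nm")
    axes[0].legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
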