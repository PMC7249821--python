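"""Image and signal metrics: FWHM, CNR, SNR, NEP, fluence conversion, DOF.

Conventions
-----------
* FWHM is estimated from a least-squares Gaussian fit (amplitude, centre,
  σ, offset); FWHM = 2·sqrt(2·ln 2)·σ ≈ 2.3548·σ.
* CNR = (peak in the signal region − mean of the background region) divided
  by the standard deviation of the background region.  The definition is a
  declared choice; measured CNR values depend on the region placement and
  are not comparable across instruments.
* SNR = envelope peak amplitude / RMS of a signal-free noise window.
* NEP (noise-equivalent pressure) = initial source pressure / SNR — the
  initial pressure whose reconstructed amplitude equals the noise RMS.
* Fluence↔pressure: p0 = Γ·μa·F with Γ the Grueneisen parameter and μa the
  optical absorption coefficient; 1 Pa corresponds to 1 J/m³ of absorbed
  energy density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GaussianProfileFit",
    "FitFailureWarning",
    "DofResult",
    "fit_gaussian_profile",
    "fwhm",
    "cnr",
    "snr",
    "nep",
    "fluence_for_pressure",
    "pressure_from_fluence",
    "dof_from_profile",
    "resolution_table",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


class FitFailureWarning(UserWarning):
    """Gaussian fit did not converge or explains the profile poorly."""


@dataclass(frozen=True)
class GaussianProfileFit:
    """Result of a Gaussian fit to a single-peak amplitude profile."""

    amplitude: float
    center: float
    sigma: float
    offset: float
    r_squared: float
    ok: bool

    @property
    def fwhm(self) -> float:
        """Full width at half maximum, in the units of the fitted axis."""
        return FWHM_PER_SIGMA * self.sigma


def _gaussian(x, amplitude, center, sigma, offset):
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2) + offset


def fit_gaussian_profile(x, profile, r_squared_min: float = 0.8) -> GaussianProfileFit:
    """Least-squares Gaussian fit to a profile with a single dominant peak.

    ``ok`` is False (with a :class:`FitFailureWarning`) when the fit fails
    to converge or R² falls below ``r_squared_min``; the best available
    parameters are still returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(profile, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 5:
        raise ValueError("profile needs >= 5 samples on a matching 1-D axis")
    offset0 = float(y.min())
    amp0 = float(y.max() - offset0)
    c0 = float(x[np.argmax(y)])
    # second-moment width guess around the peak
    w = np.clip(y - offset0, 0.0, None)
    sigma0 = float(np.sqrt(np.sum(w * (x - c0) ** 2) / np.sum(w))) if w.sum() > 0 else 1.0
    sigma0 = max(sigma0, float(np.mean(np.diff(x))))
    try:
        popt, _ = curve_fit(
            _gaussian,
            x,
            y,
            p0=[amp0, c0, sigma0, offset0],
            bounds=(
                [0.0, x.min() - (x.max() - x.min()), 1e-12, -np.inf],
                [np.inf, x.max() + (x.max() - x.min()), np.inf, np.inf],
            ),
            maxfev=20000,
        )
        resid = y - _gaussian(x, *popt)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        ok = r2 >= r_squared_min
    except RuntimeError:
        popt, r2, ok = [amp0, c0, sigma0, offset0], 0.0, False
    if not ok:
        warnings.warn(
            f"Gaussian fit explains the profile poorly (R² = {r2:.3f})",
            FitFailureWarning,
            stacklevel=2,
        )
    return GaussianProfileFit(
        amplitude=float(popt[0]),
        center=float(popt[1]),
        sigma=float(abs(popt[2])),
        offset=float(popt[3]),
        r_squared=float(r2),
        ok=bool(ok),
    )


def fwhm(x_mm, profile) -> float:
    """Gaussian-fit FWHM of a profile sampled on positions in mm, in µm."""
    return 1000.0 * fit_gaussian_profile(x_mm, profile).fwhm


def cnr(image, signal_roi, background_roi) -> float:
    """Contrast-to-noise ratio between two disjoint regions of interest.

    ROIs are boolean masks (or index arrays) into ``image``:
    (peak of signal ROI − mean of background ROI) / std of background ROI.
    """
    image = np.asarray(image, dtype=float)
    sig = image[signal_roi]
    bg = image[background_roi]
    if sig.size == 0 or bg.size == 0:
        raise ValueError("empty region of interest")
    sd = float(bg.std())
    if sd == 0:
        raise ValueError("background has zero variance; CNR undefined")
    return (float(sig.max()) - float(bg.mean())) / sd


def snr(ascan, noise_window) -> float:
    """Peak amplitude over RMS of a signal-free noise window.

    ``noise_window`` is a slice or boolean mask into ``ascan`` that must
    exclude the signal.
    """
    a = np.asarray(ascan, dtype=float)
    noise = a[noise_window]
    if noise.size == 0:
        raise ValueError("empty noise window")
    rms = float(np.sqrt(np.mean(noise**2)))
    if rms == 0:
        raise ValueError("zero noise RMS; SNR undefined")
    return float(np.abs(a).max()) / rms


def nep(p0_pa: float, snr_value: float) -> float:
    """Noise-equivalent pressure in Pa: initial pressure / SNR."""
    if snr_value <= 0:
        raise ValueError("SNR must be positive")
    return p0_pa / snr_value


def fluence_for_pressure(p_pa: float, grueneisen: float, mu_a_per_mm: float) -> float:
    """Local optical fluence (mJ/cm²) required for an initial pressure (Pa).

    From p0 = Γ·μa·F with 1 Pa ≡ 1 J/m³ of absorbed energy density:
    F [J/m²] = p / (Γ · μa[m⁻¹]); converted to mJ/cm² this is
    F = p / (Γ · μa[mm⁻¹]) · 10⁻⁴.
    """
    if p_pa <= 0 or grueneisen <= 0 or mu_a_per_mm <= 0:
        raise ValueError("all arguments must be positive")
    return p_pa / (grueneisen * mu_a_per_mm) * 1e-4


def pressure_from_fluence(
    fluence_mj_cm2: float, grueneisen: float, mu_a_per_mm: float
) -> float:
    """Inverse of :func:`fluence_for_pressure`: initial pressure in Pa."""
    if fluence_mj_cm2 <= 0 or grueneisen <= 0 or mu_a_per_mm <= 0:
        raise ValueError("all arguments must be positive")
    return fluence_mj_cm2 * grueneisen * mu_a_per_mm * 1e4


@dataclass(frozen=True)
class DofResult:
    """Depth-of-field interval from an amplitude-versus-depth profile."""

    z_low: float
    z_high: float
    extent: float
    threshold: float


def dof_from_profile(depths, peak_amplitudes, drop_db: float = 6.0) -> DofResult:
    """Largest contiguous depth interval within ``drop_db`` of the maximum.

    Amplitude threshold is max · 10^(−drop_db/20); the interval endpoints
    are the first/last grid depths of the longest run above threshold.
    """
    z = np.asarray(depths, dtype=float)
    a = np.asarray(peak_amplitudes, dtype=float)
    if z.shape != a.shape or z.ndim != 1 or z.size < 3:
        raise ValueError("need matching 1-D arrays with >= 3 depths")
    thr = float(a.max()) * 10.0 ** (-drop_db / 20.0)
    above = a >= thr
    best = (0, -1)
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - 1 - start > best[1] - best[0]:
                best = (start, i - 1)
            start = None
    lo, hi = best
    return DofResult(
        z_low=float(z[lo]), z_high=float(z[hi]), extent=float(z[hi] - z[lo]), threshold=thr
    )


def resolution_table(depths, lateral_fwhm_um, axial_fwhm_um) -> pd.DataFrame:
    """Tabulate per-depth lateral/axial FWHM values (µm) with their means."""
    df = pd.DataFrame(
        {
            "depth_mm": np.asarray(depths, dtype=float),
            "lateral_fwhm_um": np.asarray(lateral_fwhm_um, dtype=float),
            "axial_fwhm_um": np.asarray(axial_fwhm_um, dtype=float),
        }
    )
    return df
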