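"""Analytic model primitives shared by the generators and the fitters.

All are plain vectorized functions of numpy arrays; units follow the
package convention (ns, nm, Å⁻¹).
"""

from __future__ import annotations

import numpy as np

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_irf(t: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area Gaussian instrument response on the channel grid.

    A near-zero FWHM degenerates to a single-channel delta.
    """
    t = np.asarray(t, dtype=float)
    if fwhm <= 1e-9:
        irf = np.zeros_like(t)
        irf[int(np.argmin(np.abs(t - center)))] = 1.0
        return irf
    sigma = fwhm * _FWHM_TO_SIGMA
    irf = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    s = irf.sum()
    if s <= 0:
        raise ValueError("IRF center lies outside the channel window")
    return irf / s


def multi_exponential(t: np.ndarray, lifetimes, amplitudes) -> np.ndarray:
    """Σ aᵢ·exp(−t/τᵢ) on t ≥ 0 (t measured from channel zero)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for tau, a in zip(lifetimes, amplitudes):
        out += a * np.exp(-t / tau)
    return out


def convolve_irf(irf: np.ndarray, decay: np.ndarray) -> np.ndarray:
    """Causal discrete convolution truncated to the channel window."""
    return np.convolve(irf, decay)[: decay.size]


def shift_curve(y: np.ndarray, shift_channels: float) -> np.ndarray:
    """Shift a sampled curve by a fractional number of channels (linear interp)."""
    n = y.size
    idx = np.arange(n) - shift_channels
    return np.interp(idx, np.arange(n), y, left=0.0, right=0.0)


def lognormal_band(
    wl: np.ndarray, center: float, width: float, asymmetry: float, amplitude: float = 1.0
) -> np.ndarray:
    """Siano–Metzler asymmetric lognormal emission band.

    ``center`` is the peak wavelength (nm), ``width`` the FWHM (nm) and
    ``asymmetry`` ρ > 1 skews the band to the red; ρ → 1 recovers a
    Gaussian. Intensity is zero beyond the finite support edge.
    """
    wl = np.asarray(wl, dtype=float)
    if width <= 0:
        raise ValueError("band width must be positive")
    rho = float(asymmetry)
    if rho <= 0:
        raise ValueError("asymmetry must be positive")
    if abs(rho - 1.0) < 1e-6:
        sigma = width * _FWHM_TO_SIGMA
        return amplitude * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    arg = 1.0 + (wl - center) * (rho**2 - 1.0) / (width * rho)
    out = np.zeros_like(wl)
    ok = arg > 0
    out[ok] = amplitude * np.exp(-(np.log(2.0) / np.log(rho) ** 2) * np.log(arg[ok]) ** 2)
    return out


def gaussian_peak(x: np.ndarray, center: float, fwhm: float, amplitude: float) -> np.ndarray:
    sigma = fwhm * _FWHM_TO_SIGMA
    return amplitude * np.exp(-0.5 * ((np.asarray(x, float) - center) / sigma) ** 2)


def lorentzian_peak(x: np.ndarray, center: float, hwhm: float, amplitude: float) -> np.ndarray:
    """Lorentzian with unit peak height ``amplitude`` at ``center``."""
    return amplitude * hwhm**2 / ((np.asarray(x, float) - center) ** 2 + hwhm**2)
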