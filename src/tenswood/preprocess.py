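"""Raman / FT-IR spectral pre-processing.

The Raman chain is despike -> crop (510-1,800 cm^-1) -> asymmetric
least-squares baseline (lambda = 5,000, p = 0.001) -> total-area
normalization -> Savitzky-Golay smoothing (order 1, frame 3). The FT-IR
chain is crop -> 2-point linear baseline (anchors 812 and 1,809 cm^-1) ->
area normalization.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.signal
import scipy.sparse
import scipy.sparse.linalg

from .types import SpectralMap, Spectrum


@dataclass
class PreprocessConfig:
    crop_lo: float = 510.0
    crop_hi: float = 1800.0
    als_lambda: float = 5000.0
    als_p: float = 0.001
    als_max_iter: int = 50
    savgol_order: int = 1
    savgol_frame: int = 3
    despike_window: int = 5
    despike_z: float = 8.0
    ftir_anchor_lo: float = 812.0
    ftir_anchor_hi: float = 1809.0
    norm_region: tuple[float, float] | None = None  # None = full cropped range

    def __post_init__(self) -> None:
        if self.crop_lo >= self.crop_hi:
            raise ValueError("crop_lo must be < crop_hi")
        if self.als_lambda <= 0:
            raise ValueError("ALS lambda must be > 0")
        if not (0 < self.als_p < 1):
            raise ValueError("ALS p must be in (0, 1)")
        if self.savgol_frame < 3 or self.savgol_frame % 2 == 0:
            raise ValueError("SavGol frame must be odd and >= 3")
        if self.savgol_order >= self.savgol_frame:
            raise ValueError("SavGol order must be < frame")


def despike(spectrum: Spectrum, window: int = 5,
            z_threshold: float = 8.0) -> tuple[Spectrum, np.ndarray]:
    """Remove single-channel cosmic spikes by running-median z-scoring.

    Channels whose residual against the running median exceeds
    ``z_threshold`` robust (MAD-based) standard deviations are replaced by
    the local median. Returns the cleaned spectrum and the flagged channel
    indices. A behavioral stand-in for the instrument vendor's proprietary
    cosmic-ray filter.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    y = spectrum.intensities
    if window >= y.size:
        raise ValueError("window must be smaller than the spectrum")
    med = scipy.ndimage.median_filter(y, size=window, mode="nearest")
    resid = y - med
    # noise scale from first differences: immune to the zero-inflated
    # residual distribution the median filter produces
    d = np.diff(y)
    robust_sd = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2)
    if robust_sd == 0:
        robust_sd = np.std(resid) or 1.0
    # a cosmic spike towers over its local amplitude (tens of times it),
    # so require the residual to exceed the local median as well — this
    # keeps sharp but genuine Raman bands intact on low-noise spectra
    spikes = np.nonzero((np.abs(resid) > z_threshold * robust_sd)
                        & (np.abs(resid) > 3.0 * np.abs(med)))[0]
    cleaned = y.copy()
    cleaned[spikes] = med[spikes]
    return Spectrum(spectrum.wavenumbers, cleaned), spikes


def crop(spectrum: Spectrum, lo: float = 510.0, hi: float = 1800.0) -> Spectrum:
    """Retain channels with lo <= wavenumber <= hi, order preserved."""
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"crop range [{lo}, {hi}] retains no channels")
    return Spectrum(spectrum.wavenumbers[mask], spectrum.intensities[mask])


def als_baseline(spectrum: Spectrum, lam: float = 5000.0, p: float = 0.001,
                 n_iter: int = 50, tol: float = 1e-8) -> tuple[np.ndarray, Spectrum]:
    """Asymmetric least-squares (Whittaker) baseline estimation.

    Minimizes sum_i w_i (y_i - z_i)^2 + lam * sum_i (d2 z_i)^2 with
    asymmetric weights w_i = p where y_i > z_i else 1 - p, iterated to
    weight convergence (relative change < ``tol``) or ``n_iter`` sweeps.
    Returns (baseline, baseline-corrected spectrum).
    """
    y = spectrum.intensities
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities must be finite")
    m = y.size
    d = scipy.sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(m - 2, m))
    penalty = lam * (d.T @ d)
    w = np.ones(m)
    z = y.copy()
    for _ in range(n_iter):
        a = scipy.sparse.diags(w) + penalty
        z = scipy.sparse.linalg.spsolve(a.tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    return z, Spectrum(spectrum.wavenumbers, y - z)


def area_normalize(spectrum: Spectrum,
                   region: tuple[float, float] | None = None) -> Spectrum:
    """Scale so the trapezoid area over ``region`` (default full range) is 1."""
    nu, y = spectrum.wavenumbers, spectrum.intensities
    if region is None:
        mask = np.ones(nu.size, dtype=bool)
    else:
        mask = (nu >= region[0]) & (nu <= region[1])
        if mask.sum() < 2:
            raise ValueError("normalization region covers fewer than 2 channels")
    area = np.trapezoid(y[mask], nu[mask])
    if area <= 0:
        raise ValueError("non-positive area; cannot normalize")
    return Spectrum(nu, y / area)


def savgol(spectrum: Spectrum, order: int = 1, frame: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing; with order 1 / frame 3 the interior equals
    the centered 3-point mean. Edges use a polynomial fit to the terminal
    window rather than padding."""
    if frame % 2 == 0 or frame < 3:
        raise ValueError("frame must be odd and >= 3")
    if frame >= len(spectrum):
        raise ValueError("frame must be smaller than the spectrum")
    if order >= frame:
        raise ValueError("order must be < frame")
    sm = scipy.signal.savgol_filter(spectrum.intensities, frame, order,
                                    mode="interp")
    return Spectrum(spectrum.wavenumbers, sm)


def linear_baseline_2pt(spectrum: Spectrum, a: float = 812.0,
                        b: float = 1809.0) -> Spectrum:
    """Subtract the straight line through (a, y(a)) and (b, y(b)).

    Anchor intensities are linearly interpolated when the anchors fall
    between grid points; anchors outside the grid clamp to the end values.
    """
    nu, y = spectrum.wavenumbers, spectrum.intensities
    ya = float(np.interp(a, nu, y))
    yb = float(np.interp(b, nu, y))
    line = ya + (yb - ya) * (nu - a) / (b - a)
    return Spectrum(nu, y - line)


def preprocess_spectrum(spectrum: Spectrum, config: PreprocessConfig,
                        mode: str = "raman") -> tuple[Spectrum, dict]:
    """Full chain on one spectrum; returns the result and QC flags."""
    qc: dict = {}
    if mode == "raman":
        sp, spikes = despike(spectrum, config.despike_window, config.despike_z)
        qc["n_spikes"] = int(spikes.size)
        sp = crop(sp, config.crop_lo, config.crop_hi)
        _, sp = als_baseline(sp, config.als_lambda, config.als_p,
                             config.als_max_iter)
        sp = area_normalize(sp, config.norm_region)
        sp = savgol(sp, config.savgol_order, config.savgol_frame)
    elif mode == "ftir":
        sp = crop(spectrum, config.crop_lo, config.crop_hi)
        sp = linear_baseline_2pt(sp, config.ftir_anchor_lo, config.ftir_anchor_hi)
        sp = area_normalize(sp, config.norm_region)
    else:
        raise ValueError("mode must be 'raman' or 'ftir'")
    return sp, qc


def preprocess_map(smap: SpectralMap, config: PreprocessConfig | None = None,
                   mode: str = "raman") -> tuple[SpectralMap, list[dict]]:
    """Apply the pre-processing chain voxel-wise to a spectral map."""
    config = config or PreprocessConfig()
    out_rows = []
    qc_all = []
    grid_out = None
    for i in range(smap.n_voxels):
        sp, qc = preprocess_spectrum(smap.spectrum(i), config, mode)
        out_rows.append(sp.intensities)
        qc_all.append(qc)
        grid_out = sp.wavenumbers
    out = smap.replace_intensities(np.vstack(out_rows), wavenumbers=grid_out)
    return out, qc_all
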