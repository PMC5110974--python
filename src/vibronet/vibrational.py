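"""Velocity autocorrelation functions and vibrational power spectra.

The VACF C(τ) = ⟨Σ_i w_i v_i(t+τ)·v_i(t)⟩_t / ⟨Σ_i w_i |v_i(t)|²⟩_t (weights
w_i = 1 or the atomic masses) is averaged over all valid time origins, and its
Fourier transform projects out the underlying frequencies of the molecular
fluctuations on a cm⁻¹ axis.  Spectra computed this way from classical
trajectories are typically 10–15 cm⁻¹ blue-shifted relative to experimental
far-infrared modes, which `blue_shift_match` accounts for when pairing
simulated and measured peak tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .constants import C_CM_PER_FS
from .trajectory import AngleSeries, AtomSelection, Trajectory

__all__ = [
    "CorrelationSeries",
    "PowerSpectrum",
    "PeakTable",
    "vacf",
    "autocorrelation",
    "power_spectrum",
    "torsional_spectrum",
    "find_peaks",
    "blue_shift_match",
    "BlueShiftAssignment",
]


@dataclass
class CorrelationSeries:
    """Normalized autocorrelation: value at lag 0 is 1 for non-degenerate input."""

    lags: np.ndarray  # fs
    values: np.ndarray
    n_samples: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0]) if len(self.lags) > 1 else 0.0


@dataclass
class PowerSpectrum:
    """One-sided power spectrum on a strictly increasing cm⁻¹ grid.

    ``resolution`` is the physical resolution 1/(c · total lag span); the grid
    itself may be finer through zero padding.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    window: str
    resolution: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# window={self.window} resolution_cm={self.resolution:.6g}\n")
            fh.write("wavenumber_cm\tintensity\n")
            for w, i in zip(self.wavenumbers, self.intensities):
                fh.write(f"{w:.6f}\t{i:.8e}\n")


@dataclass
class PeakTable:
    """Peak positions (cm⁻¹, ascending), heights and prominences."""

    positions: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


def _fft_autocorr_sums(x: np.ndarray) -> np.ndarray:
    """Σ_t x(t) x(t+τ) for τ = 0..T-1 along axis 0, summed over other axes."""
    T = x.shape[0]
    nfft = 1
    while nfft < 2 * T:
        nfft *= 2
    X = np.fft.rfft(x, n=nfft, axis=0)
    acorr = np.fft.irfft((X * np.conj(X)).real, n=nfft, axis=0)[:T]
    if acorr.ndim > 1:
        acorr = acorr.sum(axis=tuple(range(1, acorr.ndim)))
    return acorr


def autocorrelation(series: np.ndarray, dt: float, max_lag_fs: float | None = None) -> CorrelationSeries:
    """Normalized autocorrelation of a scalar (or multi-channel) series.

    Channels beyond axis 0 are summed before normalization, so a set of atoms
    contributes through the sum of its per-atom dot products.
    """
    x = np.asarray(series, dtype=float)
    T = x.shape[0]
    if T < 2:
        raise ValueError("need at least 2 frames")
    n_lags = T if max_lag_fs is None else int(round(max_lag_fs / dt)) + 1
    if n_lags > T:
        raise ValueError("max_lag must be shorter than the total duration")
    sums = _fft_autocorr_sums(x)[:n_lags]
    counts = T - np.arange(n_lags)
    numerator = sums / counts
    denom = float((x * x).sum()) / T
    if denom < 1e-300:
        raise ValueError("degenerate input: series is identically zero")
    return CorrelationSeries(
        lags=np.arange(n_lags) * dt,
        values=numerator / denom,
        n_samples=counts,
    )


def vacf(
    traj: Trajectory,
    sel: AtomSelection | None = None,
    max_lag_fs: float | None = None,
    mass_weighted: bool = False,
    finite_difference: bool = False,
) -> CorrelationSeries:
    """Velocity autocorrelation function of the selected atoms.

    ``finite_difference=True`` derives central-difference velocities from the
    positions when the trajectory carries none (logged as approximate).
    """
    sub = traj.subset(sel.as_array()) if sel is not None else traj
    if sub.velocities is None:
        if not finite_difference:
            raise ValueError(
                "trajectory carries no velocities; pass finite_difference=True "
                "to approximate them from positions"
            )
        warnings.warn(
            "velocities approximated by central differences of positions",
            stacklevel=2,
        )
        v = (sub.coords[2:] - sub.coords[:-2]) / (2.0 * sub.dt)
    else:
        v = sub.velocities
    if not np.any(v):
        raise ValueError("degenerate input: all velocities are zero")
    if mass_weighted:
        w = np.sqrt(np.asarray(sub.atoms["mass"], dtype=float))
        v = v * w[None, :, None]
    return autocorrelation(v, sub.dt, max_lag_fs)


def power_spectrum(
    corr: CorrelationSeries,
    window: str = "hann",
    zero_pad_factor: int = 1,
    grid_resolution_cm: float | None = 4.0,
) -> PowerSpectrum:
    """One-sided power spectrum of a correlation series on a cm⁻¹ axis.

    The series is extended by even symmetry (the autocorrelation of a
    stationary process is even), windowed, zero padded so the wavenumber grid
    spacing is at most ``grid_resolution_cm`` (default 4 cm⁻¹, matching the
    resolution at which far-infrared spectra are customarily reported), and
    Fourier transformed.  Intensities satisfy Parseval's identity: their sum
    equals the energy of the windowed, symmetrized correlation.
    """
    c = np.asarray(corr.values, dtype=float)
    L = len(c)
    if L < 8:
        raise ValueError("need at least 8 lags")
    dt = corr.dt
    if window not in ("none", "hann"):
        raise ValueError("window must be 'none' or 'hann'")
    # even extension: c[L-1] ... c[1] c[0] c[1] ... c[L-1], length 2L-1
    sym = np.concatenate([c[::-1], c[1:]])
    M = len(sym)
    if window == "hann":
        sym = sym * np.hanning(M)
    n = M * max(1, int(zero_pad_factor))
    if grid_resolution_cm is not None:
        n_needed = int(np.ceil(1.0 / (C_CM_PER_FS * grid_resolution_cm * dt)))
        n = max(n, n_needed)
    F = np.fft.rfft(sym, n=n)
    power_full = np.abs(F) ** 2 / n
    intensities = power_full.copy()
    intensities[1:] *= 2.0
    if n % 2 == 0:
        intensities[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=dt)  # cycles per fs
    wavenumbers = freqs / C_CM_PER_FS
    span = (L - 1) * dt
    return PowerSpectrum(
        wavenumbers=wavenumbers,
        intensities=intensities,
        window=window,
        resolution=1.0 / (C_CM_PER_FS * span) if span > 0 else np.inf,
    )


def torsional_spectrum(
    angles: AngleSeries,
    window: str = "hann",
    max_undefined_fraction: float = 0.01,
    max_lag_fs: float | None = None,
    grid_resolution_cm: float | None = 4.0,
) -> PowerSpectrum:
    """Power spectrum of a mean-removed torsional / angular time series.

    Frames flagged undefined (collinear geometry) are linearly interpolated,
    provided they are fewer than ``max_undefined_fraction`` of the series.
    A constant angle yields an identically zero spectrum.
    """
    vals = np.asarray(angles.values, dtype=float)
    bad = np.asarray(angles.undefined, dtype=bool) | np.isnan(vals)
    n = len(vals)
    if n < 8:
        raise ValueError("need at least 8 frames")
    if bad.sum() > max_undefined_fraction * n:
        raise ValueError(
            f"{bad.sum()} of {n} frames are undefined "
            f"(> {max_undefined_fraction:.0%}); refusing to interpolate"
        )
    if bad.any():
        good = np.nonzero(~bad)[0]
        vals = np.interp(np.arange(n), good, vals[good])
    centered = vals - vals.mean()
    if float((centered**2).sum()) < 1e-300:
        # constant series: all intensity sat at zero frequency and is removed
        zero = CorrelationSeries(
            lags=np.arange(n) * angles.dt,
            values=np.zeros(n),
            n_samples=n - np.arange(n),
        )
        return power_spectrum(zero, window=window, grid_resolution_cm=grid_resolution_cm)
    corr = autocorrelation(centered, angles.dt, max_lag_fs)
    return power_spectrum(corr, window=window, grid_resolution_cm=grid_resolution_cm)


def find_peaks(spec: PowerSpectrum, min_prominence_fraction: float = 0.05) -> PeakTable:
    """Local maxima with prominence ≥ fraction × max intensity, ascending."""
    if not (0.0 < min_prominence_fraction <= 1.0):
        raise ValueError("prominence fraction must be in (0, 1]")
    top = float(spec.intensities.max()) if len(spec.intensities) else 0.0
    if top <= 0.0:
        return PeakTable(np.array([]), np.array([]), np.array([]))
    idx, props = _scipy_find_peaks(
        spec.intensities, prominence=min_prominence_fraction * top
    )
    return PeakTable(
        positions=spec.wavenumbers[idx],
        heights=spec.intensities[idx],
        prominences=props["prominences"],
    )


@dataclass
class BlueShiftAssignment:
    """One-to-one pairing of simulated and experimental peaks.

    ``matches`` holds (sim, exp, shift) with shift = sim − exp inside the
    allowed interval; peaks with no admissible partner stay unmatched.
    """

    matches: list[tuple[float, float, float]]
    unmatched_sim: list[float]
    unmatched_exp: list[float]


def blue_shift_match(
    sim_peaks: PeakTable | np.ndarray,
    exp_peaks: PeakTable | np.ndarray,
    shift_range: tuple[float, float] = (10.0, 15.0),
) -> BlueShiftAssignment:
    """Greedily pair simulated with experimental peaks under a blue shift.

    A pairing is admissible when sim − exp lies inside ``shift_range``
    (default 10–15 cm⁻¹, the typical classical-MD blue shift against
    far-infrared measurements).  Admissible pairs are taken greedily in order
    of increasing distance of (sim − exp) from the interval midpoint.
    """
    lo, hi = shift_range
    if lo > hi:
        raise ValueError("shift_range must be (low, high)")
    sims = list(np.asarray(sim_peaks.positions if isinstance(sim_peaks, PeakTable) else sim_peaks, dtype=float))
    exps = list(np.asarray(exp_peaks.positions if isinstance(exp_peaks, PeakTable) else exp_peaks, dtype=float))
    mid = 0.5 * (lo + hi)
    candidates = []
    for i, s in enumerate(sims):
        for j, e in enumerate(exps):
            shift = s - e
            if lo <= shift <= hi:
                candidates.append((abs(shift - mid), i, j, shift))
    candidates.sort()
    used_s: set[int] = set()
    used_e: set[int] = set()
    matches = []
    for _, i, j, shift in candidates:
        if i in used_s or j in used_e:
            continue
        used_s.add(i)
        used_e.add(j)
        matches.append((sims[i], exps[j], shift))
    matches.sort()
    return BlueShiftAssignment(
        matches=matches,
        unmatched_sim=sorted(s for i, s in enumerate(sims) if i not in used_s),
        unmatched_exp=sorted(e for j, e in enumerate(exps) if j not in used_e),
    )
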