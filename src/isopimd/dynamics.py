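"""Diffusion and vibrational spectra from centroid trajectories.

Diffusion comes from the mean-square displacement of the oxygen
ring-polymer centroids (MSD(t) = 6 D t at long times), fitted across a
temperature grid with the Arrhenius law ``D = D0 exp(-E_A / k_B T)``
above the crossover and the mode-coupling power law
``D = D1 (T - T_MCT)^gamma`` below it.  Spectra are Fourier transforms
of centroid velocity / total-dipole autocorrelation functions; in RPMD
the centroid time-correlation function approximates the Kubo-transformed
quantum one, so band positions are the validated quantity while line
shapes carry thermostat/ring-polymer broadening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import C_CM_PER_PS, HBAR, KB

__all__ = [
    "centroid_msd",
    "diffusion_from_msd",
    "arrhenius_fit",
    "mct_fit",
    "crossover_temperature",
    "autocorrelation",
    "spectral_density",
    "vdos_from_velocities",
    "ir_spectrum",
    "SpectralDensity",
    "peak_position",
]


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------


def centroid_msd(
    positions: np.ndarray, dt: float, max_lag: int | None = None, cell_length: float | None = None
):
    """Multiple-time-origin MSD of unwrapped centroid coordinates.

    ``positions``: (n_frames, n_particles, 3), nm, already unwrapped.
    A frame-to-frame jump larger than half the box (when ``cell_length``
    is given) indicates wrapped input and raises.  Returns (lag times,
    MSD in nm^2).
    """
    x = np.asarray(positions, dtype=float)
    n_frames = x.shape[0]
    if cell_length is not None and n_frames > 1:
        jumps = np.abs(np.diff(x, axis=0)).max()
        if jumps > 0.5 * cell_length:
            raise ValueError(
                "frame-to-frame jump exceeds half the box: unwrap the "
                "trajectory before computing the MSD"
            )
    if max_lag is None:
        max_lag = n_frames // 2
    max_lag = min(max_lag, n_frames - 1)
    # FFT-based multiple-origin average, per particle and dimension
    nfft = 1 << int(np.ceil(np.log2(2 * n_frames)))
    s2 = (x**2).sum(axis=-1)  # (n_frames, n_particles)
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft((fx * fx.conj()).sum(axis=-1), n=nfft, axis=0)[:n_frames].real
    counts = n_frames - np.arange(n_frames)
    sab = acf / counts[:, None]
    csum = np.concatenate([np.zeros((1, x.shape[1])), s2]).cumsum(axis=0)
    msd = np.empty((max_lag + 1, x.shape[1]))
    for lag in range(max_lag + 1):
        # sum of s2[t] + s2[t+lag] over valid origins
        head = csum[n_frames - lag] - csum[0]
        tail = csum[n_frames] - csum[lag]
        msd[lag] = (head + tail) / (n_frames - lag) - 2.0 * sab[lag]
    times = np.arange(max_lag + 1) * dt
    return times, msd.mean(axis=1)


def diffusion_from_msd(
    times: np.ndarray, msd: np.ndarray, window: tuple[float, float] | None = None
):
    """D (nm^2/ps) from the slope of the linear MSD regime, MSD = 6 D t.

    ``window`` is a (t_min, t_max) fraction-free time window in ps; the
    default uses the second half of the available lags.  Warns when the
    log-log slope is below 0.9 (sub-diffusive / ballistic input).
    Returns (D, D_err).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(msd, dtype=float)
    if window is None:
        lo = len(t) // 2
        sel = slice(lo, None)
    else:
        sel = (t >= window[0]) & (t <= window[1])
    ts, ys = t[sel], y[sel]
    mask = ts > 0
    ts, ys = ts[mask], ys[mask]
    if len(ts) < 3:
        raise ValueError("too few points in the MSD fit window")
    if np.all(ys > 0):
        slope_ll = np.polyfit(np.log(ts), np.log(ys), 1)[0]
        if slope_ll < 0.9 or slope_ll > 1.5:
            warnings.warn(
                f"MSD window not diffusive (log-log slope {slope_ll:.2f})",
                stacklevel=2,
            )
    coef, cov = np.polyfit(ts, ys, 1, cov=True)
    return coef[0] / 6.0, float(np.sqrt(cov[0, 0]) / 6.0)


def _arrhenius(t, d0, ea):
    return d0 * np.exp(-ea / (KB * t))


def arrhenius_fit(d_table, t_min: float = 300.0):
    """Fit D(T) >= t_min with D = D0 exp(-E_A/k_B T).

    ``d_table``: DataFrame with columns T and y (D in A^2/ps) as produced
    by the curve-family generator, or a (T, D) tuple of arrays.  Returns
    dict with D0, E_A and their standard errors.
    """
    t, d = _unpack_table(d_table)
    sel = t >= t_min
    t, d = t[sel], d[sel]
    if np.any(d <= 0):
        raise ValueError("non-positive diffusion coefficients in fit range")
    if len(t) < 3:
        raise ValueError("need at least 3 points for the Arrhenius fit")
    # log-linear start, then nonlinear refinement
    b, a = np.polyfit(1.0 / t, np.log(d), 1)
    p0 = (float(np.exp(a)), float(-b * KB))
    popt, pcov = curve_fit(_arrhenius, t, d, p0=p0, maxfev=10000)
    perr = np.sqrt(np.diag(pcov))
    return {
        "D0": popt[0],
        "D0_err": perr[0],
        "E_A": popt[1],
        "E_A_err": perr[1],
        "window": (float(t.min()), float(t.max())),
    }


def _mct(t, d1, t_mct, gamma):
    return d1 * (t - t_mct) ** gamma


def mct_fit(d_table, t_min: float = 220.0, t_max: float = 300.0):
    """Fit D(T) in [t_min, t_max] with the MCT law D1 (T - T_MCT)^gamma.

    T_MCT is bounded below the lowest fitted temperature.  Raises on
    non-convergence with diagnostics; parameters are sensitive to the
    fitting window, so the window is reported alongside.
    """
    t, d = _unpack_table(d_table)
    sel = (t >= t_min) & (t <= t_max)
    t, d = t[sel], d[sel]
    if len(t) < 4:
        raise ValueError("need at least 4 points for the MCT fit")
    tm0 = t.min() - 30.0
    try:
        popt, pcov = curve_fit(
            _mct,
            t,
            d,
            p0=(d.max() / (t.max() - tm0) ** 2, tm0, 2.0),
            bounds=([0.0, 0.0, 0.3], [np.inf, t.min() - 1e-6, 6.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"MCT fit did not converge on window [{t_min}, {t_max}] "
            f"({len(t)} points): {exc}"
        ) from exc
    perr = np.sqrt(np.diag(pcov))
    return {
        "D1": popt[0],
        "D1_err": perr[0],
        "T_MCT": popt[1],
        "T_MCT_err": perr[1],
        "gamma": popt[2],
        "gamma_err": perr[2],
        "window": (float(t.min()), float(t.max())),
    }


def crossover_temperature(arr: dict, mct: dict, bracket=(150.0, 400.0)) -> float:
    """Temperature where the Arrhenius and MCT branches intersect."""
    from scipy.optimize import brentq

    def diff(t):
        return _arrhenius(t, arr["D0"], arr["E_A"]) - _mct(
            t, mct["D1"], mct["T_MCT"], mct["gamma"]
        )

    lo = max(bracket[0], mct["T_MCT"] + 1.0)
    ts = np.linspace(lo, bracket[1], 400)
    vals = np.array([diff(t) for t in ts])
    sign = np.sign(vals)
    idx = np.where(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise ValueError("fitted branches do not intersect in bracket")
    return float(brentq(diff, ts[idx[0]], ts[idx[0] + 1]))


def _unpack_table(d_table):
    try:  # pandas DataFrame from make_curve_family
        return (
            np.asarray(d_table["T"], dtype=float),
            np.asarray(d_table["y"], dtype=float),
        )
    except (KeyError, TypeError, IndexError):
        t, d = d_table
        return np.asarray(t, dtype=float), np.asarray(d, dtype=float)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


@dataclass
class SpectralDensity:
    """Uniform frequency grid (cm^-1) with intensities (arbitrary units)."""

    frequencies: np.ndarray
    intensities: np.ndarray
    kind: str  # "VDOS" or "IR"
    metadata: dict

    def peak(self, f_min: float = 0.0, f_max: float | None = None) -> float:
        return peak_position(self.frequencies, self.intensities, f_min, f_max)

    @property
    def grid_spacing(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def peak_position(freqs, intens, f_min: float = 0.0, f_max: float | None = None) -> float:
    """Location (cm^-1) of the highest peak inside the requested band."""
    f = np.asarray(freqs)
    s = np.asarray(intens)
    sel = f >= f_min
    if f_max is not None:
        sel &= f <= f_max
    if not np.any(sel):
        raise ValueError("empty frequency band")
    return float(f[sel][np.argmax(s[sel])])


def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased multiple-origin autocorrelation via FFT; axis 0 is time."""
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fx * fx.conj(), n=nfft, axis=0)[: max_lag + 1].real
    counts = n - np.arange(max_lag + 1)
    shape = (-1,) + (1,) * (x.ndim - 1)
    return acf / counts.reshape(shape)


def spectral_density(
    series: np.ndarray,
    dt: float,
    weights: np.ndarray | None = None,
    acf_fraction: float = 0.25,
    pad_factor: int = 4,
):
    """One-sided power spectrum of a (possibly multi-channel) series.

    The autocorrelation over ``acf_fraction`` of the trajectory is summed
    over channels (weighted), Hann-windowed, zero-padded and cosine
    transformed.  Returns (wavenumbers cm^-1, intensity).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    else:
        x = x.reshape(x.shape[0], -1)
    n = x.shape[0]
    max_lag = max(8, int(n * acf_fraction))
    max_lag = min(max_lag, n - 1)
    acf = autocorrelation(x, max_lag)
    if weights is not None:
        w = np.broadcast_to(np.asarray(weights, dtype=float).reshape(1, -1), acf.shape)
        total = (acf * w).sum(axis=1)
    else:
        total = acf.sum(axis=1)
    window = np.hanning(2 * (max_lag + 1))[max_lag + 1 :]
    wtotal = total * window
    nfft = pad_factor * 2 * (max_lag + 1)
    # one-sided cosine transform of the symmetric ACF
    ext = np.zeros(nfft)
    ext[: max_lag + 1] = wtotal
    ext[-max_lag:] = wtotal[1:][::-1]
    spec = np.fft.rfft(ext).real * dt
    freqs_cm = np.fft.rfftfreq(nfft, d=dt) / C_CM_PER_PS
    return freqs_cm, spec


def vdos_from_velocities(
    velocities: np.ndarray,
    masses: np.ndarray,
    dt: float,
    acf_fraction: float = 0.25,
    pad_factor: int = 4,
) -> SpectralDensity:
    """Vibrational density of states from centroid velocities.

    ``velocities``: (n_frames, ..., 3) centroid velocities at uniform
    stride ``dt`` (ps); ``masses`` broadcastable over the particle axes.
    The mass-weighted velocity autocorrelation is the classical
    (centroid) stand-in for the Kubo-transformed one.  Sampling must
    resolve the stretch band: Nyquist below 4500 cm^-1 is refused.
    """
    nyquist_cm = 1.0 / (2.0 * dt * C_CM_PER_PS)
    if nyquist_cm < 4500.0:
        raise ValueError(
            f"velocity stride too coarse: Nyquist {nyquist_cm:.0f} cm^-1 "
            "cannot resolve the stretch band (need >= 4500)"
        )
    v = np.asarray(velocities, dtype=float)
    flat = v.reshape(v.shape[0], -1)
    m = np.broadcast_to(
        np.asarray(masses, dtype=float)[..., None], v.shape[1:]
    ).reshape(-1)
    freqs, spec = spectral_density(
        flat, dt, weights=m, acf_fraction=acf_fraction, pad_factor=pad_factor
    )
    return SpectralDensity(
        freqs,
        spec,
        "VDOS",
        {
            "dt_ps": dt,
            "acf_fraction": acf_fraction,
            "pad_factor": pad_factor,
            "convention": "mass-weighted centroid VACF, Hann window",
        },
    )


def ir_spectrum(
    dipoles: np.ndarray,
    dt: float,
    temperature: float,
    acf_fraction: float = 0.25,
    pad_factor: int = 4,
) -> SpectralDensity:
    """IR absorption spectrum from the total-dipole autocorrelation.

    Intensity is ``omega * tanh(beta hbar omega / 2)`` times the Fourier
    transform of the centroid dipole ACF (harmonic quantum-correction
    convention, recorded in the metadata).  Peak positions are the
    validated quantity; line widths carry ring-polymer broadening.
    """
    nyquist_cm = 1.0 / (2.0 * dt * C_CM_PER_PS)
    if nyquist_cm < 4500.0:
        raise ValueError(
            f"dipole stride too coarse: Nyquist {nyquist_cm:.0f} cm^-1 "
            "cannot resolve the stretch band (need >= 4500)"
        )
    mu = np.asarray(dipoles, dtype=float)
    freqs, spec = spectral_density(
        mu, dt, acf_fraction=acf_fraction, pad_factor=pad_factor
    )
    beta = 1.0 / (KB * temperature)
    omega = 2.0 * np.pi * freqs * C_CM_PER_PS  # rad/ps
    corr = omega * np.tanh(0.5 * beta * HBAR * omega)
    return SpectralDensity(
        freqs,
        corr * spec,
        "IR",
        {
            "dt_ps": dt,
            "temperature_K": temperature,
            "convention": "omega*tanh(beta hbar omega/2) x FT of dipole ACF",
        },
    )
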