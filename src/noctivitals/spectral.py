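"""Lomb-Scargle spectral estimation for irregularly sampled tachograms.

A nocturnal tachogram is a beat-interval series indexed by beat time, which is
irregular by construction (each sample arrives one heartbeat after the last).
The classical Lomb-Scargle periodogram handles this sampling directly, without
interpolating onto a uniform grid, and is therefore the estimator used for the
frequency-domain heart-rate-variability indices.

The periodogram is evaluated with the Press-Rybicki algorithm: the trigonometric
sums are spread onto a uniform grid by Lagrange extirpolation and computed with
a single FFT, reducing the cost from O(n_samples * n_freqs) to
O((n_samples + n_freqs) log n_freqs). A whole night is ~36,000 beats evaluated
on ~70,000 frequencies, so the direct sum is not practical. The output matches
the direct (unnormalized) Lomb-Scargle definition used by
``scipy.signal.lombscargle``.

Band powers are reported in absolute ms^2, normalized so that the integral of
the periodogram over the full frequency grid equals the sample variance of the
series (Parseval contract); consequently total power approximates SDNN^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BandPowers",
    "FREQUENCY_BANDS",
    "lomb_scargle",
    "band_powers",
]

#: HRV band edges in Hz; closed on the left, open on the right.
#: ULF is (0, 0.0033) since the periodogram grid excludes zero frequency.
FREQUENCY_BANDS: dict[str, tuple[float, float]] = {
    "ulf": (0.0, 0.0033),
    "vlf": (0.0033, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.40),
}

#: Upper edge of total power integration, Hz.
TP_EDGE = 0.40

#: Minimum record span (s) for LF/HF to be estimated at all.
MIN_SPAN_S = 30 * 60.0

#: Minimum record span (s) for the slow bands (ULF/VLF) to be reported.
SLOW_BAND_SPAN_S = 5 * 3600.0


def _extirpolate(x: np.ndarray, y: np.ndarray, n: int, m: int) -> np.ndarray:
    """Spread samples ``y`` at real-valued positions ``x`` onto an integer grid.

    Lagrange extirpolation of order ``m`` (Press & Rybicki); positions must lie
    in [0, n).
    """
    result = np.zeros(n, dtype=y.dtype)

    on_grid = x % 1 == 0
    if on_grid.any():
        np.add.at(result, x[on_grid].astype(np.intp), y[on_grid])
        x, y = x[~on_grid], y[~on_grid]
    if len(x) == 0:
        return result

    ilo = np.clip((x - m // 2).astype(np.intp), 0, n - m)
    numerator = y * np.prod(x - ilo - np.arange(m)[:, np.newaxis], axis=0)
    denominator = float(math.factorial(m - 1))
    for j in range(m):
        if j > 0:
            denominator *= j / (j - m)
        ind = ilo + (m - 1 - j)
        np.add.at(result, ind, numerator / (denominator * (x - ind)))
    return result


def _trig_sum(
    t: np.ndarray,
    h: np.ndarray,
    df: float,
    nf: int,
    f0: float = 0.0,
    freq_factor: float = 1.0,
    grid_oversampling: int = 5,
    m: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Compute S_k = sum h sin(2 pi f_k t), C_k = sum h cos(2 pi f_k t).

    Frequencies are f_k = (f0 + k df) * freq_factor for k = 0..nf-1, evaluated
    via extirpolation onto a 2^p grid followed by one inverse FFT.
    """
    df = df * freq_factor
    f0 = f0 * freq_factor
    if df <= 0:
        raise ValueError("df must be positive")

    nfft = 1
    while nfft < nf * grid_oversampling:
        nfft <<= 1

    t0 = t.min()
    if f0 > 0:
        h = h * np.exp(2j * np.pi * f0 * (t - t0))
    h = np.asarray(h, dtype=complex)
    tnorm = ((t - t0) * nfft * df) % nfft
    grid = _extirpolate(tnorm, h, nfft, m)

    fftgrid = np.fft.ifft(grid)[:nf]
    if t0 != 0:
        f = f0 + df * np.arange(nf)
        fftgrid = fftgrid * np.exp(2j * np.pi * t0 * f)

    c = nfft * fftgrid.real
    s = nfft * fftgrid.imag
    return s, c


def lomb_scargle(
    t: np.ndarray, y: np.ndarray, df: float, nf: int, center: bool = True
) -> np.ndarray:
    """Unnormalized Lomb-Scargle periodogram at frequencies df*(1..nf) Hz.

    Matches the classical definition used by ``scipy.signal.lombscargle``
    (with its default normalization), i.e. power in units of y^2 scaled by
    n_samples/2 at a fully coherent frequency.

    Parameters
    ----------
    t : array of sample times, seconds.
    y : array of sample values.
    df : frequency spacing, Hz.
    nf : number of frequencies.
    center : subtract the sample mean first (the tachogram convention).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-D arrays of equal length")
    if len(t) < 2:
        raise ValueError("need at least two samples")
    if center:
        y = y - y.mean()

    sh, ch = _trig_sum(t, y, df, nf, f0=df)
    s2, c2 = _trig_sum(t, np.ones_like(y), df, nf, f0=df, freq_factor=2.0)

    n = len(t)
    omega_tau = 0.5 * np.arctan2(s2, c2)
    cos2wt = np.cos(2 * omega_tau)
    sin2wt = np.sin(2 * omega_tau)
    cc = 0.5 * (n + c2 * cos2wt + s2 * sin2wt)
    ss = 0.5 * (n - c2 * cos2wt - s2 * sin2wt)

    cw, sw = np.cos(omega_tau), np.sin(omega_tau)
    yc = ch * cw + sh * sw
    ys = sh * cw - ch * sw

    # guard degenerate denominators at frequencies commensurate with sampling
    eps = np.finfo(float).tiny
    power = 0.5 * (yc**2 / np.maximum(cc, eps) + ys**2 / np.maximum(ss, eps))
    return power


@dataclass(frozen=True)
class BandPowers:
    """Frequency-domain powers of one night's tachogram, absolute ms^2.

    ``ulf``/``vlf`` are NaN when the record is too short (<5 h span) to
    resolve the slow bands; ``lf_hf`` is NaN when HF is exactly zero.
    """

    tp: float
    ulf: float
    vlf: float
    lf: float
    hf: float
    lf_hf: float


def band_powers(
    beat_times: np.ndarray,
    beat_intervals: np.ndarray,
    oversample: int = 5,
    fmax: float = 0.5,
) -> BandPowers:
    """Integrate the tachogram periodogram over the standard HRV bands.

    The interval series (ms) is indexed by the onset time of each interval,
    i.e. interval i spans beat_times[i]..beat_times[i+1] and is placed at
    beat_times[i]. The periodogram is evaluated on the grid
    f = df, 2 df, ..., fmax with df = 1/(oversample * span) and rescaled so
    its integral over the full grid equals the sample variance (ddof=1) of
    the intervals; band powers are the corresponding partial sums.

    Raises
    ------
    ValueError
        If beat times are not strictly increasing, lengths are inconsistent,
        or the span is under 30 minutes.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    beat_intervals = np.asarray(beat_intervals, dtype=float)
    if len(beat_times) != len(beat_intervals) + 1:
        raise ValueError("expected len(beat_times) == len(beat_intervals) + 1")
    if np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")

    t = beat_times[:-1]
    y = beat_intervals
    span = t[-1] - t[0]
    if span < MIN_SPAN_S:
        raise ValueError(
            f"record spans {span / 60:.1f} min; at least 30 min are required "
            "for LF/HF estimation"
        )

    variance = float(np.var(y, ddof=1))
    if variance <= 1e-10:
        # constant tachogram: no oscillatory power in any band
        return BandPowers(tp=0.0, ulf=0.0, vlf=0.0, lf=0.0, hf=0.0, lf_hf=float("nan"))

    df = 1.0 / (oversample * span)
    nf = int(np.floor(fmax / df))
    power = lomb_scargle(t, y, df, nf)
    freqs = df * np.arange(1, nf + 1)
    total = power.sum()

    def integrate(lo: float, hi: float, closed_right: bool = False) -> float:
        if closed_right:
            mask = (freqs >= lo) & (freqs <= hi)
        else:
            mask = (freqs >= lo) & (freqs < hi)
        return float(variance * power[mask].sum() / total)

    slow_ok = span >= SLOW_BAND_SPAN_S
    ulf = integrate(*FREQUENCY_BANDS["ulf"]) if slow_ok else float("nan")
    vlf = integrate(*FREQUENCY_BANDS["vlf"]) if slow_ok else float("nan")
    lf = integrate(*FREQUENCY_BANDS["lf"])
    hf = integrate(*FREQUENCY_BANDS["hf"])
    tp = integrate(0.0, TP_EDGE, closed_right=True)
    lf_hf = lf / hf if hf > 0 else float("nan")
    return BandPowers(tp=tp, ulf=ulf, vlf=vlf, lf=lf, hf=hf, lf_hf=lf_hf)
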