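"""Tremor signal features: resultant acceleration, spline smoothing,
approximate entropy and FFT peak frequency.

These operate on tri-axial accelerometer recordings (synthetic or real)
and on single-axis model outputs alike.  Approximate entropy follows the
classical regularity statistic

    ApEn(m, r, N) = phi_m(r) - phi_{m+1}(r),
    phi_k(r) = (N-k+1)^-1 * sum_i log( C_i^k(r) ),
    C_i^k(r) = #{ j : max_a |u(i+a) - u(j+a)| <= r } / (N-k+1),

with Chebyshev (max-norm) distances and self-matches included in the
counts, so the statistic is well defined (no log 0) and non-negative up to
numerical noise for stationary series.  Lower ApEn means a more regular,
more predictable signal — rest tremor is more regular than healthy
physiological movement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

STATE_LABELS = ("pre", "during", "post")


@dataclass
class TriaxialRecording:
    """Uniformly sampled tri-axial acceleration (consistent arbitrary units)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs_hz: float

    def __post_init__(self):
        n = len(self.times)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("times, x, y, z must have equal length")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if n > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, 1.0 / self.fs_hz, rtol=1e-6, atol=1e-9):
                raise ValueError("times inconsistent with fs_hz")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "x": self.x, "y": self.y, "z": self.z})

    @classmethod
    def from_csv(cls, path, fs_hz: Optional[float] = None) -> "TriaxialRecording":
        df = pd.read_csv(path, comment="#")
        missing = {"t", "x", "y", "z"} - set(df.columns)
        if missing:
            raise ValueError(f"accelerometer CSV missing columns: {sorted(missing)}")
        t = df["t"].to_numpy(float)
        if fs_hz is None:
            fs_hz = 1.0 / float(np.median(np.diff(t)))
        return cls(times=t, x=df["x"].to_numpy(float), y=df["y"].to_numpy(float),
                   z=df["z"].to_numpy(float), fs_hz=fs_hz)


@dataclass
class RecordingSession:
    """Pre/during/post recording states, each a list of interval recordings."""

    subject: str
    states: dict[str, list[TriaxialRecording]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.states) - set(STATE_LABELS)
        if unknown:
            raise ValueError(f"unknown state labels: {sorted(unknown)}")


@dataclass(frozen=True)
class ApEnParams:
    """Approximate-entropy settings.

    ``r`` is a tolerance radius; with ``r_is_fraction`` (the default, the
    de facto standard for physiological series) it is interpreted as a
    fraction of the series SD, making ApEn amplitude-scale invariant.
    """

    m: int = 2
    r: float = 0.2
    r_is_fraction: bool = True

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")

    def radius(self, series: np.ndarray) -> float:
        return self.r * float(np.std(series)) if self.r_is_fraction else self.r


@dataclass(frozen=True)
class SpectralPeak:
    freq_hz: float
    amplitude: float
    band: tuple[float, float]
    resolution_hz: float = 0.0

    def __post_init__(self):
        if not (self.band[0] <= self.freq_hz <= self.band[1]):
            raise ValueError("peak frequency outside search band")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def resultant_acceleration(rec: TriaxialRecording) -> np.ndarray:
    """Euclidean norm sqrt(x^2 + y^2 + z^2), sample by sample."""
    return np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)


def smooth_recording(
    series: np.ndarray, fs_hz: float, smoothing_param: Optional[float] = None
) -> np.ndarray:
    """Cubic smoothing-spline fit evaluated on the original grid.

    ``smoothing_param`` is the spline's roughness penalty: 0 reproduces the
    input exactly (interpolation limit), None selects it by generalized
    cross-validation.
    """
    series = np.asarray(series, float)
    if series.size < 4:
        raise ValueError("need at least 4 samples to fit a cubic spline")
    t = np.arange(series.size) / fs_hz
    spl = make_smoothing_spline(t, series, lam=smoothing_param)
    return np.asarray(spl(t), float)


def _phi_pair(u: np.ndarray, m: int, r: float) -> tuple[float, float]:
    """(phi_m, phi_{m+1}) sharing one pairwise-distance pass.

    Chebyshev matching of k-length templates factorizes into scalar
    matches: max_a |u[i+a]-u[j+a]| <= r  iff  every shifted pair matches.
    One boolean N x N matrix therefore serves all embedding dimensions.
    """
    n = u.size
    close = np.abs(u[:, None] - u[None, :]) <= r
    phis = []
    match = close
    for k in range(1, m + 2):
        if k > 1:
            match = match[:-1, :-1] & close[k - 1 :, k - 1 :]
        if k >= m:
            n_vec = n - k + 1
            counts = match.sum(axis=1)
            phis.append(float(np.mean(np.log(counts / n_vec))))
    return phis[0], phis[1]


def approximate_entropy(series: np.ndarray, params: ApEnParams = ApEnParams()) -> float:
    """ApEn(m, r) of a scalar series (see module docstring for conventions).

    A constant series returns exactly 0 (every template matches every
    other at both embedding lengths).
    """
    u = np.asarray(series, float)
    if u.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if u.size <= params.m + 1:
        raise ValueError(f"series length {u.size} too short for m={params.m}")
    if np.ptp(u) == 0.0:
        return 0.0
    r = params.radius(u)
    if r <= 0:
        return 0.0
    phi_m, phi_m1 = _phi_pair(u, params.m, r)
    return phi_m - phi_m1


def peak_frequency(
    series: np.ndarray,
    fs_hz: float,
    band_hz: tuple[float, float] = (2.0, 12.0),
    window: Optional[str] = None,
) -> SpectralPeak:
    """Dominant spectral component within a band.

    Mean-removed magnitude spectrum via the FFT (rectangular window by
    default, optional Hann), normalized so a unit-amplitude on-bin sinusoid
    has peak amplitude 1.  Frequency resolution is fs/N.
    """
    u = np.asarray(series, float)
    n = u.size
    if n < 2:
        raise ValueError("series too short for a spectrum")
    lo, hi = band_hz
    if not (0 <= lo < hi) or lo >= fs_hz / 2:
        raise ValueError(f"invalid band {band_hz} for fs={fs_hz}")
    u = u - u.mean()
    if window == "hann":
        w = np.hanning(n)
        u = u * w
        norm = w.sum() / 2.0
    elif window is None:
        norm = n / 2.0
    else:
        raise ValueError("window must be None or 'hann'")
    spec = np.abs(np.fft.rfft(u)) / norm
    freqs = np.fft.rfftfreq(n, 1.0 / fs_hz)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band_hz} contains no FFT bins at resolution {fs_hz/n:.4g} Hz")
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(spec[idx])]
    return SpectralPeak(
        freq_hz=float(freqs[best]),
        amplitude=float(spec[best]),
        band=(lo, hi),
        resolution_hz=fs_hz / n,
    )


def vector_spectrum_peak(
    rec: TriaxialRecording, band_hz: tuple[float, float] = (2.0, 12.0)
) -> SpectralPeak:
    """Tremor peak from the rotation-invariant tri-axial vector spectrum.

    Sums the mean-removed power of the three axes before the peak search.
    Unlike the spectrum of the resultant-acceleration norm — which, for a
    zero-mean signal, is a rectified waveform peaking at twice the tremor
    frequency — the vector spectrum peaks at the physical tremor frequency.
    """
    n = rec.n_samples
    power = np.zeros(n // 2 + 1)
    for axis in (rec.x, rec.y, rec.z):
        a = np.asarray(axis, float)
        power += np.abs(np.fft.rfft(a - a.mean())) ** 2
    amp = np.sqrt(power) / (n / 2.0)
    freqs = np.fft.rfftfreq(n, 1.0 / rec.fs_hz)
    lo, hi = band_hz
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band_hz} contains no FFT bins")
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(amp[idx])]
    return SpectralPeak(float(freqs[best]), float(amp[best]), (lo, hi), rec.fs_hz / n)


def session_features(
    session: RecordingSession,
    apen_params: ApEnParams = ApEnParams(),
    band_hz: tuple[float, float] = (2.0, 12.0),
    smoothing_param: Optional[float] = None,
    smooth: bool = False,
) -> pd.DataFrame:
    """Per-interval feature table for one pre/during/post session.

    For every recording interval: mean resultant acceleration, ApEn of the
    RA series, and the tremor peak frequency/amplitude from the vector
    spectrum.  Returns a tidy frame with columns
    (subject, state, interval, mean_ra, apen, peak_freq_hz, peak_amp).
    Set ``smooth=True`` to spline-smooth the RA series first.
    """
    missing = [s for s in STATE_LABELS if s not in session.states or not session.states[s]]
    if missing:
        raise ValueError(f"session {session.subject!r} missing states: {missing}")
    rows = []
    for state in STATE_LABELS:
        for k, rec in enumerate(session.states[state]):
            ra = resultant_acceleration(rec)
            if smooth:
                ra = smooth_recording(ra, rec.fs_hz, smoothing_param)
            peak = vector_spectrum_peak(rec, band_hz)
            rows.append(
                {
                    "subject": session.subject,
                    "state": state,
                    "interval": k,
                    "mean_ra": float(np.mean(ra)),
                    "apen": approximate_entropy(ra, apen_params),
                    "peak_freq_hz": peak.freq_hz,
                    "peak_amp": peak.amplitude,
                }
            )
    return pd.DataFrame(rows)


def state_summary(features: pd.DataFrame) -> pd.DataFrame:
    """Average the per-interval features to one row per (subject, state)."""
    value_cols = ["mean_ra", "apen", "peak_freq_hz", "peak_amp"]
    return (
        features.groupby(["subject", "state"], sort=False)[value_cols]
        .mean()
        .reset_index()
    )
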