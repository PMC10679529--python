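"""Model experiments and paired statistics.

Four experiments mirror the study design:

* healthy-vs-PD contrast of the network outputs (amplitudes, peak
  frequencies, SC-MS approximate entropy);
* a continuous pre/during/post stimulation run of the PD model;
* a coupling-weight sweep with an exponential regression a*exp(b*B) and
  derivative-based sensitivities over the healthy and PD weight ranges;
* Wilcoxon signed-rank pre/post statistics on cohort feature tables, with
  an advisory Lilliefors normality check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import wilcoxon

from tremorloop.features import ApEnParams, approximate_entropy, peak_frequency, state_summary
from tremorloop.oscillators import (
    CouplingConfig,
    SimulationConfig,
    TrajectorySet,
    UNIT_LABELS,
    default_params,
    preset_state,
    simulate_network,
)
from tremorloop.stimulation import StimulationProtocol, StimulationWaveform, protocol_drive

#: model-output ApEn cadence: 12.5 samples per cycle of the SC-MS 10-Hz
#: rhythm.  100 Hz would be exactly 10 samples/cycle — a commensurate
#: sampling at which ApEn of the near-periodic PD output degenerates.
APEN_RESAMPLE_HZ = 125.0
#: ApEn window lengths (samples at APEN_RESAMPLE_HZ)
APEN_N_STATE = 600
APEN_N_PROTOCOL = 1200

HEALTHY_MID_B = 35.0
PD_MID_B = 5.0
HEALTHY_B_RANGE = (30.0, 40.0)
PD_B_RANGE = (1.0, 10.0)


# ---------------------------------------------------------------------------
# result containers

@dataclass
class StateComparison:
    amplitude_healthy: dict[str, float]
    amplitude_pd: dict[str, float]
    peakfreq_healthy: dict[str, float]
    peakfreq_pd: dict[str, float]
    apen_healthy: float
    apen_pd: float
    meta: dict = field(default_factory=dict)


@dataclass
class SweepResult:
    B_grid: np.ndarray
    amplitudes: pd.DataFrame  # one row per grid point, one column per unit
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.B_grid = np.asarray(self.B_grid, float)
        if np.any(np.diff(self.B_grid) <= 0):
            raise ValueError("B_grid must be strictly increasing")
        if len(self.amplitudes) != self.B_grid.size:
            raise ValueError("one amplitude row per grid point required")


@dataclass
class ExponentialFit:
    """f(B) = a * exp(b*B) with derivative-based sensitivities."""

    a: float
    exp_rate_b: float
    rss: float
    sens_healthy: float
    sens_pd: float
    init: tuple[float, float] = (np.nan, np.nan)


@dataclass
class ProtocolFeatures:
    mean_accel: dict[str, float]
    apen: dict[str, float]
    peak_freq: dict[str, float]
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# basic measures

def amplitude_measure(series: np.ndarray, mode: str = "mean_abs") -> float:
    """Activity measure of a steady-state window: mean |Y| (default) or RMS."""
    u = np.asarray(series, float)
    if u.size == 0:
        raise ValueError("empty analysis window")
    if mode == "mean_abs":
        return float(np.mean(np.abs(u)))
    if mode == "rms":
        return float(np.sqrt(np.mean(u**2)))
    raise ValueError("mode must be 'mean_abs' or 'rms'")


def _resample(series: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    """Integer-stride decimation (the model outputs are band-limited far
    below the target Nyquist, so no anti-alias filter is needed)."""
    step = fs_from / fs_to
    if abs(step - round(step)) > 1e-9:
        raise ValueError(f"fs ratio {fs_from}/{fs_to} is not an integer")
    return series[:: int(round(step))]


def _model_apen(
    series: np.ndarray, fs_hz: float, apen_params: ApEnParams, n_samples: int
) -> float:
    u = _resample(np.asarray(series, float), fs_hz, APEN_RESAMPLE_HZ)
    return approximate_entropy(u[:n_samples], apen_params)


# ---------------------------------------------------------------------------
# experiments

def compare_states(
    sim: Optional[SimulationConfig] = None,
    healthy_B: float | Sequence[float] | None = None,
    pd_B: float | Sequence[float] | None = None,
    apen_params: ApEnParams = ApEnParams(),
    seed: Optional[int] = None,
) -> StateComparison:
    """Matched healthy/PD simulations differing only in coupling weights.

    Amplitude is the steady-state mean |Y| per unit; peak frequencies come
    from the mean-removed magnitude spectrum of the steady window; ApEn is
    computed on the SC-MS output resampled to ``APEN_RESAMPLE_HZ`` over a
    window of ``APEN_N_STATE`` samples (ApEn is length sensitive).
    """
    sim = sim or SimulationConfig()
    results = {}
    for label, B in (("healthy", healthy_B), ("pd", pd_B)):
        params, coupling = preset_state(label, B, seed)
        traj = simulate_network(sim, params, coupling)
        sl = traj.steady_slice
        amps, freqs = {}, {}
        for unit in UNIT_LABELS:
            w = traj.unit(unit)[sl]
            amps[unit] = amplitude_measure(w)
            freqs[unit] = peak_frequency(w, traj.fs_hz, band_hz=(0.0, traj.fs_hz / 2)).freq_hz
        apen = _model_apen(traj.y_s[sl], traj.fs_hz, apen_params, APEN_N_STATE)
        results[label] = (amps, freqs, apen, coupling)
    return StateComparison(
        amplitude_healthy=results["healthy"][0],
        amplitude_pd=results["pd"][0],
        peakfreq_healthy=results["healthy"][1],
        peakfreq_pd=results["pd"][1],
        apen_healthy=results["healthy"][2],
        apen_pd=results["pd"][2],
        meta={
            "healthy_weights": results["healthy"][3].weights(),
            "pd_weights": results["pd"][3].weights(),
            "apen": {"m": apen_params.m, "r": apen_params.r,
                     "r_is_fraction": apen_params.r_is_fraction,
                     "resample_hz": APEN_RESAMPLE_HZ, "n": APEN_N_STATE},
            "amplitude_mode": "mean_abs",
            "t_end": sim.t_end,
        },
    )


@dataclass(frozen=True)
class ProtocolWindows:
    """Feature windows within each protocol phase (seconds).

    ``settle_during`` allows the entrainment transient to pass before the
    during-stimulation window opens; ``settle_post`` skips the switch-off
    edge while keeping the decaying offline drive inside the window.
    """

    settle_pre: float = 10.0
    settle_during: float = 15.0
    settle_post: float = 5.0
    length: float = 30.0


def simulate_protocol(
    proto: Optional[StimulationProtocol] = None,
    state: str = "pd",
    apen_params: ApEnParams = ApEnParams(),
    sim: Optional[SimulationConfig] = None,
    windows: ProtocolWindows = ProtocolWindows(),
    weight: float | Sequence[float] | None = None,
) -> ProtocolFeatures:
    """One continuous pre/during/post run with features per phase.

    If the waveform frequency is unset, it is taken from the SC-MS peak of
    an unstimulated baseline run — the model analog of reading each
    patient's tremor peak before choosing the tACS frequency.
    """
    proto = proto or StimulationProtocol()
    params, coupling = preset_state(state, weight)

    wf = proto.waveform
    if wf.mode != "off" and wf.freq_w_hz is None:
        base_sim = SimulationConfig(
            t_end=max(proto.pre_duration, 30.0), dt_out=0.001, transient_discard=10.0
        )
        base = simulate_network(base_sim, params, coupling)
        f0 = peak_frequency(
            base.y_s[base.steady_slice], base.fs_hz, band_hz=(0.0, base.fs_hz / 2)
        ).freq_hz
        wf = replace(wf, freq_w_hz=f0)
        proto = replace(proto, waveform=wf)

    sim = sim or SimulationConfig(t_end=proto.t_end, dt_out=0.001, transient_discard=10.0)
    if sim.t_end < proto.t_end:
        raise ValueError("simulation shorter than the stimulation protocol")
    traj = simulate_network(sim, params, coupling, stim=lambda t: protocol_drive(t, proto))

    fs = traj.fs_hz
    starts = {
        "pre": windows.settle_pre,
        "during": proto.pre_duration + windows.settle_during,
        "post": proto.pre_duration + proto.stim_duration + windows.settle_post,
    }
    ends_max = {
        "pre": proto.pre_duration,
        "during": proto.pre_duration + proto.stim_duration,
        "post": proto.t_end,
    }
    mean_accel, apen, pkf = {}, {}, {}
    for phase in ("pre", "during", "post"):
        t0 = starts[phase]
        t1 = min(t0 + windows.length, ends_max[phase])
        if t1 <= t0:
            raise ValueError(f"empty feature window for phase {phase!r}")
        w = traj.y_s[int(round(t0 * fs)) : int(round(t1 * fs))]
        mean_accel[phase] = amplitude_measure(w)
        apen[phase] = _model_apen(w, fs, apen_params, APEN_N_PROTOCOL)
        pkf[phase] = peak_frequency(w, fs, band_hz=(0.0, fs / 2)).freq_hz
    return ProtocolFeatures(
        mean_accel=mean_accel,
        apen=apen,
        peak_freq=pkf,
        meta={
            "waveform": {"A": wf.amplitude_A, "f_hz": wf.freq_w_hz,
                         "b": wf.decay_b, "mode": wf.mode},
            "protocol": (proto.pre_duration, proto.stim_duration, proto.post_duration),
            "weights": coupling.weights(),
            "windows": (windows.settle_pre, windows.settle_during,
                        windows.settle_post, windows.length),
            "apen": {"m": apen_params.m, "r": apen_params.r,
                     "resample_hz": APEN_RESAMPLE_HZ, "n": APEN_N_PROTOCOL},
        },
    )


def sweep_coupling(
    B_grid: Sequence[float],
    sim: Optional[SimulationConfig] = None,
    weights: str = "tied",
) -> SweepResult:
    """Amplitude of each unit while sweeping the coupling weight.

    By default all three weights are tied to a single B per grid point
    (the sweep's x-axis is one weight value); ``weights='BR_only'`` sweeps
    the mutual cortex-cerebellum weight alone, holding B1=B2 at the PD
    midpoint.
    """
    B_grid = np.asarray(B_grid, float)
    if np.any((B_grid < 1.0) | (B_grid > 40.0)):
        raise ValueError("B grid must lie within [1, 40]")
    sim = sim or SimulationConfig()
    params = default_params()
    rows = []
    for B in B_grid:
        if weights == "tied":
            coupling = CouplingConfig(BR=B, B1=B, B2=B)
        elif weights == "BR_only":
            coupling = CouplingConfig(BR=B, B1=PD_MID_B, B2=PD_MID_B)
        else:
            raise ValueError("weights must be 'tied' or 'BR_only'")
        traj = simulate_network(sim, params, coupling)
        sl = traj.steady_slice
        rows.append({u: amplitude_measure(traj.unit(u)[sl]) for u in UNIT_LABELS})
    return SweepResult(
        B_grid=B_grid,
        amplitudes=pd.DataFrame(rows),
        meta={"weights": weights, "t_end": sim.t_end, "amplitude_mode": "mean_abs"},
    )


def fit_exponential(B: Sequence[float], amplitudes: Sequence[float]) -> ExponentialFit:
    """Nonlinear least squares for f(B) = a*exp(b*B).

    Initialized from the closed-form log-linear regression of log(amp) on
    B; raises with the initialization attached if the refinement fails.
    """
    B = np.asarray(B, float)
    y = np.asarray(amplitudes, float)
    if B.size < 3:
        raise ValueError("need at least 3 points to fit an exponential")
    if np.any(y <= 0):
        raise ValueError("amplitudes must be positive")
    slope, intercept = np.polyfit(B, np.log(y), 1)
    p0 = (math.exp(intercept), slope)
    try:
        popt, _ = curve_fit(lambda b_, a, b: a * np.exp(b * b_), B, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"exponential fit failed to converge (log-linear init a={p0[0]:.6g}, "
            f"b={p0[1]:.6g})"
        ) from exc
    a, b = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - a * np.exp(b * B)) ** 2))
    fit = ExponentialFit(a=a, exp_rate_b=b, rss=rss, sens_healthy=np.nan,
                         sens_pd=np.nan, init=p0)
    fit.sens_healthy = sensitivity(fit, HEALTHY_B_RANGE)
    fit.sens_pd = sensitivity(fit, PD_B_RANGE)
    return fit


def loglinear_fit(B: Sequence[float], amplitudes: Sequence[float]) -> tuple[float, float]:
    """Closed-form log-linear solution (a, b); the fit initializer."""
    B = np.asarray(B, float)
    slope, intercept = np.polyfit(B, np.log(np.asarray(amplitudes, float)), 1)
    return math.exp(intercept), float(slope)


def sensitivity(
    fit: ExponentialFit, B_range: tuple[float, float], endpoints: bool = False
) -> float | tuple[float, float, float]:
    """Derivative a*b*exp(b*B) of the fitted curve over a weight range.

    Evaluated at the range midpoint; with ``endpoints=True`` returns
    (midpoint, low-end, high-end) values.
    """
    lo, hi = B_range
    if hi < lo:
        raise ValueError("empty range")
    a, b = fit.a, fit.exp_rate_b

    def deriv(B):
        return a * b * math.exp(b * B)

    mid = deriv(0.5 * (lo + hi))
    if endpoints:
        return mid, deriv(lo), deriv(hi)
    return mid


# ---------------------------------------------------------------------------
# paired statistics

FEATURE_COLUMNS = ("mean_ra", "apen", "peak_freq_hz")


def _lilliefors_p(values: np.ndarray) -> float:
    """Kolmogorov–Smirnov normality check with estimated parameters."""
    from statsmodels.stats.diagnostic import lilliefors

    if np.ptp(values) == 0:
        return 0.0  # degenerate: certainly not a continuous normal sample
    return float(lilliefors(values, dist="norm")[1])


def _wilcoxon_p(pre: np.ndarray, other: np.ndarray) -> float:
    """Wilcoxon signed-rank p (Pratt zeros, exact for n <= 25).

    All-zero differences carry no evidence against the null: p = 1.
    """
    diff = other - pre
    if np.all(diff == 0):
        return 1.0
    n = len(diff)
    try:
        res = wilcoxon(other, pre, zero_method="pratt",
                       method="exact" if n <= 25 else "auto")
    except ValueError:
        res = wilcoxon(other, pre, zero_method="pratt", method="auto")
    return float(res.pvalue)


def paired_stats(
    features: pd.DataFrame,
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """During-vs-pre and post-vs-pre paired tests per feature.

    ``features`` is a tidy per-interval or per-(subject, state) table; it
    is averaged to one row per (subject, state) first.  Percent change is
    (pre - x)/pre * 100 per subject, reported as the cohort mean.  The
    Lilliefors normality p per condition is advisory; the Wilcoxon
    signed-rank test is always used, mirroring a non-normal small-n
    design.
    """
    if "interval" in features.columns:
        features = state_summary(features)
    wide = {}
    for state in ("pre", "during", "post"):
        sub = features[features["state"] == state].set_index("subject")
        if sub.empty:
            raise ValueError(f"no rows for state {state!r}")
        wide[state] = sub
    subjects = sorted(set(wide["pre"].index))
    for state in ("during", "post"):
        missing = set(subjects) ^ set(wide[state].index)
        if missing:
            raise ValueError(f"unpaired subjects for state {state!r}: {sorted(missing)}")
    if len(subjects) < 5:
        raise ValueError("need at least 5 paired subjects")

    rows = []
    for col in feature_columns:
        pre = wide["pre"].loc[subjects, col].to_numpy(float)
        for comparison in ("during", "post"):
            x = wide[comparison].loc[subjects, col].to_numpy(float)
            pct = float(np.mean((pre - x) / pre * 100.0))
            p = _wilcoxon_p(pre, x)
            rows.append(
                {
                    "feature": col,
                    "comparison": f"{comparison}_vs_pre",
                    "n": len(subjects),
                    "percent_change": pct,
                    "p_value": p,
                    "significant": p < alpha,
                    "normality_p_pre": _lilliefors_p(pre),
                    f"normality_p_{comparison}": _lilliefors_p(x),
                }
            )
    return pd.DataFrame(rows)
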