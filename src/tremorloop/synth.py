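"""Synthetic tri-axial accelerometer cohorts with the clinical session
structure.

Each subject carries a rest tremor in the 4–7 Hz band: a dominant
sinusoid with second/third harmonics, slow cycle-to-cycle amplitude and
frequency jitter, additive wideband noise and low-frequency baseline
wander, distributed over the three axes by a fixed unit loading vector.
A session records three states (pre / during / post stimulation), each
65 s containing three 15-s intervals separated by 10-s gaps; only the
intervals produce data.

The stimulation effect is injected multiplicatively: the during and post
interval signals (tremor, noise and drift together) are scaled by the
profile's attenuation factors, so the mean resultant acceleration scales
by exactly the same factor and the pipeline-recovered percent change is
defined on the quantity the statistics report.  Regularity is manipulated
separately by shrinking (during) or boosting (post) the jitter and the
relative noise level, which moves approximate entropy without touching
the injected amplitude effect.

Gravity is excluded by default (recordings are treated as high-pass
filtered); an optional constant 1-g offset is available.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from tremorloop.features import RecordingSession, TriaxialRecording, STATE_LABELS

TREMOR_BAND_HZ = (4.0, 7.0)
GRAVITY = 9.81


@dataclass(frozen=True)
class SubjectSpec:
    """Per-subject tremor parameters (acceleration units ~ m/s^2)."""

    tremor_freq_hz: float
    base_amplitude: float
    harmonic_ratios: tuple[float, float]
    noise_sd: float
    axis_loading: tuple[float, float, float]
    drift_sd: float
    freq_jitter_sd: float
    amp_jitter_sd: float
    seed: int

    def __post_init__(self):
        lo, hi = TREMOR_BAND_HZ
        if not (lo <= self.tremor_freq_hz <= hi):
            raise ValueError(f"tremor_freq_hz must lie in [{lo}, {hi}] Hz")
        if self.base_amplitude <= 0:
            raise ValueError("base_amplitude must be positive")
        norm = math.sqrt(sum(a * a for a in self.axis_loading))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError("axis_loading must have unit norm")


@dataclass(frozen=True)
class EffectProfile:
    """Injected stimulation effect.

    Defaults reproduce the reported group-level amplitude effects: the
    during-stimulation resultant acceleration is attenuated to 24% of
    pre (a 76% reduction) and the post-stimulation one to 32% (68%).
    """

    during_scale: float = 0.24
    post_scale: float = 0.32
    during_noise_regularity: float = 0.25
    post_jitter_boost: float = 1.5

    def __post_init__(self):
        for name in ("during_scale", "post_scale"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.during_noise_regularity <= 0 or self.post_jitter_boost <= 0:
            raise ValueError("regularity factors must be positive")

    @classmethod
    def identity(cls) -> "EffectProfile":
        return cls(1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class SessionSpec:
    """Recording-session timing; defaults mirror the clinical protocol."""

    state_duration_s: float = 65.0
    intervals_per_state: int = 3
    interval_duration_s: float = 15.0
    gap_s: float = 10.0
    fs_hz: float = 100.0

    def __post_init__(self):
        span = (
            self.intervals_per_state * self.interval_duration_s
            + (self.intervals_per_state - 1) * self.gap_s
        )
        if span > self.state_duration_s + 1e-9:
            raise ValueError(
                f"intervals ({span} s) do not fit in the state duration "
                f"({self.state_duration_s} s)"
            )
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")


def generate_subject(seed: int) -> SubjectSpec:
    """Draw one subject: frequency uniform in the tremor band, amplitude
    log-normal around 1 m/s^2, random unit axis loading."""
    rng = np.random.default_rng(seed)
    freq = float(rng.uniform(*TREMOR_BAND_HZ))
    amp = float(np.exp(rng.normal(0.0, 0.4)))
    h2 = float(rng.uniform(0.15, 0.35))
    h3 = float(rng.uniform(0.05, 0.15))
    loading = rng.normal(size=3)
    loading /= np.linalg.norm(loading)
    return SubjectSpec(
        tremor_freq_hz=freq,
        base_amplitude=amp,
        harmonic_ratios=(h2, h3),
        noise_sd=0.10 * amp,
        axis_loading=tuple(float(a) for a in loading),
        drift_sd=0.05 * amp,
        freq_jitter_sd=0.02,
        amp_jitter_sd=0.10,
        seed=int(seed),
    )


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, sigma_samples: float) -> np.ndarray:
    """Zero-mean low-pass Gaussian process with target SD."""
    if sd == 0:
        return np.zeros(n)
    raw = gaussian_filter1d(rng.normal(size=n), sigma_samples, mode="reflect")
    s = raw.std()
    return raw * (sd / s) if s > 0 else np.zeros(n)


def _interval_signal(
    subject: SubjectSpec,
    spec: SessionSpec,
    rng: np.random.Generator,
    jitter_factor: float,
    noise_factor: float,
) -> np.ndarray:
    """One interval's tri-axial signal, shape (n, 3), before state scaling."""
    fs = spec.fs_hz
    n = int(round(spec.interval_duration_s * fs))
    h2, h3 = subject.harmonic_ratios

    freq_jit = _smooth_noise(rng, n, subject.freq_jitter_sd * jitter_factor, 0.15 * fs)
    amp_jit = _smooth_noise(rng, n, subject.amp_jitter_sd * jitter_factor, 0.15 * fs)
    phase0 = rng.uniform(0, 2 * np.pi)
    psi2, psi3 = rng.uniform(0, 2 * np.pi, 2)

    inst_freq = subject.tremor_freq_hz * (1.0 + freq_jit)
    phase = phase0 + 2 * np.pi * np.cumsum(inst_freq) / fs
    wave = np.sin(phase) + h2 * np.sin(2 * phase + psi2) + h3 * np.sin(3 * phase + psi3)
    tremor = subject.base_amplitude * (1.0 + amp_jit) * wave

    out = np.empty((n, 3))
    for ax in range(3):
        noise = rng.normal(0.0, subject.noise_sd * noise_factor, n)
        drift = _smooth_noise(rng, n, subject.drift_sd, 1.0 * fs)
        out[:, ax] = subject.axis_loading[ax] * tremor + noise + drift
    return out


def generate_session(
    subject: SubjectSpec,
    effect: EffectProfile = EffectProfile(),
    session: SessionSpec = SessionSpec(),
    include_gravity: bool = False,
) -> RecordingSession:
    """Produce a pre/during/post session for one subject.

    Gaps between intervals yield no samples.  The effect profile scales
    the complete during/post signals multiplicatively and adjusts their
    jitter/noise regularity; an identity profile gives three statistically
    identical states.
    """
    rng = np.random.default_rng([subject.seed, 20_220_415])
    state_cfg = {
        "pre": (1.0, 1.0, 1.0),
        "during": (effect.during_scale, effect.during_noise_regularity,
                   effect.during_noise_regularity),
        "post": (effect.post_scale, effect.post_jitter_boost, effect.post_jitter_boost),
    }
    fs = session.fs_hz
    states: dict[str, list[TriaxialRecording]] = {}
    for state in STATE_LABELS:
        scale, jitter_factor, noise_factor = state_cfg[state]
        recs = []
        for k in range(session.intervals_per_state):
            sig = scale * _interval_signal(subject, session, rng, jitter_factor, noise_factor)
            if include_gravity:
                sig[:, 2] += GRAVITY
            t0 = k * (session.interval_duration_s + session.gap_s)
            t = t0 + np.arange(sig.shape[0]) / fs
            recs.append(
                TriaxialRecording(times=t, x=sig[:, 0], y=sig[:, 1], z=sig[:, 2], fs_hz=fs)
            )
        states[state] = recs
    return RecordingSession(
        subject=f"S{subject.seed}",
        states=states,
        meta={"subject_spec": asdict(subject), "effect": asdict(effect),
              "session": asdict(session), "include_gravity": include_gravity},
    )


def generate_cohort(
    n: int = 15,
    master_seed: int = 0,
    effect: EffectProfile = EffectProfile(),
    session: SessionSpec = SessionSpec(),
) -> list[RecordingSession]:
    """n independent subjects with sub-seeds derived from ``master_seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(child.generate_state(1)[0]) for child in ss.spawn(n)]
    sessions = []
    for i, seed in enumerate(seeds):
        subject = generate_subject(seed)
        sess = generate_session(subject, effect, session)
        sess.subject = f"S{i:02d}"
        sessions.append(sess)
    return sessions


# ---------------------------------------------------------------------------
# disk round-trip

def write_cohort(sessions: list[RecordingSession], outdir) -> Path:
    """Write per-interval CSVs plus a manifest mapping subject/state/interval."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": {}}
    for sess in sessions:
        entry: dict = {"states": {}, "meta": sess.meta}
        for state, recs in sess.states.items():
            files = []
            for k, rec in enumerate(recs):
                fname = f"{sess.subject}_{state}_{k}.csv"
                rec.to_frame().to_csv(outdir / fname, index=False, float_format="%.8g")
                files.append({"file": fname, "fs_hz": rec.fs_hz})
            entry["states"][state] = files
        manifest["subjects"][sess.subject] = entry
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=float))
    return path


def read_cohort(manifest_path) -> list[RecordingSession]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    sessions = []
    for subject, entry in manifest["subjects"].items():
        states = {}
        for state, files in entry["states"].items():
            states[state] = [
                TriaxialRecording.from_csv(base / f["file"], fs_hz=f["fs_hz"])
                for f in files
            ]
        sessions.append(RecordingSession(subject=subject, states=states,
                                         meta=entry.get("meta", {})))
    return sessions
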