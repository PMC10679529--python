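"""tACS drive waveforms and the pre/during/post stimulation protocol.

The online (during-stimulation) drive is a plain sinusoid A*sin(2*pi*f*t);
the offline (post-stimulation) drive multiplies it by a decaying
exponential exp(-b*t) to mimic the fading effect after the electrodes come
off.  The offline sinusoid restarts its own clock at stimulation end; no
phase continuity is enforced across the boundary.

The drive value is in the model's dimensionless force units (the paper
never maps the 2-mA physical current to model units).  The default
amplitude is a calibration constant chosen once so that the
during-stimulation SC-MS activity drops measurably; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

TWO_PI = 2.0 * math.pi

#: calibrated default drive amplitude (model force units)
DEFAULT_AMPLITUDE = 160.0
#: default offline decay rate, 1/s
DEFAULT_DECAY = 0.05


@dataclass(frozen=True)
class StimulationWaveform:
    """tACS waveform: amplitude, frequency (Hz), offline decay rate (1/s)."""

    amplitude_A: float = DEFAULT_AMPLITUDE
    freq_w_hz: Optional[float] = None
    decay_b: float = DEFAULT_DECAY
    mode: str = "online"

    def __post_init__(self):
        if self.mode not in ("off", "online", "offline"):
            raise ValueError("mode must be off, online or offline")
        if self.amplitude_A < 0:
            raise ValueError("amplitude_A must be >= 0")
        if self.mode != "off" and self.freq_w_hz is not None and self.freq_w_hz <= 0:
            # None means "determine from the pre-stimulation tremor peak"
            raise ValueError("freq_w_hz must be > 0 when mode != off")
        if self.mode == "offline" and self.decay_b <= 0:
            raise ValueError("decay_b must be > 0 in offline mode")


@dataclass(frozen=True)
class StimulationProtocol:
    """Pre / stimulation / post durations (s) around one waveform.

    Defaults are a desk-scale analog of the clinical session (65 s
    recording, 15 min stimulation, 65 s recording): 30 s pre, 60 s
    stimulation, 60 s post.
    """

    pre_duration: float = 30.0
    stim_duration: float = 60.0
    post_duration: float = 60.0
    waveform: StimulationWaveform = StimulationWaveform()

    def __post_init__(self):
        for name in ("pre_duration", "stim_duration", "post_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def t_end(self) -> float:
        return self.pre_duration + self.stim_duration + self.post_duration

    def clinical(self) -> "StimulationProtocol":
        """The full clinical timing: 65 s pre, 15 min stimulation, 65 s post."""
        return StimulationProtocol(65.0, 900.0, 65.0, self.waveform)


def stim_online(t: float, wf: StimulationWaveform) -> float:
    """Online drive A*sin(2*pi*f*t); t measured from stimulation onset."""
    if wf.mode == "off":
        return 0.0
    return wf.amplitude_A * math.sin(TWO_PI * wf.freq_w_hz * t)


def stim_offline(t: float, wf: StimulationWaveform) -> float:
    """Offline drive A*exp(-b*t)*sin(2*pi*f*t); t from stimulation end."""
    if t < 0:
        raise ValueError("offline time must be >= 0 (measured from stimulation end)")
    if wf.mode == "off":
        return 0.0
    return wf.amplitude_A * math.exp(-wf.decay_b * t) * math.sin(TWO_PI * wf.freq_w_hz * t)


def protocol_drive(t: float, proto: StimulationProtocol) -> float:
    """Composite drive at absolute time t: zero / online / offline."""
    wf = proto.waveform
    if wf.mode == "off" or wf.amplitude_A == 0:
        return 0.0
    if t < proto.pre_duration:
        return 0.0
    t_stim = t - proto.pre_duration
    if t_stim <= proto.stim_duration:
        return stim_online(t_stim, wf)
    return stim_offline(t_stim - proto.stim_duration, wf)


def drive_trace(times: np.ndarray, proto: StimulationProtocol) -> np.ndarray:
    """Vectorized :func:`protocol_drive` over a time grid."""
    return np.array([protocol_drive(float(t), proto) for t in times])
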