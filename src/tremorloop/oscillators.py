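"""Three-unit coupled Van der Pol network for Parkinsonian rest tremor.

The model couples cortex, cerebellum and spinal-circuit/muscular-system
(SC-MS) units, each a Van der Pol oscillator

    Y'' - (lam - Y^2) Y' + p^2 Y = force,

where ``lam`` is the bifurcation parameter (lam <= 0 suppresses the limit
cycle; 0 < lam << 1 gives a near-sinusoidal cycle of amplitude ~2*sqrt(lam))
and ``p`` the intrinsic frequency.  Basal ganglia enter only through the
static coupling weights:

    cortex      force = BR*(Y_ce - Y_co)
    cerebellum  force = BR*(Y_co - Y_ce) + B1*Y_s + I(t)
    SC-MS       force = B2*Y_co

with I(t) the tACS drive into the cerebellum.  Weights sit in [30, 40] in
the healthy state and [1, 10] in the Parkinsonian state: high dopamine
(high weights) quenches the loop, low dopamine lets every unit run hot.

Time convention
---------------
The equations above live in a dimensionless model time tau in which a unit
with intrinsic parameter ``p`` completes ``p/(2*pi)`` cycles per tau.  The
printed p values (15, 20, 10) are intrinsic frequencies in Hz, which pins
the unit of tau: ``tau = 2*pi * t_seconds``.  All public interfaces use
seconds; internally the right-hand side is expressed directly in seconds,

    dY/dt = V
    dV/dt = 2*pi*(lam - Y^2)*V - (2*pi*p)^2 * Y + (2*pi)^2 * force,

which is the exact time-rescaling of the dimensionless system (amplitudes
unchanged, intrinsic frequency of a free unit = p in Hz).  The ``force``
argument is always in the dimensionless equation's units, i.e. coupling
weights multiply raw unit outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

TWO_PI = 2.0 * math.pi
_FORCE_SCALE = TWO_PI * TWO_PI

UNIT_LABELS = ("cortex", "cerebellum", "scms")

#: stated model constants: bifurcation parameter and intrinsic frequencies
DEFAULT_LAMBDA = 0.3
DEFAULT_P_HZ = {"cortex": 15.0, "cerebellum": 20.0, "scms": 10.0}

#: coupling-weight ranges for the two states and their midpoint presets
HEALTHY_RANGE = (30.0, 40.0)
PD_RANGE = (1.0, 10.0)


class NumericalBlowupError(RuntimeError):
    """Raised when the integration produces non-finite values."""

    def __init__(self, t: float):
        self.t = t
        super().__init__(f"non-finite state encountered at t={t:.6g} s")


@dataclass(frozen=True)
class OscillatorParams:
    """Per-unit Van der Pol parameters."""

    label: str
    lam: float = DEFAULT_LAMBDA
    p_hz: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.label not in UNIT_LABELS:
            raise ValueError(f"label must be one of {UNIT_LABELS}, got {self.label!r}")
        if self.p_hz is None:
            object.__setattr__(self, "p_hz", DEFAULT_P_HZ[self.label])
        if not np.isfinite(self.lam) or not np.isfinite(self.p_hz):
            raise ValueError("lam and p_hz must be finite")
        if self.p_hz <= 0:
            raise ValueError("p_hz must be positive")
        if not (0.0 < self.lam < 1.0):
            warnings.warn(
                f"lam={self.lam} is outside the weakly nonlinear regime (0, 1); "
                "lam<=0 suppresses oscillation, lam>1 yields strong harmonics",
                stacklevel=2,
            )


def default_params() -> tuple[OscillatorParams, OscillatorParams, OscillatorParams]:
    """The stated parameter set: lam=0.3, p = (15, 20, 10) Hz."""
    return tuple(OscillatorParams(label) for label in UNIT_LABELS)  # type: ignore[return-value]


@dataclass(frozen=True)
class CouplingConfig:
    """Inter-unit weights; the model's dopamine abstraction.

    BR couples cortex and cerebellum mutually (same value both directions),
    B1 feeds SC-MS output back into the cerebellum, B2 drives SC-MS from
    the cortex.
    """

    BR: float
    B1: float
    B2: float
    state_label: str = "custom"

    def __post_init__(self):
        if self.state_label not in ("healthy", "pd", "custom"):
            raise ValueError("state_label must be healthy, pd or custom")
        for name in ("BR", "B1", "B2"):
            w = getattr(self, name)
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"coupling weight {name} must be finite and >= 0")

    def weights(self) -> tuple[float, float, float]:
        return (self.BR, self.B1, self.B2)


@dataclass(frozen=True)
class NetworkState:
    """Outputs y = (Y_co, Y_ce, Y_s), derivatives v, at time t (seconds)."""

    y: tuple[float, float, float]
    v: tuple[float, float, float]
    t: float = 0.0

    def __post_init__(self):
        if len(self.y) != 3 or len(self.v) != 3:
            raise ValueError("y and v must have length 3")
        if not all(np.isfinite(self.y)) or not all(np.isfinite(self.v)):
            raise ValueError("state values must be finite")

    def as_vector(self) -> np.ndarray:
        y, v = self.y, self.v
        return np.array([y[0], v[0], y[1], v[1], y[2], v[2]], float)


#: default deterministic initial state; the origin is a fixed point and
#: must be avoided
DEFAULT_INITIAL_STATE = NetworkState(y=(0.1, 0.1, 0.1), v=(0.0, 0.0, 0.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings (seconds).

    ``transient_discard`` marks the initial stretch excluded from feature
    computation downstream; the full trajectory is always returned.
    """

    t_end: float = 120.0
    dt_out: float = 0.001
    transient_discard: Optional[float] = None
    initial_state: NetworkState = DEFAULT_INITIAL_STATE
    solver_rel_tol: float = 1e-8
    solver_abs_tol: float = 1e-10
    seed: Optional[int] = None

    def __post_init__(self):
        if self.transient_discard is None:
            # default: first 25% of the run, at least 10 s
            object.__setattr__(
                self, "transient_discard", min(max(0.25 * self.t_end, 10.0), self.t_end)
            )
        if not (self.t_end > self.transient_discard >= 0) and self.t_end != self.transient_discard:
            raise ValueError("need t_end > transient_discard >= 0")
        if self.dt_out <= 0:
            raise ValueError("dt_out must be positive")

    def check_sampling(self, params: Sequence[OscillatorParams]) -> None:
        fs = 1.0 / self.dt_out
        need = 4.0 * max(p.p_hz for p in params)
        if fs < need:
            raise ValueError(
                f"dt_out={self.dt_out} gives fs={fs:.3g} Hz < 4x max intrinsic "
                f"frequency ({need:.3g} Hz)"
            )

    def randomized(self, seed: int) -> "SimulationConfig":
        """Seeded uniform initial-condition perturbation in [-0.5, 0.5]."""
        rng = np.random.default_rng(seed)
        y = tuple(rng.uniform(-0.5, 0.5, 3))
        return replace(self, initial_state=NetworkState(y=y, v=(0.0, 0.0, 0.0)), seed=seed)


@dataclass
class TrajectorySet:
    """Sampled outputs of one simulation run (times in seconds)."""

    times: np.ndarray
    y_co: np.ndarray
    y_ce: np.ndarray
    y_s: np.ndarray
    stim_trace: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.times)
        for name in ("y_co", "y_ce", "y_s", "stim_trace"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match times")
        if n > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must be strictly increasing and uniform")

    @property
    def fs_hz(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])

    @property
    def steady_slice(self) -> slice:
        """Index window after the configured transient discard."""
        t0 = self.meta.get("transient_discard", 0.0)
        return slice(int(round(t0 * self.fs_hz)), None)

    def unit(self, label: str) -> np.ndarray:
        return {"cortex": self.y_co, "cerebellum": self.y_ce, "scms": self.y_s}[label]

    def to_csv(self, path) -> None:
        """Delimited-text export; parameters as key=value header comments."""
        header_lines = [f"# {k}={v!r}" for k, v in sorted(self.meta.items())]
        header_lines.append("t,y_co,y_ce,y_s,stim")
        data = np.column_stack([self.times, self.y_co, self.y_ce, self.y_s, self.stim_trace])
        with open(path, "w") as fh:
            fh.write("\n".join(header_lines) + "\n")
            np.savetxt(fh, data, delimiter=",", fmt="%.10g")

    @classmethod
    def from_csv(cls, path) -> "TrajectorySet":
        import ast

        meta = {}
        with open(path) as fh:
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                try:
                    meta[key.strip()] = ast.literal_eval(val)
                except (ValueError, SyntaxError):
                    meta[key.strip()] = val
        data = np.loadtxt(path, delimiter=",", skiprows=len(meta) + 1)
        return cls(times=data[:, 0], y_co=data[:, 1], y_ce=data[:, 2],
                   y_s=data[:, 3], stim_trace=data[:, 4], meta=meta)


def vdp_derivative(
    y: float, v: float, params: OscillatorParams, force: float = 0.0
) -> tuple[float, float]:
    """Time derivative of one Van der Pol unit, in seconds.

    Returns ``(dy/dt, dv/dt)`` with

        dv/dt = 2*pi*(lam - y^2)*v - (2*pi*p)^2*y + (2*pi)^2*force.

    ``force`` is in dimensionless-equation units (see module docstring).
    """
    if not (np.isfinite(y) and np.isfinite(v) and np.isfinite(force)):
        raise NumericalBlowupError(float("nan"))
    omega = TWO_PI * params.p_hz
    dv = TWO_PI * (params.lam - y * y) * v - omega * omega * y + _FORCE_SCALE * force
    return v, dv


def network_derivative(
    state: NetworkState,
    params: Sequence[OscillatorParams],
    coupling: CouplingConfig,
    stim_value: float = 0.0,
) -> np.ndarray:
    """Full network derivative at ``state`` (flat order y_co,v_co,...,y_s,v_s)."""
    if len(params) != 3:
        raise ValueError("need parameters for all three units")
    yco, yce, ys = state.y
    BR, B1, B2 = coupling.weights()
    forces = (
        BR * (yce - yco),
        BR * (yco - yce) + B1 * ys + stim_value,
        B2 * yco,
    )
    out = np.empty(6)
    for i, (p, f) in enumerate(zip(params, forces)):
        dy, dv = vdp_derivative(state.y[i], state.v[i], p, f)
        out[2 * i] = dy
        out[2 * i + 1] = dv
    return out


def simulate_network(
    sim: SimulationConfig,
    params: Optional[Sequence[OscillatorParams]] = None,
    coupling: Optional[CouplingConfig] = None,
    stim: Optional[Callable[[float], float]] = None,
) -> TrajectorySet:
    """Integrate the network and sample it on a uniform grid.

    ``stim`` is any callable t_seconds -> drive value (e.g.
    :func:`tremorloop.stimulation.protocol_drive` partially applied); None
    means no stimulation.  Adaptive RK45 with dense interpolation onto the
    ``dt_out`` grid; the full trajectory is returned and
    ``meta['transient_discard']`` marks the analysis window start.
    """
    if params is None:
        params = default_params()
    if coupling is None:
        coupling = preset_state("pd")[1]
    sim.check_sampling(params)

    lam = np.array([p.lam for p in params])
    om2 = np.array([(TWO_PI * p.p_hz) ** 2 for p in params])
    BR, B1, B2 = coupling.weights()
    drive = stim if stim is not None else (lambda t: 0.0)

    l0, l1, l2 = lam
    w0, w1, w2 = om2

    def rhs(t, s):
        yco, vco, yce, vce, ys, vs = s
        stim_val = drive(t)
        return (
            vco,
            TWO_PI * (l0 - yco * yco) * vco - w0 * yco + _FORCE_SCALE * (BR * (yce - yco)),
            vce,
            TWO_PI * (l1 - yce * yce) * vce - w1 * yce
            + _FORCE_SCALE * (BR * (yco - yce) + B1 * ys + stim_val),
            vs,
            TWO_PI * (l2 - ys * ys) * vs - w2 * ys + _FORCE_SCALE * (B2 * yco),
        )

    n_out = int(round(sim.t_end / sim.dt_out))
    t_eval = np.arange(n_out) * sim.dt_out
    sol = solve_ivp(
        rhs,
        (0.0, sim.t_end),
        sim.initial_state.as_vector(),
        method="RK45",
        t_eval=t_eval,
        rtol=sim.solver_rel_tol,
        atol=sim.solver_abs_tol,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(f"integration failed at t={last_t:.6g} s: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        bad = np.argmax(~np.all(np.isfinite(sol.y), axis=0))
        raise NumericalBlowupError(sol.t[bad])

    stim_trace = np.array([drive(t) for t in t_eval])
    meta = {
        "t_end": sim.t_end,
        "dt_out": sim.dt_out,
        "transient_discard": sim.transient_discard,
        "lam": tuple(lam),
        "p_hz": tuple(p.p_hz for p in params),
        "BR": BR,
        "B1": B1,
        "B2": B2,
        "state_label": coupling.state_label,
        "rel_tol": sim.solver_rel_tol,
        "abs_tol": sim.solver_abs_tol,
        "seed": sim.seed,
        "initial_y": sim.initial_state.y,
        "initial_v": sim.initial_state.v,
    }
    return TrajectorySet(
        times=t_eval,
        y_co=sol.y[0],
        y_ce=sol.y[2],
        y_s=sol.y[4],
        stim_trace=stim_trace,
        meta=meta,
    )


def preset_state(
    label: str,
    weight: Optional[float | Sequence[float]] = None,
    seed: Optional[int] = None,
) -> tuple[tuple[OscillatorParams, ...], CouplingConfig]:
    """Stated parameter presets for the healthy and Parkinsonian states.

    Weights default to the range midpoint (healthy 35, PD 5); pass a scalar
    or an (BR, B1, B2) triple inside the state's range, or a seed to draw
    uniformly from the range.
    """
    ranges = {"healthy": HEALTHY_RANGE, "pd": PD_RANGE}
    defaults = {"healthy": 35.0, "pd": 5.0}
    if label not in ranges:
        raise ValueError("label must be 'healthy' or 'pd'")
    lo, hi = ranges[label]

    if weight is None:
        if seed is not None:
            rng = np.random.default_rng(seed)
            w = tuple(rng.uniform(lo, hi, 3))
        else:
            w = (defaults[label],) * 3
    elif np.isscalar(weight):
        w = (float(weight),) * 3  # type: ignore[arg-type]
    else:
        w = tuple(float(x) for x in weight)  # type: ignore[union-attr]
        if len(w) != 3:
            raise ValueError("weight triple must have length 3")
    for x in w:
        if not (lo <= x <= hi):
            raise ValueError(
                f"weight {x} outside the {label} range [{lo}, {hi}]"
            )
    coupling = CouplingConfig(BR=w[0], B1=w[1], B2=w[2], state_label=label)
    return default_params(), coupling
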