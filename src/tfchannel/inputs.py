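"""Synthetic TF nuclear-concentration inputs.

The stimulus strength is encoded in one of three properties of the TF's
nuclear concentration, ``TF(t)``, built from square pulses on ``[0, 100]``
min:

* **duration** (label 0) — a single pulse of amplitude 100 starting at
  ``t = 0`` whose length (1-10 min) is the input;
* **amplitude** (label 1) — a single 10-min pulse starting at ``t = 0``
  whose height (0-100 a.u.) is the input;
* **frequency** (label 2) — 1-min pulses of amplitude 100 whose start
  times follow a homogeneous Poisson process; the mean rate
  ((0, 0.1]/min) is the input.

The realized concentration is ``TF(t) = |A_det(t) + eta|`` where
``A_det`` is the deterministic pulse amplitude (capped at 100 when
frequency-mode pulses overlap) and ``eta`` is Gaussian amplitude noise of
standard deviation 10.  The noise redraw cadence — once per schedule
segment (default) or at every integration step — is configurable; see
``docs/methods.md`` for the rationale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from typing import NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "Modulation",
    "MODULATION_RANGES",
    "TF_MAX",
    "NOISE_SD_DEFAULT",
    "TOTAL_TIME_DEFAULT",
    "DEFAULT_NOISE_CADENCE",
    "InputSpec",
    "Pulse",
    "PulseSchedule",
    "TFTrajectory",
    "build_schedule",
    "realize_trajectory",
    "input_grid",
]


class Modulation(IntEnum):
    """The three stimulus-encoding modes, with their conventional labels."""

    DURATION = 0
    AMPLITUDE = 1
    FREQUENCY = 2

    @classmethod
    def coerce(cls, value) -> "Modulation":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            return cls[value.upper()]
        return cls(int(value))


#: input-value range per modulation (min, a.u., 1/min respectively);
#: the frequency interval is half-open — 0 is excluded
MODULATION_RANGES = {
    Modulation.DURATION: (1.0, 10.0),
    Modulation.AMPLITUDE: (0.0, 100.0),
    Modulation.FREQUENCY: (0.0, 0.1),
}

#: maximum deterministic TF concentration (a.u.)
TF_MAX = 100.0
#: standard deviation of the additive Gaussian amplitude noise (a.u.)
NOISE_SD_DEFAULT = 10.0
#: simulation window (min)
TOTAL_TIME_DEFAULT = 100.0
#: noise redraw cadence: "segment" (once per constant piece of the pulse
#: schedule) or "step" (independent draw at every grid point)
DEFAULT_NOISE_CADENCE = "segment"


@dataclass(frozen=True)
class InputSpec:
    """A modulation mode together with its scalar input value.

    ``pulse_duration`` defaults to the mode's convention: the input itself
    for duration modulation, 10 min for amplitude, 1 min for frequency.
    """

    modulation: Modulation
    value: float
    total_time: float = TOTAL_TIME_DEFAULT
    noise_sd: float = NOISE_SD_DEFAULT
    pulse_amplitude: float = TF_MAX
    pulse_duration: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "modulation", Modulation.coerce(self.modulation))
        lo, hi = MODULATION_RANGES[self.modulation]
        ok = lo <= self.value <= hi
        if self.modulation is Modulation.FREQUENCY:
            ok = lo < self.value <= hi
        if not ok:
            raise ValueError(
                f"{self.modulation.name.lower()} input {self.value!r} outside "
                f"its range ({lo}, {hi})"
            )
        if self.total_time <= 0 or self.noise_sd < 0:
            raise ValueError("total_time must be > 0 and noise_sd >= 0")
        if self.pulse_duration is None:
            default = {
                Modulation.DURATION: self.value,
                Modulation.AMPLITUDE: 10.0,
                Modulation.FREQUENCY: 1.0,
            }[self.modulation]
            object.__setattr__(self, "pulse_duration", default)


class Pulse(NamedTuple):
    start: float
    end: float
    amplitude: float


@dataclass
class PulseSchedule:
    """The deterministic part of ``TF(t)``: a list of square pulses."""

    pulses: list
    total_time: float = TOTAL_TIME_DEFAULT

    def __post_init__(self) -> None:
        self.pulses = [Pulse(*p) for p in self.pulses]
        for p in self.pulses:
            if not (0.0 <= p.start <= p.end <= self.total_time):
                raise ValueError(f"pulse {p} outside [0, {self.total_time}]")
            if p.amplitude < 0:
                raise ValueError(f"pulse amplitude must be >= 0, got {p}")

    def segments(self, cap: float = TF_MAX):
        """Piecewise-constant representation of the deterministic amplitude.

        Returns ``(bounds, amps)`` with ``bounds`` of length ``len(amps)+1``
        starting at 0 and ending at ``total_time``; overlapping pulses sum
        but are capped at ``cap``.
        """
        events = {0.0, self.total_time}
        for p in self.pulses:
            events.add(p.start)
            events.add(p.end)
        bounds = np.array(sorted(events), dtype=float)
        amps = np.zeros(bounds.size - 1, dtype=float)
        for p in self.pulses:
            i = np.searchsorted(bounds, p.start)
            j = np.searchsorted(bounds, p.end)
            amps[i:j] += p.amplitude
        np.minimum(amps, cap, out=amps)
        return bounds, amps

    def amplitude_at(self, t, cap: float = TF_MAX):
        """Deterministic amplitude at time(s) ``t`` (right-open pulses)."""
        bounds, amps = self.segments(cap=cap)
        idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, amps.size - 1)
        return amps[idx]

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_time": self.total_time,
                "pulses": [list(p) for p in self.pulses],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PulseSchedule":
        obj = json.loads(text)
        return cls(pulses=obj["pulses"], total_time=obj["total_time"])


@dataclass
class TFTrajectory:
    """A realized, noisy TF concentration on a uniform time grid."""

    t: np.ndarray
    tf: np.ndarray
    schedule: PulseSchedule
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.tf = np.asarray(self.tf, dtype=float)
        if self.t.shape != self.tf.shape:
            raise ValueError("time grid and TF values must have equal length")
        if np.any(self.tf < 0):
            raise ValueError("realized TF values must be >= 0")

    def to_csv(self) -> str:
        lines = ["time_min,tf_au"]
        lines += [f"{t:.6g},{v:.10g}" for t, v in zip(self.t, self.tf)]
        return "\n".join(lines) + "\n"


def build_schedule(spec: InputSpec, rng=None) -> PulseSchedule:
    """Deterministic pulse schedule for an input specification.

    Duration and amplitude modes are deterministic single pulses starting
    at ``t = 0`` and ignore ``rng``.  Frequency mode draws pulse start
    times as a homogeneous Poisson process of rate ``spec.value`` on
    ``[0, total_time]`` (exponential inter-arrival gaps from ``t = 0``); a
    pulse extending past the window is truncated.
    """
    m = spec.modulation
    if m is Modulation.DURATION:
        return PulseSchedule(
            [(0.0, min(spec.value, spec.total_time), spec.pulse_amplitude)],
            spec.total_time,
        )
    if m is Modulation.AMPLITUDE:
        return PulseSchedule(
            [(0.0, min(spec.pulse_duration, spec.total_time), spec.value)],
            spec.total_time,
        )
    if rng is None:
        raise ValueError("frequency modulation requires an rng for pulse timing")
    pulses = []
    t = rng.exponential(1.0 / spec.value)
    while t < spec.total_time:
        pulses.append((t, min(t + spec.pulse_duration, spec.total_time), spec.pulse_amplitude))
        t += rng.exponential(1.0 / spec.value)
    return PulseSchedule(pulses, spec.total_time)


def realize_trajectory(
    schedule: PulseSchedule,
    dt: float,
    rng,
    noise_sd: float = NOISE_SD_DEFAULT,
    total_time: Optional[float] = None,
    noise_cadence: str = DEFAULT_NOISE_CADENCE,
    seed: Optional[int] = None,
) -> TFTrajectory:
    """Realize ``TF(t) = |A_det(t) + eta|`` on the simulation grid.

    ``noise_cadence`` selects how often the Gaussian perturbation ``eta``
    is redrawn: ``"segment"`` draws one value per constant piece of the
    schedule (pulses *and* gaps each get an independent draw), ``"step"``
    draws independently at every grid point.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt!r}")
    if noise_cadence not in ("segment", "step"):
        raise ValueError(f"unknown noise_cadence {noise_cadence!r}")
    total = schedule.total_time if total_time is None else total_time
    n_steps = int(round(total / dt))
    t = np.arange(n_steps) * dt
    bounds, amps = schedule.segments()
    seg_idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, amps.size - 1)
    a_det = amps[seg_idx]
    if noise_cadence == "step":
        eta = rng.normal(0.0, noise_sd, size=n_steps)
    else:
        eta = rng.normal(0.0, noise_sd, size=amps.size)[seg_idx]
    return TFTrajectory(t=t, tf=np.abs(a_det + eta), schedule=schedule, seed=seed)


def input_grid(modulation, n_values: int = 200) -> np.ndarray:
    """``n_values`` evenly spaced input values spanning the mode's range.

    The duration and amplitude grids include both endpoints; the frequency
    grid covers ``(0, 0.1]`` with equal spacing and excludes 0.
    """
    modulation = Modulation.coerce(modulation)
    if n_values < 2:
        raise ValueError(f"n_values must be >= 2, got {n_values!r}")
    lo, hi = MODULATION_RANGES[modulation]
    if modulation is Modulation.FREQUENCY:
        return hi * np.arange(1, n_values + 1) / n_values
    return np.linspace(lo, hi, n_values)
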