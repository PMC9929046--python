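"""Stochastic simulation of transcription driven by noisy TF pulses.

mRNA production is a birth-death process: births at rate
``k2*hill(TF(t))*P1(t)`` and deaths at rate ``d2*X``, advanced with a
grid-synchronous tau-leap on the same Euler grid used for ``P1`` (births
``~ Poisson(rate*dt)``, deaths ``~ Binomial(X, 1 - exp(-d2*dt))``).  The
response variable is the accumulated output ``Out(T) = sum_{t<T} X(t)*dt``
evaluated at the study's time cuts Ta/Tb/Tc, which depend on the
modulation mode; for duration modulation Ta is event-defined (the pulse
end) rather than a fixed time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._kernels import ensemble_kernel, transcription_kernel
from .inputs import (
    DEFAULT_NOISE_CADENCE,
    InputSpec,
    Modulation,
    PulseSchedule,
    TFTrajectory,
    TOTAL_TIME_DEFAULT,
    build_schedule,
)
from .model import ConfigurationError, KineticParams, hill

__all__ = [
    "SimConfig",
    "SimResult",
    "GridResult",
    "CutTimes",
    "CUT_LABELS",
    "cut_times_for",
    "simulate_transcription",
    "run_ensemble",
    "run_grid",
]

CUT_LABELS = ("Ta", "Tb", "Tc")


@dataclass(frozen=True)
class SimConfig:
    """Numerical settings shared by all simulations of one study.

    ``dt = 0.01`` min gives >= 100 Euler steps per 1-min pulse and
    satisfies the tau-leap/Euler stability requirements over the whole
    sampled parameter space.
    """

    dt: float = 0.01
    total_time: float = TOTAL_TIME_DEFAULT
    n_reps: int = 1500
    seed: int = 0
    record_trajectories: bool = False
    noise_cadence: str = DEFAULT_NOISE_CADENCE
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.total_time <= 0:
            raise ConfigurationError("dt and total_time must be > 0")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if self.noise_cadence not in ("segment", "step"):
            raise ConfigurationError(
                f"unknown noise_cadence {self.noise_cadence!r}"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.total_time / self.dt))

    def check_params(self, params: KineticParams) -> None:
        if (params.k1 + params.d1) * self.dt >= 1.0:
            raise ConfigurationError(
                f"dt={self.dt!r} violates (k1 + d1)*dt < 1 for {params}"
            )
        if params.d2 * self.dt > 0.1:
            raise ConfigurationError(
                f"dt={self.dt!r} too coarse for d2={params.d2!r}"
            )

    def replace(self, **changes) -> "SimConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class CutTimes:
    """The three output-integration cuts for one input realization."""

    Ta: float
    Tb: float
    Tc: float
    Ta_is_event: bool = False

    def __post_init__(self) -> None:
        if not self.Ta <= self.Tb <= self.Tc:
            raise ValueError(f"cut times must be ordered, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.Ta, self.Tb, self.Tc], dtype=float)


def cut_times_for(modulation, input_value: float) -> CutTimes:
    """Study cut times per modulation mode.

    Frequency: (10, 50, 100) min.  Amplitude: (1, 10, 100) min, Tb being
    the common pulse end.  Duration: Ta is the pulse end itself (the input
    value), with Tb = 10 and Tc = 100 min.
    """
    modulation = Modulation.coerce(modulation)
    if modulation is Modulation.FREQUENCY:
        return CutTimes(10.0, 50.0, 100.0)
    if modulation is Modulation.AMPLITUDE:
        return CutTimes(1.0, 10.0, 100.0)
    return CutTimes(float(input_value), 10.0, 100.0, Ta_is_event=True)


@dataclass
class SimResult:
    """Realized outputs of one ensemble (or one replicate).

    ``outs[r, i]`` is ``Out(record_times[i])`` for replicate ``r``.
    ``x`` optionally holds recorded copy-number trajectories.
    """

    outs: np.ndarray
    record_times: np.ndarray
    input_value: Optional[float] = None
    modulation: Optional[Modulation] = None
    x: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def to_csv(self, labels: Optional[Sequence[str]] = None) -> str:
        labels = list(labels) if labels is not None else [
            f"out_t{t:g}" for t in self.record_times
        ]
        lines = ["input_value,rep," + ",".join(labels)]
        for r, row in enumerate(np.atleast_2d(self.outs)):
            vals = ",".join(f"{v:.10g}" for v in row)
            lines.append(f"{self.input_value if self.input_value is not None else ''},{r},{vals}")
        return "\n".join(lines) + "\n"


@dataclass
class GridResult:
    """Ensemble outputs over a whole input grid.

    ``outs[i, r, c]`` is the output of replicate ``r`` of input
    ``inputs[i]`` at recording time ``record_times[i, c]`` (recording
    times may differ across inputs only through an event-defined Ta).
    """

    inputs: np.ndarray
    outs: np.ndarray
    record_times: np.ndarray
    modulation: Modulation
    seed: int


def _record_steps(record_times: np.ndarray, dt: float, n_steps: int) -> np.ndarray:
    steps = np.rint(np.asarray(record_times, dtype=float) / dt).astype(np.int64)
    if np.any(steps > n_steps):
        raise ConfigurationError("record time beyond total_time")
    return steps


def simulate_transcription(
    params: KineticParams,
    tf: TFTrajectory | np.ndarray,
    p1: np.ndarray,
    config: SimConfig,
    record_times: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
) -> SimResult:
    """One stochastic transcription replicate for a realized TF and P1.

    ``tf`` and ``p1`` must live on the simulation grid of ``config``; the
    per-step birth propensity is ``k2*hill(tf[s])*p1[s]``.  Returns the
    full copy-number trajectory plus outputs at ``record_times`` (all
    three cuts of the modulation by default must be supplied explicitly).
    """
    config.check_params(params)
    tf_values = tf.tf if isinstance(tf, TFTrajectory) else np.asarray(tf, float)
    p1 = np.asarray(p1, dtype=float)
    if tf_values.shape != p1.shape or tf_values.shape[0] != config.n_steps:
        raise ConfigurationError(
            f"tf/p1 length {tf_values.shape[0]} does not match the "
            f"configured grid of {config.n_steps} steps"
        )
    rate_dt = params.k2 * hill(tf_values, params.Kd, params.n) * p1 * config.dt
    p_death = 1.0 - np.exp(-params.d2 * config.dt)
    kseed = int(config.seed if seed is None else seed) % (2**32)
    x_traj, out_traj = transcription_kernel(kseed, rate_dt, p_death, config.dt)
    if record_times is None:
        record_times = [config.total_time]
    record_times = np.asarray(record_times, dtype=float)
    steps = _record_steps(record_times, config.dt, config.n_steps)
    outs = np.where(steps > 0, out_traj[np.maximum(steps - 1, 0)], 0.0)
    return SimResult(
        outs=outs,
        record_times=record_times,
        x=x_traj,
        seed=kseed,
    )


def _segment_arrays(schedules, dt: float):
    """Concatenate per-replicate piecewise-constant amplitudes for the kernel."""
    ends_list, amps_list = [], []
    offsets = np.zeros(len(schedules) + 1, dtype=np.int64)
    for i, sched in enumerate(schedules):
        bounds, amps = sched.segments()
        ends_list.append(bounds[1:])
        amps_list.append(amps)
        offsets[i + 1] = offsets[i] + amps.size
    return (
        np.concatenate(ends_list),
        np.concatenate(amps_list),
        offsets,
    )


def run_ensemble(
    params: KineticParams,
    spec: InputSpec,
    config: SimConfig,
    record_times: Optional[Sequence[float]] = None,
) -> SimResult:
    """Independent replicates of one input value.

    Every replicate gets fresh amplitude noise, fresh pulse timing
    (frequency mode) and fresh transcription randomness; all randomness
    derives deterministically from ``config.seed``.
    """
    config.check_params(params)
    if record_times is None:
        record_times = cut_times_for(spec.modulation, spec.value).as_array()
    record_times = np.asarray(record_times, dtype=float)
    order = np.argsort(record_times, kind="stable")
    sorted_times = record_times[order]
    n_steps = config.n_steps
    steps = _record_steps(sorted_times, config.dt, n_steps)

    ss = np.random.SeedSequence(config.seed)
    sched_ss, kernel_ss = ss.spawn(2)
    if spec.modulation is Modulation.FREQUENCY:
        rng = np.random.default_rng(sched_ss)
        schedules = [build_schedule(spec, rng) for _ in range(config.n_reps)]
    else:
        schedules = [build_schedule(spec)] * config.n_reps
    seg_ends, seg_amps, seg_off = _segment_arrays(schedules, config.dt)
    kseed = int(kernel_ss.generate_state(1, dtype=np.uint32)[0])

    positive = steps > 0
    rec_steps = steps[positive]
    out_pos = np.zeros((config.n_reps, rec_steps.size), dtype=float)
    ensemble_kernel(
        kseed,
        seg_ends,
        seg_amps,
        seg_off,
        n_steps,
        config.dt,
        config.noise_sd,
        config.noise_cadence == "step",
        params.k1,
        params.k2,
        params.n,
        params.Kd,
        params.d1,
        params.d2,
        rec_steps,
        out_pos,
    )
    outs_sorted = np.zeros((config.n_reps, record_times.size), dtype=float)
    outs_sorted[:, positive] = out_pos
    outs = np.empty_like(outs_sorted)
    outs[:, order] = outs_sorted
    return SimResult(
        outs=outs,
        record_times=record_times,
        input_value=spec.value,
        modulation=spec.modulation,
        seed=kseed,
    )


def run_grid(
    params: KineticParams,
    modulation,
    config: SimConfig,
    record_times: Optional[Sequence[float]] = None,
    n_inputs: int = 200,
    use_cuts: bool = False,
) -> GridResult:
    """Ensembles over the full discretized input grid of one modulation.

    With ``use_cuts=True`` the recording times are the modulation's three
    cuts (per input, honouring the event-defined Ta of duration mode);
    otherwise ``record_times`` is a common time grid for all inputs.
    Per-input seeds are spawned deterministically from ``config.seed``.
    """
    from .inputs import input_grid  # local to avoid cycle at module load

    modulation = Modulation.coerce(modulation)
    values = input_grid(modulation, n_inputs)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(values))
    if use_cuts:
        times_per_input = [
            cut_times_for(modulation, v).as_array() for v in values
        ]
    else:
        if record_times is None:
            raise ConfigurationError(
                "run_grid needs record_times when use_cuts is False"
            )
        base = np.asarray(record_times, dtype=float)
        times_per_input = [base] * len(values)

    n_rec = times_per_input[0].size
    outs = np.empty((len(values), config.n_reps, n_rec), dtype=float)
    rec_matrix = np.empty((len(values), n_rec), dtype=float)
    for i, value in enumerate(values):
        spec = InputSpec(
            modulation=modulation,
            value=float(value),
            total_time=config.total_time,
            noise_sd=config.noise_sd,
        )
        sub_seed = int(children[i].generate_state(1, dtype=np.uint32)[0])
        res = run_ensemble(
            params,
            spec,
            config.replace(seed=sub_seed),
            record_times=times_per_input[i],
        )
        outs[i] = res.outs
        rec_matrix[i] = times_per_input[i]
    return GridResult(
        inputs=values,
        outs=outs,
        record_times=rec_matrix,
        modulation=modulation,
        seed=config.seed,
    )
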