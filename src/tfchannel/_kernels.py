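"""Numba kernels for the stochastic transcription simulator.

The inner loop advances, per replicate and per Euler step of width ``dt``:

* the realized TF concentration ``|A_det + eta|`` (noise redrawn per
  schedule segment or per step),
* the deterministic promoter activation ``P1`` (explicit Euler),
* the mRNA copy number ``X`` via a grid-synchronous tau-leap —
  ``births ~ Poisson(k2*hill*P1*dt)`` and
  ``deaths ~ Binomial(X, 1 - exp(-d2*dt))`` drawn from the step's
  pre-update state,
* the left-Riemann accumulator ``Out = sum X*dt``.

Randomness uses numba's internal Mersenne-Twister state, seeded once per
kernel call, which makes every call bit-reproducible for a given seed.
"""

import numpy as np
from numba import njit

__all__ = ["ensemble_kernel", "transcription_kernel"]


@njit(cache=True, fastmath=True)
def _hill_scalar(tf, Kd, hn):
    if tf <= 0.0:
        return 0.0
    return 1.0 / (1.0 + (tf / Kd) ** (-hn))


@njit(cache=True, fastmath=True)
def ensemble_kernel(
    seed,
    seg_ends,
    seg_amps,
    seg_off,
    n_steps,
    dt,
    noise_sd,
    per_step_noise,
    k1,
    k2,
    hn,
    Kd,
    d1,
    d2,
    rec_steps,
    out,
):
    """Simulate all replicates of one input value.

    ``seg_ends``/``seg_amps`` hold the piecewise-constant deterministic
    amplitude of every replicate, concatenated; replicate ``r`` owns slice
    ``seg_off[r]:seg_off[r+1]``.  Segment ``j`` spans from the previous
    end (0 for the first) to ``seg_ends[j]``.  ``rec_steps`` are sorted
    step counts (>= 1) after which the accumulated output is recorded into
    ``out[r, i]``.
    """
    np.random.seed(seed)
    p_death = 1.0 - np.exp(-d2 * dt)
    n_reps = seg_off.size - 1
    n_rec = rec_steps.size
    for r in range(n_reps):
        lo = seg_off[r]
        hi = seg_off[r + 1]
        seg = lo
        seg_end_step = int(np.ceil(seg_ends[seg] / dt - 1e-9))
        eta = np.random.normal(0.0, noise_sd)
        tf = abs(seg_amps[seg] + eta)
        h = _hill_scalar(tf, Kd, hn)
        birth = k2 * h * dt
        gain = k1 * h
        P1 = 0.0
        X = 0
        acc = 0.0
        ri = 0
        for s in range(n_steps):
            while s >= seg_end_step and seg + 1 < hi:
                seg += 1
                seg_end_step = int(np.ceil(seg_ends[seg] / dt - 1e-9))
                if not per_step_noise:
                    eta = np.random.normal(0.0, noise_sd)
                    tf = abs(seg_amps[seg] + eta)
                    h = _hill_scalar(tf, Kd, hn)
                    birth = k2 * h * dt
                    gain = k1 * h
            if per_step_noise:
                eta = np.random.normal(0.0, noise_sd)
                tf = abs(seg_amps[seg] + eta)
                h = _hill_scalar(tf, Kd, hn)
                birth = k2 * h * dt
                gain = k1 * h
            acc += X * dt
            births = np.random.poisson(birth * P1)
            deaths = 0
            if X > 0:
                deaths = np.random.binomial(X, p_death)
            X += births - deaths
            P1 += dt * (gain - (gain + d1) * P1)
            if P1 < 0.0:
                P1 = 0.0
            elif P1 > 1.0:
                P1 = 1.0
            while ri < n_rec and s + 1 == rec_steps[ri]:
                out[r, ri] = acc
                ri += 1


@njit(cache=True, fastmath=True)
def transcription_kernel(seed, rate_dt, p_death, dt):
    """Single-replicate transcription given precomputed per-step rates.

    ``rate_dt[s]`` is the birth propensity times ``dt`` at step ``s``.
    Returns the mRNA copy-number trajectory ``X`` (pre-update value at
    each grid time) and the running left-Riemann output ``Out`` evaluated
    after each step.
    """
    np.random.seed(seed)
    n = rate_dt.size
    x_traj = np.zeros(n, dtype=np.int64)
    out_traj = np.zeros(n, dtype=np.float64)
    X = 0
    acc = 0.0
    for s in range(n):
        x_traj[s] = X
        acc += X * dt
        out_traj[s] = acc
        births = np.random.poisson(rate_dt[s])
        deaths = 0
        if X > 0:
            deaths = np.random.binomial(X, p_death)
        X += births - deaths
    return x_traj, out_traj
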