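"""Deterministic core of the two-step promoter model.

A transcription factor (TF) activates a promoter in a cooperative fashion.
Binding/unbinding is fast and enters through the Hill term

    hill(tf) = tf**n / (tf**n + Kd**n),

and the probability ``P1`` that the promoter is in its active state obeys

    dP1/dt = k1*hill(TF(t)) - (k1*hill(TF(t)) + d1) * P1,

with ``P0 = 1 - P1`` implicit.  Transcription (handled stochastically in
:mod:`tfchannel.simulate`) proceeds at rate ``k2*hill(TF(t))*P1`` and mRNA
degrades at rate ``d2``.  This module holds the kinetic-parameter container
and the deterministic operations: the Hill function and the explicit-Euler
integration of ``P1``.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "D2_DEFAULT",
    "ConfigurationError",
    "KineticParams",
    "PromoterState",
    "hill",
    "integrate_promoter",
]

#: canonical parameter order used by all flat serializations
PARAM_NAMES = ("k1", "k2", "n", "Kd", "d1", "d2")

#: mRNA degradation rate held fixed throughout the study (1/min)
D2_DEFAULT = 0.12


class ConfigurationError(ValueError):
    """An invalid numerical configuration (e.g. an unstable Euler step)."""


@dataclass(frozen=True)
class KineticParams:
    """One promoter: the six kinetic parameters of the transcription model.

    Parameters
    ----------
    k1 : float
        Maximum promoter-activation rate (1/min).
    k2 : float
        Maximum transcription rate (1/min).
    n : float
        Hill cooperativity (dimensionless); treated as continuous.
    Kd : float
        Effective dissociation constant, in the same arbitrary units as the
        TF concentration.
    d1 : float
        Promoter inactivation rate (1/min).
    d2 : float
        mRNA degradation rate (1/min); fixed at 0.12 in all study
        configurations.
    """

    k1: float
    k2: float
    n: float
    Kd: float
    d1: float
    d2: float = D2_DEFAULT

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"KineticParams.{name} must be finite and > 0, got {value!r}"
                )
            object.__setattr__(self, name, float(value))

    # -- flat serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, record: dict) -> "KineticParams":
        return cls(**{name: float(record[name]) for name in PARAM_NAMES})

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "KineticParams":
        return cls.from_dict(json.loads(text))

    def to_csv(self) -> str:
        """One CSV row with header ``k1,k2,n,Kd,d1,d2``."""
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=list(PARAM_NAMES))
        writer.writeheader()
        writer.writerow(self.to_dict())
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "KineticParams":
        rows = list(csv.DictReader(io.StringIO(text)))
        if len(rows) != 1:
            raise ValueError(f"expected exactly one CSV data row, got {len(rows)}")
        return cls.from_dict(rows[0])

    def replace(self, **changes) -> "KineticParams":
        return replace(self, **changes)


@dataclass
class PromoterState:
    """Active-promoter probability ``P1``; ``P0 = 1 - P1`` is implicit."""

    P1: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.P1 <= 1.0:
            raise ValueError(f"P1 must lie in [0, 1], got {self.P1!r}")


def hill(tf, Kd: float, n: float):
    """Cooperative activation term ``tf**n / (tf**n + Kd**n)``.

    Evaluated as ``1 / (1 + (tf/Kd)**(-n))`` so that both tails saturate
    cleanly (underflow gives exactly 0 or 1) even for large ``n``.

    Parameters
    ----------
    tf : float or array_like
        TF concentration(s), arbitrary units, >= 0.
    Kd : float
        Dissociation constant, > 0, same units as ``tf``.
    n : float
        Hill coefficient, > 0.

    Returns
    -------
    float or ndarray
        Value(s) in ``[0, 1)``, monotone nondecreasing in ``tf``.
    """
    if not (np.isfinite(Kd) and Kd > 0):
        raise ValueError(f"Kd must be finite and > 0, got {Kd!r}")
    if not (np.isfinite(n) and n > 0):
        raise ValueError(f"n must be finite and > 0, got {n!r}")
    tf_arr = np.asarray(tf, dtype=float)
    if np.any(tf_arr < 0):
        raise ValueError("tf must be >= 0")
    ratio = tf_arr / Kd
    with np.errstate(divide="ignore", over="ignore", under="ignore"):
        out = 1.0 / (1.0 + ratio ** (-float(n)))
    out = np.where(tf_arr == 0.0, 0.0, out)
    if np.isscalar(tf) or np.ndim(tf) == 0:
        return float(out)
    return out


def integrate_promoter(
    params: KineticParams,
    tf_values: np.ndarray,
    dt: float,
    p1_init: float = 0.0,
) -> np.ndarray:
    """Forward-Euler integration of the promoter-activation ODE.

    ``tf_values`` samples ``TF(t)`` on a uniform grid of step ``dt``; the
    returned series gives ``P1`` on the same grid, with ``P1[0] = p1_init``
    and ``P1[i+1]`` computed from ``tf_values[i]``.

    The explicit scheme cannot leave ``[0, 1]`` as long as
    ``(k1 + d1)*dt < 1`` (the activation gain ``k1*hill <= k1``); that
    stability condition is enforced, and the trajectory is clamped to
    ``[0, 1]`` as a numerical no-op safeguard.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be > 0, got {dt!r}")
    if (params.k1 + params.d1) * dt >= 1.0:
        raise ConfigurationError(
            f"Euler step dt={dt!r} violates (k1 + d1)*dt < 1 for "
            f"k1={params.k1!r}, d1={params.d1!r}; reduce dt"
        )
    if not 0.0 <= p1_init <= 1.0:
        raise ValueError(f"p1_init must lie in [0, 1], got {p1_init!r}")
    tf_values = np.asarray(tf_values, dtype=float)
    gain = params.k1 * hill(tf_values, params.Kd, params.n)
    p1 = np.empty(tf_values.shape[0], dtype=float)
    p1[0] = p1_init
    d1 = params.d1
    current = p1_init
    for i in range(tf_values.shape[0] - 1):
        g = gain[i]
        current = current + dt * (g - (g + d1) * current)
        if current < 0.0:
            current = 0.0
        elif current > 1.0:
            current = 1.0
        p1[i + 1] = current
    return p1
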