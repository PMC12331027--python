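"""Canopy and tuber-partition growth functions over thermal time.

Canopy cover follows the beta growth function

    W(t) = Wmax · [1 + (te − t)/(te − tm)] · (t/te)^(te/(te − tm)),   0 ≤ tm < te

whose growth rate peaks at t = tm and which reaches its maximum Wmax at
t = te.  The harvest index (tuber dry mass fraction of total dry mass)
follows a Gompertz curve

    HI(t) = A · exp(−exp(−(t − Tu)/b))

with maximum partition rate at t = Tu and asymptote A; b sets the
thermal-time scale of the transition.  Both run on thermal time t in °C·d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CanopyParameters",
    "PartitionParameters",
    "beta_canopy",
    "gompertz_partition",
    "tuber_initiation_tt",
]


@dataclass(frozen=True)
class CanopyParameters:
    """Beta-function canopy parameters.

    wmax : maximum canopy cover fraction, (0, 1].
    tm   : thermal time of maximum canopy growth rate, °C·d.
    te   : thermal time at which maximum cover is reached, °C·d; tm < te.
    """

    wmax: float
    tm: float
    te: float

    def __post_init__(self) -> None:
        if not (0 < self.wmax <= 1):
            raise ValueError(f"wmax must be in (0, 1], got {self.wmax}")
        if not (0 <= self.tm < self.te):
            raise ValueError(f"need 0 <= tm < te, got tm={self.tm}, te={self.te}")


@dataclass(frozen=True)
class PartitionParameters:
    """Gompertz tuber-partition parameters.

    a_max : asymptotic (maximum) harvest index, (0, 1].
    tu    : thermal time of maximum partition rate, °C·d.
    b     : thermal-time scale of the transition, °C·d.
    """

    a_max: float
    tu: float
    b: float

    def __post_init__(self) -> None:
        if not (0 < self.a_max <= 1):
            raise ValueError(f"a_max must be in (0, 1], got {self.a_max}")
        if self.tu <= 0:
            raise ValueError(f"tu must be positive, got {self.tu}")
        if self.b <= 0:
            raise ValueError(f"b must be positive, got {self.b}")


def beta_canopy(tt, p: CanopyParameters):
    """Beta-function canopy cover at thermal time ``tt`` (°C·d).

    Vectorized over ``tt``.  For tt > te the cover is held at wmax (the
    post-maximum maintenance phase; senescence is applied by the caller).
    The result is clamped to [0, wmax] against floating-point overshoot.
    """
    tt = np.asarray(tt, dtype=float)
    if np.any(tt < 0):
        raise ValueError("thermal time must be non-negative")
    t = np.minimum(tt, p.te)
    span = p.te - p.tm
    with np.errstate(divide="ignore"):
        # (t/te)^(te/span) -> 0 as t -> 0; computed in log space for stability
        frac = np.where(t > 0, t / p.te, 1.0)
        power = np.where(t > 0, np.exp((p.te / span) * np.log(frac)), 0.0)
    w = p.wmax * (1.0 + (p.te - t) / span) * power
    w = np.clip(w, 0.0, p.wmax)
    return w if w.ndim else float(w)


def gompertz_partition(tt, p: PartitionParameters):
    """Gompertz harvest index at thermal time ``tt`` (°C·d); vectorized."""
    tt = np.asarray(tt, dtype=float)
    if np.any(tt < 0):
        raise ValueError("thermal time must be non-negative")
    y = p.a_max * np.exp(-np.exp(-(tt - p.tu) / p.b))
    return y if y.ndim else float(y)


def tuber_initiation_tt(p: PartitionParameters, threshold: float) -> float:
    """Thermal time at which the partition function first reaches ``threshold``.

    Tuber initiation is defined as the minimal detectable partition; the
    Gompertz form inverts analytically:

        t = Tu − b · ln(−ln(threshold / A))
    """
    if not (0 < threshold < p.a_max):
        raise ValueError(
            f"threshold must be in (0, a_max={p.a_max}), got {threshold}"
        )
    return p.tu - p.b * math.log(-math.log(threshold / p.a_max))
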