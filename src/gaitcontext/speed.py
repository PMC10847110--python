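"""Stride-speed estimation from stride frequency.

Walking speed and stride frequency are tightly coupled: over the range of
normal walking, stride speed v (m/s) follows a power law in stride
frequency f (Hz),

    v = exp( ln(a * f) / (1 - b) )  =  (a * f) ** (1 / (1 - b)),

with per-participant parameters a > 0 and b < 1 obtained from an external
calibration. The inverse map f = v**(1-b) / a is exact and is what the
synthetic-cohort generator uses to schedule stride timing from sampled
speeds.

Speeds are made dimensionless by dividing by sqrt(g * l0), where l0 is leg
length, removing body-size effects before any across-participant model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GRAVITY


@dataclass(frozen=True)
class SpeedModel:
    """Power-law stride speed model with parameters ``a`` (>0), ``b`` (<1)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"speed parameter a must be > 0, got {self.a}")
        if self.b >= 1:
            raise ValueError(f"speed parameter b must be < 1, got {self.b}")


def stride_speed(f, model: SpeedModel):
    """Map stride frequency (Hz) to stride speed (m/s).

    Vectorized over ``f``; scalar input returns a scalar.

    Raises
    ------
    ValueError
        If any frequency is non-positive or the model has b >= 1.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise ValueError("stride frequency must be positive")
    v = np.exp(np.log(model.a * f_arr) / (1.0 - model.b))
    return float(v) if np.isscalar(f) else v


def stride_frequency(v, model: SpeedModel):
    """Exact inverse of :func:`stride_speed`: f = v**(1-b) / a."""
    v_arr = np.asarray(v, dtype=float)
    if np.any(v_arr <= 0):
        raise ValueError("stride speed must be positive")
    f = np.power(v_arr, 1.0 - model.b) / model.a
    return float(f) if np.isscalar(v) else f


def normalize_speed(v, leg_length_m: float, g: float = GRAVITY):
    """Dimensionless speed v / sqrt(g * l0)."""
    if leg_length_m <= 0:
        raise ValueError("leg length must be positive")
    return v / np.sqrt(g * leg_length_m)


def denormalize_speed(v_norm, leg_length_m: float, g: float = GRAVITY):
    """Exact inverse of :func:`normalize_speed`."""
    if leg_length_m <= 0:
        raise ValueError("leg length must be positive")
    return v_norm * np.sqrt(g * leg_length_m)
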