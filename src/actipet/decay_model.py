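"""Multi-exponential decay forward model for induced-activity TACs.

The measured count rate of an irradiated volume, with biological washout
neglected, is a sum of exponentials plus a constant background:

    S(t) = Σₖ Sₖ · 2^(−t / T½,ₖ) + K

with the amplitudes Sₖ defined at the reference time t = 0 (end of
irradiation).  A dynamic PET frame reports the time-average of S(t) over
the frame interval, which this module evaluates in closed form:

    mean over [a, b] = Σₖ Sₖ · T½,ₖ / (ln2 · (b−a)) · (2^(−a/T½,ₖ) − 2^(−b/T½,ₖ)) + K

All times are minutes; the acquisition starts one transport delay
(default 7 min) after the end of irradiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DecayComponent",
    "MultiExpModel",
    "AcquisitionSchedule",
    "decay_constant",
    "decay_correct",
    "model_rate",
    "frame_mean_rate",
    "predicted_tac",
    "default_schedule",
]

LN2 = math.log(2.0)


def decay_constant(half_life: float) -> float:
    """Decay constant λ = ln2 / T½ in min⁻¹.  Raises for T½ ≤ 0."""
    if not half_life > 0:
        raise ValueError(f"half_life must be > 0, got {half_life}")
    return LN2 / half_life


def decay_correct(amplitude: float, half_life: float, delta_t: float) -> float:
    """Correct a rate measured ``delta_t`` after the reference back to it.

    Returns ``amplitude * 2**(delta_t / half_life)``; a negative ``delta_t``
    decays the value forward in time instead.
    """
    if not half_life > 0:
        raise ValueError(f"half_life must be > 0, got {half_life}")
    return amplitude * 2.0 ** (delta_t / half_life)


@dataclass(frozen=True)
class DecayComponent:
    """One exponential term: amplitude Sₖ at reference time and half-life."""

    amplitude: float
    half_life: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not self.half_life > 0:
            raise ValueError(f"half_life must be > 0, got {self.half_life}")


@dataclass(frozen=True)
class MultiExpModel:
    """Sum-of-exponentials count-rate model with constant background K."""

    components: tuple[DecayComponent, ...]
    constant: float = 0.0
    reference_time: float = 0.0  # minutes; 0 = end of irradiation

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("model needs at least one component")
        if self.constant < 0:
            raise ValueError(f"constant K must be >= 0, got {self.constant}")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c.amplitude for c in self.components])

    @property
    def half_lives(self) -> np.ndarray:
        return np.array([c.half_life for c in self.components])


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Frame timing of a dynamic acquisition, in minutes after irradiation end.

    ``transport_delay`` is the patient-transport interval between end of
    irradiation and the first frame start; ``frame_bounds`` are [start, end]
    pairs on the same clock, non-overlapping and strictly increasing.
    """

    transport_delay: float = 7.0
    frame_bounds: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for start, end in self.frame_bounds:
            if not end > start:
                raise ValueError(f"frame [{start}, {end}] has non-positive length")
            if start < prev_end:
                raise ValueError("frames overlap or are out of order")
            prev_end = end

    @property
    def n_frames(self) -> int:
        return len(self.frame_bounds)

    @property
    def bounds_array(self) -> np.ndarray:
        return np.asarray(self.frame_bounds, dtype=float).reshape(-1, 2)

    @property
    def durations(self) -> np.ndarray:
        b = self.bounds_array
        return b[:, 1] - b[:, 0]


def default_schedule(
    transport_delay: float = 7.0, n_frames: int = 15, frame_length: float = 2.0
) -> AcquisitionSchedule:
    """The study protocol: 7-min transport delay, then 15 frames of 2 min."""
    bounds = tuple(
        (transport_delay + i * frame_length, transport_delay + (i + 1) * frame_length)
        for i in range(n_frames)
    )
    return AcquisitionSchedule(transport_delay=transport_delay, frame_bounds=bounds)


def model_rate(model: MultiExpModel, t: float | np.ndarray) -> float | np.ndarray:
    """Instantaneous count rate at time ``t`` (minutes from reference)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0 (minutes from the reference time)")
    out = np.full_like(t_arr, model.constant, dtype=float)
    for c in model.components:
        out = out + c.amplitude * 2.0 ** (-t_arr / c.half_life)
    return out if out.ndim else float(out)


def frame_mean_rate(model: MultiExpModel, frame: Sequence[float]) -> float:
    """Time-averaged rate over one frame, in closed form."""
    start, end = float(frame[0]), float(frame[1])
    if start < 0:
        raise ValueError("frame start must be >= 0")
    if not end > start:
        raise ValueError(f"zero- or negative-length frame [{start}, {end}]")
    dur = end - start
    total = model.constant
    for c in model.components:
        total += (
            c.amplitude
            * c.half_life
            / (LN2 * dur)
            * (2.0 ** (-start / c.half_life) - 2.0 ** (-end / c.half_life))
        )
    return total


def frame_basis(half_lives: Sequence[float], frame_bounds: np.ndarray) -> np.ndarray:
    """Frame-averaged basis matrix: column k = unit-amplitude exponential k.

    Used both to predict TACs and, by the fitter, as the design matrix of
    the non-negative linear least-squares problem.
    """
    bounds = np.asarray(frame_bounds, dtype=float).reshape(-1, 2)
    dur = bounds[:, 1] - bounds[:, 0]
    cols = []
    for t_half in half_lives:
        if not t_half > 0:
            raise ValueError(f"half_life must be > 0, got {t_half}")
        cols.append(
            t_half
            / (LN2 * dur)
            * (2.0 ** (-bounds[:, 0] / t_half) - 2.0 ** (-bounds[:, 1] / t_half))
        )
    return np.column_stack(cols) if cols else np.empty((len(bounds), 0))


def predicted_tac(model: MultiExpModel, schedule: AcquisitionSchedule):
    """Noiseless frame-averaged TAC of ``model`` over ``schedule``."""
    from .tac_io import TimeActivityCurve  # local import: avoid cycle

    basis = frame_basis(model.half_lives, schedule.bounds_array)
    values = basis @ model.amplitudes + model.constant
    return TimeActivityCurve(
        frame_bounds=schedule.frame_bounds, values=tuple(values), voi_label="predicted"
    )
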