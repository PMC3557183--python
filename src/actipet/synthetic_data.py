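"""Synthetic TACs and miniature dynamic phantoms.

The generator emulates the acquisition the analysis assumes: a patient
irradiated with high-energy photons is scanned starting one transport
delay (~7 min) after beam-off, for 15 frames of 2 min.  Component
amplitudes derive from the tissue's hydrogen-adjusted elemental
composition (count-rate fraction = mass fraction × optional yield weight,
renormalized); optional contaminant components (e.g. ³⁰P at 2.5 min from
bone) can be appended.  Counting noise is Poisson on per-frame counts —
the regime of interest is explicitly low-count (activity a few percent of
a diagnostic FDG scan) — converted back to rates.  Biological washout is
deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .composition import h_adjust
from .decay_model import (
    AcquisitionSchedule,
    DecayComponent,
    MultiExpModel,
    default_schedule,
    predicted_tac,
)
from .reference_data import (
    ACTIVATABLE_ELEMENTS,
    NuclideTable,
    default_nuclide_table,
    get_raw_composition,
)
from .tac_io import DynamicVolume, TimeActivityCurve, VoiMask

__all__ = [
    "SimulationSpec",
    "composition_to_model",
    "simulate_tac",
    "simulate_phantom",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to generate one synthetic TAC.

    ``tissue`` is a bundled tissue name or an explicit element→fraction
    mapping (raw input is hydrogen-adjusted internally).
    ``amplitude_scale`` is the expected number of counts a frame of unit
    mean rate would collect per minute; it sets the Poisson noise level.
    ``contaminants`` are extra decay components appended verbatim.
    """

    tissue: Union[str, Mapping[str, float]]
    yield_weights: Mapping[str, float] = field(default_factory=dict)
    amplitude_scale: float = 1e4
    background_K: float = 0.0
    schedule: AcquisitionSchedule = field(default_factory=default_schedule)
    contaminants: tuple[DecayComponent, ...] = ()
    noise: str = "none"  # "none" | "poisson"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"noise must be 'none' or 'poisson', got {self.noise!r}")
        if self.noise != "none":
            if self.seed is None:
                raise ValueError("a seed is mandatory when noise is enabled")
            if not self.amplitude_scale > 0:
                raise ValueError("amplitude_scale must be > 0 with Poisson noise")


def _resolve_fractions(spec: SimulationSpec) -> Mapping[str, float]:
    if isinstance(spec.tissue, str):
        return h_adjust(get_raw_composition(spec.tissue)).fractions
    return h_adjust(spec.tissue).fractions


def composition_to_model(
    spec: SimulationSpec, nuclide_table: Optional[NuclideTable] = None
) -> MultiExpModel:
    """Forward model implied by a tissue composition.

    One component per element with amplitude = fraction × yield weight
    (renormalized so the element amplitudes sum to 1), half-life from the
    nuclide table; contaminants are appended unchanged; K is the
    background constant; the reference time is end of irradiation.
    """
    table = nuclide_table or default_nuclide_table()
    fractions = _resolve_fractions(spec)
    unknown = set(fractions) - set(ACTIVATABLE_ELEMENTS)
    if unknown:
        raise ValueError(f"composition has non-activatable elements: {unknown}")
    weighted = {
        el: f * float(spec.yield_weights.get(el, 1.0)) for el, f in fractions.items()
    }
    total = sum(weighted.values())
    if total <= 0:
        raise ValueError("weighted composition sums to zero")
    components = tuple(
        DecayComponent(
            amplitude=w / total,
            half_life=table.by_parent(el).half_life,
            label=table.by_parent(el).symbol,
        )
        for el, w in weighted.items()
        if w > 0
    ) + tuple(spec.contaminants)
    return MultiExpModel(
        components=components, constant=spec.background_K, reference_time=0.0
    )


def _apply_poisson(
    values: np.ndarray,
    durations: np.ndarray,
    amplitude_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-frame counts at expectation scale·rate·duration, return rates."""
    expected_counts = amplitude_scale * values * durations
    counts = rng.poisson(expected_counts)
    return counts / (durations * amplitude_scale)


def simulate_tac(
    spec: SimulationSpec, nuclide_table: Optional[NuclideTable] = None
) -> TimeActivityCurve:
    """One synthetic TAC; identical seeds give identical output."""
    model = composition_to_model(spec, nuclide_table)
    tac = predicted_tac(model, spec.schedule)
    if spec.noise == "none":
        return TimeActivityCurve(
            tac.frame_bounds, tac.values, voi_label="synthetic"
        )
    rng = np.random.default_rng(spec.seed)
    rates = _apply_poisson(
        tac.values_array, spec.schedule.durations, spec.amplitude_scale, rng
    )
    return TimeActivityCurve(
        tac.frame_bounds, tuple(float(v) for v in rates), voi_label="synthetic"
    )


def _box_mask(grid: Sequence[int], lo: Sequence[int], hi: Sequence[int]) -> np.ndarray:
    m = np.zeros(tuple(grid), dtype=bool)
    m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return m


def simulate_phantom(
    spec_fat: SimulationSpec,
    spec_bladder: SimulationSpec,
    grid: Sequence[int] = (16, 16, 16),
    nuclide_table: Optional[NuclideTable] = None,
) -> tuple[DynamicVolume, VoiMask, VoiMask]:
    """Miniature two-region dynamic phantom.

    Region 1 (a superficial shell slab, standing in for subcutaneous fat)
    follows ``spec_fat``'s model; region 2 (a central block, the bladder)
    follows ``spec_bladder``; everywhere else is zero.  Both specs must
    share a schedule.  With Poisson noise enabled each voxel is an
    independent draw; seeding makes the volume reproducible.
    """
    grid = tuple(int(g) for g in grid)
    if len(grid) != 3 or any(g < 4 for g in grid) or any(g > 64 for g in grid):
        raise ValueError(f"grid must be 3-D with sides in [4, 64], got {grid}")
    if spec_fat.schedule.frame_bounds != spec_bladder.schedule.frame_bounds:
        raise ValueError("both specs must share one acquisition schedule")
    nx, ny, nz = grid
    fat_mask = _box_mask(grid, (0, 0, 0), (max(nx // 8, 1), ny, nz))
    c0 = [g // 2 for g in grid]
    half = [max(g // 6, 1) for g in grid]
    bl_mask = _box_mask(
        grid,
        [c - h for c, h in zip(c0, half)],
        [c + h for c, h in zip(c0, half)],
    )
    if (fat_mask & bl_mask).any():
        raise RuntimeError("phantom regions overlap")

    schedule = spec_fat.schedule
    tac_fat = predicted_tac(composition_to_model(spec_fat, nuclide_table), schedule)
    tac_bl = predicted_tac(
        composition_to_model(spec_bladder, nuclide_table), schedule
    )
    n_frames = schedule.n_frames
    data = np.zeros(grid + (n_frames,), dtype=float)
    data[fat_mask, :] = tac_fat.values_array
    data[bl_mask, :] = tac_bl.values_array

    noisy = [s for s in (spec_fat, spec_bladder) if s.noise == "poisson"]
    if noisy:
        rng = np.random.default_rng(noisy[0].seed)
        durations = schedule.durations
        for spec, mask in ((spec_fat, fat_mask), (spec_bladder, bl_mask)):
            if spec.noise != "poisson":
                continue
            idx = np.where(mask)
            for i, j, k in zip(*idx):
                data[i, j, k, :] = _apply_poisson(
                    data[i, j, k, :], durations, spec.amplitude_scale, rng
                )
    volume = DynamicVolume(
        data=data, voxel_size=(2.0, 2.0, 2.0), frame_bounds=schedule.frame_bounds
    )
    return volume, VoiMask(fat_mask, label="fat"), VoiMask(bl_mask, label="bladder")
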