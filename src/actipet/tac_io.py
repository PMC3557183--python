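"""Time–activity curve container and I/O.

A TAC is the sequence of per-frame mean count rates of one volume of
interest.  Frame values are raw, decay-uncorrected rates: all decay
handling belongs to the model and the fitter, mirroring an acquisition
protocol that disables scanner-side decay correction (e.g. by declaring a
long-lived isotope such as ⁶⁸Ge).

CSV dialect: header ``frame_start_min,frame_end_min,mean_rate``, decimal
point, UTF-8.  Floats are written with ``repr`` precision so a
write → read round trip is bit-exact.

4-D dynamic volumes and 3-D VOI masks are NIfTI-1 files (via nibabel);
because NIfTI-1 carries no per-frame timing, frame bounds travel in a JSON
sidecar written next to the volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "TimeActivityCurve",
    "DynamicVolume",
    "VoiMask",
    "read_tac_csv",
    "write_tac_csv",
    "extract_tac",
    "read_dynamic_volume",
    "write_dynamic_volume",
    "read_voi_mask",
    "write_voi_mask",
]

TAC_HEADER = "frame_start_min,frame_end_min,mean_rate"


class TacParseError(ValueError):
    """Raised for a malformed TAC CSV; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-frame mean count rates for one VOI.

    ``frame_bounds`` are [start, end] minutes since end of irradiation,
    non-overlapping and increasing; ``values`` holds one finite,
    non-negative mean rate per frame.
    """

    frame_bounds: tuple[tuple[float, float], ...]
    values: tuple[float, ...]
    voi_label: str = ""

    def __post_init__(self) -> None:
        if len(self.frame_bounds) != len(self.values):
            raise ValueError(
                f"{len(self.values)} values for {len(self.frame_bounds)} frames"
            )
        prev_end = -np.inf
        for start, end in self.frame_bounds:
            if not end > start:
                raise ValueError(f"frame [{start}, {end}] has non-positive length")
            if start < prev_end:
                raise ValueError("frames overlap or are out of order")
            prev_end = end
        vals = np.asarray(self.values, dtype=float)
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
            raise ValueError("TAC values must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def bounds_array(self) -> np.ndarray:
        return np.asarray(self.frame_bounds, dtype=float).reshape(-1, 2)

    @property
    def values_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def midpoints(self) -> np.ndarray:
        b = self.bounds_array
        return 0.5 * (b[:, 0] + b[:, 1])


@dataclass(frozen=True)
class DynamicVolume:
    """4-D dynamic image (x, y, z, frame) with voxel size and frame timing."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_bounds: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D array, got {self.data.ndim}-D")
        if self.data.shape[3] != len(self.frame_bounds):
            raise ValueError(
                f"{self.data.shape[3]} frames in array, "
                f"{len(self.frame_bounds)} frame bounds"
            )


@dataclass(frozen=True)
class VoiMask:
    """Boolean 3-D mask congruent with a volume's spatial grid."""

    data: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D mask, got {self.data.ndim}-D")
        if self.data.dtype != bool:
            object.__setattr__(self, "data", self.data.astype(bool))
        if not self.data.any():
            raise ValueError("VOI mask is empty")


def write_tac_csv(tac: TimeActivityCurve, path: str | Path) -> None:
    """Write a TAC in the package CSV dialect (bit-exact round trip)."""
    lines = [TAC_HEADER]
    for (start, end), v in zip(tac.frame_bounds, tac.values):
        lines.append(f"{start!r},{end!r},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_tac_csv(path: str | Path, voi_label: str = "") -> TimeActivityCurve:
    """Read and validate a TAC CSV; parse errors name the offending line."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines()]
    if not lines or lines[0].strip() != TAC_HEADER:
        raise TacParseError(f"expected header {TAC_HEADER!r}", line=1)
    bounds, values = [], []
    for i, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        parts = ln.split(",")
        if len(parts) != 3:
            raise TacParseError(f"expected 3 fields, got {len(parts)}", line=i)
        try:
            start, end, rate = (float(p) for p in parts)
        except ValueError:
            raise TacParseError(f"non-numeric field in {ln!r}", line=i) from None
        bounds.append((start, end))
        values.append(rate)
    if not values:
        raise TacParseError("file contains a header but no frames")
    try:
        return TimeActivityCurve(tuple(bounds), tuple(values), voi_label=voi_label)
    except ValueError as exc:
        raise TacParseError(str(exc)) from exc


def extract_tac(volume: DynamicVolume, mask: VoiMask) -> TimeActivityCurve:
    """Per-frame mean of the voxel values under the mask.

    The VOI statistic is the mean, not the sum: the analysis is of relative
    count rates, and a sum differs only by the constant voxel count.
    """
    if mask.data.shape != volume.data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.data.shape} does not match "
            f"volume grid {volume.data.shape[:3]}"
        )
    means = volume.data[mask.data, :].mean(axis=0)
    return TimeActivityCurve(
        frame_bounds=volume.frame_bounds,
        values=tuple(float(v) for v in means),
        voi_label=mask.label,
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_dynamic_volume(volume: DynamicVolume, path: str | Path) -> None:
    """Write a 4-D NIfTI-1 plus a JSON sidecar with the frame bounds."""
    path = Path(path)
    affine = np.diag(list(volume.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float64), affine), str(path))
    sidecar = {"frame_bounds_min": [list(b) for b in volume.frame_bounds]}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1), encoding="utf-8")


def read_dynamic_volume(
    path: str | Path,
    frame_bounds: Optional[Sequence[Sequence[float]]] = None,
) -> DynamicVolume:
    """Read a 4-D NIfTI-1; frame bounds come from the sidecar unless given."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if frame_bounds is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no frame timing: sidecar {sidecar} missing and none supplied"
            )
        frame_bounds = json.loads(sidecar.read_text())["frame_bounds_min"]
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicVolume(
        data=data,
        voxel_size=voxel,
        frame_bounds=tuple(tuple(float(t) for t in b) for b in frame_bounds),
    )


def write_voi_mask(mask: VoiMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), np.eye(4)), str(Path(path)))


def read_voi_mask(path: str | Path, label: str = "") -> VoiMask:
    img = nib.load(str(Path(path)))
    return VoiMask(data=np.asarray(img.dataobj) > 0, label=label)
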