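"""Frame schedules, time-activity curves, and ROI extraction.

Time is handled in minutes internally (rate constants are 1/min); file
formats carry frame times in seconds, matching scanner conventions, and
are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

GA68_HALF_LIFE_MIN = 67.71  # Ga-68 physical half-life

__all__ = [
    "GA68_HALF_LIFE_MIN",
    "FrameSchedule",
    "TimeActivityCurve",
    "LabeledImage4D",
    "frame_midpoints",
    "cumulative_integral",
    "decay_correct",
    "extract_roi_tac",
    "default_schedule",
    "long_schedule",
    "read_labeled_image_nifti",
    "write_labeled_image_nifti",
    "read_schedule_csv",
    "read_tac_csv",
    "write_tac_csv",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered PET frame boundaries, in seconds from injection."""

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if starts.shape != ends.shape or starts.ndim != 1:
            raise ValueError("starts and ends must be 1-D and equal length")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(ends <= starts):
            raise ValueError("each frame end must exceed its start")

    def __len__(self) -> int:
        return self.starts.size

    @property
    def n_frames(self) -> int:
        return self.starts.size

    @property
    def durations_s(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def durations_min(self) -> np.ndarray:
        return (self.ends - self.starts) / 60.0

    @property
    def midpoints_min(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0 / 60.0

    @property
    def total_duration_s(self) -> float:
        return float(self.ends[-1] - self.starts[0])

    def frame_covering(self, start_s: float, end_s: float) -> int | None:
        """Index of the frame exactly spanning [start_s, end_s], if any."""
        hit = np.flatnonzero(
            np.isclose(self.starts, start_s) & np.isclose(self.ends, end_s)
        )
        return int(hit[0]) if hit.size else None


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity concentration (kBq/mL) per frame for one region.

    ``decay_corrected`` marks whether values are referred back to the
    injection time (the scanner convention for reconstructed frames).
    Noisy curves may dip below zero; negative values are preserved.
    """

    schedule: FrameSchedule
    values: np.ndarray
    region_label: str = ""
    decay_corrected: bool = True
    volume_ml: float | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.schedule),):
            raise ValueError(
                f"values length {values.size} != frame count {len(self.schedule)}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("TAC values must be finite")

    def with_values(self, values: np.ndarray, **kw) -> "TimeActivityCurve":
        return replace(self, values=np.asarray(values, dtype=float), **kw)


@dataclass(frozen=True)
class LabeledImage4D:
    """A 4-D dynamic image (x, y, z, frame) with an integer label mask."""

    voxels: np.ndarray
    voxel_volume_ml: float
    labels: np.ndarray
    label_names: dict = field(default_factory=dict)

    def __post_init__(self):
        voxels = np.asarray(self.voxels, dtype=float)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "labels", labels)
        if voxels.ndim != 4:
            raise ValueError("voxels must be 4-D (x, y, z, frame)")
        if labels.shape != voxels.shape[:3]:
            raise ValueError("label mask must match the spatial dimensions")
        if self.voxel_volume_ml <= 0:
            raise ValueError("voxel volume must be positive")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Frame mid-times in minutes, (start + end) / 2."""
    return schedule.midpoints_min


def cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Trapezoidal ∫₀ᵗ C dτ evaluated at frame midpoints (kBq·min/mL).

    The grid is {0, t₁, t₂, …} with C(0) = 0: no tracer is present before
    injection, so the first trapezoid rises from zero.  Linear in the TAC
    values, and non-decreasing whenever they are non-negative.
    """
    t = tac.schedule.midpoints_min
    if np.any(np.diff(t) <= 0):
        raise ValueError("frame midpoints must be strictly increasing")
    grid = np.concatenate(([0.0], t))
    vals = np.concatenate(([0.0], tac.values))
    return np.cumsum(np.diff(grid) * (vals[1:] + vals[:-1]) / 2.0)


def decay_correct(
    tac: TimeActivityCurve,
    half_life_min: float = GA68_HALF_LIFE_MIN,
    direction: str = "to_injection",
) -> TimeActivityCurve:
    """Apply (or undo) physical-decay correction at frame mid-times.

    ``to_injection`` multiplies by 2^(t_mid / T_half), referring measured
    concentrations back to injection time; ``undo`` divides.
    """
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    factor = np.exp2(tac.schedule.midpoints_min / half_life_min)
    if direction == "to_injection":
        return tac.with_values(tac.values * factor, decay_corrected=True)
    if direction == "undo":
        return tac.with_values(tac.values / factor, decay_corrected=False)
    raise ValueError(f"unknown direction {direction!r}")


def extract_roi_tac(
    image: LabeledImage4D, schedule: FrameSchedule, label: int
) -> TimeActivityCurve:
    """Mean TAC over all voxels carrying ``label``, with region volume.

    Volume is voxel count × voxel volume — the segmentation-based organ
    volume used for whole-organ receptor content.
    """
    if image.voxels.shape[3] != len(schedule):
        raise ValueError("frame dimension does not match the schedule")
    mask = image.labels == label
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise KeyError(f"label {label} not present in mask")
    values = image.voxels[mask].mean(axis=0)
    name = image.label_names.get(label, str(label))
    return TimeActivityCurve(
        schedule=schedule,
        values=values,
        region_label=name,
        volume_ml=n_vox * image.voxel_volume_ml,
    )


# ---------------------------------------------------------------------------
# I/O and the packaged acquisition schedule
# ---------------------------------------------------------------------------

def default_schedule() -> FrameSchedule:
    """The packaged 30-frame, 60-min dynamic acquisition schedule.

    12 × 10 s, 6 × 30 s, 5 × 120 s, 5 × 300 s, 2 × 600 s — fine early
    frames over the arterial peak, coarse late frames, ending with two
    600-s frames of which the last spans the 50–60-min static window.
    """
    durations = np.repeat([10.0, 30.0, 120.0, 300.0, 600.0], [12, 6, 5, 5, 2])
    ends = np.cumsum(durations)
    starts = ends - durations
    return FrameSchedule(starts=starts, ends=ends)


def long_schedule() -> FrameSchedule:
    """A 33-frame, 90-min variant of the dynamic schedule (5 × 600-s tail).

    Reversible-tracer quantification (Logan Vt) needs the longer
    acquisition: slow binding equilibration biases Vt low on a 60-min
    scan.
    """
    durations = np.repeat([10.0, 30.0, 120.0, 300.0, 600.0], [12, 6, 5, 5, 5])
    ends = np.cumsum(durations)
    starts = ends - durations
    return FrameSchedule(starts=starts, ends=ends)


def read_schedule_csv(path) -> FrameSchedule:
    df = pd.read_csv(path)
    return FrameSchedule(
        starts=df["frame_start_s"].to_numpy(float),
        ends=df["frame_end_s"].to_numpy(float),
    )


def read_tac_csv(path) -> dict[str, TimeActivityCurve]:
    """Read a multi-region TAC table: frame_start_s, frame_end_s, <regions...>."""
    df = pd.read_csv(path)
    schedule = FrameSchedule(
        starts=df["frame_start_s"].to_numpy(float),
        ends=df["frame_end_s"].to_numpy(float),
    )
    out = {}
    for col in df.columns:
        if col in ("frame_start_s", "frame_end_s"):
            continue
        out[col] = TimeActivityCurve(
            schedule=schedule, values=df[col].to_numpy(float), region_label=col
        )
    return out


def write_tac_csv(path, tacs: dict[str, TimeActivityCurve]) -> None:
    first = next(iter(tacs.values()))
    df = pd.DataFrame(
        {
            "frame_start_s": first.schedule.starts,
            "frame_end_s": first.schedule.ends,
        }
    )
    for name, tac in tacs.items():
        if tac.schedule is not first.schedule and not (
            np.array_equal(tac.schedule.starts, first.schedule.starts)
            and np.array_equal(tac.schedule.ends, first.schedule.ends)
        ):
            raise ValueError("all TACs in one file must share a schedule")
        df[name] = tac.values
    df.to_csv(path, index=False)


def read_labeled_image_nifti(
    image_path, mask_path, label_map_yaml=None
) -> LabeledImage4D:
    """Load a 4-D dynamic image and its integer label mask from NIfTI.

    Voxel volume (mL) comes from the image header zooms (mm³ / 1000).
    ``label_map_yaml``: optional YAML file mapping integer region codes
    to names, e.g. ``1: pancreas``.
    """
    img = nib.load(str(image_path))
    mask = nib.load(str(mask_path))
    voxels = np.asarray(img.dataobj, dtype=float)
    labels = np.rint(np.asarray(mask.dataobj)).astype(int)
    zooms = img.header.get_zooms()[:3]
    voxel_volume_ml = float(np.prod(zooms)) / 1000.0
    names = {}
    if label_map_yaml is not None:
        with open(label_map_yaml) as fh:
            names = {int(k): str(v) for k, v in yaml.safe_load(fh).items()}
    return LabeledImage4D(
        voxels=voxels, voxel_volume_ml=voxel_volume_ml,
        labels=labels, label_names=names,
    )


def write_labeled_image_nifti(image: LabeledImage4D, image_path, mask_path,
                              label_map_yaml=None) -> None:
    """Write a LabeledImage4D as a NIfTI pair (isotropic voxels whose
    volume matches ``voxel_volume_ml``), plus an optional label-map YAML."""
    side_mm = (image.voxel_volume_ml * 1000.0) ** (1.0 / 3.0)
    affine = np.diag([side_mm, side_mm, side_mm, 1.0])
    nib.save(nib.Nifti1Image(image.voxels.astype(np.float32), affine),
             str(image_path))
    nib.save(nib.Nifti1Image(image.labels.astype(np.int16), affine),
             str(mask_path))
    if label_map_yaml is not None and image.label_names:
        with open(label_map_yaml, "w") as fh:
            yaml.safe_dump({int(k): str(v)
                            for k, v in image.label_names.items()}, fh)


def packaged_fixture(name: str):
    """Path-like handle to a CSV shipped with the package."""
    return resources.files("petkin.data").joinpath(name)
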