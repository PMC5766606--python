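"""Display geometry, run design, and binary stimulus-aperture construction.

The experiment presents a bar that sweeps across a square grey "carpet"
occluder in the four cardinal directions.  Everything downstream of the
renderer only needs to know *where* the bar was on each fMRI volume, so the
stimulus is reduced to a movie of binary masks on a visual-field raster:
one frame per retained volume, 1 inside the bar rectangle, 0 elsewhere.
All three stimulus conditions (illusory-contour, occlusion, low-contrast
luminance) share identical bar geometry and therefore the identical movie.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DisplayGeometry",
    "CarpetSpec",
    "RunDesign",
    "VisualFieldGrid",
    "ApertureMovie",
    "BAR_DIRECTIONS",
    "px_to_deg",
    "build_run_design",
    "bar_rect",
    "build_aperture_movie",
]

BAR_DIRECTIONS = ("bar_right", "bar_up", "bar_left", "bar_down")


class GeometryError(ValueError):
    """Invalid display geometry or grid coverage."""


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical projection geometry of the stimulus display.

    Defaults describe a 36.8 x 20.2 cm screen at 1920 x 1080 px viewed
    from 68 cm.
    """

    screen_width_cm: float = 36.8
    screen_height_cm: float = 20.2
    res_x_px: int = 1920
    res_y_px: int = 1080
    view_dist_cm: float = 68.0

    def __post_init__(self) -> None:
        for name in ("screen_width_cm", "screen_height_cm", "res_x_px",
                     "res_y_px", "view_dist_cm"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CarpetSpec:
    """Geometry of the carpet occluder and the mapping bar, in degrees.

    The bar is 0.9 deg wide and overlaps the brick background by 2.1 deg on
    either side of the 6.7 deg occluder, giving a 10.9 deg long bar.
    """

    occluder_side_deg: float = 6.7
    brick_side_deg: float = 11.4
    bar_width_deg: float = 0.9
    bar_overlap_deg: float = 2.1
    plus_sign_halfwidth_deg: float = 0.75

    def __post_init__(self) -> None:
        if not self.occluder_side_deg < self.brick_side_deg:
            raise GeometryError("occluder must be smaller than the brick image")

    @property
    def bar_length_deg(self) -> float:
        """Long-axis extent: occluder side plus the overlap on each side."""
        return self.occluder_side_deg + 2.0 * self.bar_overlap_deg


@dataclass(frozen=True)
class RunDesign:
    """Trial sequence and timing of one scanning run.

    A run is 10 s of blank dummy volumes followed by six 30 s trials:
    four bar sweeps in the order Right, Up, Left, Down with a null trial
    after the second and fourth sweep.  Dummy volumes are discarded.
    """

    trial_sequence: tuple[str, ...] = (
        "bar_right", "bar_up", "null", "bar_left", "bar_down", "null")
    trial_dur_s: float = 30.0
    step_dur_s: float = 1.0
    steps_per_sweep: int = 30
    dummy_dur_s: float = 10.0
    tr_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("trial_dur_s", "step_dur_s", "dummy_dur_s", "tr_s"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        for label in self.trial_sequence:
            if label != "null" and label not in BAR_DIRECTIONS:
                raise GeometryError(f"unknown trial label {label!r}")

    @property
    def n_dummy_volumes(self) -> int:
        return int(round(self.dummy_dur_s / self.tr_s))

    @property
    def n_volumes_total(self) -> int:
        total_s = self.dummy_dur_s + len(self.trial_sequence) * self.trial_dur_s
        return int(round(total_s / self.tr_s))

    @property
    def n_volumes_retained(self) -> int:
        return self.n_volumes_total - self.n_dummy_volumes

    @property
    def volumes_per_trial(self) -> int:
        return int(round(self.trial_dur_s / self.tr_s))


@dataclass(frozen=True)
class VisualFieldGrid:
    """Square raster over the visual field; x rightward, y upward, deg units.

    Cells are centre-sampled: a cell counts as inside a rectangle iff its
    centre does.  Default covers +-8.5 deg at 0.1 deg resolution.
    """

    x_min_deg: float = -8.5
    x_max_deg: float = 8.5
    y_min_deg: float = -8.5
    y_max_deg: float = 8.5
    cell_deg: float = 0.1

    def __post_init__(self) -> None:
        if self.cell_deg <= 0:
            raise GeometryError("cell_deg must be positive")
        if not (math.isclose(-self.x_min_deg, self.x_max_deg)
                and math.isclose(-self.y_min_deg, self.y_max_deg)):
            raise GeometryError("grid must be symmetric about fixation")

    @property
    def x_centers(self) -> np.ndarray:
        n = int(round((self.x_max_deg - self.x_min_deg) / self.cell_deg))
        return self.x_min_deg + (np.arange(n) + 0.5) * self.cell_deg

    @property
    def y_centers(self) -> np.ndarray:
        n = int(round((self.y_max_deg - self.y_min_deg) / self.cell_deg))
        return self.y_min_deg + (np.arange(n) + 0.5) * self.cell_deg

    @property
    def shape(self) -> tuple[int, int]:
        """(n_y, n_x) raster shape; rows index y, columns index x."""
        return (self.y_centers.size, self.x_centers.size)

    @property
    def cell_area(self) -> float:
        return self.cell_deg ** 2

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_centers, self.y_centers)


@dataclass
class ApertureMovie:
    """Binary aperture masks, one frame per retained volume.

    frames has shape (n_volumes_retained, n_y, n_x); frame_times_s are
    volume onsets relative to run start (the dummy period precedes frame 0).
    """

    frames: np.ndarray
    frame_times_s: np.ndarray
    grid: VisualFieldGrid
    design: RunDesign = field(repr=False, default_factory=RunDesign)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if not np.isin(self.frames, (0, 1)).all():
            raise ValueError("aperture frames must be binary")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def save(self, path) -> None:
        """Write frames as a .npy array with a JSON sidecar (grid spec and
        frame times) next to it."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        path = Path(path)
        np.save(path.with_suffix(".npy"), self.frames)
        sidecar = dict(grid=asdict(self.grid),
                       frame_times_s=self.frame_times_s.tolist(),
                       design=asdict(self.design))
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "ApertureMovie":
        import json
        from pathlib import Path

        path = Path(path)
        frames = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        design_kw = dict(meta["design"])
        design_kw["trial_sequence"] = tuple(design_kw["trial_sequence"])
        return cls(frames=frames,
                   frame_times_s=np.asarray(meta["frame_times_s"]),
                   grid=VisualFieldGrid(**meta["grid"]),
                   design=RunDesign(**design_kw))


def px_to_deg(pixels: float, geom: DisplayGeometry | None = None) -> float:
    """Convert an on-screen extent in pixels to degrees of visual angle.

    Uses the full tangent formula 2*atan(s / 2d) with the vertical pixel
    pitch (screen_height_cm / res_y_px); this reproduces the display's
    printed conversions (428 px -> 6.7 deg, 728 px -> 11.4 deg, 5 px ->
    0.08 deg, 1080 px -> 16.9 deg).
    """
    if geom is None:
        geom = DisplayGeometry()
    if pixels < 0:
        raise ValueError("pixel extent must be non-negative")
    size_cm = pixels * geom.screen_height_cm / geom.res_y_px
    return math.degrees(2.0 * math.atan2(size_cm, 2.0 * geom.view_dist_cm))


def build_run_design(**overrides) -> RunDesign:
    """Construct the default run design, optionally overriding timing fields."""
    return RunDesign(**overrides)


def bar_rect(direction: str, step_index: int,
             carpet: CarpetSpec | None = None,
             steps_per_sweep: int = 30) -> tuple[float, float, float, float]:
    """Axis-aligned bar rectangle (x_min, x_max, y_min, y_max) in degrees.

    The bar's long axis is perpendicular to its motion.  Centres advance by
    occluder_side / steps_per_sweep per step and span the occluder
    symmetrically: the first centre sits at -occluder/2 + step/2 along the
    motion axis (sign flipped for leftward/downward sweeps).
    """
    if carpet is None:
        carpet = CarpetSpec()
    if direction not in BAR_DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    if not 0 <= step_index < steps_per_sweep:
        raise IndexError(
            f"step_index {step_index} outside [0, {steps_per_sweep})")

    step = carpet.occluder_side_deg / steps_per_sweep
    start = -carpet.occluder_side_deg / 2.0 + step / 2.0
    centre = start + step_index * step
    if direction in ("bar_left", "bar_down"):
        centre = -centre

    half_w = carpet.bar_width_deg / 2.0
    half_len = carpet.bar_length_deg / 2.0
    if direction in ("bar_right", "bar_left"):   # horizontal motion, vertical bar
        return (centre - half_w, centre + half_w, -half_len, half_len)
    return (-half_len, half_len, centre - half_w, centre + half_w)


def _rasterize_rect(rect: tuple[float, float, float, float],
                    grid: VisualFieldGrid) -> np.ndarray:
    x_min, x_max, y_min, y_max = rect
    xin = (grid.x_centers >= x_min) & (grid.x_centers <= x_max)
    yin = (grid.y_centers >= y_min) & (grid.y_centers <= y_max)
    return np.outer(yin, xin).astype(np.uint8)


def build_aperture_movie(design: RunDesign | None = None,
                         carpet: CarpetSpec | None = None,
                         grid: VisualFieldGrid | None = None) -> ApertureMovie:
    """Rasterize the run design into a binary aperture movie.

    One frame per retained volume; frames within a bar trial mark the bar
    rectangle of that 1 s step; null-trial frames are all-zero.  The dummy
    period produces no frames (those volumes are discarded) but is part of
    the timeline via frame_times_s.
    """
    design = design or RunDesign()
    carpet = carpet or CarpetSpec()
    grid = grid or VisualFieldGrid()

    half_len = carpet.bar_length_deg / 2.0
    half_occ = carpet.occluder_side_deg / 2.0
    if (grid.x_max_deg < max(half_len, half_occ)
            or grid.y_max_deg < max(half_len, half_occ)):
        raise GeometryError("grid does not cover the bar sweep region")

    n_y, n_x = grid.shape
    frames = np.zeros((design.n_volumes_retained, n_y, n_x), dtype=np.uint8)
    vols_per_trial = design.volumes_per_trial
    vols_per_step = int(round(design.step_dur_s / design.tr_s))

    vol = 0
    for label in design.trial_sequence:
        if label == "null":
            vol += vols_per_trial
            continue
        for step in range(design.steps_per_sweep):
            rect = bar_rect(label, step, carpet, design.steps_per_sweep)
            mask = _rasterize_rect(rect, grid)
            for _ in range(vols_per_step):
                frames[vol] = mask
                vol += 1
    if vol not in (design.n_volumes_retained,):
        # only possible when steps * step_dur != trial_dur
        raise GeometryError("trial timing inconsistent with sweep steps")

    times = design.dummy_dur_s + np.arange(design.n_volumes_retained) * design.tr_s
    return ApertureMovie(frames=frames, frame_times_s=times,
                         grid=grid, design=design)
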