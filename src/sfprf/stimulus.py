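"""Visual-field geometry and bar-aperture construction for pRF mapping.

The mapping stimulus is a 1.15°-wide bar of band-pass noise that sweeps a
15°-diameter circular aperture in eight directions (bottom-to-top first, each
subsequent sweep rotated 45° clockwise), with 25 half-overlapping steps per
sweep.  The visible region is further restricted by a central occluder and by
two 20°-wide wedges over the vertical meridian, so that each hemifield can be
adapted independently without stimulating the other.

All apertures are *binary* masks sampled on a square grid of visual-field
coordinates: the model is fit against a binary representation of the bar, not
against the rendered noise carrier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FieldGrid",
    "MaskGeometry",
    "RunDesign",
    "ApertureSequence",
    "make_field_grid",
    "adapter_region_mask",
    "bar_mask",
    "build_run_apertures",
    "geometric_mean_sf",
]


@dataclass(frozen=True)
class FieldGrid:
    """Square sampling grid over the visual field.

    x increases rightward, y increases upward, origin at fixation.  Sample
    coordinates are symmetric about zero; ``half_extent`` must be an integer
    multiple of ``resolution``.
    """

    half_extent: float = 7.5
    resolution: float = 0.1

    def __post_init__(self) -> None:
        if self.half_extent <= 0:
            raise ValueError(f"half_extent must be > 0, got {self.half_extent}")
        if not (0 < self.resolution <= self.half_extent):
            raise ValueError(
                f"resolution must be in (0, half_extent], got {self.resolution}"
            )
        n = self.half_extent / self.resolution
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ValueError(
                "half_extent must be an integer multiple of resolution "
                f"(got {self.half_extent}/{self.resolution})"
            )

    @property
    def n_samples(self) -> int:
        """Samples along one axis (odd: includes 0 and both extremes)."""
        return 2 * round(self.half_extent / self.resolution) + 1

    @property
    def x(self) -> np.ndarray:
        return np.linspace(-self.half_extent, self.half_extent, self.n_samples)

    @property
    def y(self) -> np.ndarray:
        return self.x.copy()

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of shape (n, n); row 0 is y = +half_extent."""
        # image convention: first axis runs top (y = +half_extent) to bottom
        xx, yy = np.meshgrid(self.x, self.y[::-1])
        return xx, yy

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_samples)


@dataclass(frozen=True)
class MaskGeometry:
    """Aperture / occluder geometry (degrees of visual angle).

    ``wedge_full_width`` is the full polar-angle width of each of the two
    gray wedges centred on the upper and lower vertical meridian.
    """

    aperture_radius: float = 7.5
    central_occluder_diameter: float = 0.7
    wedge_full_width: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.central_occluder_diameter < 2 * self.aperture_radius):
            raise ValueError("central occluder must fit inside the aperture")
        if not (0 <= self.wedge_full_width < 180):
            raise ValueError("wedge_full_width must be in [0, 180)")


#: Geometry used for the psychophysics display (radius 7.7°, ~1° occluder).
PSYCHOPHYSICS_GEOMETRY = MaskGeometry(
    aperture_radius=7.7, central_occluder_diameter=2.0, wedge_full_width=20.0
)


@dataclass(frozen=True)
class RunDesign:
    """Temporal layout of one mapping run (units: volumes, TR = 1 s).

    25 baseline + 30 initial adaptation + 8 sweeps of 25 bar steps with a
    25-volume blank after sweep 4 and after sweep 8 + 25 closing baseline
    = 330 volumes; the 250 sweep/blank volumes are the mapping sequence.
    """

    tr: float = 1.0
    n_baseline_pre: int = 25
    n_adapt: int = 30
    n_sweeps: int = 8
    n_bar_steps: int = 25
    n_blank: int = 25
    blank_after_sweeps: tuple[int, ...] = (4, 8)
    n_baseline_post: int = 25
    bar_width: float = 1.15

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.bar_width <= 0:
            raise ValueError("tr and bar_width must be positive")
        if min(self.n_sweeps, self.n_bar_steps) < 1:
            raise ValueError("need at least one sweep and one bar step")

    @property
    def step_size(self) -> float:
        """Bar-centre step: half the bar width (half-overlapping bars)."""
        return self.bar_width / 2

    @property
    def n_mapping(self) -> int:
        return (
            self.n_sweeps * self.n_bar_steps
            + len(self.blank_after_sweeps) * self.n_blank
        )

    @property
    def n_volumes(self) -> int:
        return (
            self.n_baseline_pre + self.n_adapt + self.n_mapping + self.n_baseline_post
        )

    @property
    def mapping_slice(self) -> slice:
        start = self.n_baseline_pre + self.n_adapt
        return slice(start, start + self.n_mapping)


@dataclass
class ApertureSequence:
    """Per-volume binary visual-field masks with frame annotations.

    ``frames`` has shape (T, n, n) with values in {0, 1}; annotations are
    ``baseline``, ``adaptation``, ``blank`` or ``bar:<sweep>:<step>``.
    """

    grid: FieldGrid
    frames: np.ndarray
    annotations: list[str]
    tr: float = 1.0
    design: RunDesign | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] != len(self.annotations):
            raise ValueError("frames/annotations mismatch")
        if self.frames.shape[1:] != self.grid.shape:
            raise ValueError("frame shape does not match grid")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def mapping_indices(self) -> np.ndarray:
        """Indices of the mapping sequence (bar and blank volumes)."""
        return np.array(
            [
                i
                for i, a in enumerate(self.annotations)
                if a == "blank" or a.startswith("bar:")
            ],
            dtype=int,
        )

    def coarsen(self, factor: int = 2) -> "ApertureSequence":
        """Subsample the spatial grid by an integer factor (for fast fitting).

        Keeps every ``factor``-th sample on a symmetric lattice through the
        centre sample (fixation), so the result is again a valid grid; its
        half-extent shrinks to the outermost kept sample.
        """
        if factor < 1:
            raise ValueError("factor must be >= 1")
        if factor == 1:
            return self
        n = self.grid.n_samples
        c = (n - 1) // 2
        idx = np.arange(c % factor, n, factor)
        if idx.size < 3:
            raise ValueError(f"coarsening by {factor} leaves too few samples")
        grid = FieldGrid(
            float((idx[-1] - c) * self.grid.resolution),
            self.grid.resolution * factor,
        )
        return ApertureSequence(
            grid=grid,
            frames=np.ascontiguousarray(self.frames[np.ix_(range(self.frames.shape[0]), idx, idx)]),
            annotations=list(self.annotations),
            tr=self.tr,
            design=self.design,
        )


def make_field_grid(half_extent: float = 7.5, resolution: float = 0.1) -> FieldGrid:
    """Construct a :class:`FieldGrid`; (7.5, 0.1) gives 151×151 samples."""
    return FieldGrid(half_extent=half_extent, resolution=resolution)


def adapter_region_mask(
    grid: FieldGrid,
    geom: MaskGeometry = MaskGeometry(),
    hemifield: str = "both",
) -> np.ndarray:
    """Binary mask of the stimulated (adapter) region.

    A sample is inside iff its centre lies strictly within the aperture
    radius, at or beyond the occluder radius, outside both vertical-meridian
    wedges, and in the requested hemifield (left: x < 0, right: x > 0).
    """
    if hemifield not in ("left", "right", "both"):
        raise ValueError(f"hemifield must be left/right/both, got {hemifield!r}")
    xx, yy = grid.mesh()
    r = np.hypot(xx, yy)
    mask = (r < geom.aperture_radius) & (r >= geom.central_occluder_diameter / 2)
    half_wedge = math.radians(geom.wedge_full_width / 2)
    # angular distance from the upper / lower vertical meridian
    up = np.arctan2(np.abs(xx), yy)
    down = np.arctan2(np.abs(xx), -yy)
    mask &= (up >= half_wedge) & (down >= half_wedge)
    if hemifield == "left":
        mask &= xx < 0
    elif hemifield == "right":
        mask &= xx > 0
    return mask.astype(np.uint8)


def bar_mask(
    grid: FieldGrid,
    sweep: int,
    step: int,
    bar_width: float = 1.15,
    n_steps: int = 25,
) -> np.ndarray:
    """Binary mask of an infinite bar at one sweep/step.

    Sweep 0 moves bottom→top (horizontal bar); sweep k is rotated 45·k°
    clockwise (screen convention, y up: the motion-direction angle decreases
    by 45° per sweep).  The 25 bar centres are spaced ``bar_width/2`` apart,
    symmetric about fixation along the motion axis, so the middle step lies
    on the axis through fixation.
    """
    if not (0 <= sweep <= 7):
        raise IndexError(f"sweep index must be 0..7, got {sweep}")
    if not (0 <= step < n_steps):
        raise IndexError(f"step index must be 0..{n_steps - 1}, got {step}")
    # motion direction at 90° − 45°·sweep; exact table so opposite sweeps
    # negate the projection bit-exactly (cardinals and diagonals alike)
    h = math.sqrt(0.5)
    cos_t, sin_t = [
        (0.0, 1.0), (h, h), (1.0, 0.0), (h, -h),
        (0.0, -1.0), (-h, -h), (-1.0, 0.0), (-h, h),
    ][sweep]
    xx, yy = grid.mesh()
    proj = xx * cos_t + yy * sin_t
    centre = (step - (n_steps - 1) / 2) * (bar_width / 2)
    return (np.abs(proj - centre) <= bar_width / 2).astype(np.uint8)


def build_run_apertures(
    design: RunDesign = RunDesign(),
    geom: MaskGeometry = MaskGeometry(),
    grid: FieldGrid = FieldGrid(),
) -> ApertureSequence:
    """Assemble the full 330-volume aperture sequence for one mapping run.

    Bar frames are the infinite-bar mask intersected with the adapter region
    (both hemifields); baseline, initial-adaptation and blank frames are all
    zero (the adapters stimulate the same region in every volume, so they
    contribute no mapping signal and are not represented).
    """
    region = adapter_region_mask(grid, geom, "both")
    frames = np.zeros((design.n_volumes, *grid.shape), dtype=np.uint8)
    annotations: list[str] = []
    annotations += ["baseline"] * design.n_baseline_pre
    annotations += ["adaptation"] * design.n_adapt
    t = design.n_baseline_pre + design.n_adapt
    for sweep in range(design.n_sweeps):
        for step in range(design.n_bar_steps):
            frames[t] = (
                bar_mask(grid, sweep, step, design.bar_width, design.n_bar_steps)
                & region
            )
            annotations.append(f"bar:{sweep}:{step}")
            t += 1
        if (sweep + 1) in design.blank_after_sweeps:
            annotations += ["blank"] * design.n_blank
            t += design.n_blank
    annotations += ["baseline"] * design.n_baseline_post
    assert len(annotations) == design.n_volumes
    return ApertureSequence(
        grid=grid, frames=frames, annotations=annotations, tr=design.tr, design=design
    )


def geometric_mean_sf(f1: float, f2: float) -> float:
    """Geometric mean of two spatial frequencies (cpd): √(f1·f2).

    The mapping/reference SF is the geometric mean of the two adapter SFs
    (0.5 and 3.5 cpd → ≈1.3 cpd), equidistant from both in log space.
    """
    if f1 <= 0 or f2 <= 0:
        raise ValueError("spatial frequencies must be positive")
    return math.sqrt(f1 * f2)
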