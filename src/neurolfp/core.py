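"""Domain types and geometric primitives for extracellular field modeling.

Units follow electrophysiology convention throughout the public API:
micrometres for lengths, milliseconds for time, nanoamperes for membrane
currents, microvolts for potentials, S/m for extracellular conductivity
(resistivity in Ohm·m).  Conversion to SI happens inside the forward
formulas only.

Sign convention: outward (membrane-to-extracellular) current is positive;
a net outward current produces a positive extracellular potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class NeuroLFPError(Exception):
    """Base class for errors raised by this package."""


class GeometryError(NeuroLFPError):
    """Degenerate or invalid source/electrode geometry."""


class ConfigurationError(NeuroLFPError):
    """Invalid parameter or configuration value."""


class DataError(NeuroLFPError):
    """Inconsistent or malformed data (shapes, files, tables)."""


class SolverError(NeuroLFPError):
    """Numerical integration failure in the cable simulator."""


class ConvergenceError(NeuroLFPError):
    """A numerical routine failed to reach its requested tolerance."""


@dataclass(frozen=True)
class Point3:
    """A point in 3-D space, coordinates in micrometres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise GeometryError(f"non-finite coordinates: {(self.x, self.y, self.z)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def of(cls, obj: "Point3 | Sequence[float]") -> "Point3":
        if isinstance(obj, Point3):
            return obj
        x, y, z = (float(v) for v in obj)
        return cls(x, y, z)

    def __add__(self, other: "Point3") -> "Point3":
        return Point3(self.x + other.x, self.y + other.y, self.z + other.z)


@dataclass(frozen=True)
class SegmentSource:
    """A cylindrical current source: the axis segment of one neurite compartment.

    A zero-length segment must be flagged ``spherical`` (an equivalent-sphere
    soma source); it is always treated as a point source by the forward
    schemas since the line-source formula is undefined at zero length.
    """

    id: str
    p_start: Point3
    p_end: Point3
    diameter: float
    spherical: bool = False

    def __post_init__(self) -> None:
        if not (self.diameter > 0 and math.isfinite(self.diameter)):
            raise GeometryError(f"segment {self.id}: diameter must be > 0, got {self.diameter}")
        if self.length == 0.0 and not self.spherical:
            raise GeometryError(
                f"segment {self.id}: zero length is only allowed for spherical (soma) sources"
            )

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p_end.as_array() - self.p_start.as_array()))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.p_start.as_array() + self.p_end.as_array())


@dataclass
class SourceSet:
    """An ordered set of segment sources with their transmembrane currents.

    ``currents`` has shape (n_sources, n_steps) in nA, outward-positive, on a
    uniform time base ``t0 + k*dt`` (ms).
    """

    segments: list[SegmentSource]
    currents: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        if self.currents.ndim != 2:
            raise DataError(f"currents must be 2-D, got shape {self.currents.shape}")
        if self.currents.shape[0] != len(self.segments):
            raise DataError(
                f"currents has {self.currents.shape[0]} rows but there are "
                f"{len(self.segments)} segments"
            )
        if not self.dt > 0:
            raise DataError(f"dt must be > 0, got {self.dt}")
        if not np.all(np.isfinite(self.currents)):
            raise DataError("currents contain non-finite values")

    @property
    def n_sources(self) -> int:
        return len(self.segments)

    @property
    def n_steps(self) -> int:
        return self.currents.shape[1]

    @property
    def time(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_steps)

    # geometry as flat arrays, used by the vectorized forward solvers
    def starts(self) -> np.ndarray:
        return np.array([s.p_start.as_array() for s in self.segments]).reshape(-1, 3)

    def ends(self) -> np.ndarray:
        return np.array([s.p_end.as_array() for s in self.segments]).reshape(-1, 3)

    def midpoints(self) -> np.ndarray:
        return np.array([s.midpoint for s in self.segments]).reshape(-1, 3)

    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.segments], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.segments], dtype=float)

    def spherical_mask(self) -> np.ndarray:
        return np.array([s.spherical for s in self.segments], dtype=bool)

    @classmethod
    def concat(cls, parts: Iterable["SourceSet"]) -> "SourceSet":
        parts = list(parts)
        if not parts:
            raise DataError("cannot concatenate an empty list of SourceSets")
        first = parts[0]
        for p in parts[1:]:
            if p.n_steps != first.n_steps or p.dt != first.dt or p.t0 != first.t0:
                raise DataError("SourceSets must share an identical time base to concatenate")
        segments = [s for p in parts for s in p.segments]
        currents = np.vstack([p.currents for p in parts])
        return cls(segments, currents, first.dt, first.t0)

    @classmethod
    def empty(cls, n_steps: int, dt: float, t0: float = 0.0) -> "SourceSet":
        return cls([], np.zeros((0, n_steps)), dt, t0)


@dataclass
class Medium:
    """Extracellular medium: ohmic conductivity plus RC-filter parameters.

    sigma        conductivity, S/m (resistivity = 1/sigma, Ohm·m)
    e_r          stored RC medium resistance, Ohm·m (squid-axon cytoplasmic
                 resistivity convention, 0.35 Ohm·m)
    e_c          stored RC medium capacitance, F/m^2 (specific membrane
                 capacitance, 1 uF/cm^2)
    tau          RC filter time constant, ms. Exposed directly because
                 e_r*e_c (Ohm·m · F/m^2) does not reduce to a time without
                 an extra length scale; e_r and e_c are kept for provenance.
    min_distance source-electrode clamping floor, um; forward formulas never
                 evaluate closer than max(min_distance, segment radius).
    """

    sigma: float = 0.3
    e_r: float = 0.35
    e_c: float = 0.01
    tau: float = 5.0
    min_distance: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")
        if not self.tau > 0:
            raise ConfigurationError(f"tau must be > 0, got {self.tau}")
        if not self.min_distance > 0:
            raise ConfigurationError(f"min_distance must be > 0, got {self.min_distance}")

    @property
    def resistivity(self) -> float:
        """Extracellular resistivity, Ohm·m (exactly 1/sigma)."""
        return 1.0 / self.sigma

    @classmethod
    def from_resistivity(cls, resistivity: float, **kwargs) -> "Medium":
        if not resistivity > 0:
            raise ConfigurationError(f"resistivity must be > 0, got {resistivity}")
        return cls(sigma=1.0 / resistivity, **kwargs)


@dataclass(frozen=True)
class Electrode:
    position: Point3
    label: str


@dataclass(frozen=True)
class GridSpec:
    nx: int
    ny: int
    pitch: float
    plane: str = "xy"
    origin: Point3 = field(default_factory=lambda: Point3(0.0, 0.0, 0.0))


@dataclass
class ElectrodeArray:
    """Ordered recording points, optionally carrying regular-grid metadata."""

    electrodes: list[Electrode]
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        labels = [e.label for e in self.electrodes]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("electrode labels must be unique")
        if self.grid is not None and self.grid.nx * self.grid.ny != len(self.electrodes):
            raise ConfigurationError(
                f"grid metadata ({self.grid.nx}x{self.grid.ny}) inconsistent with "
                f"{len(self.electrodes)} electrodes"
            )

    def __len__(self) -> int:
        return len(self.electrodes)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.electrodes]

    def positions(self) -> np.ndarray:
        return np.array([e.position.as_array() for e in self.electrodes]).reshape(-1, 3)

    @classmethod
    def single(cls, position: Point3 | Sequence[float], label: str = "e0") -> "ElectrodeArray":
        return cls([Electrode(Point3.of(position), label)])


@dataclass
class LFPTrace:
    """Per-electrode extracellular potential traces.

    ``values`` has shape (n_electrodes, n_steps) in uV; ``time`` in ms is
    strictly increasing with a uniform step.
    """

    time: np.ndarray
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.labels), self.time.size):
            raise DataError(
                f"inconsistent trace dimensions: values {self.values.shape}, "
                f"{len(self.labels)} labels, {self.time.size} time points"
            )
        if self.time.size >= 2:
            steps = np.diff(self.time)
            if not (np.all(steps > 0) and np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12)):
                raise DataError("time must be strictly increasing with a uniform step")

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    @property
    def dt(self) -> float:
        if self.time.size < 2:
            raise DataError("trace too short to define a time step")
        return float(self.time[1] - self.time[0])

    def crop(self, t_min: float, t_max: float) -> "LFPTrace":
        mask = (self.time >= t_min) & (self.time <= t_max)
        if not mask.any():
            raise DataError(f"empty crop window [{t_min}, {t_max}] ms")
        return LFPTrace(self.time[mask], self.values[:, mask], list(self.labels))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.time})
        for i, lab in enumerate(self.labels):
            df[lab] = self.values[i]
        return df


def line_coordinates(segment: SegmentSource, electrode: Point3 | Sequence[float]):
    """Cylindrical coordinates of an electrode relative to a line segment.

    Returns ``(r, h, l)`` in um: ``r`` is the perpendicular distance from the
    electrode to the infinite line through the segment axis; ``h`` is the
    signed axial coordinate of the electrode's projection measured from the
    segment *end* (positive beyond the end, negative alongside or behind);
    ``l = length + h`` is the same coordinate measured from the segment start.

    Raises GeometryError for a zero-length segment.
    """
    a = segment.p_start.as_array()
    b = segment.p_end.as_array()
    e = Point3.of(electrode).as_array()
    axis = b - a
    ds = float(np.linalg.norm(axis))
    if ds == 0.0:
        raise GeometryError(f"segment {segment.id}: zero-length segment has no line coordinates")
    u = axis / ds
    l = float(np.dot(e - a, u))
    h = l - ds
    perp = (e - a) - l * u
    r = float(np.linalg.norm(perp))
    return r, h, l


_PLANE_AXES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


def make_grid(
    nx: int = 4,
    ny: int = 4,
    pitch: float = 100.0,
    plane: str = "xy",
    origin: Point3 | Sequence[float] = (0.0, 0.0, 0.0),
) -> ElectrodeArray:
    """Build a regular electrode grid (default 4x4 at 100 um pitch).

    Electrodes are ordered row-major from the origin: the first plane axis
    varies fastest within a row, the second indexes rows. Labels are
    ``r{row}c{col}``.
    """
    if nx < 1 or ny < 1:
        raise ConfigurationError(f"grid dimensions must be >= 1, got {nx}x{ny}")
    if not pitch > 0:
        raise ConfigurationError(f"pitch must be > 0, got {pitch}")
    if plane not in _PLANE_AXES:
        raise ConfigurationError(f"unknown plane {plane!r}; expected one of {sorted(_PLANE_AXES)}")
    origin = Point3.of(origin)
    i1, i2 = _PLANE_AXES[plane]
    base = origin.as_array()
    electrodes = []
    for iy in range(ny):
        for ix in range(nx):
            pos = base.copy()
            pos[i1] += ix * pitch
            pos[i2] += iy * pitch
            electrodes.append(Electrode(Point3(*pos), f"r{iy}c{ix}"))
    return ElectrodeArray(electrodes, GridSpec(nx, ny, pitch, plane, origin))
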