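"""Readers and writers: SWC morphologies, currents tables, configs, traces.

The currents interchange format is a directory holding ``geometry.csv``
(one row per compartment: id, endpoints, diameter), ``currents.csv``
(rows = compartments, columns = time steps, nA) and ``meta.json``
(dt_ms, t0_ms, units). A single-file HDF5 variant is selected by an
``.h5``/``.hdf5`` path suffix. All writes use a fixed CSV dialect (comma,
header row, '.' decimal, 9 significant digits) so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cablesim import CableModel, ChannelSet, Compartment, CurrentInjection, StimulusProtocol
from .core import (
    ConfigurationError,
    DataError,
    ElectrodeArray,
    Electrode,
    LFPTrace,
    Point3,
    SegmentSource,
    SourceSet,
    make_grid,
)

FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------------------
# SWC morphology


def read_swc(path, default_channels: ChannelSet | None = None) -> CableModel:
    """Parse a standard 7-column SWC reconstruction into a compartment tree.

    Columns: id, type, x, y, z, radius, parent (um; diameter = 2*radius).
    Each non-root sample becomes a cylindrical compartment from its parent's
    coordinates to its own; a single-point soma sample becomes a spherical
    compartment. Coordinates are taken as-is (no recentering). Parse errors
    (non-numeric fields, duplicate ids, unknown parents) name the offending
    line. Compartments default to passive membrane unless ``default_channels``
    is given.
    """
    path = Path(path)
    channels = default_channels or ChannelSet.passive()
    rows: dict[int, tuple[float, float, float, float, int]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise DataError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
        try:
            sid = int(fields[0])
            x, y, z, radius = (float(v) for v in fields[2:6])
            parent = int(fields[6])
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        if sid in rows:
            raise DataError(f"{path}:{lineno}: duplicate sample id {sid}")
        if radius <= 0:
            raise DataError(f"{path}:{lineno}: radius must be > 0")
        rows[sid] = (x, y, z, radius, parent)
        order.append(sid)
    if not rows:
        raise DataError(f"{path}: no samples found")
    for sid in order:
        parent = rows[sid][4]
        if parent != -1 and parent not in rows:
            line_no = _swc_line_of(path, sid)
            raise DataError(f"{path}:{line_no}: sample {sid} references unknown parent {parent}")

    comps: list[Compartment] = []
    for sid in order:
        x, y, z, radius, parent = rows[sid]
        if parent == -1:
            half = radius
            comps.append(
                Compartment(
                    id=str(sid),
                    length=2 * radius,
                    diameter=2 * radius,
                    p0=Point3(x, y, z - half),
                    p1=Point3(x, y, z + half),
                    parent=None,
                    channels=channels,
                    spherical=True,
                )
            )
        else:
            px, py, pz, _, _ = rows[parent]
            p0 = Point3(px, py, pz)
            p1 = Point3(x, y, z)
            length = float(np.linalg.norm(p1.as_array() - p0.as_array()))
            if length == 0:
                raise DataError(
                    f"{path}:{_swc_line_of(path, sid)}: zero-length segment at sample {sid}"
                )
            comps.append(
                Compartment(
                    id=str(sid),
                    length=length,
                    diameter=2 * radius,
                    p0=p0,
                    p1=p1,
                    parent=str(parent),
                    channels=channels,
                )
            )
    return CableModel(comps)


def _swc_line_of(path: Path, sample_id: int) -> int:
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line and not line.startswith("#") and line.split()[0] == str(sample_id):
            return lineno
    return 0


# ---------------------------------------------------------------------------
# Currents table


def write_currents(sources: SourceSet, path) -> None:
    """Write a SourceSet to the interchange format (directory or HDF5)."""
    path = Path(path)
    geo = pd.DataFrame(
        {
            "id": [s.id for s in sources.segments],
            "x0": [s.p_start.x for s in sources.segments],
            "y0": [s.p_start.y for s in sources.segments],
            "z0": [s.p_start.z for s in sources.segments],
            "x1": [s.p_end.x for s in sources.segments],
            "y1": [s.p_end.y for s in sources.segments],
            "z1": [s.p_end.z for s in sources.segments],
            "diameter": [s.diameter for s in sources.segments],
            "spherical": [int(s.spherical) for s in sources.segments],
        }
    )
    if len(set(geo["id"])) != len(geo):
        raise DataError("segment ids must be unique to write a currents table")
    meta = {"dt_ms": sources.dt, "t0_ms": sources.t0, "units": "nA"}
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.attrs["dt_ms"] = sources.dt
            f.attrs["t0_ms"] = sources.t0
            f.attrs["units"] = "nA"
            f.create_dataset("currents", data=sources.currents)
            for col in geo.columns:
                data = geo[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                f.create_dataset(f"geometry/{col}", data=data)
        return
    path.mkdir(parents=True, exist_ok=True)
    geo.to_csv(path / "geometry.csv", index=False, float_format=FLOAT_FMT)
    cur = pd.DataFrame(sources.currents, columns=[f"t{k}" for k in range(sources.n_steps)])
    cur.insert(0, "id", geo["id"])
    cur.to_csv(path / "currents.csv", index=False, float_format=FLOAT_FMT)
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_currents(path) -> SourceSet:
    """Read a currents table written by :func:`write_currents`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            dt = float(f.attrs["dt_ms"])
            t0 = float(f.attrs["t0_ms"])
            currents = f["currents"][...]
            geo = {
                col: f[f"geometry/{col}"][...]
                for col in ("id", "x0", "y0", "z0", "x1", "y1", "z1", "diameter", "spherical")
            }
            ids = [v.decode() if isinstance(v, bytes) else str(v) for v in geo["id"]]
    else:
        if not path.is_dir():
            raise DataError(f"currents table not found: {path}")
        meta = json.loads((path / "meta.json").read_text())
        dt, t0 = float(meta["dt_ms"]), float(meta["t0_ms"])
        geo_df = pd.read_csv(path / "geometry.csv")
        cur_df = pd.read_csv(path / "currents.csv")
        if len(geo_df) != len(cur_df) or not np.array_equal(
            geo_df["id"].astype(str).to_numpy(), cur_df["id"].astype(str).to_numpy()
        ):
            raise DataError(f"{path}: geometry and currents rows disagree")
        currents = cur_df.drop(columns=["id"]).to_numpy(dtype=float)
        geo = {c: geo_df[c].to_numpy() for c in geo_df.columns}
        ids = [str(v) for v in geo["id"]]
    segments = [
        SegmentSource(
            ids[i],
            Point3(float(geo["x0"][i]), float(geo["y0"][i]), float(geo["z0"][i])),
            Point3(float(geo["x1"][i]), float(geo["y1"][i]), float(geo["z1"][i])),
            float(geo["diameter"][i]),
            spherical=bool(int(geo["spherical"][i])),
        )
        for i in range(len(ids))
    ]
    if currents.ndim != 2 or currents.shape[0] != len(segments):
        raise DataError(
            f"{path}: currents matrix has {currents.shape[0]} rows for {len(segments)} segments"
        )
    return SourceSet(segments, currents, dt, t0)


# ---------------------------------------------------------------------------
# Electrode and protocol configs


def read_electrodes(path) -> ElectrodeArray:
    """Electrode config JSON: explicit points or a grid specification.

    Either ``{"electrodes": [[x, y, z], ...]}`` (um) or
    ``{"grid": {"nx", "ny", "pitch_um", "plane", "origin"}}``.
    """
    cfg = json.loads(Path(path).read_text())
    if "electrodes" in cfg:
        pts = cfg["electrodes"]
        return ElectrodeArray(
            [Electrode(Point3.of(p), f"e{i}") for i, p in enumerate(pts)]
        )
    if "grid" in cfg:
        g = cfg["grid"]
        return make_grid(
            nx=int(g.get("nx", 4)),
            ny=int(g.get("ny", 4)),
            pitch=float(g.get("pitch_um", 100.0)),
            plane=g.get("plane", "xy"),
            origin=g.get("origin", (0.0, 0.0, 0.0)),
        )
    raise ConfigurationError(f"{path}: expected an 'electrodes' or 'grid' key")


def read_protocol(path, model: CableModel) -> StimulusProtocol:
    """Protocol file (JSON or YAML): current injections and spike trains.

    ``{"injections": [{"target", "amp_pA", "onset_ms", "dur_ms"}, ...],
    "spike_trains": [{"synapse": idx, "times_ms": [...]}, ...]}``
    """
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    injections = [
        CurrentInjection(
            target=str(inj["target"]),
            amp_pA=float(inj["amp_pA"]),
            onset=float(inj["onset_ms"]),
            dur=float(inj["dur_ms"]),
        )
        for inj in cfg.get("injections", [])
    ]
    trains: dict[int, list[float]] = {}
    for tr in cfg.get("spike_trains", []):
        idx = int(tr["synapse"])
        if not 0 <= idx < len(model.synapses):
            raise ConfigurationError(f"{path}: synapse index {idx} out of range")
        trains[idx] = [float(t) for t in tr["times_ms"]]
    return StimulusProtocol(injections=injections, spike_trains=trains)


# ---------------------------------------------------------------------------
# Trace output


def write_lfp_csv(trace: LFPTrace, path) -> None:
    """Write a trace as CSV: time_ms column plus one column per electrode."""
    trace.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FMT)


def write_amplitude_map_csv(trace: LFPTrace, array: ElectrodeArray, path) -> None:
    """Per-electrode peak magnitude (uV), with grid row/col when available."""
    peaks = np.abs(trace.values - trace.values[:, :1]).max(axis=1)
    df = pd.DataFrame({"label": trace.labels, "peak_uV": peaks})
    if array.grid is not None:
        nx = array.grid.nx
        df["row"] = [i // nx for i in range(len(array))]
        df["col"] = [i % nx for i in range(len(array))]
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
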