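"""Shared trajectory data model and on-disk formats.

Ion trajectories are held as dense per-frame arrays (``NaN`` marks frames
where an ion has no recorded position) and serialized to a tab-separated
table with a JSON metadata sidecar — a deliberately language-neutral,
diff-able format that any MD toolchain can emit.

Axis convention: z is the pore axis, z = 0 at the membrane center and
positive z pointing to the extracellular side; negative positions point
into the direction of the intracellular side.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["time_ns", "ion_id", "species", "valence", "x_A", "y_A", "z_A"]

#: Uniform-spacing tolerance for frame times, in ns.
TIME_TOL_NS = 1e-6


class TrajectoryFormatError(ValueError):
    """Raised when an on-disk trajectory violates the tabular contract."""


@dataclass
class TrajectoryMetadata:
    """Condition metadata carried alongside a set of ion tracks."""

    voltage_mV: float = 0.0
    temperature_K: float = 310.0
    label: str = ""
    replica: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.voltage_mV):
            raise ValueError("voltage_mV must be finite")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")


@dataclass
class PoreGeometry:
    """Axial positions of the two pore constrictions.

    ``z_sf`` is the upper (selectivity-filter) constriction and ``z_gate``
    the lower (intracellular-gate) constriction; the pore is the region
    between them. ``pore_radius`` bounds radial membership when lateral
    coordinates are available.
    """

    z_sf: float
    z_gate: float
    pore_radius: float = 8.0

    def __post_init__(self) -> None:
        if not self.z_gate < self.z_sf:
            raise ValueError(f"z_gate ({self.z_gate}) must lie below z_sf ({self.z_sf})")
        if self.pore_radius <= 0:
            raise ValueError("pore_radius must be positive")


@dataclass
class IonTracks:
    """Per-ion position time series on a common, uniformly spaced time grid.

    Attributes
    ----------
    times : (n_frames,) array, ns, strictly increasing, uniformly spaced.
    ion_ids : (n_ions,) int array of unique ion identifiers.
    species : list of species labels, one per ion.
    valences : (n_ions,) signed int array (elementary charges).
    z : (n_frames, n_ions) array of axial positions in Å; NaN = missing.
    x, y : optional lateral coordinates, same shape as z.
    box_length_z : periodic box length along z in Å (used when periodic).
    periodic : whether z is wrapped into the periodic box.
    """

    times: np.ndarray
    ion_ids: np.ndarray
    species: list[str]
    valences: np.ndarray
    z: np.ndarray
    x: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    box_length_z: float = 0.0
    periodic: bool = False
    meta: TrajectoryMetadata = field(default_factory=TrajectoryMetadata)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ion_ids = np.asarray(self.ion_ids, dtype=int)
        self.valences = np.asarray(self.valences, dtype=int)
        self.z = np.asarray(self.z, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.z.shape != (self.n_frames, self.n_ions):
            raise ValueError(f"z shape {self.z.shape} != (n_frames={self.n_frames}, n_ions={self.n_ions})")
        if len(self.species) != self.n_ions:
            raise ValueError("species list length mismatch")
        dt = np.diff(self.times)
        if self.n_frames > 1:
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if np.ptp(dt) > TIME_TOL_NS:
                raise ValueError("frame times must be uniformly spaced")
        if len(np.unique(self.ion_ids)) != self.n_ions:
            raise ValueError("ion_ids must be unique")
        if self.periodic and self.box_length_z <= 0:
            raise ValueError("periodic tracks need box_length_z > 0")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_ions(self) -> int:
        return len(self.ion_ids)

    @property
    def dt_ns(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need >= 2 frames for a time step")
        return float(self.times[1] - self.times[0])

    @property
    def t_total_ns(self) -> float:
        """Trajectory length: last minus first frame time."""
        return float(self.times[-1] - self.times[0])

    def has_xy(self) -> bool:
        return self.x is not None and self.y is not None

    def ion_index(self, ion_id: int) -> int:
        idx = np.flatnonzero(self.ion_ids == ion_id)
        if idx.size == 0:
            raise KeyError(f"unknown ion_id {ion_id}")
        return int(idx[0])

    def select_species(self, *names: str) -> "IonTracks":
        """Subset of tracks restricted to the given species labels."""
        keep = np.array([s in names for s in self.species], dtype=bool)
        return IonTracks(
            times=self.times,
            ion_ids=self.ion_ids[keep],
            species=[s for s, k in zip(self.species, keep) if k],
            valences=self.valences[keep],
            z=self.z[:, keep],
            x=None if self.x is None else self.x[:, keep],
            y=None if self.y is None else self.y[:, keep],
            box_length_z=self.box_length_z,
            periodic=self.periodic,
            meta=self.meta,
        )

    def unwrapped_z(self) -> np.ndarray:
        """All-ion unwrapped z array; identity when not periodic."""
        if not self.periodic:
            return self.z.copy()
        out = np.empty_like(self.z)
        for j in range(self.n_ions):
            out[:, j] = unwrap_z(self.z[:, j], self.box_length_z)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for j, ion in enumerate(self.ion_ids):
            ok = np.isfinite(self.z[:, j])
            df = pd.DataFrame(
                {
                    "time_ns": self.times[ok],
                    "ion_id": ion,
                    "species": self.species[j],
                    "valence": self.valences[j],
                    "x_A": self.x[ok, j] if self.x is not None else np.nan,
                    "y_A": self.y[ok, j] if self.y is not None else np.nan,
                    "z_A": self.z[ok, j],
                }
            )
            frames.append(df)
        return pd.concat(frames, ignore_index=True)[TRACK_COLUMNS]


def unwrap_z(z: np.ndarray, box_length_z: float) -> np.ndarray:
    """Remove periodic jumps from a wrapped 1-D coordinate series.

    Uses the minimum-image convention on successive displacements: each step
    is mapped into (-L/2, L/2]. A step whose true magnitude reached L/2
    is ambiguous and cannot be recovered; such steps are flagged with a
    warning rather than silently unwrapped.
    """
    z = np.asarray(z, dtype=float)
    if box_length_z <= 0:
        raise ValueError("box_length_z must be positive")
    if z.size < 2:
        return z.copy()
    dz = np.diff(z)
    shifted = dz - box_length_z * np.round(dz / box_length_z)
    ambiguous = np.isclose(np.abs(shifted), box_length_z / 2.0, atol=1e-9)
    if np.any(ambiguous):
        warnings.warn(
            f"{int(ambiguous.sum())} step(s) of exactly half the box length: "
            "unwrapping is ambiguous there",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.empty_like(z)
    out[0] = z[0]
    np.cumsum(shifted, out=out[1:])
    out[1:] += z[0]
    return out


def wrap_z(z: np.ndarray, box_length_z: float, z_min: float = None) -> np.ndarray:
    """Wrap a continuous coordinate into [z_min, z_min + L)."""
    z = np.asarray(z, dtype=float)
    if z_min is None:
        z_min = -box_length_z / 2.0
    return (z - z_min) % box_length_z + z_min


# ---------------------------------------------------------------------------
# On-disk format: TSV + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_tracks(tracks: IonTracks, path: str | Path) -> None:
    """Write tracks as TSV plus a ``<path>.json`` metadata sidecar."""
    path = Path(path)
    df = tracks.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    meta = {
        "box_length_z_A": tracks.box_length_z,
        "periodic": tracks.periodic,
        "voltage_mV": tracks.meta.voltage_mV,
        "temperature_K": tracks.meta.temperature_K,
        "label": tracks.meta.label,
        "replica": tracks.meta.replica,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_tracks(path: str | Path) -> IonTracks:
    """Read a TSV trajectory (with sidecar) back into :class:`IonTracks`.

    Rows may appear in any order; they are sorted by (ion, time). Duplicate
    (time, ion) rows and missing required columns are rejected with a
    diagnostic naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing required column(s) {missing}")
    dup = df.duplicated(subset=["time_ns", "ion_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise TrajectoryFormatError(
            f"{path}: duplicate record for ion {int(row.ion_id)} "
            f"at time {row.time_ns} ns (row {int(np.flatnonzero(dup.values)[0]) + 2})"
        )
    df = df.sort_values(["ion_id", "time_ns"], kind="mergesort")

    times = np.unique(df["time_ns"].to_numpy(dtype=float))
    t_index = {t: i for i, t in enumerate(times)}
    ion_ids = np.unique(df["ion_id"].to_numpy(dtype=int))
    n_f, n_i = len(times), len(ion_ids)
    z = np.full((n_f, n_i), np.nan)
    x = np.full((n_f, n_i), np.nan)
    y = np.full((n_f, n_i), np.nan)
    species = [""] * n_i
    valences = np.zeros(n_i, dtype=int)
    ion_index = {ion: j for j, ion in enumerate(ion_ids)}
    for ion, grp in df.groupby("ion_id", sort=False):
        j = ion_index[int(ion)]
        sp = grp["species"].unique()
        if len(sp) > 1:
            raise TrajectoryFormatError(f"{path}: ion {ion} has conflicting species {list(sp)}")
        species[j] = str(sp[0])
        valences[j] = int(grp["valence"].iloc[0])
        rows = [t_index[t] for t in grp["time_ns"].to_numpy(dtype=float)]
        z[rows, j] = grp["z_A"].to_numpy(dtype=float)
        x[rows, j] = grp["x_A"].to_numpy(dtype=float)
        y[rows, j] = grp["y_A"].to_numpy(dtype=float)

    sidecar = _sidecar_path(path)
    box, periodic, meta = 0.0, False, TrajectoryMetadata()
    if sidecar.exists():
        m = json.loads(sidecar.read_text())
        box = float(m.get("box_length_z_A", 0.0))
        periodic = bool(m.get("periodic", False))
        meta = TrajectoryMetadata(
            voltage_mV=float(m.get("voltage_mV", 0.0)),
            temperature_K=float(m.get("temperature_K", 310.0)),
            label=str(m.get("label", "")),
            replica=int(m.get("replica", 0)),
        )
    have_xy = np.isfinite(x).any() or np.isfinite(y).any()
    return IonTracks(
        times=times,
        ion_ids=ion_ids,
        species=species,
        valences=valences,
        z=z,
        x=x if have_xy else None,
        y=y if have_xy else None,
        box_length_z=box,
        periodic=periodic,
        meta=meta,
    )


def from_mdanalysis(
    universe,
    selection: str,
    species: str,
    valence: int,
    box_length_z: float = 0.0,
    periodic: bool = False,
    meta: Optional[TrajectoryMetadata] = None,
) -> IonTracks:
    """Adapter: build :class:`IonTracks` from an MDAnalysis Universe.

    Optional convenience — MDAnalysis is imported lazily and is not a core
    dependency. Positions are taken in Å as stored; time converted from ps
    to ns.
    """
    atoms = universe.select_atoms(selection)
    n_i = len(atoms)
    try:
        ids = np.asarray(atoms.ids, dtype=int)
    except Exception:  # topology without id records: fall back to indices
        ids = np.asarray(atoms.ix, dtype=int)
    times, zs, xs, ys = [], [], [], []
    for ts in universe.trajectory:
        times.append(ts.time / 1000.0)  # ps -> ns
        pos = atoms.positions
        xs.append(pos[:, 0].copy())
        ys.append(pos[:, 1].copy())
        zs.append(pos[:, 2].copy())
    return IonTracks(
        times=np.asarray(times),
        ion_ids=ids,
        species=[species] * n_i,
        valences=np.full(n_i, valence, dtype=int),
        z=np.asarray(zs),
        x=np.asarray(xs),
        y=np.asarray(ys),
        box_length_z=box_length_z,
        periodic=periodic,
        meta=meta or TrajectoryMetadata(),
    )


def concat_tracks(tracks_list: Sequence[IonTracks]) -> IonTracks:
    """Concatenate replicas in time, relabelling ion ids to stay unique.

    Replicas must share species composition and box; times are re-stamped
    onto one continuous uniform grid.
    """
    if not tracks_list:
        raise ValueError("nothing to concatenate")
    first = tracks_list[0]
    dt = first.dt_ns
    all_ids, all_species, all_val, blocks_z, blocks_x, blocks_y = [], [], [], [], [], []
    offset = 0
    total_frames = sum(t.n_frames for t in tracks_list)
    t0 = first.times[0]
    times = t0 + dt * np.arange(total_frames)
    row = 0
    have_xy = all(t.has_xy() for t in tracks_list)
    n_ions_total = sum(t.n_ions for t in tracks_list)
    Z = np.full((total_frames, n_ions_total), np.nan)
    X = np.full((total_frames, n_ions_total), np.nan) if have_xy else None
    Y = np.full((total_frames, n_ions_total), np.nan) if have_xy else None
    col = 0
    for t in tracks_list:
        Z[row : row + t.n_frames, col : col + t.n_ions] = t.z
        if have_xy:
            X[row : row + t.n_frames, col : col + t.n_ions] = t.x
            Y[row : row + t.n_frames, col : col + t.n_ions] = t.y
        all_ids.extend(int(i) + offset for i in t.ion_ids)
        all_species.extend(t.species)
        all_val.extend(int(v) for v in t.valences)
        offset = max(all_ids) + 1
        row += t.n_frames
        col += t.n_ions
    return IonTracks(
        times=times,
        ion_ids=np.asarray(all_ids),
        species=all_species,
        valences=np.asarray(all_val),
        z=Z,
        x=X,
        y=Y,
        box_length_z=first.box_length_z,
        periodic=first.periodic,
        meta=first.meta,
    )
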