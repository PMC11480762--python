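"""Permeation-event detection, conductance, and selectivity.

A permeation event is one complete traversal of the pore: an inward event
starts when the ion's continuous z-path crosses the selectivity-filter
plane (z_sf) downward and completes when it subsequently crosses the gate
plane (z_gate) downward without first returning above z_sf; the outward
rule is the mirror image. Conductance follows the event-counting relation

    C_ion = N_p * Q_ion / (t_traj * V_tm)

expressed in pS, with mean +/- SE estimated from overlapping 50-ns
windows. Selectivity between two carriers is the ratio of their total
event counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .trajectory import IonTracks, PoreGeometry
from .units import ELEMENTARY_CHARGE_C

INWARD = "inward"
OUTWARD = "outward"


@dataclass
class PermeationEvent:
    ion_id: int
    species: str
    valence: int
    direction: str  # inward = extracellular -> intracellular
    t_enter_ns: float  # last crossing of the entry plane before traversal
    t_exit_ns: float  # first crossing of the far plane

    def __post_init__(self) -> None:
        if not self.t_enter_ns < self.t_exit_ns:
            raise ValueError("t_enter must precede t_exit")
        if self.direction not in (INWARD, OUTWARD):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def signed_carriers(self) -> int:
        """Charge carriers moved, signed by direction (inward positive)."""
        sign = 1 if self.direction == INWARD else -1
        return sign * abs(self.valence)


@dataclass
class ConductanceEstimate:
    mean_pS: float
    se_pS: float
    n_events: int
    t_total_ns: float
    voltage_mV: float
    window_ns: float
    stride_ns: float


@dataclass
class SelectivityRatio:
    numerator_count: int
    denominator_count: int

    @property
    def ratio(self) -> float:
        """numerator/denominator; +inf when only the denominator is empty,
        NaN (undefined) for 0/0."""
        if self.denominator_count > 0:
            return self.numerator_count / self.denominator_count
        return math.inf if self.numerator_count > 0 else math.nan


def _crossing_steps(z: np.ndarray, plane: float, wrap_ok: np.ndarray):
    """Step indices where z crosses ``plane`` downward / upward.

    A position exactly on the plane counts as below it. Steps flagged as
    periodic wrap jumps never count as plane crossings.
    """
    above = z > plane
    down = above[:-1] & ~above[1:] & wrap_ok
    up = ~above[:-1] & above[1:] & wrap_ok
    return down, up


def detect_events(tracks: IonTracks, geometry: PoreGeometry) -> list[PermeationEvent]:
    """Detect complete pore traversals for every ion.

    Works directly on wrapped coordinates: a step larger than half the box
    is a periodic re-entry, not a plane crossing. When lateral coordinates
    are present, a crossing only counts if the ion lies within the pore
    radius at the arriving frame. Each traversal yields exactly one event;
    events are disjoint in time per ion.
    """
    zmin, zmax = np.nanmin(tracks.z), np.nanmax(tracks.z)
    sf_reachable = zmin <= geometry.z_sf <= zmax
    gate_reachable = zmin <= geometry.z_gate <= zmax
    if not (sf_reachable or gate_reachable):
        raise ValueError(
            f"geometry planes ({geometry.z_gate}, {geometry.z_sf}) outside "
            f"data z-range [{zmin:.1f}, {zmax:.1f}]"
        )
    events: list[PermeationEvent] = []
    half_box = tracks.box_length_z / 2.0 if tracks.periodic else np.inf
    times = tracks.times
    for j in range(tracks.n_ions):
        z = tracks.z[:, j]
        ok = np.isfinite(z[:-1]) & np.isfinite(z[1:])
        dz = np.abs(np.diff(z))
        wrap_ok = ok & (dz < half_box)
        if tracks.has_xy():
            r2 = tracks.x[:, j] ** 2 + tracks.y[:, j] ** 2
            wrap_ok &= np.nan_to_num(r2[1:]) <= geometry.pore_radius**2
        sf_down, sf_up = _crossing_steps(z, geometry.z_sf, wrap_ok)
        gate_down, gate_up = _crossing_steps(z, geometry.z_gate, wrap_ok)
        # merge the four crossing streams into one time-ordered sequence;
        # within a step the ion moves monotonically, so crossings are
        # processed in spatial order along the direction of motion
        steps = np.flatnonzero(sf_down | sf_up | gate_down | gate_up)
        armed_in = armed_out = False
        t_in = t_out = 0.0
        ion_id = int(tracks.ion_ids[j])
        species = tracks.species[j]
        valence = int(tracks.valences[j])
        for s in steps:
            t = float(times[s + 1])
            if sf_down[s] or gate_down[s]:  # downward motion: SF first
                if sf_down[s]:
                    armed_in = True
                    # crossing both planes in one step: enter at the frame
                    # before so t_enter < t_exit holds
                    t_in = float(times[s]) if gate_down[s] else t
                if gate_down[s]:
                    armed_out = False
                    if armed_in:
                        events.append(
                            PermeationEvent(
                                ion_id=ion_id,
                                species=species,
                                valence=valence,
                                direction=INWARD,
                                t_enter_ns=t_in,
                                t_exit_ns=t,
                            )
                        )
                        armed_in = False
            else:  # upward motion: gate first
                if gate_up[s]:
                    armed_out = True
                    t_out = float(times[s]) if sf_up[s] else t
                if sf_up[s]:
                    armed_in = False
                    if armed_out:
                        events.append(
                            PermeationEvent(
                                ion_id=ion_id,
                                species=species,
                                valence=valence,
                                direction=OUTWARD,
                                t_enter_ns=t_out,
                                t_exit_ns=t,
                            )
                        )
                        armed_out = False
    events.sort(key=lambda e: (e.t_exit_ns, e.ion_id))
    return events


def conductance_total(
    n_events: int,
    valence: int,
    t_total_ns: float,
    voltage_mV: float,
    signed: bool = False,
) -> float:
    """Event-counting conductance in pS.

    C = N_p * |q| e / (t * |V|); ``signed`` negates the value for carriers
    counted against the inward-cation convention (pass a negative
    ``n_events`` for outward/anion contributions in that case).
    """
    if t_total_ns <= 0:
        raise ValueError("t_total must be positive")
    if voltage_mV == 0:
        raise ValueError(
            "conductance is undefined at 0 mV; report the event count instead"
        )
    n = n_events if signed else abs(n_events)
    coulombs = n * abs(valence) * ELEMENTARY_CHARGE_C
    siemens = coulombs / (t_total_ns * 1e-9 * abs(voltage_mV) * 1e-3)
    return siemens * 1e12


def signed_carrier_count(events: Sequence[PermeationEvent]) -> float:
    """Net carriers moved with the inward convention (outward counts
    negative), summed over events — the N_p*|q| entering an overall,
    direction-aware conductance."""
    return float(sum(e.signed_carriers for e in events))


def conductance_windows(
    events: Sequence[PermeationEvent],
    t_total_ns: float,
    voltage_mV: float,
    window_ns: float = 50.0,
    stride_ns: float = 25.0,
    t_start_ns: float = 0.0,
    signed: bool = False,
) -> ConductanceEstimate:
    """Mean +/- SE conductance from overlapping windows.

    The event-counting relation is applied per window to events whose exit
    time falls inside it; the estimate is the mean and standard error over
    windows. With uniformly spaced events this equals the total-trajectory
    value up to one window's quantization.
    """
    if window_ns > t_total_ns:
        raise ValueError("window longer than the trajectory")
    if voltage_mV == 0:
        raise ValueError("conductance is undefined at 0 mV")
    starts = []
    s = t_start_ns
    while s + window_ns <= t_start_ns + t_total_ns + 1e-9:
        starts.append(s)
        s += stride_ns
    if not starts:
        raise ValueError("zero windows")
    t_exit = np.array([e.t_exit_ns for e in events])
    weight = np.array(
        [e.signed_carriers if signed else abs(e.valence) for e in events]
    )
    values = np.empty(len(starts))
    for i, s0 in enumerate(starts):
        in_w = (t_exit >= s0) & (t_exit < s0 + window_ns)
        carriers = weight[in_w].sum() if len(events) else 0.0
        values[i] = (
            carriers
            * ELEMENTARY_CHARGE_C
            / (window_ns * 1e-9 * abs(voltage_mV) * 1e-3)
            * 1e12
        )
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return ConductanceEstimate(
        mean_pS=mean,
        se_pS=se,
        n_events=len(events),
        t_total_ns=t_total_ns,
        voltage_mV=voltage_mV,
        window_ns=window_ns,
        stride_ns=stride_ns,
    )


def selectivity_ratio(
    events_a: Union[int, Sequence[PermeationEvent]],
    events_b: Union[int, Sequence[PermeationEvent]],
) -> SelectivityRatio:
    """Ratio of total permeation counts between two carriers (e.g. Na/Ca)."""
    n_a = events_a if isinstance(events_a, int) else len(events_a)
    n_b = events_b if isinstance(events_b, int) else len(events_b)
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be >= 0")
    return SelectivityRatio(numerator_count=n_a, denominator_count=n_b)


def write_events(events: Sequence[PermeationEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "ion_id": e.ion_id,
                "species": e.species,
                "valence": e.valence,
                "direction": e.direction,
                "t_enter_ns": e.t_enter_ns,
                "t_exit_ns": e.t_exit_ns,
            }
            for e in events
        ],
        columns=["ion_id", "species", "valence", "direction", "t_enter_ns", "t_exit_ns"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[PermeationEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        PermeationEvent(
            ion_id=int(r.ion_id),
            species=str(r.species),
            valence=int(r.valence),
            direction=str(r.direction),
            t_enter_ns=float(r.t_enter_ns),
            t_exit_ns=float(r.t_exit_ns),
        )
        for r in df.itertuples()
    ]
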