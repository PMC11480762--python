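"""Synthetic pore: Langevin ion trajectories and companion fixtures.

Generates every input the analysis pipeline consumes — overdamped
(Brownian) ion dynamics in a configurable 1-D pore energy landscape with a
voltage tilt, harmonically biased umbrella windows, coupled binding-site
occupancy series, and pseudo-water configurations — so every downstream
stage is testable without MD data.

Model: each ion follows the overdamped Langevin update

    z(t+dt) = z(t) - D dt d/dz[U(z) + q phi(z)] + sqrt(2 D dt) xi

with U the species potential in kBT, phi a linear voltage ramp (in kBT
per elementary charge) confined to the membrane span [z_gate, z_sf], q the
signed valence, and xi standard normal. z is periodic over the box. The
stationary distribution at zero voltage is Boltzmann in U; at non-zero
voltage the ramp drives a steady-state flux whose direction follows the
sign of q * V, and the voltage force on a divalent ion is exactly twice
that on a monovalent one. Ion-ion interaction reduces to an optional
hard-core exclusion inside the pore — enough to produce knock-on-like
occupancy coupling, with no electrostatics between mobile ions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .ssi import OccupancySeries, VACANT
from .trajectory import IonTracks, TrajectoryMetadata
from .units import DEFAULT_TEMPERATURE_K, voltage_mV_to_kBT_per_e
from .wham import (
    DEFAULT_SPACING_A,
    DEFAULT_SPRING_KJ_MOL_NM2,
    UmbrellaWindow,
    spring_kj_mol_nm2_to_kBT_A2,
)

PotentialFn = Callable[[np.ndarray], np.ndarray]


@dataclass
class SpeciesSpec:
    """One mobile species: label, signed valence, diffusion coefficient, count."""

    name: str
    valence: int
    diffusion_A2_per_ns: float
    count: int

    def __post_init__(self) -> None:
        if self.diffusion_A2_per_ns <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass
class PoreModel:
    """The 1-D pore environment the Langevin generator samples from.

    ``potential`` is either a single callable U(z) in kBT or a mapping
    from species name to callable (species-dependent landscapes). The
    transmembrane voltage drops linearly over ``[z_gate, z_sf]``; negative
    voltage means the intracellular (low-z) side is negative, driving
    cations inward (toward decreasing z).
    """

    potential: Union[PotentialFn, dict]
    species: list[SpeciesSpec]
    z_min: float = -30.0
    z_max: float = 30.0
    z_gate: float = -15.0
    z_sf: float = 10.0
    voltage_mV: float = 0.0
    temperature_K: float = DEFAULT_TEMPERATURE_K
    pore_radius: float = 8.0
    generate_xy: bool = False

    def __post_init__(self) -> None:
        if not (self.z_min < self.z_gate < self.z_sf < self.z_max):
            raise ValueError("need z_min < z_gate < z_sf < z_max")

    @property
    def box_length_z(self) -> float:
        return self.z_max - self.z_min

    def potential_for(self, name: str) -> PotentialFn:
        if isinstance(self.potential, dict):
            return self.potential[name]
        return self.potential

    def voltage_energy_kBT(self, z: np.ndarray, valence: float) -> np.ndarray:
        """Electrostatic energy q*phi(z) in kBT for a given valence."""
        v = voltage_mV_to_kBT_per_e(self.voltage_mV, self.temperature_K)
        frac = np.clip((self.z_sf - np.asarray(z)) / (self.z_sf - self.z_gate), 0.0, 1.0)
        return valence * v * frac


@dataclass
class SimSpec:
    """Numerical parameters of one Langevin run."""

    dt_ns: float = 0.001
    n_steps: int = 10_000
    save_stride: int = 1
    seed: int = 0
    exclusion_A: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")


def _numeric_grad(fn: PotentialFn, z: np.ndarray, h: float = 1e-4) -> np.ndarray:
    return (fn(z + h) - fn(z - h)) / (2.0 * h)


def simulate_ions(model: PoreModel, spec: SimSpec) -> IonTracks:
    """Run overdamped Langevin dynamics for every ion in the model.

    Returns wrapped, periodic tracks on a uniform grid of saved frames.
    Identical (model, spec) inputs produce bit-identical output. A
    non-finite force aborts with a diagnostic naming the position, since it
    indicates a mis-specified potential.
    """
    rng = np.random.default_rng(spec.seed)
    names, valences, Ds, pots = [], [], [], []
    for sp in model.species:
        pot = model.potential_for(sp.name)
        for _ in range(sp.count):
            names.append(sp.name)
            valences.append(sp.valence)
            Ds.append(sp.diffusion_A2_per_ns)
            pots.append(pot)
    n_ions = len(names)
    if n_ions == 0:
        raise ValueError("model contains no ions")
    valence_arr = np.asarray(valences, dtype=float)
    D = np.asarray(Ds, dtype=float)
    L = model.box_length_z
    z0, z1 = model.z_min, model.z_max
    gate, sf = model.z_gate, model.z_sf
    v_kBT = voltage_mV_to_kBT_per_e(model.voltage_mV, model.temperature_K)
    ramp_slope = v_kBT / (sf - gate)  # d(phi)/dz per unit charge, kBT/A

    # group ions by shared potential so gradients vectorize per group
    groups: dict[int, list[int]] = {}
    group_pot: dict[int, PotentialFn] = {}
    for i, p in enumerate(pots):
        groups.setdefault(id(p), []).append(i)
        group_pot[id(p)] = p

    z = rng.uniform(z0, z1, size=n_ions)
    if spec.exclusion_A is not None and n_ions > 1:
        # start from a configuration that already satisfies the hard core
        for _ in range(1000):
            bad = _exclusion_violators(z, gate, sf, spec.exclusion_A)
            if not bad.size:
                break
            z[bad] = rng.uniform(z0, z1, size=bad.size)
        else:
            raise RuntimeError("could not place ions with the requested exclusion")
    n_saved = spec.n_steps // spec.save_stride + 1
    Z = np.empty((n_saved, n_ions))
    Z[0] = z
    if model.generate_xy:
        R = model.pore_radius
        xy = rng.uniform(-R, R, size=(n_ions, 2))
        XY = np.empty((n_saved, n_ions, 2))
        XY[0] = xy
    row = 1
    sqrt_term = np.sqrt(2.0 * D * spec.dt_ns)
    Ddt = D * spec.dt_ns
    force = np.empty(n_ions)
    for step in range(1, spec.n_steps + 1):
        for key, idx in groups.items():
            force[idx] = -_numeric_grad(group_pot[key], z[idx])
        # voltage ramp force only inside the membrane span
        in_span = (z > gate) & (z < sf)
        force += np.where(in_span, valence_arr * ramp_slope, 0.0)
        if not np.all(np.isfinite(force)):
            bad = int(np.flatnonzero(~np.isfinite(force))[0])
            raise RuntimeError(
                f"non-finite force on ion {bad} at z = {z[bad]:.3f} A "
                "(potential mis-specified?)"
            )
        z_new = z + Ddt * force + sqrt_term * rng.standard_normal(n_ions)
        z_new = (z_new - z0) % L + z0
        if spec.exclusion_A is not None and n_ions > 1:
            z_new = _apply_exclusion(z, z_new, gate, sf, spec.exclusion_A)
        z = z_new
        if model.generate_xy:
            xy = xy + np.sqrt(2.0 * D * spec.dt_ns)[:, None] * rng.standard_normal((n_ions, 2))
            r = np.hypot(xy[:, 0], xy[:, 1])
            over = r > R
            if np.any(over):  # reflect back inside the cylinder
                scale = (2 * R - r[over]) / r[over]
                xy[over] *= scale[:, None]
        if step % spec.save_stride == 0:
            Z[row] = z
            if model.generate_xy:
                XY[row] = xy
            row += 1
    times = spec.dt_ns * spec.save_stride * np.arange(n_saved)
    return IonTracks(
        times=times,
        ion_ids=np.arange(n_ions),
        species=names,
        valences=np.asarray(valences, dtype=int),
        z=Z,
        x=XY[:, :, 0] if model.generate_xy else None,
        y=XY[:, :, 1] if model.generate_xy else None,
        box_length_z=L,
        periodic=True,
        meta=TrajectoryMetadata(
            voltage_mV=model.voltage_mV, temperature_K=model.temperature_K
        ),
    )


def _violating_pairs(z, gate, sf, d_min):
    """In-pore neighbor pairs closer than d_min, as (i, j) index tuples."""
    in_pore = (z >= gate) & (z <= sf)
    idx = np.flatnonzero(in_pore)
    if idx.size < 2:
        return []
    order = idx[np.argsort(z[idx], kind="stable")]
    return [
        (int(a), int(b))
        for a, b in zip(order[:-1], order[1:])
        if abs(z[b] - z[a]) < d_min
    ]


def _exclusion_violators(z, gate, sf, d_min):
    """Higher-index members of violating pairs (used for initial placement)."""
    bad = {max(a, b) for a, b in _violating_pairs(z, gate, sf, d_min)}
    return np.asarray(sorted(bad), dtype=int)


def _apply_exclusion(z_old, z_new, gate, sf, d_min):
    """Single-file hard core inside the pore: revert moves that land two
    ions closer than d_min between the constrictions. Within a violating
    pair the moved ion yields (higher index first), and reversion repeats
    until a fixed point — one exists because the previous configuration is
    valid, so reverting every mover always resolves a pair."""
    z_new = z_new.copy()
    for _ in range(len(z_new)):
        pairs = _violating_pairs(z_new, gate, sf, d_min)
        if not pairs:
            break
        progress = False
        for a, b in pairs:
            for i in sorted((a, b), reverse=True):
                if z_new[i] != z_old[i]:
                    z_new[i] = z_old[i]
                    progress = True
                    break
        if not progress:
            break
    return z_new


# ---------------------------------------------------------------------------
# Umbrella-window generator
# ---------------------------------------------------------------------------

def make_umbrella_dataset(
    potential: PotentialFn,
    k_spring: float = DEFAULT_SPRING_KJ_MOL_NM2,
    spacing_A: float = DEFAULT_SPACING_A,
    range_A: tuple[float, float] = (-10.0, 10.0),
    n_samples: int = 1000,
    seed: int = 0,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> list[UmbrellaWindow]:
    """Biased samples for a ladder of harmonic umbrella windows.

    Window centers are spaced arithmetically by ``spacing_A`` over
    ``range_A``; each window draws ``n_samples`` i.i.d. points from the
    biased Boltzmann density exp(-[U(z) + k/2 (z-z_c)^2]/kBT) by
    inverse-CDF sampling on a fine grid. A spring too weak for adjacent
    windows to overlap (bias sigma < spacing/4) is recorded as a warning
    flag in the window metadata, not silently accepted.
    """
    lo, hi = range_A
    if spacing_A <= 0:
        raise ValueError("spacing must be positive")
    centers = np.arange(lo, hi + 0.5 * spacing_A, spacing_A)
    if centers.size < 2:
        raise ValueError("range must cover at least 2 windows")
    k_kBT = spring_kj_mol_nm2_to_kBT_A2(k_spring, temperature_K)
    sigma_bias = np.sqrt(1.0 / k_kBT) if k_kBT > 0 else np.inf
    weak = sigma_bias * 4.0 < spacing_A
    rng = np.random.default_rng(seed)
    pad = 6.0 * sigma_bias if np.isfinite(sigma_bias) else (hi - lo)
    windows = []
    for c in centers:
        grid = np.linspace(c - pad, c + pad, 4001)
        logw = -(potential(grid) + 0.5 * k_kBT * (grid - c) ** 2)
        logw -= logw.max()
        w = np.exp(logw)
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        u = rng.uniform(size=n_samples)
        samples = np.interp(u, cdf, grid)
        meta = {"spacing_A": spacing_A, "seed": seed}
        if weak:
            meta["warning"] = "spring too weak for window overlap at this spacing"
        windows.append(
            UmbrellaWindow(
                center_A=float(c),
                k_spring=k_spring,
                samples_A=samples,
                temperature_K=temperature_K,
                meta=meta,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# Coupled occupancy generator (knock-on fixture)
# ---------------------------------------------------------------------------

def make_coupled_occupancy(
    p_occ: float = 0.5,
    coupling: float = 0.0,
    n_frames: int = 10_000,
    dt_ps: float = 20.0,
    seed: int = 0,
    flip_rate: float = 0.1,
) -> tuple[OccupancySeries, OccupancySeries]:
    """Two binding-site occupancy series with tunable transition coupling.

    Each site is a two-state (occupied/vacant) Markov chain with stationary
    occupancy ``p_occ`` and per-frame transition propensity set by
    ``flip_rate``. At ``coupling = 0`` the chains are independent; at
    ``coupling = 1`` every occupancy transition at site A is mirrored at
    site B in the same frame; intermediate values interpolate the
    per-frame mirroring probability. Occupant ids are drawn from a shared
    counter; vacancy is the sentinel -1.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    if not 0.0 < p_occ < 1.0:
        raise ValueError("p_occ must lie strictly inside (0, 1)")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    # two-state chain: P(vac->occ) = r*p, P(occ->vac) = r*(1-p) has
    # stationary occupancy p for any rate scale r.
    p_bind = flip_rate * p_occ
    p_release = flip_rate * (1.0 - p_occ)

    ids_a = np.empty(n_frames, dtype=int)
    ids_b = np.empty(n_frames, dtype=int)
    next_id = 0
    occ_a = rng.uniform() < p_occ
    occ_b = rng.uniform() < p_occ
    cur_a = cur_b = VACANT
    if occ_a:
        cur_a, next_id = next_id, next_id + 1
    if occ_b:
        cur_b, next_id = next_id, next_id + 1
    ids_a[0], ids_b[0] = cur_a, cur_b
    for t in range(1, n_frames):
        # site A evolves freely
        toggled_a = rng.uniform() < (p_bind if cur_a == VACANT else p_release)
        if toggled_a:
            if cur_a == VACANT:
                cur_a, next_id = next_id, next_id + 1
            else:
                cur_a = VACANT
        # site B mirrors A's toggle with probability `coupling`,
        # otherwise takes its own Markov step
        if rng.uniform() < coupling:
            toggled_b = toggled_a
        else:
            toggled_b = rng.uniform() < (p_bind if cur_b == VACANT else p_release)
        if toggled_b:
            if cur_b == VACANT:
                cur_b, next_id = next_id, next_id + 1
            else:
                cur_b = VACANT
        ids_a[t], ids_b[t] = cur_a, cur_b
    return (
        OccupancySeries(ids=ids_a, dt_ps=dt_ps, site_label="A"),
        OccupancySeries(ids=ids_b, dt_ps=dt_ps, site_label="B"),
    )


# ---------------------------------------------------------------------------
# Pseudo-water generator (solvation fixture)
# ---------------------------------------------------------------------------

def make_waters(
    ion_positions: np.ndarray,
    mean_count,
    placement_radius: float,
    seed: int = 0,
    n_background: int = 0,
    background_box: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Place pseudo-waters around ions with a z-dependent mean shell count.

    For each ion, ``Poisson(mean_count(z_ion))`` waters are placed uniformly
    inside a sphere of ``placement_radius``; optional background waters are
    scattered uniformly in a bounding box. Returns ``(waters, truth)``
    where ``truth[i]`` is the number of waters generated for ion i — the
    ground-truth first-shell count for oracle tests.
    """
    ion_positions = np.atleast_2d(np.asarray(ion_positions, dtype=float))
    if callable(mean_count):
        mu = np.array([mean_count(p[2]) for p in ion_positions], dtype=float)
    else:
        mu = np.full(len(ion_positions), float(mean_count))
    if np.any(mu < 0):
        raise ValueError("mean_count must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mu)
    waters = []
    for pos, n in zip(ion_positions, counts):
        if n == 0:
            continue
        direction = rng.standard_normal((n, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        r = placement_radius * rng.uniform(size=n) ** (1.0 / 3.0)
        waters.append(pos + direction * r[:, None])
    if n_background > 0:
        lo, hi = background_box if background_box is not None else (-50.0, 50.0)
        waters.append(rng.uniform(lo, hi, size=(n_background, 3)))
    if waters:
        waters = np.vstack(waters)
    else:
        waters = np.empty((0, 3))
    return waters, counts


# ---------------------------------------------------------------------------
# Reference landscapes
# ---------------------------------------------------------------------------

def gaussian_feature(center: float, height_kBT: float, width_A: float) -> PotentialFn:
    """A single Gaussian well (height < 0) or barrier (height > 0)."""

    def U(z):
        return height_kBT * np.exp(-0.5 * ((np.asarray(z, dtype=float) - center) / width_A) ** 2)

    return U


def sum_potential(*features: PotentialFn) -> PotentialFn:
    def U(z):
        z = np.asarray(z, dtype=float)
        total = np.zeros_like(z)
        for f in features:
            total = total + f(z)
        return total

    return U


def channel_landscapes(
    epv_z: float = 14.0,
    cavity_z: float = -3.0,
    funnel_z: float = 5.0,
    gate_z: float = -15.0,
    mono_well_kBT: float = 1.5,
    di_funnel_barrier_kBT: float = 4.0,
    gate_barrier_kBT: float = 1.5,
) -> dict:
    """Species-dependent pore landscapes mimicking a monovalent-selective
    channel: monovalent ions see shallow wells at the outer vestibule and
    the central cavity with a modest gate barrier; divalent ions see the
    vestibule well but a hydrophobic-funnel barrier at the cavity entrance
    and a raised gate barrier, so they dwell above the filter instead of
    in the cavity.
    """
    mono = sum_potential(
        gaussian_feature(epv_z, -mono_well_kBT, 2.5),
        gaussian_feature(cavity_z, -mono_well_kBT, 3.5),
        gaussian_feature(gate_z, gate_barrier_kBT, 2.0),
    )
    di = sum_potential(
        gaussian_feature(epv_z, -2.0, 2.5),
        gaussian_feature(funnel_z, di_funnel_barrier_kBT, 2.5),
        gaussian_feature(gate_z, gate_barrier_kBT + 1.0, 2.0),
    )
    return {"mono": mono, "di": di}
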