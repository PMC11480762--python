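"""Ion density, energy, binding-site, and solvation-shell profiles.

Axial densities are per-frame position histograms along the pore axis.
Their negative logarithm — after Gaussian smoothing of the counts — is an
estimate of the (nonequilibrium) energy surface in kBT, gauged so the
global minimum is zero; minima mark binding sites and maxima barriers.
Solvation profiles count first-shell waters within species-specific radii
(defaults: Na+ 3.1 Å, K+ 3.5 Å, Ca2+ 3.0 Å) and report the per-z-bin
mean, again Gaussian-smoothed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from .permeation import detect_events
from .trajectory import IonTracks, PoreGeometry

DEFAULT_SHELL_RADII_A = {"Na": 3.1, "K": 3.5, "Ca": 3.0}


@dataclass
class DensityProfile:
    edges_A: np.ndarray
    counts: np.ndarray
    species: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.edges_A = np.asarray(self.edges_A, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.edges_A) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.counts.shape != (self.edges_A.size - 1,):
            raise ValueError("counts/edges shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def centers_A(self) -> np.ndarray:
        return 0.5 * (self.edges_A[:-1] + self.edges_A[1:])


@dataclass
class EnergyProfile:
    """-log density in kBT with min = 0 on sampled bins; unsampled masked."""

    z_A: np.ndarray
    energy_kBT: np.ndarray
    mask: np.ndarray  # True where the bin is unsampled
    sigma_bins: float = 2.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.energy_kBT[~self.mask])):
            raise ValueError("energy must be finite on unmasked bins")


@dataclass
class SolvationSpec:
    """First-solvation-shell radii per species, Å."""

    radii_A: dict = field(default_factory=lambda: dict(DEFAULT_SHELL_RADII_A))

    def __post_init__(self) -> None:
        for name, r in self.radii_A.items():
            if r <= 0:
                raise ValueError(f"radius for {name} must be positive")

    def radius_for(self, species: str) -> float:
        return self.radii_A[species]


@dataclass
class DensityGrid3D:
    origin_A: np.ndarray
    spacing_A: float
    counts: np.ndarray  # (nx, ny, nz)
    mask_radius_A: float = 10.0

    def __post_init__(self) -> None:
        if self.spacing_A <= 0:
            raise ValueError("spacing must be positive")


def axial_density(
    tracks: IonTracks,
    z_range: tuple[float, float],
    bin_width_A: float = 0.5,
    species_filter: Optional[str] = None,
    permeants_only: bool = False,
    geometry: Optional[PoreGeometry] = None,
) -> DensityProfile:
    """Histogram of per-frame axial positions.

    With ``permeants_only`` (requires ``geometry``), only ions that
    complete at least one pore traversal are retained. Total counts equal
    the number of retained (frame, ion) pairs inside the range.
    """
    if bin_width_A <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = z_range
    n_bins = max(int(np.ceil((hi - lo) / bin_width_A)), 1)
    edges = lo + bin_width_A * np.arange(n_bins + 1)
    keep = np.ones(tracks.n_ions, dtype=bool)
    if species_filter is not None:
        keep &= np.array([s == species_filter for s in tracks.species])
    if permeants_only:
        if geometry is None:
            raise ValueError("permeants_only requires a PoreGeometry")
        permeant_ids = {e.ion_id for e in detect_events(tracks, geometry)}
        keep &= np.array([int(i) in permeant_ids for i in tracks.ion_ids])
    z = tracks.z[:, keep].ravel()
    z = z[np.isfinite(z)]
    if z.size == 0:
        warnings.warn("empty selection: density profile has no samples",
                      RuntimeWarning, stacklevel=2)
    counts, _ = np.histogram(z, bins=edges)
    return DensityProfile(
        edges_A=edges,
        counts=counts.astype(float),
        species=species_filter or "all",
    )


def neg_log_density(profile: DensityProfile, sigma_bins: float = 2.0) -> EnergyProfile:
    """Negative-log-density energy estimate in kBT.

    Counts are Gaussian-smoothed (sigma in bins), then E = -ln(count),
    gauged so the sampled minimum is zero. Zero-count bins are masked, not
    pseudo-counted. Invariant under a global rescaling of the counts.
    """
    if np.all(profile.counts == 0):
        raise ValueError("all-zero density profile: no energy estimate possible")
    if sigma_bins > 0:
        smoothed = gaussian_filter1d(profile.counts, sigma=sigma_bins, mode="nearest")
    else:
        smoothed = profile.counts.astype(float)
    mask = smoothed <= 0
    energy = np.full_like(smoothed, np.nan)
    energy[~mask] = -np.log(smoothed[~mask])
    energy[~mask] -= np.nanmin(energy[~mask])
    return EnergyProfile(
        z_A=profile.centers_A, energy_kBT=energy, mask=mask, sigma_bins=sigma_bins
    )


def find_binding_sites(
    energy: EnergyProfile, min_depth_kBT: float = 0.5
) -> list[tuple[float, float, float]]:
    """Locate binding sites as minima of the energy profile.

    A site is a local minimum whose depth relative to the lower of its two
    flanking maxima exceeds ``min_depth_kBT``. Returns (z_min, depth,
    extent) triplets sorted by z, the extent being the z-span over which
    the profile stays within ``min_depth`` of the minimum.
    """
    z = energy.z_A[~energy.mask]
    e = energy.energy_kBT[~energy.mask]
    if e.size < 3:
        return []
    sites = []
    for i in range(1, e.size - 1):
        if not (e[i] <= e[i - 1] and e[i] <= e[i + 1]):
            continue
        if e[i] == e[i + 1]:  # plateau: take the left edge only
            continue
        # flanking maxima: highest point reached before the profile drops
        # below this minimum again on either side
        left_max = e[i]
        for k in range(i - 1, -1, -1):
            left_max = max(left_max, e[k])
            if e[k] < e[i]:
                break
        right_max = e[i]
        for k in range(i + 1, e.size):
            right_max = max(right_max, e[k])
            if e[k] < e[i]:
                break
        depth = min(left_max, right_max) - e[i]
        if depth > min_depth_kBT:
            # contiguous run of bins within min_depth of the minimum
            run = [i]
            k = i - 1
            while k >= 0 and e[k] <= e[i] + min_depth_kBT:
                run.append(k)
                k -= 1
            k = i + 1
            while k < e.size and e[k] <= e[i] + min_depth_kBT:
                run.append(k)
                k += 1
            extent = float(z[max(run)] - z[min(run)])
            sites.append((float(z[i]), float(depth), extent))
    sites.sort(key=lambda s: s[0])
    return sites


def density_grid_3d(
    positions: np.ndarray,
    spacing_A: float = 1.0,
    reference_points: Optional[np.ndarray] = None,
    mask_radius_A: float = 10.0,
) -> DensityGrid3D:
    """Voxel counts of cation positions near a reference point set.

    Only positions within ``mask_radius_A`` of any reference point (e.g. a
    protein surface, or the pore cylinder for synthetic runs) are binned.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[1] != 3:
        raise ValueError("positions must be (n, 3)")
    if reference_points is not None and len(positions):
        tree = cKDTree(np.atleast_2d(reference_points))
        d, _ = tree.query(positions)
        positions = positions[d <= mask_radius_A]
    if len(positions) == 0:
        warnings.warn("no positions within the mask: empty 3D grid",
                      RuntimeWarning, stacklevel=2)
        return DensityGrid3D(
            origin_A=np.zeros(3),
            spacing_A=spacing_A,
            counts=np.zeros((1, 1, 1)),
            mask_radius_A=mask_radius_A,
        )
    lo = positions.min(axis=0)
    hi = positions.max(axis=0)
    n = np.maximum(np.ceil((hi - lo) / spacing_A).astype(int), 1)
    edges = [lo[d] + spacing_A * np.arange(n[d] + 1) for d in range(3)]
    for d in range(3):  # make sure the top edge covers the max
        if edges[d][-1] < hi[d]:
            edges[d] = np.append(edges[d], edges[d][-1] + spacing_A)
    counts, _ = np.histogramdd(positions, bins=edges)
    return DensityGrid3D(
        origin_A=lo, spacing_A=spacing_A, counts=counts, mask_radius_A=mask_radius_A
    )


def first_shell_count(
    ion_position: np.ndarray, water_positions: np.ndarray, radius_A: float
) -> int:
    """Number of waters within ``radius_A`` of the ion (boundary inclusive)."""
    if radius_A <= 0:
        raise ValueError("radius must be positive")
    water_positions = np.atleast_2d(np.asarray(water_positions, dtype=float))
    if water_positions.size == 0:
        return 0
    d = np.linalg.norm(water_positions - np.asarray(ion_position, dtype=float), axis=1)
    return int(np.sum(d <= radius_A))


def solvation_profile(
    tracks: IonTracks,
    waters_per_frame: Sequence[np.ndarray],
    spec: SolvationSpec,
    z_range: tuple[float, float],
    bin_width_A: float = 0.5,
    sigma_bins: float = 2.0,
    species_filter: Optional[str] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean first-shell water count vs z, Gaussian-smoothed.

    ``waters_per_frame`` holds one (n_waters, 3) array per frame. Requires
    lateral coordinates on the tracks. Returns (bin centers, smoothed mean
    count, mask) where the mask flags bins no ion visited; smoothing runs
    over the sampled bins only.
    """
    if not tracks.has_xy():
        raise ValueError("solvation profiles need 3-D ion coordinates")
    if len(waters_per_frame) != tracks.n_frames:
        raise ValueError("need one water configuration per frame")
    lo, hi = z_range
    n_bins = max(int(np.ceil((hi - lo) / bin_width_A)), 1)
    edges = lo + bin_width_A * np.arange(n_bins + 1)
    sums = np.zeros(n_bins)
    visits = np.zeros(n_bins)
    for f in range(tracks.n_frames):
        waters = np.atleast_2d(np.asarray(waters_per_frame[f], dtype=float))
        for j in range(tracks.n_ions):
            if species_filter is not None and tracks.species[j] != species_filter:
                continue
            zj = tracks.z[f, j]
            if not np.isfinite(zj) or not (lo <= zj < edges[-1]):
                continue
            pos = np.array([tracks.x[f, j], tracks.y[f, j], zj])
            radius = spec.radius_for(tracks.species[j])
            b = min(int((zj - lo) / bin_width_A), n_bins - 1)
            if waters.size:
                sums[b] += first_shell_count(pos, waters, radius)
            visits[b] += 1
    mask = visits == 0
    mean = np.full(n_bins, np.nan)
    mean[~mask] = sums[~mask] / visits[~mask]
    smoothed = mean.copy()
    if sigma_bins > 0 and (~mask).sum() > 1:
        smoothed[~mask] = gaussian_filter1d(mean[~mask], sigma=sigma_bins, mode="nearest")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, smoothed, mask


def write_profile_tsv(z: np.ndarray, value: np.ndarray, mask: np.ndarray, path: str | Path) -> None:
    out = np.column_stack([z, np.where(mask, np.nan, value), mask.astype(int)])
    np.savetxt(path, out, delimiter="\t", header="z_A\tvalue\tmasked", comments="", fmt="%.6f")


def write_dx(grid: DensityGrid3D, path: str | Path) -> None:
    """Export a 3-D density grid as an OpenDX scalar field (text)."""
    nx, ny, nz = grid.counts.shape
    o = grid.origin_A
    d = grid.spacing_A
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {o[0]:.4f} {o[1]:.4f} {o[2]:.4f}",
        f"delta {d:.4f} 0 0",
        f"delta 0 {d:.4f} 0",
        f"delta 0 0 {d:.4f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.counts.ravel(order="C")
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.6g}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    Path(path).write_text("\n".join(lines) + "\n")
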