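"""Density, energy, binding-site, 3-D grid, and solvation analyses."""

import numpy as np
import pytest

from permeon import (
    IonTracks,
    PoreGeometry,
    SolvationSpec,
    axial_density,
    density_grid_3d,
    find_binding_sites,
    first_shell_count,
    make_waters,
    neg_log_density,
    solvation_profile,
)
from permeon.profiles import DensityProfile, EnergyProfile, write_dx


def stationary_tracks(z_values, species=None, with_xy=False):
    z = np.tile(np.asarray(z_values, dtype=float), (10, 1))
    n = z.shape[1]
    kw = dict(x=np.zeros_like(z), y=np.zeros_like(z)) if with_xy else {}
    return IonTracks(
        times=0.02 * np.arange(10),
        ion_ids=np.arange(n),
        species=species or ["Na"] * n,
        valences=np.ones(n, dtype=int),
        z=z,
        **kw,
    )


class TestAxialDensity:
    def test_stationary_ion_single_bin(self):
        t = stationary_tracks([3.1])
        prof = axial_density(t, (-10, 10), bin_width_A=0.5)
        assert prof.counts.sum() == 10
        assert np.count_nonzero(prof.counts) == 1

    def test_counts_equal_bruteforce_tally(self, rng):
        z = rng.uniform(-10, 10, size=(50, 4))
        t = IonTracks(
            times=0.02 * np.arange(50),
            ion_ids=np.arange(4),
            species=["Na"] * 4,
            valences=np.ones(4, dtype=int),
            z=z,
        )
        prof = axial_density(t, (-10, 10), bin_width_A=1.0)
        brute = np.zeros(20)
        for f in range(50):
            for j in range(4):
                b = int((z[f, j] + 10) // 1.0)
                brute[min(b, 19)] += 1
        assert np.array_equal(prof.counts, brute)
        assert prof.counts.sum() == 200

    def test_species_filter(self):
        t = stationary_tracks([1.0, 5.0], species=["Na", "Ca"])
        prof = axial_density(t, (-10, 10), species_filter="Ca")
        assert prof.counts.sum() == 10

    def test_permeants_only_drops_non_traversing_ions(self):
        # one ion traverses fully, one stays put
        traverser = np.linspace(20, -20, 50)
        sitter = np.full(50, 2.0)
        t = IonTracks(
            times=0.02 * np.arange(50),
            ion_ids=np.array([0, 1]),
            species=["Na", "Na"],
            valences=np.ones(2, dtype=int),
            z=np.column_stack([traverser, sitter]),
        )
        geom = PoreGeometry(z_sf=10.0, z_gate=-10.0)
        prof = axial_density(t, (-20, 20), permeants_only=True, geometry=geom)
        assert prof.counts.sum() == 50  # only the traverser's frames

    def test_empty_selection_warns(self):
        t = stationary_tracks([1.0])
        with pytest.warns(RuntimeWarning, match="empty selection"):
            axial_density(t, (-10, 10), species_filter="K")


class TestNegLogDensity:
    def test_uniform_profile_flat_zero(self):
        prof = DensityProfile(edges_A=np.arange(0, 11.0), counts=np.full(10, 50.0))
        e = neg_log_density(prof)
        assert np.allclose(e.energy_kBT, 0.0)

    def test_gauge_invariance_under_count_scaling(self, rng):
        counts = rng.integers(1, 1000, size=40).astype(float)
        prof1 = DensityProfile(edges_A=np.arange(41.0), counts=counts)
        prof2 = DensityProfile(edges_A=np.arange(41.0), counts=counts * 10)
        e1 = neg_log_density(prof1)
        e2 = neg_log_density(prof2)
        assert np.allclose(e1.energy_kBT, e2.energy_kBT)

    def test_zero_count_bins_masked_not_neglog_zero(self):
        counts = np.array([0.0, 0, 0, 5, 9, 5, 0, 0, 0, 0])
        prof = DensityProfile(edges_A=np.arange(11.0), counts=counts)
        e = neg_log_density(prof, sigma_bins=0.0)
        assert e.mask[0] and e.mask[-1]
        assert np.isfinite(e.energy_kBT[~e.mask]).all()

    def test_all_zero_profile_rejected(self):
        prof = DensityProfile(edges_A=np.arange(5.0), counts=np.zeros(4))
        with pytest.raises(ValueError):
            neg_log_density(prof)

    def test_boltzmann_inversion_recovers_generating_potential(
        self, equilibrium_tracks, double_well_potential
    ):
        """On zero-voltage Langevin data, -log density matches the input
        landscape within 0.3 kBT RMS on well-sampled bins."""
        prof = axial_density(equilibrium_tracks, (-30, 30), bin_width_A=0.5)
        energy = neg_log_density(prof, sigma_bins=2.0)
        ok = ~energy.mask & (prof.counts > 200)
        ref = double_well_potential(energy.z_A[ok])
        diff = energy.energy_kBT[ok] - ref
        diff -= diff.mean()
        assert np.sqrt((diff**2).mean()) < 0.3


class TestFindBindingSites:
    def energy(self, values):
        v = np.asarray(values, dtype=float)
        return EnergyProfile(
            z_A=np.arange(len(v), dtype=float),
            energy_kBT=v - v.min(),
            mask=np.zeros(len(v), dtype=bool),
        )

    def test_single_well(self):
        e = self.energy([3, 2, 1, 0.2, 1, 2, 3])
        sites = find_binding_sites(e, min_depth_kBT=0.5)
        assert len(sites) == 1
        assert sites[0][0] == 3.0

    def test_double_well_positions(self):
        e = self.energy([2, 0.1, 1.8, 2.5, 1.9, 0.3, 2.2])
        sites = find_binding_sites(e, min_depth_kBT=0.5)
        assert [s[0] for s in sites] == [1.0, 5.0]

    def test_monotone_profile_no_sites(self):
        e = self.energy(np.linspace(0, 5, 20))
        assert find_binding_sites(e) == []

    def test_shallow_minimum_below_depth_ignored(self):
        e = self.energy([1.0, 0.8, 1.0, 0.0, 2.0])
        sites = find_binding_sites(e, min_depth_kBT=0.5)
        assert [s[0] for s in sites] == [3.0]


class TestDensityGrid3D:
    def test_single_ion_single_voxel(self):
        pos = np.array([[0.5, 0.5, 0.5]] * 7)
        grid = density_grid_3d(pos, spacing_A=1.0)
        assert grid.counts.sum() == 7
        assert np.count_nonzero(grid.counts) == 1

    def test_mask_radius_zero_empty(self):
        pos = np.array([[1.0, 2.0, 3.0]])
        ref = np.array([[50.0, 50.0, 50.0]])
        with pytest.warns(RuntimeWarning, match="no positions"):
            grid = density_grid_3d(pos, reference_points=ref, mask_radius_A=0.0)
        assert grid.counts.sum() == 0

    def test_total_equals_bruteforce_masked_count(self, rng):
        pos = rng.uniform(-15, 15, size=(500, 3))
        axis = np.column_stack([np.zeros(31), np.zeros(31), np.linspace(-15, 15, 31)])
        grid = density_grid_3d(pos, spacing_A=2.0, reference_points=axis, mask_radius_A=10.0)
        brute = 0
        for p in pos:
            d = np.min(np.linalg.norm(axis - p, axis=1))
            brute += d <= 10.0
        assert grid.counts.sum() == brute

    def test_dx_export_well_formed(self, tmp_path, rng):
        grid = density_grid_3d(rng.uniform(0, 5, size=(50, 3)), spacing_A=1.0)
        path = tmp_path / "density.dx"
        write_dx(grid, path)
        text = path.read_text()
        assert "gridpositions" in text and "data follows" in text


class TestFirstShell:
    def test_no_waters_zero(self):
        assert first_shell_count([0, 0, 0], np.empty((0, 3)), 3.1) == 0

    def test_boundary_water_counted_inclusive(self):
        waters = np.array([[3.1, 0.0, 0.0]])
        assert first_shell_count([0, 0, 0], waters, 3.1) == 1
        assert first_shell_count([0, 0, 0], waters, 3.0999) == 0

    def test_matches_bruteforce_distance_count(self, rng):
        ion = rng.uniform(-5, 5, size=3)
        waters = rng.uniform(-8, 8, size=(200, 3))
        brute = sum(1 for w in waters if np.sqrt(((w - ion) ** 2).sum()) <= 3.5)
        assert first_shell_count(ion, waters, 3.5) == brute


class TestSolvationProfile:
    def make_tracks_and_waters(self, mean_fn, n_frames=30, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.uniform(-15, 15, size=(n_frames, 6))
        # ions laterally separated so their water shells never overlap
        x = np.tile(30.0 * np.arange(6), (n_frames, 1))
        t = IonTracks(
            times=0.02 * np.arange(n_frames),
            ion_ids=np.arange(6),
            species=["Na"] * 6,
            valences=np.ones(6, dtype=int),
            z=z,
            x=x,
            y=np.zeros_like(z),
        )
        waters = []
        for f in range(n_frames):
            pos = np.column_stack([t.x[f], t.y[f], t.z[f]])
            w, _ = make_waters(pos, mean_fn, placement_radius=3.0, seed=seed + f)
            waters.append(w)
        return t, waters

    def test_constant_mean_gives_flat_profile(self):
        t, waters = self.make_tracks_and_waters(6.0, n_frames=60)
        spec = SolvationSpec(radii_A={"Na": 3.1})
        z, mean, mask = solvation_profile(t, waters, spec, (-15, 15), bin_width_A=3.0)
        # ions sit far apart on average; recovered means scatter around 6
        assert np.nanmean(mean[~mask]) == pytest.approx(6.0, abs=0.5)

    def test_step_in_mean_count_recovered(self):
        # dehydration step inside a "filter" region: 6 waters -> 3 waters
        def mean_fn(z):
            return 3.0 if -5.0 <= z <= 5.0 else 6.0

        t, waters = self.make_tracks_and_waters(mean_fn, n_frames=80, seed=3)
        spec = SolvationSpec(radii_A={"Na": 3.1})
        z, mean, mask = solvation_profile(
            t, waters, spec, (-15, 15), bin_width_A=2.5, sigma_bins=0.0
        )
        inside = (z > -4) & (z < 4) & ~mask
        outside = ((z < -7) | (z > 7)) & ~mask
        assert np.nanmean(mean[inside]) < np.nanmean(mean[outside]) - 1.5

    def test_no_waters_zero_profile(self):
        t, _ = self.make_tracks_and_waters(0.0, n_frames=10)
        empty = [np.empty((0, 3))] * t.n_frames
        spec = SolvationSpec(radii_A={"Na": 3.1})
        _, mean, mask = solvation_profile(t, empty, spec, (-15, 15))
        assert np.all(mean[~mask] == 0.0)

    def test_radius_must_be_positive(self):
        with pytest.raises(ValueError):
            SolvationSpec(radii_A={"Na": -1.0})
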