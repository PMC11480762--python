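"""Langevin generator: stationary statistics, drift, determinism, fixtures."""

import numpy as np
import pytest

from permeon import (
    PoreModel,
    SimSpec,
    SpeciesSpec,
    first_shell_count,
    make_coupled_occupancy,
    make_umbrella_dataset,
    make_waters,
    simulate_ions,
)
from permeon.synthetic import channel_landscapes
from permeon.units import spring_kj_mol_nm2_to_kBT_A2, voltage_mV_to_kBT_per_e


def flat(z):
    return np.zeros_like(np.asarray(z, dtype=float))


def make_model(potential, voltage=0.0, species=None):
    return PoreModel(
        potential=potential,
        species=species or [SpeciesSpec("mono", 1, 10.0, 8)],
        voltage_mV=voltage,
    )


class TestSimulateIons:
    def test_flat_potential_uniform_distribution(self):
        tracks = simulate_ions(make_model(flat), SimSpec(dt_ns=0.01, n_steps=30_000, seed=1))
        counts, _ = np.histogram(tracks.z.ravel(), bins=12, range=(-30, 30))
        frac = counts / counts.sum()
        assert np.all(np.abs(frac - 1 / 12) < 0.02)

    def test_harmonic_potential_boltzmann_variance(self):
        kappa = 1.0  # kBT / A^2 -> stationary variance 1/kappa = 1 A^2

        def U(z):
            return 0.5 * kappa * np.asarray(z, dtype=float) ** 2

        tracks = simulate_ions(
            make_model(U), SimSpec(dt_ns=0.001, n_steps=60_000, seed=2)
        )
        z = tracks.z[5000:]  # discard equilibration from uniform start
        assert np.var(z) == pytest.approx(1.0 / kappa, rel=0.05)

    def test_same_seed_bit_identical(self):
        model = make_model(flat, voltage=-100.0)
        spec = SimSpec(dt_ns=0.002, n_steps=2000, seed=5)
        a = simulate_ions(model, spec)
        b = simulate_ions(model, spec)
        assert np.array_equal(a.z, b.z)

    def test_nonfinite_force_aborts_with_diagnostic(self):
        def bad(z):
            return np.where(np.asarray(z) > 0, np.inf, 0.0)

        with pytest.raises(RuntimeError, match="non-finite force"):
            simulate_ions(make_model(bad), SimSpec(n_steps=100, seed=0))

    def test_flux_sign_follows_voltage(self):
        for v, sign in ((-300.0, -1.0), (300.0, +1.0)):
            tracks = simulate_ions(
                make_model(flat, voltage=v), SimSpec(dt_ns=0.002, n_steps=20_000, seed=3)
            )
            drift = np.diff(tracks.unwrapped_z(), axis=0).sum()
            assert np.sign(drift) == sign

    def test_valence_doubles_voltage_drift(self):
        # flat landscape, voltage force active only inside the membrane span
        model = PoreModel(
            potential=flat,
            species=[SpeciesSpec("mono", 1, 10.0, 20), SpeciesSpec("di", 2, 10.0, 20)],
            voltage_mV=-400.0,
        )
        tracks = simulate_ions(model, SimSpec(dt_ns=0.002, n_steps=40_000, seed=4))
        uz = tracks.unwrapped_z()
        in_span = (tracks.z[:-1] > model.z_gate) & (tracks.z[:-1] < model.z_sf)
        dz = np.diff(uz, axis=0)
        mono = np.array([s == "mono" for s in tracks.species])
        drift_mono = dz[:, mono][in_span[:, mono]].mean()
        drift_di = dz[:, ~mono][in_span[:, ~mono]].mean()
        assert drift_di / drift_mono == pytest.approx(2.0, rel=0.10)

    def test_boltzmann_inversion_of_zero_voltage_run(
        self, equilibrium_tracks, double_well_potential
    ):
        # -log of the long-run z histogram equals U up to a constant
        counts, edges = np.histogram(
            equilibrium_tracks.z.ravel(), bins=np.arange(-30, 30.5, 0.5)
        )
        centers = 0.5 * (edges[:-1] + edges[1:])
        ok = counts > 200
        est = -np.log(counts[ok].astype(float))
        ref = double_well_potential(centers[ok])
        diff = est - ref
        diff -= diff.mean()
        assert np.sqrt((diff**2).mean()) < 0.3

    def test_exclusion_enforces_minimum_distance_in_pore(self):
        model = PoreModel(
            potential=flat,
            species=[SpeciesSpec("mono", 1, 10.0, 10)],
            voltage_mV=0.0,
        )
        spec = SimSpec(dt_ns=0.002, n_steps=5000, seed=6, exclusion_A=2.0)
        tracks = simulate_ions(model, spec)
        in_pore = (tracks.z >= model.z_gate) & (tracks.z <= model.z_sf)
        worst = np.inf
        for f in range(tracks.n_frames):
            zs = np.sort(tracks.z[f][in_pore[f]])
            if zs.size > 1:
                worst = min(worst, np.diff(zs).min())
        assert worst >= 2.0 - 1e-9


class TestUmbrellaDataset:
    def test_flat_potential_sample_matches_bias_gaussian(self):
        wins = make_umbrella_dataset(flat, range_A=(-1.0, 1.0), n_samples=20_000, seed=1)
        w = wins[0]
        k = spring_kj_mol_nm2_to_kBT_A2(w.k_spring)
        assert w.samples_A.mean() == pytest.approx(w.center_A, abs=0.02)
        assert w.samples_A.var() == pytest.approx(1.0 / k, rel=0.05)

    def test_centers_arithmetic_with_default_spacing(self):
        wins = make_umbrella_dataset(flat, range_A=(-2.0, 2.0), n_samples=10, seed=0)
        centers = [w.center_A for w in wins]
        assert np.allclose(np.diff(centers), 0.25)

    def test_seed_reproducible(self):
        a = make_umbrella_dataset(flat, range_A=(-1, 1), n_samples=50, seed=9)
        b = make_umbrella_dataset(flat, range_A=(-1, 1), n_samples=50, seed=9)
        assert all(np.array_equal(x.samples_A, y.samples_A) for x, y in zip(a, b))

    def test_weak_spring_flagged(self):
        wins = make_umbrella_dataset(
            flat, k_spring=1000.0, spacing_A=5.0, range_A=(-10, 10), n_samples=10, seed=0
        )
        assert all("warning" in w.meta for w in wins)


class TestCoupledOccupancy:
    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            make_coupled_occupancy(n_frames=0)

    def test_coupling_bounds_enforced(self):
        with pytest.raises(ValueError):
            make_coupled_occupancy(coupling=1.5)

    def test_stationary_occupancy_matches_p_occ(self):
        a, _ = make_coupled_occupancy(p_occ=0.3, coupling=0.0, n_frames=50_000, seed=1)
        assert np.mean(a.ids != -1) == pytest.approx(0.3, abs=0.03)

    def test_full_coupling_mirrors_transitions(self):
        a, b = make_coupled_occupancy(p_occ=0.5, coupling=1.0, n_frames=5000, seed=2)
        toggles_a = (a.ids[1:] != -1) != (a.ids[:-1] != -1)
        toggles_b = (b.ids[1:] != -1) != (b.ids[:-1] != -1)
        assert np.array_equal(toggles_a, toggles_b)

    def test_ids_fresh_and_vacancy_sentinel(self):
        a, b = make_coupled_occupancy(p_occ=0.5, coupling=0.5, n_frames=2000, seed=3)
        ids = np.concatenate([a.ids, b.ids])
        assert set(ids[ids < 0]) <= {-1}


class TestMakeWaters:
    def test_zero_mean_no_background_gives_zero_counts(self):
        ions = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 20.0]])
        waters, truth = make_waters(ions, mean_count=0.0, placement_radius=3.0, seed=0)
        assert waters.shape == (0, 3)
        assert np.all(truth == 0)
        assert first_shell_count(ions[0], waters, 3.0) == 0

    def test_poisson_mean_recovered(self):
        ions = np.column_stack([np.zeros(400), np.zeros(400), np.linspace(-20, 20, 400)])
        _, truth = make_waters(ions, mean_count=5.0, placement_radius=3.0, seed=1)
        assert truth.mean() == pytest.approx(5.0, abs=3 * np.sqrt(5.0 / 400))

    def test_counts_match_first_shell_oracle_when_isolated(self):
        # ions spaced far apart: generated waters stay in their own shell
        ions = np.column_stack([np.zeros(20), np.zeros(20), 20.0 * np.arange(20)])
        waters, truth = make_waters(ions, mean_count=4.0, placement_radius=3.0, seed=2)
        for i, pos in enumerate(ions):
            assert first_shell_count(pos, waters, 3.0) == truth[i]

    def test_seed_reproducible(self):
        ions = np.array([[0.0, 0.0, 0.0]])
        w1, _ = make_waters(ions, 5.0, 3.0, seed=4)
        w2, _ = make_waters(ions, 5.0, 3.0, seed=4)
        assert np.array_equal(w1, w2)


def test_channel_landscapes_divalent_funnel_barrier():
    land = channel_landscapes(di_funnel_barrier_kBT=4.0)
    z = np.linspace(-25, 25, 500)
    # the divalent landscape has a barrier near the cavity entrance that the
    # monovalent one lacks
    assert land["di"](np.array([5.0]))[0] > 3.0
    assert land["mono"](np.array([5.0]))[0] < 1.0
    assert np.all(np.isfinite(land["di"](z)))
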