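# permeon

In-silico electrophysiology analysis for ion-channel permeation, with a
built-in Langevin pore simulator so that every stage runs and is tested
without any MD data.

Given per-ion trajectories along a pore axis, the package:

- detects complete **permeation events** (selectivity-filter plane to
  gate plane traversals, periodic-boundary aware) and checks them against
  a brute-force oracle in the test suite;
- estimates **single-channel conductance** by event counting,
  `C = N_p · Q / (t · V)`, as totals and as windowed means ± SE, plus
  **selectivity ratios** from per-species counts;
- profiles **axial ion density**, converts it to a relative free-energy
  profile by `−ln ρ(z)` (Boltzmann inversion), and locates **binding
  sites** as local minima; 3-D density grids export to OpenDX;
- counts **first-solvation-shell waters** around permeating cations and
  profiles the mean coordination number along the axis;
- quantifies **binding-site cooperativity** as excess state-specific
  information (exSSI): mutual information between discrete
  occupancy-transition streams of two sites, minus a circular-shift
  noise threshold;
- computes **potentials of mean force** from umbrella-sampling windows
  by self-consistent WHAM (log-space, block-analysis errors), validated
  against an independent maximum-likelihood solver;
- generates all inputs synthetically: overdamped **Langevin dynamics**
  of ions in configurable 1-D landscapes with a membrane-confined
  voltage ramp, umbrella windows, coupled binding-site occupancies, and
  solvation-shell waters.

## Quick start

The event-counting conductance relation, applied to one published worked
example (15 monovalent events over 3000 ns at −50 mV):

```python
>>> from permeon import conductance_total
>>> conductance_total(15, 1, 3000.0, -50.0)
16.021766339999996        # pS; prints as 16 pS after rounding
```

End to end on synthetic data:

```python
from permeon import (PoreModel, SimSpec, SpeciesSpec, simulate_ions,
                     detect_events, conductance_total, PoreGeometry)
from permeon.synthetic import channel_landscapes

land = channel_landscapes()                 # monovalent + divalent landscapes
model = PoreModel(
    potential={"mono": land["mono"], "di": land["di"]},
    species=[SpeciesSpec("mono", 1, 10.0, 12), SpeciesSpec("di", 2, 8.0, 12)],
    voltage_mV=-340.0,
)
tracks = simulate_ions(model, SimSpec(dt_ns=0.002, n_steps=100_000, seed=42))
events = detect_events(tracks, PoreGeometry(z_sf=10.0, z_gate=-15.0))
n_in = sum(e.direction == "inward" and e.species == "mono" for e in events)
print(conductance_total(n_in, 1, tracks.t_total_ns, -340.0), "pS")
```

The same stages are exposed on the command line (`permeon --help`):
`simulate`, `events`, `conductance`, `selectivity`, `profile`,
`density3d`, `ssi`, `wham`, `run` (YAML-configured pipeline), and
`reproduce`.

## Repository layout

- `src/permeon/` — the library: `trajectory`, `permeation`, `profiles`,
  `ssi`, `wham`, `synthetic`, `pipeline`, `cli`, `units`.
- `analysis/` — numbered driver scripts (the study, in execution order).
- `tests/` — test suite; `tests/oracles.py` holds the independent
  brute-force reference implementations.
- `scripts/acceptance.py` — standalone worked-example JSON emitter.
- `docs/methods.md` — model definitions, parameter conventions, and
  numerical choices.
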