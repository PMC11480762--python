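#!/usr/bin/env python
"""Stage 1: Langevin pore simulations across a voltage ladder.

Simulates a mixed monovalent/divalent ion population in the built-in
two-landscape pore (divalent species face an extra funnel barrier) at
three transmembrane voltages, and writes the per-ion track tables that the
downstream stages (02-04) consume.

Output: results/tracks/tracks_<voltage>mV.tsv (+ JSON sidecars)
"""

from pathlib import Path

from permeon import PoreModel, SimSpec, SpeciesSpec, simulate_ions, write_tracks
from permeon.synthetic import channel_landscapes

VOLTAGES_MV = [-100.0, -340.0, -610.0]
SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results" / "tracks"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    land = channel_landscapes()
    for i, v in enumerate(VOLTAGES_MV):
        model = PoreModel(
            potential={"mono": land["mono"], "di": land["di"]},
            species=[
                SpeciesSpec("mono", 1, 10.0, 12),
                SpeciesSpec("di", 2, 8.0, 12),
            ],
            voltage_mV=v,
        )
        spec = SimSpec(dt_ns=0.002, n_steps=100_000, save_stride=2, seed=SEED + i)
        tracks = simulate_ions(model, spec)
        path = OUT / f"tracks_{int(v)}mV.tsv"
        write_tracks(tracks, path)
        print(f"{v:+.0f} mV: {tracks.n_frames} frames x {tracks.n_ions} ions -> {path}")


if __name__ == "__main__":
    main()
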