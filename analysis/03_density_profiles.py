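#!/usr/bin/env python
"""Stage 3: axial ion density, -log-density energy profiles, binding sites.

Builds per-species density histograms along the pore axis from the
stage-1 tracks, converts them to relative free-energy profiles, and
reports local minima as candidate binding sites.

Input:  results/tracks/tracks_<voltage>mV.tsv  (run 01 first)
Output: results/energy_<voltage>mV_<species>.tsv, results/binding_sites.tsv
"""

from pathlib import Path

import pandas as pd

from permeon import axial_density, find_binding_sites, neg_log_density, read_tracks
from permeon.profiles import write_profile_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    site_rows = []
    for path in sorted(ROOT.glob("tracks/tracks_*mV.tsv")):
        tracks = read_tracks(path)
        v = float(path.stem.split("_")[1][:-2])
        for sp in sorted(set(tracks.species)):
            density = axial_density(tracks, (-30, 30), bin_width_A=0.5, species_filter=sp)
            energy = neg_log_density(density, sigma_bins=2.0)
            out = ROOT / f"energy_{int(v)}mV_{sp}.tsv"
            write_profile_tsv(energy.z_A, energy.energy_kBT, energy.mask, out)
            for z_min, depth, extent in find_binding_sites(energy, min_depth_kBT=0.5):
                site_rows.append(
                    {"voltage_mV": v, "species": sp, "z_A": round(z_min, 2),
                     "depth_kBT": round(depth, 2), "extent_A": round(extent, 2)}
                )
    df = pd.DataFrame(site_rows)
    out = ROOT / "binding_sites.tsv"
    df.to_csv(out, sep="\t", index=False)
    print(df.to_string(index=False) if len(df) else "no binding sites found")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
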