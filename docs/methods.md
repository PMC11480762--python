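# Methods

Definitions, parameter conventions, and numerical choices behind each
analysis stage. Units throughout: Å for length, ns for time, mV for
voltage, kBT for energy at T = 310 K (kBT = 4.2804 × 10⁻²¹ J =
2.5775 kJ/mol; 1 e·mV = 0.03743 kBT, so 50 mV ≈ 1.87 kBT per unit
charge).

## Coordinate model

A trajectory (`IonTracks`) is a frame-by-ion matrix of axial positions
`z` (optionally lateral `x`, `y`), with per-ion species and valence.
Frames are uniform in time; missing ions are NaN. Coordinates may be
wrapped into a periodic box of length `L` along z; `unwrap_z` removes
jumps by minimum-image convention and warns when a single step exceeds
`L/2`, where unwrapping is ambiguous. The TSV format is long-form
(`time_ns, ion_id, species, valence, x_A, y_A, z_A`) with a JSON sidecar
for box/metadata.

## Permeation events

The pore is delimited by two planes: the selectivity filter `z_sf`
(extracellular side) and the gate `z_gate` (intracellular side), with
`z_sf > z_gate`. An **inward** event is a crossing of the SF plane in the
−z direction followed by a crossing of the gate plane in the −z direction
with no intervening +z re-crossing of the SF plane; **outward** is the
mirror image. A crossing is `z_prev > p ≥ z_next` (downward) or
`z_prev ≤ p < z_next` (upward); under periodic wrapping, steps of
`|Δz| ≥ L/2` are treated as wraps, not crossings. When one step crosses
both planes, the crossings are processed in the direction of motion and
the entry time is the earlier frame. An optional pore radius discards
crossings outside the pore cylinder. The implementation is verified
exactly (times included) against a frame-by-frame oracle that scans
continuous coordinates against all periodic images of the planes.

## Conductance and selectivity

Event-counting conductance: `C = N_p · |q| e / (t · |V|)`, reported in
pS with `t` in ns and `V` in mV. `conductance_total` applies it to a
whole trajectory; `conductance_windows` applies it per overlapping time
window (default 50 ns window, 25 ns stride, events assigned by exit
time) and reports mean ± SE over windows. Conductance is undefined at
0 mV and raises. The signed variant counts outward carriers negatively,
which is how the overall (net) conductance of a mixed condition is
formed. Selectivity `P_A/P_B` is the ratio of total event counts; 0/0 is
NaN and n/0 is +inf.

The published per-condition event counts are recorded as data
(`permeon.pipeline.PUBLISHED_COUNTS`), and `reproduce_published_table`
recomputes every derivable printed conductance from them. Three printed
applied-field values (19, 17, 85 pS) derive from per-window means rather
than totals and are flagged as non-matching by construction; total
trajectory times are 3000 ns for the double-membrane campaigns (3
replicas × 500 ns × 2 channels; 900 ns for the 0 mV control) and 750 ns
for single-channel applied-field campaigns (3 × 250 ns).

## Density, energy, and solvation profiles

Axial density is a histogram of z positions (default 0.5 Å bins),
optionally filtered to one species or to permeating ions only (frames of
ions that complete at least one event). The energy profile is
`F(z) = −ln ρ(z)` in kBT, after optional Gaussian smoothing of the
counts (default σ = 2 bins); empty bins are masked, never treated as
zero energy, and the profile is gauged to min 0. Binding sites are local
minima with depth ≥ `min_depth_kBT` (default 0.5) relative to the lower
flanking maximum; the reported extent is the contiguous span within that
depth. 3-D density grids (default 1 Å spacing) can be masked to voxels
within a cutoff of reference points and exported as OpenDX.

First-shell coordination counts waters within a species-specific radius
of the ion (boundary inclusive): Na⁺ 3.1 Å, K⁺ 3.5 Å, Ca²⁺ 3.0 Å. The
solvation profile bins these counts by the ion's z and reports the
per-bin mean, smoothed only across sampled bins.

## Cooperativity (SSI / exSSI)

Each binding site (an axial interval, optional radial cutoff) yields an
occupancy series on a 20 ps grid: the id of the ion nearest the site
center among those inside, or −1 when vacant. Consecutive frames map to
a 5-symbol transition alphabet: stay-occupied, stay-vacant, bind,
release, exchange. The SSI of two sites is the plug-in mutual
information (bits) between their transition streams. The noise threshold
is the 0.95 quantile of the SSI under circular shifts of one stream
(≥ 10 shuffles, default 100), which preserves marginals and
autocorrelation while destroying cross-correlation; exSSI =
max(SSI − threshold, 0). Replicas are aggregated as mean ± SE of
per-replica exSSI (SE undefined for one replica).

## Umbrella sampling and WHAM

Windows are harmonic restraints `w_i(z) = ½ k (z − z_i)²` with k in the
MD convention (kJ mol⁻¹ nm⁻²; default 1000, i.e. 3.880 kBT/Å² at 310 K)
spaced 0.25 Å apart. WHAM iterates the standard self-consistency
equations in log space (logsumexp) on a 0.25 Å grid until the largest
change in any window free energy is below 10⁻⁶ kBT. The PMF grid is
clipped to the restraint-center range (sparse histogram tails beyond the
outermost centers are noise), and — critically for correctness — the
per-window sample counts `N_i` are recomputed over the kept bins so that
`Σ_z M_z = Σ_i N_i`; violating this normalization makes the WHAM
likelihood unbounded and biases the profile. Non-overlapping windows
raise with the gap location; hitting the iteration cap returns an
unconverged profile with a warning. Per-bin standard errors come from
block analysis: contiguous blocks per window, WHAM per block,
gauge-aligned SE over blocks. The test suite checks the iterative solver
against an independent direct minimization of the convex WHAM likelihood
(scipy L-BFGS) and against the known generating landscape (4 kBT barrier
recovered within 0.5 kBT).

## Synthetic generator

Ions follow overdamped Langevin dynamics,
`z ← z − D Δt ∂_z[U(z) + qφ(z)] + √(2DΔt) ξ`, with energies in kBT and a
linear voltage ramp confined to the membrane span `[z_gate, z_sf]`
(constant force inside, zero outside). The box is periodic in z (default
[−30, 30] Å); optional lateral coordinates are reflected inside the pore
cylinder. Forces come from numeric central differences of the supplied
potential; non-finite forces abort with a diagnostic. An optional
hard-core exclusion enforces a minimum axial separation. The built-in
`channel_landscapes()` provide a monovalent landscape (vestibule and
cavity wells, modest gate barrier) and a divalent landscape with an
additional funnel barrier between filter and cavity — the ingredient
that makes the pore monovalent-selective at low voltage and lets that
selectivity erode as the driving force grows.

Umbrella windows are drawn by inverse-CDF sampling from the exact biased
Boltzmann density (no dynamics); a warning is attached when the spring
is too weak for adjacent windows to overlap. Coupled occupancy pairs are
two-state Markov chains with stationary occupancy `p_occ` in which the
second chain copies the first chain's toggle with probability
`coupling`. Solvation waters are Poisson-distributed counts placed
uniformly in a sphere around each ion.

The generator is scoped to what the analyses consume: 1-D ion motion
with independent ions (unless exclusion is enabled), no explicit
solvent, membrane, or protein degrees of freedom.

## Determinism and limitations

All stochastic stages take explicit seeds; the pipeline derives
per-stage seeds from one global seed via SHA-256, so a config + seed
pair reproduces byte-identical reports. Known limitations: plug-in MI is
positively biased for short streams (the shuffle threshold absorbs this
in practice); windowed conductance SE underestimates for strongly
clustered events; binding-site extent is resolution-limited by the
histogram bin width; the Langevin model has no inertia, hydrodynamics,
or ion-ion electrostatics, so only the analysis pipeline — not channel
physics — is being validated quantitatively.
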