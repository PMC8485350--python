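# Methods

`poredyn` analyses molecular-dynamics trajectories of membrane-embedded
nanotube channels — stacks of cyclic peptide rings held together by
inter-ring backbone hydrogen bonds, forming a water- and ion-conducting
pore through a lipid bilayer. This note describes the models and
estimators, the choices that were genuinely open, and what the synthetic
validation data does and does not establish.

## Conventions

All lengths are nm and all times ps internally (the GROMACS convention);
angles are reported in degrees. Atom and frame indices are 0-based in
memory; 1-based numbering appears only inside file records. Boxes are
orthorhombic; triclinic input raises an explicit error. The unit
conversion used for diffusion coefficients is **1 m²/s = 1e6 nm²/ps**,
stated here once and applied in exactly one place in the code.

## Pore region and geometry

The channel axis is fixed to the membrane normal (+z) rather than fitted
per frame, so every z-based analysis (occupancy, density profiles, ion
traces) shares one region convention. A `PoreRegion` is a cylinder:
`z_lo <= z < z_hi` and radial distance *strictly* less than a bound. The
half-open/strict convention makes classification a partition and gives an
unambiguous answer for particles exactly on a face: they are outside.

`derive_pore_region` takes the z-limits from the mean z of the two
terminal-ring backbone planes (optionally widened by a margin) and the
axis from the backbone centroid; the radial bound defaults to the mean
backbone ring radius, i.e. the lumen boundary.

The radius profile is a slab method replacing a grid-probe channel
annotator: the pore is cut into z-slabs (default 0.05 nm, half-open) and
each slab reports min over its atoms of (radial distance to the axis −
vdW radius), floored at 0. Empty slabs are recorded as missing (NaN),
never as zero — a gap in atom coverage is not a closed pore. vdW radii
come from a small built-in Bondi-style element table, overridable per
call. Because the minimum is taken per slab, the profile is exactly
rotation-invariant about the axis and translation along the axis only
shifts the grid.

The tilt angle is the angle between +z and the vector from the backbone
stack centroid to a terminal-ring centroid, folded into [0°, 90°]; both
tube ends are reported.

## Water confinement and survival

A water is inside the pore by its **oxygen position only** — one
unambiguous site, consistent with the density maps. Positions are wrapped
into the primary box before classification; no unwrapping is needed for
occupancy. Equilibrium averages default to discarding the first 20% of
each trajectory.

Survival probability: P(t) is the fraction of waters inside at an origin
t0 that remain inside through t0 + t, averaged over origins. Two choices
matter:

* **continuous residence** (default): the molecule must be inside at
  every intermediate frame, the strict reading of "remaining
  encapsulated"; an intermittent variant (inside at both endpoints,
  excursions allowed) is an option;
* **fixed origin set**: origins are every frame that leaves room for the
  *maximum* lag, identical across lags. With a lag-dependent origin set
  the averaged curve can rise spuriously when a low-occupancy origin
  drops out of the average; with a fixed set the continuous curve is
  non-increasing by construction. The maximum lag defaults to half the
  trajectory span, trading lag range for origin statistics.

## Displacement windows and diffusion

Windowed displacements follow the windows-over-the-run protocol: by
default 160 windows of 100 ps (200 and 500 ps are equally supported),
with start frames evenly spaced — and therefore possibly overlapping —
over the span that leaves room for a full window. A molecule contributes
a window pass only if it is inside the region at **every** frame of the
window; its contribution is the squared net displacement between the
window's endpoints. Contributions are pooled over windows and molecules
and histogrammed to unit probability mass.

Displacements and MSDs always use unwrapped coordinates: periodic jumps
are removed by accumulating per-step minimum-image displacements, which
requires every per-step move to be below half the box (a step of exactly
half the box is ambiguous and raises an error; larger true steps are
fundamentally undetectable from wrapped data, which is why the input
frame spacing must resolve the motion).

`estimate_diffusion` computes the origin-averaged MSD with the standard
FFT decomposition (O(N log N) per atom) and fits a least-squares slope
over a lag window (default 50–500 ps, chosen to sit beyond the
short-time regime but well inside the statistically solid part of the
curve). D = slope/(2d) with d = 3 for full 3-D motion or d = 1 for axial
(z-only) motion, the relevant mode inside a pore where radial motion is
bounded. The reported standard error is the OLS slope error; for
strongly correlated MSD points it is optimistic, which is why validation
uses ground-truth recovery rather than the error bar.

## Hydrogen bonds

Detection is geometric: donor–acceptor distance ≤ 0.35 nm and deviation
of D–H···A from linearity ≤ 30°, the common geometric convention and the
default of the major MD analysis suites; both thresholds are
configurable, and the angle is defined at the hydrogen (the angle between
the D→H and H→A vectors). Donor hydrogens are resolved by file order:
each H attaches to the most recent preceding heavy N/O of its residue,
the layout every standard writer emits. Neighbour search is a periodic
k-d tree; all distances are minimum-image.

The inter-ring capacity of an ideal stack is `amides_per_ring ×
(n_rings − 1)`: each adjacent ring pair can form one bond per amide.
The synthetic stack builder places pseudo-amide N–H/C=O sites so that
the detector finds exactly this number (see below), which ties the
arithmetic and the geometric route together in the tests.

Bond lifetime kinetics are reported as the **intermittent**
autocorrelation c(t) = ⟨h(t0)h(t0+t)⟩/⟨h(t0)⟩ with h the presence
indicator: the bond may break and reform. Origins run over every frame
that leaves room for the lag (maximal averaging), so c(0) = 1 and
c ∈ [0, 1] exactly. The continuous variant (presence required at every
intermediate frame) is available but off by default. Validation uses a
two-state Markov (telegraph) process, whose closed form is
c(n) = π₁ + (1 − π₁)λⁿ with λ = 1 − α − β and π₁ = β/(α+β) for per-step
break/form probabilities α, β.

## Density maps and symmetry

Maps accumulate inside-water oxygen positions on half-open bins (default
0.05 nm) in the xy plane, the xz plane, or along z. Normalization
divides by the most populated bin, optionally taken jointly over a set
of maps so that replicas share a single reference; the operation is
idempotent and the joint maximum is exactly 1.

The rotational-symmetry spectrum quantifies patterns such as an
approximately 6-fold water arrangement in the lumen: bin mass in an
annulus (default [0.2, 1.0] × the map's radial extent) is assigned its
bin-centre angle θ, and the power of mode k is |Σ m e^{−ikθ}|²
normalized by the squared total mass. For a phantom sampled from an
angular density ∝ 1 + cos(kθ) the dominant mode equals k; for a uniform
ring every normalized mode is O(1/N) noise. Exact rotation invariance
holds at the level of the angular mass distribution; re-binning a
rotated point set on a square grid moves mode power by a few per cent at
the default bin size, which the tests account for.

## Ions

Per-ion z-traces carry the same inside flags (same region, same strict
tie-break) as waters. Entrants are distinct ions with at least one
inside frame. The RDF is a standard minimum-image pair histogram
(default bin 0.002 nm) normalized by the ideal-gas shell expectation,
with self-pairs excluded for overlapping groups. The first-shell cutoff
is the first local minimum after the first maximum of the smoothed g(r)
(moving average, default 5 bins); extrema must clear a prominence of 5%
of the curve's range so that noise wiggles are not mistaken for shell
structure. Following the source protocol, the cutoff is derived once
from the all-cation/water-oxygen RDF and then reused for coordination
counting of inside ions, split by oxygen source (water versus peptide
carbonyl). The selectivity summary reports entrant counts, mean inside
occupancy per species and the cation:anion ratio, flagged infinite when
no anion ever enters.

`ion_pairs_for_molarity` implements the box arithmetic
round(c·V·N_A): 0.15 M in a 12.7 × 13.4 × 8.5 nm³ box gives 131 ion
pairs.

## Synthetic generator

The generator provides ground truth, not physics:

* **Pore system** — independent Brownian walkers (ideal gas, no
  water–water forces) with per-axis Gaussian steps of variance 2·D·dt.
  A membrane slab pierced by a cylindrical pore is impermeable: steps
  ending in slab-minus-pore are specularly reflected off the slab faces
  or folded radially off the cylinder wall, iteratively (≤8 times), with
  step rejection as a fallback for unclassifiable steps — both preserve
  the uniform equilibrium density. Anion steps *entering* the pore are
  rejected with a tunable probability, emulating cation selectivity.
  Randomness uses named substreams (initial positions, steps, anion
  gate) spawned from one master seed in a fixed order, so replicas
  differ only by seed and reruns are bit-identical. Ground truth records
  the input D, per-frame inside counts per species and all entrant
  identities.
* **Idealized ring stack** — pseudo-amide N, H, C, O sites on circles of
  radius 0.5 nm (0.65 nm for the wider 12-amide ring), rings 0.48 nm
  apart, with N–O at 0.29 nm and D–H···A exactly linear across each
  interface, so the detectable bond count equals the capacity by
  construction. Parallel stacking has every ring donating upward;
  antiparallel alternates the donation direction between neighbouring
  amides. Intra-ring and diagonal site pairs fall outside the
  distance-or-angle criterion at these defaults.
* **Hydration fixture** — one cation with n oxygens at an exact shell
  radius in well-separated (Fibonacci-sphere) directions plus optional
  far oxygens, for coordination counting with a known answer.
* **Density phantom** — static points with angular density
  ∝ 1 + A·cos(kθ) in a radius band, sampled by rejection.

Default generator conditions are a scaled-down analogue of a solvated
bilayer-nanotube system: 6 nm box, 2 nm slab, 0.5 nm pore radius, 2000
waters, D = 2.3e-9 m²/s (experimental bulk water), dt = 1 ps. Diffusion
validation uses 1000 free walkers for 10 ns at dt = 10 ps at each of the
four bulk water-model coefficients (5.5, 3.2, 2.1, 2.4 × 10⁻⁹ m²/s);
at these sizes the MSD slope recovers the input to well within 5% and
preserves the models' ordering, with the two slow models within their
true 14% separation.

Because walkers do not interact, passing tests establish estimator
correctness (bookkeeping, unwrapping, normalization, boundary handling,
statistics) but say nothing about force-field physics: no hydrogen-bond
network, no single-file water motion, no electrostatics, no genuine
free-energy barrier at the pore mouth. Real trajectories are read
through the same interfaces (PDB/GRO, plus XTC/TRR where the ecosystem
reader is available).

## Pipeline

The runner consumes one YAML config naming either real inputs or a
synthetic spec (exclusively one of the two), runs the requested stages
per replica, and aggregates as mean of replicate means with the sd
across replicates. Outputs are CSV tables with unit-bearing headers,
density grids as plain matrix files, a JSON manifest (versions, seed,
full config, failures) and a plain-text log. A failing stage is recorded
and the rest proceed; the CLI exits nonzero if anything failed. Reruns
with the same seed reproduce every table byte-for-byte.

## Known limitations

* Orthorhombic boxes only; no triclinic support.
* The membrane normal is assumed to be +z; strongly tilted channels
  would need a per-frame axis fit that is deliberately not implemented.
* Donor-hydrogen resolution relies on conventional file ordering, not on
  a bonded topology; unusual atom orderings need a pre-pass.
* The OLS slope error of the diffusion fit underestimates the true
  uncertainty of correlated MSD points.
* Multi-frame GRO and PDB are always available; compressed trajectory
  formats depend on the optional reader capability.
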