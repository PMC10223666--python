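# Methods

## Scope and units

`vesitraj` analyzes trajectories of self-assembled single-chain amphiphile
vesicles (ten-carbon fatty acids as the reference chemistry) and ships a
synthetic generator that makes every estimator testable by parameter
recovery.  Internal coordinates are angstrom (the PDB native unit); all
report-facing geometry is converted to nanometre.  Times are nanoseconds
(default sampling interval 0.01 ns), diffusion coefficients nm²/ns
(numerically equal to 10⁻⁵ cm²/s).  The supported trajectory dialects are
multi-model PDB and XYZ, read and written through MDAnalysis; molecule
membership and atom roles (headgroup oxygens O1/O2, ordered tail carbons
C1..C10, peptide Cα by residue) come from a declarative YAML topology spec,
never from atom names, because XYZ carries none.

## Vesicle geometry and leaflets

The vesicle center is the mass-weighted centroid of all amphiphile atoms;
using whole monomers rather than headgroups reduces the bias introduced by
the inner/outer leaflet count imbalance.  Per-leaflet radii of gyration are
computed over the O1/O2 oxygens about that center; bilayer thickness is
`Rg_outer − Rg_inner`, and the reported radius follows the outer-shell
convention (configurable to inner or midplane) — a vesicle quoted at ~7 nm
diameter with a 1.5 nm bilayer corresponds to `2·Rg_outer`.

Leaflet labels are assigned by orientation: the cosine between the
headgroup-midpoint→C10 vector and the outward radial.  Positive cosine
(tail pointing away from the center) is inner leaflet, negative is outer,
and `|cos| < 0.2` (config) is an unassigned dead zone.  Orientation, unlike
radial distance, remains meaningful for monomers caught mid flip-flop and on
rippled patches; a radial-bimodality labeler is retained as a cross-check.
Aggregates are detected by single-linkage clustering of heavy-atom contacts
(default cutoff 6 Å), with cluster ids numbered by lowest member molecule id
so output is deterministic.

## Diffusion and flip-flops

`M(τ)` is the all-time-origin, all-particle average of squared monomer
center-of-mass displacements on a lag grid equal to the sampling interval,
computed with the standard FFT autocorrelation decomposition (algebraically
identical to the O(frames²) double loop; the tests assert equality to
1e-12).  The Einstein fit `D = slope/2E` uses a window of 10–50% of the
maximum lag by default, excluding the poorly averaged tail; the anomalous
exponent is the log–log slope over the same window, and `|α − 1| > 0.2`
(config) marks the regime anomalous, in which case no `D` is reported —
a sublinear MSD has no single Einstein constant.  Boxed trajectories must be
unwrapped first (`dynamics.unwrap`); the synthetic fixtures are box-free.

Flip-flops are counted per monomer on the leaflet-label time series with
dwell hysteresis: an event is recorded when the label switches to the
opposite leaflet and persists for `min_dwell` consecutive frames (default
20).  Flickers through the unassigned dead zone, and opposite-leaflet
excursions shorter than the dwell, are ignored by construction.

## SASA

Shrake–Rupley with a golden-spiral lattice (default 960 points per atom),
Bondi-style vdW radii, 1.4 Å probe, and a KD-tree neighbor search.  The
point lattice of each atom is oriented in a local frame built from its two
nearest overlapping neighbors, so the lattice co-rotates with the structure:
the result is invariant under rigid motion up to round-off rather than to
lattice noise.  Burial is evaluated against the selected atoms only
(default: the amphiphiles), i.e. the SASA of the selected assembly in
isolation; the selection is explicit because "system SASA" is otherwise
ambiguous.

## Chain order parameters

`S = ⟨3cos²θ − 1⟩/2` per tail carbon C2..C9.  The chain segment at carbon i
is `C(i−1)→C(i+1)`; the C–H proxy is the in-plane perpendicular — the
component of `C(i)` minus the segment midpoint orthogonal to the segment —
a standard heavy-atom reconstruction that needs no hydrogens.  θ is
measured against each monomer's own outward radial normal at its headgroup,
which is exactly equivalent to reorienting every molecule so its local
normal maps to +z and measuring against the z axis; this removes vesicle
curvature from the statistic.  Perfectly all-trans chains aligned with the
normal give S = −0.5 at every mid-chain carbon (segments parallel to the
normal, proxy perpendicular); isotropic orientations give 0.

## Density maps and RDF

Headgroup midpoints of one leaflet are projected to (cos θ, φ) about the
per-frame center; all cells subtend equal solid angle, and the density is
normalized so a uniform shell reads 1.0 everywhere.  The RDF between two
atom groups is a shell-normalized pair-distance histogram; because these are
finite, box-free systems, the default normalization uses the exact
pair-distance law of two uniform points in the bounding sphere, which makes
g → 1 at all r for a homogeneous reference (the plain shell-volume
normalization is available via `edge_correction=False`).  For strongly
inhomogeneous vesicle+peptide systems the large-r limit is approximate
either way and the curve should be read as a distance distribution.

## Peptide tilt

The helix axis is the unit vector from the first to the last residue's Cα.
The local bilayer normal averages the outward radial units of the monomers
that have any atom within 8 Å of any peptide atom (the qualification used in
the source analysis), weighted by a Gaussian kernel of headgroup distance to
the peptide centroid with σ = 0.75·cutoff.  The kernel matters: an
unweighted average over the any-atom footprint — which elongates along a
tilted helix and mixes unevenly sampled leaflets — tilts the normal by up to
~7° on planted fixtures, while the symmetrized estimator recovers planted
tilts within ~1.5°.  Frames with fewer than `min_support` (default 5)
qualifying monomers report a missing tilt.  Classification windows are
0–30° inserted C→N, 60–120° surface, 150–180° inserted N→C, else
intermediate; the windows are reporting conveniences around the three anchor
geometries and are configurable.

## Synthetic generator

The generator emulates the *assembled end state* of vesicle self-assembly,
not its pathway: a two-leaflet sphere with headgroup oxygens placed exactly
on the planted shell radii (Gaussian radial jitter σ = 0.05 nm by default),
outer tails pointing inward and inner tails outward, meeting at the
midplane.  Monomers are placed on golden-spiral lattices; a shell whose area
per monomer falls below the hexagonal footprint of a 0.45 nm disc (the
headgroup diameter scale) raises a packing error.  That guard is a density
feasibility test rather than a realized-lattice spacing test: the spiral
lattice's worst-case spacing is ~15% below the hexagonal ideal, and a
literal spacing rejection would forbid compositions that are physically
packable — including the reference 1000-monomer vesicle.

Gel-state tails are all-trans (every C–C–C–C dihedral 180°, built by
internal-coordinate chain construction with 1.53 Å bonds and 111° angles);
fluid tails draw each dihedral uniformly from {−60°, +60°, 180°}.  The two
regimes are analytically distinct for the order-parameter and SASA tests.
Gel monomers are oriented by their zigzag chain axis (C1→C3), which makes
every all-trans segment exactly parallel to the planted normal — the
end-to-end vector of a 10-carbon zigzag tilts 4.4° off the chain axis and
would blur the closed-form S = −0.5 anchor; fluid monomers are oriented by
their end-to-end vector, which keeps orientation-based leaflet labels robust
for kinked chains.

Dynamics treats monomers as rigid bodies: only centers move.  Displacements
are exact fractional Gaussian motion — increments drawn with the fGn
covariance (Cholesky factorization) and scaled so the 3-D ensemble MSD is
`6·D·t^α` at every lag.  Stationarity of the increments is essential: the
superficially simpler scheme of independently scaled per-step displacements
yields a time-origin-averaged MSD that is asymptotically *linear* in lag
regardless of α, and the anomalous flag would never trip.  Scripted
flip-flops rotate the whole monomer rigidly by π about a tangent axis
through its headgroup while its radial position interpolates to the opposite
shell over a transit window (default 10 frames, configurable because
detection hysteresis must be tested against fast and slow transits);
mid-transit the orientation passes through the dead zone, exactly as a real
translocating monomer would.  The peptide is an ideal α-helix Cα trace
(rise 1.5 Å, 100°/residue, 16 residues by default) rotated so its
end-to-end vector makes exactly the planted angle with the outward radial at
its midpoint.

Every generator spec carries a seed and is bit-reproducible; each fixture is
accompanied by a ground-truth JSON sidecar (labels, shell radii, planted D,
α, flip events, planted tilt), and all recovery tests compare against the
sidecar, not hard-coded constants.

What the generator does *not* emulate — force-field energetics, assembly
kinetics, internal vibrations, solvent structure, membrane undulations —
bounds what passing tests show: they certify the estimators (geometry,
labeling, counting, fitting, surface and angle measures) on data whose truth
is known, not the physics of any particular simulation.

## Pipeline and problem sizes

The batch pipeline runs geometry → dynamics → surface → peptide, discards
the first 10% of frames from time averages (configurable equilibration
window), fixes float formats (2 decimals for nm and D, integers for SASA),
and writes a manifest with the resolved config, its hash, and the seed;
identical config + inputs + seed reproduce every CSV byte for byte.
Unknown config keys are hard errors, and all validation problems are
reported in one pass.

Default analysis sizes were chosen so the complete test suite and the
acceptance script each run in about a minute on one CPU: recovery fixtures
use 200–1000 monomers (2 400–12 000 atoms), 25–300 frames for geometry and
flip-flop checks, and 5 × 2000 frames × 300 monomers for the diffusion
recovery, which brings the seed-averaged estimator error to a few percent.
Estimator accuracy at these sizes is representative; larger systems only
tighten the statistics.

## Known limitations

- Leaflet orientation labeling assumes quasi-spherical topology; open
  bilayer sheets or micelle-to-vesicle intermediates need the clustering
  step and a per-aggregate analysis.
- The RDF normalization treats the bounding sphere as the reference volume;
  absolute g(r) scales for strongly inhomogeneous systems are approximate.
- Anomalous-motion fixtures reproduce the ensemble MSD law, not any
  particular microscopic caging mechanism.
- PDB round trips quantize coordinates at 0.001 Å and store positions in
  float32 on write.
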