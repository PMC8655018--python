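# Methods

## The system and its order parameters

BAM, the β-barrel assembly machinery of Gram-negative bacteria, is a
five-component complex: BamA — a 16-stranded outer-membrane β-barrel
with five periplasmic POTRA domains — plus the lipoproteins BamB–E,
which together with the POTRA domains form a "periplasmic ring" under
the barrel.  Two principal conformations are distinguished by the
closure of the barrel's lateral seam (the β1/β16 strand interface) and
by a rotation of the periplasmic ring of roughly 60° between the
inward-open and outward-open states.  This package computes the order
parameters that quantify these motions.

### Ring rotation angle

The metric compares two in-plane vectors, both anchored at the BamA
barrel center, defined as the geometric center of the barrel's backbone
carbonyl carbons (author residues 425–810 by default).  The reference
vector points from the barrel center to the carbonyl-carbon center of
the accessory proteins (BamB–E) in a chosen reference structure/frame;
the measured vector is the same construction in the current frame.  The
signed angle between their in-plane projections, counterclockwise
positive when viewed from the extracellular side, is the rotation
angle, wrapped to (−180°, 180°] with optional unwrapping for continuous
traces.  Systems missing an accessory component exclude it from both
the reference and the measurement, so the angle remains comparable
across deletion constructs.

Two structures deposited in unrelated coordinate frames are compared by
first superposing the mobile structure's barrel Cα atoms onto the
reference barrel (Kabsch, residue-identity pairing) and then measuring
in the reference's membrane frame.  For membrane-aligned MD systems the
frame is simply +z (mode `z_axis`); for arbitrary structures the
`barrel_principal` mode derives the membrane normal from the barrel's
principal axes.  Because a β-barrel is wider than it is tall, the
cylinder axis is not reliably the axis of smallest inertia moment —
for height ≲ 2.45 × radius it is actually the *largest* — so the mode
selects the principal axis best aligned with the direction from the
periplasmic anchor (POTRA5 center, falling back to the accessory
centers) to the barrel center, sign-fixed to point extracellular.  Only
when no periplasmic anchor resolves does it fall back to the
smallest-variance axis.

### Lateral-seam hydrogen bonds

Backbone N–H···O=C bonds between the β1 and β16 strand selections
(defaults 424–435 and 800–810, both configurable) are detected with a
conventional geometric criterion: donor–acceptor N···O distance ≤ 3.5 Å
and, when explicit amide hydrogens are present, a D–H···A angle ≥ 150°;
without hydrogens the gate is the N···O=C angle at the acceptor ≥ 120°.
Both donor directions are scanned and each donor is matched to at most
one (nearest satisfying) acceptor, so bifurcated contacts are not
double-counted — consistent with the small integer counts the analysis
consumes.  Counts are smoothed with a centered moving average (default
window 51 frames) whose windows shrink at the series edges.

Frames are classified **closed** when the smoothed count ≥ 2, **open**
when the smoothed count < 1 *and* no cross-strand N···O pair lies within
the detection cutoff, and **tenuous** otherwise — the last capturing a
seam that keeps residual contact (e.g. a single persistent bond
averaging below one) without being stably closed.

### POTRA5 tracking

The in-plane position of a sub-domain (POTRA5, default residues
344–421) is reported relative to the per-frame barrel center, in the
membrane frame of frame 0, making the track invariant to whole-complex
translation.  Displacement between two states superposes the second
structure's barrel Cα onto the first before comparing POTRA5 Cα
centers.  "Area explored" defaults to the convex hull of the track
(deterministic and oracle-checkable); an occupancy grid
(cells × cell²) is available as a local alternative that does not
inflate with isolated excursions.

### Nanodisc density averaging

To model why the membrane-scaffold (MSP) belt nearly vanishes from
particle-aligned reconstructions, the belt is idealized as an annulus
of outer diameter 110/130/170 Å (the MSP1D1/MSP1E3D1/MSP2N2 discs) and
width 10 Å (the belt's width is not prescribed anywhere; 10 Å is a
plausible two-helix belt footprint and the conclusions are
width-robust).  N copies (default 5000) are shifted in the membrane
plane by random vectors bounded by `disc_radius − core_radius − mask`
with a 40 Å protein core and a 10 Å alignment mask, then averaged.
Shifts default to uniform over the disk of that radius — respecting the
scalar bound — with an independent-per-axis uniform square available,
since "random shifts in x and y" admits both readings.

The sampler draws a *stratified* sample of the shift distribution
(equal-probability polar cells, one jittered draw per cell; ring areas
proportional to their cell counts so every cell carries probability
exactly 1/N).  Every shift remains an unbiased draw from the stated
distribution and the map is the plain mean of the N shifted rings, but
the empirical measure converges roughly an order of magnitude faster
than i.i.d. sampling (normalized L2 error vs the expectation ≈ 0.9%
at N = 5000, 1 Å/px, 130 Å disc, where i.i.d. sampling plateaus near
3%).  Shifts are rounded to whole pixels and applied as periodic rolls;
the grid-size precondition keeps occupied pixels away from the border,
so the mean map's integral equals a single ring's exactly.

The analytic oracle is the exact expectation — the ring indicator
convolved with the shift density — computed by FFT convolution with an
8× supersampled kernel.  The radial intensity profile (mean per radial
bin) summarizes the result; the peak-to-mean contrast inside the
inscribed circle decreases monotonically with disc diameter, the
"averaged-out" conclusion.  Cross-size comparisons share one grid
(288 px at 1 Å/px for the three MSP sizes) because the default
256-px grid cannot contain the 170 Å disc plus its 55 Å shifts.

### Crosslink screening

Disulfide feasibility is proxied by Cβ–Cβ distance (the standard design
heuristic); glycine positions fall back to Cα with a flag in the
report.  Pairs are classified per state as compatible (≤ 7 Å), marginal,
or incompatible (≥ 12 Å); the published incompatible separations
(15–23 Å) sit comfortably above the default, and both thresholds are
configurable.  The published mutant panels — inward-open locks
S502C/V706C and G431C/G807C, outward-open locks D503C/N681C and
S425C/K808C, POTRA5–T4 locks E396C/R583C and G393C/G584C, and the
BamA×EspP hybrid-barrel sites (BamA 806/807 × EspP 1226, 1228, 1230,
1232, 1234) — are bundled as data.

## Synthetic data and what the tests show

The generator builds a pseudo-complex with real backbone atom names so
every selection and detector runs unchanged on synthetic and deposited
structures: a cylindrical "barrel" (chain A, residues from 425, 16
strands along +z, radius 20 Å, height 55 Å), compact accessory bodies
(chains B–E, 30 five-atom pseudo-residues each) below the membrane
plane on an asymmetric arc (0°, 45°, 90°, 135° — symmetric placements
put the combined accessory center on the barrel axis, where the angle
is undefined), and a POTRA5-like cluster.  Residue orientations are
spread uniformly within each cluster and around the barrel so that
intra-residue atom offsets cancel exactly in every geometric center,
giving exact ground truth.  Noise is isotropic Gaussian per atom per
frame (default 0 in the base spec; recovery tests use 0.5 Å, a typical
heavy-atom fluctuation scale after alignment).

Scripted trajectories rotate the accessory ring (plus POTRA cluster)
about +z, switch an exact number of register-paired seam contacts
between 2.9 Å (bound, linear N···O=C) and ≥ 6 Å (unbound), or translate
the POTRA cluster along a waypoint path.  The corresponding metrics
recover the schedules to ≤ 1° RMSE (0.5 Å noise), exactly (integer
counts), and to ≤ 0.2 Å respectively.

What passing these tests does *not* show: the toy complex has no
membrane, no side chains beyond Cβ, no correlated (collective) motion,
and its noise is uncorrelated — so recovery tolerances here bound
metric error, not the conformational heterogeneity of real
trajectories.  The worked examples on deposited structures
(inward-open 5D0O, outward-open 5LJO, the nanodisc structure 7RI5)
exercise the same code paths on real coordinates but require network
access to the PDB on first run.

## Numerical choices

- Kabsch superposition via SVD with determinant correction (proper
  rotations only); validated against an independent quaternion
  eigenvalue (Horn) oracle to 1e-9.
- Residue pairing for RMSD/superposition is by author numbering and
  atom name, no sequence alignment (the BAM depositions share BamA
  numbering); unmatched residues drop out silently, and the paired-atom
  count is reported alongside every RMSD.
- Default RMSD atom class is Cα — robust to deposition differences in
  side-chain completeness.
- Alternate locations resolve to the highest-occupancy conformer, first
  listed on ties; insertion codes are carried separately so plain
  integer selections match any insertion code.
- Angles wrap to (−180°, 180°]; exact ±180° maps to +180°.
- PDB text I/O round-trips coordinates to 1e-3 Å (the format's three
  decimals); 2D maps round-trip at float32 precision through a minimal
  MRC2014 mode-2 writer (plus npz and text-grid formats).
- Degenerate geometry is an explicit outcome, not an exception, where
  the quantity has a natural value: a <3-point or collinear track has
  hull area 0 with a `degenerate` flag; a zero-length in-plane
  accessory projection, by contrast, raises, because no angle exists.

## Known limitations

- The seam strand boundaries (424–435 / 800–810) and the POTRA5 range
  (344–421) are defaults anchored to residues named in the published
  analyses, not deposited domain annotations; both are configurable.
- The hydrogen-bond criterion is geometric; no energy or
  electrostatics.  Counts at the default cutoffs match conventional
  practice but the published per-frame counts were produced by an
  unspecified criterion, so only qualitative state behavior is
  comparable.
- The nanodisc model is 2D and CTF-free: it reproduces the averaging
  argument, not a reconstruction.
- Binary trajectory formats (DCD) are not read; multi-model PDB is the
  reference trajectory path.
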