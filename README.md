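# bamdyn

Conformational-dynamics analytics for the β-barrel assembly machinery
(BAM), the five-component complex (BamA–E) that folds outer-membrane
proteins into the outer membrane of Gram-negative bacteria.  The package
is aimed at structural biologists and simulators who need the bespoke
order parameters used to characterize BAM's two principal states —
inward-open and outward-open — on MD trajectories, deposited structures,
or synthetic test systems:

- **Periplasmic-ring rotation angle** — the signed in-plane angle of the
  accessory-lipoprotein ring (BamB–E) about the BamA β-barrel, measured
  counterclockwise as viewed from the extracellular side.  The 0°
  reference is the geometric center of the accessory carbonyl carbons in
  a chosen reference structure, relative to the barrel carbonyl-carbon
  center (BamA residues 425–810); the outward-open state sits near +63°.
- **Lateral-seam hydrogen bonds** — per-frame counts of backbone
  N–H···O=C bonds between barrel strands β1 and β16, a centered moving
  average, and an open/tenuous/closed classification of the seam.
- **POTRA5 tracking** — barrel-relative in-plane position of BamA's
  fifth POTRA domain, displacement between states, and area explored
  (convex hull or occupancy grid).
- **Nanodisc density averaging** — a Monte-Carlo model of why the
  membrane-scaffold belt washes out of particle-aligned reconstructions:
  the mean of N rings placed at random in-plane shifts bounded by
  `disc_radius − core_radius − mask`, with an exact analytic expectation
  (ring ⊛ shift density) as oracle.
- **Disulfide crosslink screening** — Cβ–Cβ (Cα for Gly) distances of
  residue pairs across conformational states, classified as
  compatible/marginal/incompatible for state-locking design; the
  published BamA and BamA×EspP mutant panels ship as data.
- **Kabsch superposition / RMSD** with residue-identity pairing, plus
  structure, multi-model-PDB trajectory, time-series and 2D-map I/O.

A synthetic-data module generates toy complexes and trajectories with
known ground truth (scripted ring rotations, exact per-frame hydrogen
bond counts, scripted domain drifts), so every metric is validated by
parameter recovery without downloading anything.

## Worked example

```sh
bamdyn synth rotation --frames 100 --angle-end 60 --noise 0.5 --seed 5 \
    --out rot.pdb --truth truth.csv
bamdyn ring-angle --trajectory rot.pdb --output angles.csv
```

`angles.csv` holds one wrapped angle per frame (`time_ns, angle_deg`,
frame 0 defines 0°).  Comparing with the scripted schedule in
`truth.csv`:

```
frame  0: truth  0.00   measured  0.000
frame 50: truth 30.30   measured 29.786
frame 99: truth 60.00   measured 60.181
RMSE 0.21 deg over 100 frames at 0.5 A positional noise
```

The nanodisc averaging argument, at the MSP1E3D1 scale (13 nm
disc, 40 Å core, 10 Å mask, 5000 copies):

```sh
bamdyn nanodisc-sim --disc-nm 13 --copies 5000 --seed 1 \
    --out avg.mrc --profile profile.csv
# -> max shift: 35.0 A; grid 256 px at 1.0 A/px
```

The radial profile of `avg.mrc` peaks just outside the protein core and
flattens as the disc diameter grows (peak-to-mean contrast ≈ 5.5 → 3.3
→ 1.6 for 11 → 13 → 17 nm discs), reproducing the conclusion that most
scaffold density is averaged out during alignment.

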