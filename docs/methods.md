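# Methods

## Model

Proteins are reduced to one bead per residue at the Calpha position; DNA to
three beads per nucleotide at the geometric centers of the phosphate, sugar
and base atom groups. The potential energy is the standard structure-based
(Go-type) form plus screened electrostatics:

- bonds and angles: harmonic, `E = k (X - X0)^2` with `k = 100 kcal/mol/A^2`
  (bonds) and `20 kcal/mol` (angles); reference values `X0` come from the
  input structure. Note the convention: no factor 1/2, so a 0.1 A bond
  stretch costs exactly 1 kcal/mol.
- dihedrals: the cosine series
  `E = f k [(1 - cos(phi - phi0)) + 1/2 (1 - cos 3(phi - phi0))]` with
  `k = 1 kcal/mol`; a plain harmonic form is available by configuration.
  `f` is a per-term flexibility scale in [0, 1].
- native contacts: 12-10 wells
  `E = f k_ij [5 (A_ij/r)^12 - 6 (A_ij/r)^10]`, `k_ij = 1 kcal/mol`,
  `A_ij` the reference Calpha-Calpha distance. Contacts are detected by the
  common heavy-atom criterion (any inter-residue heavy-atom pair within
  4.5 A, sequence separation > 3); the criterion and cutoff are
  configurable.
- excluded volume: `E = k_ev (sigma_ij/r)^12` over all remaining long-range
  pairs (separation > 3 within a chain, or inter-chain). Repulsion radii
  are per bead class (2.0 A protein, 3.7 A DNA, 3.0 A for DNA beads engaged
  by a target-site potential); per-pair `sigma_ij` is the arithmetic mean of
  the two radii (configurable). The mean rule was chosen over `max` so that
  mixed protein-DNA pairs interpolate between the class values.
- electrostatics: Debye-Hueckel,
  `E = K_C B(kappa) q_i q_j exp(-kappa r) / (eps r)` with
  `K_C = 332 kcal mol^-1 A e^-2`, `eps = 70`, `B(kappa) = 1`. Lys/Arg (and
  His when protonated; off by default) carry +1, Glu/Asp and phosphates -1.
  `kappa = sqrt(8 pi l_B N_A c_i)` for a 1:1 salt at ionic strength `c_i`
  (0.01-0.06 M supported); the Bjerrum length at eps = 70, 298 K is 8.01 A,
  giving a 28.7 A screening length at 0.01 M. No electrostatic cutoff is
  applied at desk scale; an optional shifted cutoff at a multiple of the
  screening length exists for larger systems. Every long-range pair
  interacts through exactly one of {contact, target-site term, excluded
  volume}, plus electrostatics when both beads are charged.

Target-site potentials are 12-10 terms between protein beads and DNA beads
of a bound complex (bead-group heavy atoms within the cutoff); they model a
specific site on otherwise nonspecific DNA.

## Propagation

Langevin dynamics with friction `gamma = 0.01` (reduced units), unit bead
masses, and `kBT = 0.593 kcal/mol` (298 K; the temperature is configurable).
The integrator is the BAOAB splitting with `dt = 0.005` reduced time units;
it reduces to velocity Verlet at `gamma -> 0, T = 0` and gives accurate
configurational averages at finite step (the tethered-bead variance check in
the test suite is within ~1% of equipartition). Two numerical guards keep
rare events benign: the angle-force colinearity singularity is bounded by
flooring `sin(theta)` at 0.02, and each half-drift displacement is capped at
0.5 A per component. Both caps are orders of magnitude away from typical
thermal steps (~0.01 A) and leave equilibrium statistics unchanged.

The simulation box spans x, y in [-240, 240] A and z in [-225, 225] A at
full scale (walls reflect); the DNA lies on the z-axis, centered, and is
held rigid by default (a switch allows mobile DNA). One MD step corresponds
to 50 ps, so 1e8 steps represent 5 ms; frames default to every 1000 steps
(50 ns).

The per-step cost is dominated by the nonbonded pair loop; a fused
numba kernel evaluates it (with an excluded-volume distance skip at
3 sigma, below 2e-6 kcal/mol per pair), and the test suite asserts
agreement with the plain numpy implementation. A 240-bead desk system
runs ~1e6 steps per minute on one core.

## Trajectory analysis

For each recognition region the per-frame observables are the COM
projection on the DNA axis `Z`, the distance from the axis `d`, and the
azimuth `phi = atan2(x, y)` (signed angle against the reference direction
(0, 1)). Frames with `d > R_c = 32 A` are 3D; `d <= R_c` is 1D (closed
boundary). The major-groove center line is calibrated from the phosphate
geometry: per base pair, the bisector of the wider angular gap between the
two strands' phosphates, fitted linearly against z — slope
`2 pi / (repeat x rise)`, i.e. one turn per 10 bp x 3.32 A by default.

Within 1D intervals of at least 5 ns (about 100 MD steps; applied on the
saved-frame clock and exposed as a parameter), frames within 1.5 bp of the
groove center are groove tracking, other 1D frames are hopping. Two
smoothing rules run to a fixpoint: hops spanning under 1 bp flanked by
groove tracking merge into it, and groove-tracking events shorter than
0.5 ns become hops. 1D intervals below the minimum are folded into the 3D
label so every frame carries exactly one label. A hop's span is the Z
difference between its last and first frame (signed stored, magnitude
reported). Flips of a dimer are order inversions of the two regions' Z
that persist for a debounce window (10 frames). The hopping frequency is
normalized by the total 1D time; the per-total-time variant is reported
alongside because the normalization is a genuine ambiguity.

## Diffusion metrics

Time-averaged MSDs of `Z` (A^2) and unwrapped `phi` (rad^2) are fitted over
a lag window of 50-200 frames (2.5-10 us at the 50 ns frame clock); `D` and
`D_r` are half the slope, converted to um^2/s and rad^2/s. The pitch is
`p = 2 pi sqrt(D / D_r)` (reported in A and in bp at 3.32 A/bp) and the
hopping-augmented coefficient is `D_1D = D_helix + x_hop^2 k_hop / 2` with
`x_hop` in A and `k_hop` in 1/ms. Both forms reproduce the studied system's
printed 0.03 M estimate (0.040 um^2/s) exactly; at 0.02 M the printed
inputs (9.4 bp, 3.24 /ms) give 0.0184 um^2/s, i.e. the rounded inputs carry
the printed 0.019 only to its first significant figure. The hopping
speed-up `D_1D / D_helix` at 0.02 M is 7.1-fold.

Faithful unwrapping of `phi` requires frames finer than the azimuthal
decorrelation time; at desk scale (small binder, underdamped hinge motion)
this means ~1 ns frames. With coarser frames a transiently detached domain
turns bounded azimuthal wobble into a spurious random walk of the unwrapped
angle and inflates `D_r`.

MSDs can optionally be restricted to contiguous associated stretches
(`bound_only`), so 3D excursions — which the event analysis treats
separately — do not contaminate the 1D transport estimate. The association
cut should match the system's sliding distance: the full-length repressor
slides with its recognition-helix COM at d ~ 20-30 A (hence the 32 A 1D/3D
cutoff), while the toy binder slides at d ~ 8-12 A, so its desk-scale salt
scans use d <= 15 A (sliding distance plus margin). Frames at d 15-32 A
for the toy are loitering near the DNA rather than translocating, and
including them buries the salt trends of D and pitch in drift noise.

## Synthetic systems

The generators are pure functions of (parameters, seed) and stand in for
the study's reference structures so the whole pipeline runs without
downloads.

- Ideal B-DNA: beads on regular helices (3.32 A rise, 36 deg/bp so the
  repeat is exactly 10 bp, matching the groove-tracking signature of
  interest; the crystallographic 34.3 deg/bp is a parameter away).
  Radii: phosphate 9.4 A, sugar 7.4 A, base 4.5 A; azimuths spiral inward
  from the phosphate (+-110 deg about the major-groove center) through the
  sugar (+-75 deg) to the base (+-35 deg). The base placement reflects
  base-pair centers sitting 4-5 A off-axis and, together with the spiral,
  fills the duplex core: without it the groove center line is an empty
  helical canyon that a small binder can penetrate to the axis, where the
  azimuth becomes ill-conditioned.
- Bent DNA: two ideal arms joined at a chosen base pair with a given
  inter-axis angle (bending away from the canonical binder pose), plus a
  slight outward displacement of the convex-side junction phosphates as a
  minor-groove-widening mimic. `bend_angle = 0` is bit-identical to the
  straight generator.
- Toy binder: a schematic dimeric groove binder, not a fold. Each monomer
  has an 8-residue recognition ladder that follows the groove line
  (two rails at 9.5/12.5 A from the axis, six +1 Lys on the rails facing
  the DNA), a 4-residue hinge, and a compact helix-like core; the dimer is
  a 2-fold rotation about the y-axis so the two ladders sit one helical
  turn apart on the same groove line. The ladder is triangulated with
  stiff (i,i+2)/(i,i+3) brace bonds so it behaves as the rigid folded
  element it mimics; without bracing it would crumple into the grooves.
  Native contacts use a 7 A Calpha-Calpha cutoff (appropriate for CA-only
  geometry). The `search` variant scales hinge dihedrals and hinge
  contacts by f = 0 (fully free), the `recognition` variant keeps them
  stiff — mirroring the flexible-vs-helical hinge contrast the model is
  built to probe.
- Oracle traces: (Z, d, phi) series assembled from a segment plan with
  known labels; groove segments obey the groove relation with
  sub-tolerance noise, hops decouple the azimuth (half a turn off center),
  3D segments sit beyond R_c. Ground-truth labels incorporate the two
  smoothing rules, so classifier recovery can be asserted exactly.

What the toy system does **not** emulate: real protein shape and charge
distribution, sequence effects, DNA elasticity, hydrodynamics, or the
absolute magnitudes of diffusion coefficients (the toy binder is ~100x
lighter and faster than the full-length dimeric repressor). Passing the
desk-scale tests therefore demonstrates the correctness of the machinery
and the qualitative physics (rotation-coupled sliding near the 10-bp
repeat at low salt; faster, less coupled diffusion as screening
increases), not the study's absolute numbers.

## Desk and cluster presets

The desk preset runs the toy dimer on 30-bp DNA in a reduced box
(x, y +-60 A, z +-45 A so the binder cannot slide past the duplex ends),
6e5 steps per replica, frames every 20 steps (1 ns), two replicas per salt
at {0.01, 0.02, 0.04} M, MSD window 250-1000 frames (0.25-1 us); the
salt-scan acceptance check uses six replicas per salt. These sizes keep a
full grid under ten minutes on one core. The cluster preset
records the full study conditions (100-bp DNA, the full box, 1e8 steps,
eight replicas, salts 0.01-0.06 M) for batch execution; reproducing the
study's absolute values (e.g. D_helix = 0.0026 um^2/s, 370 us groove
tracking, k_hop = 3.24 /ms at 0.02 M) additionally requires the
crystal/NMR-derived protein models, which users must supply.

## Configuration file

`grooveslide simulate --config run.yaml` accepts a YAML document with two
optional mappings, `simulation` (fields of `SimulationConfig`: `n_steps`,
`dt`, `gamma`, `kBT`, `seed`, `save_interval`, `box`, `rigid_dna`,
`record_beads`, `step_ps`) and `forcefield` (fields of `ForceFieldParams`:
`ionic_strength`, `eps`, `k_bond`, ..., `dihedral_form`,
`elec_cutoff_debye`). Every force-field constant is a named default there,
never hard-coded at call sites.

## Known limitations

- The toy binder's pitch and diffusion estimates are stochastic; two
  replicas per salt give a reliable ordering of conditions but ~10-20%
  scatter on individual values.
- The minor-groove side of the schematic duplex is shallower than real
  B-DNA; a binder can occasionally sample it, which the classifier counts
  as hopping (offset ~5 bp from the major-groove center).
- Occupancy and alignment thresholds for encounter statistics (contact
  formed below 1.2 x A_ij; alignment half-width 2 bp) are defaults for
  unspecified quantities and are exposed as parameters; occupancies are
  worth reporting at 1.1/1.2/1.5 when comparing conditions.
- Trajectories are plain-text XYZ with a JSON sidecar; there is no binary
  trajectory export.
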