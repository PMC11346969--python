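# Methods

## The structure-based potential

The forcefield is an all-heavy-atom structure-based ("Gō"-type) model:
every bonded internal coordinate is harmonic (or, for proper dihedrals,
a `[1−cos] + ½[1−cos 3·]` well) about its value in the reference
structure, native contacts are 12-6 wells whose width σ_ij equals the
reference pair distance, and everything else repels as ε_NC(σ_NC/r)¹².
The reference structure is therefore the exact global minimum: at the
reference coordinates every bonded term is zero and the contact sum is
−Σ ε_C, which the tests assert to 10⁻⁹ relative.

Reduced units throughout: energies in ε₀ = 1, Boltzmann constant 1,
temperature in units of ε, lengths in Å, and one reduced time unit
(t_ru) calibrated at ≈ 1 ns.  Fixed strengths: ε_r = 50, ε_θ = 40,
ε_χi = 10, ε_χp = 40, ε_NC = 0.1, σ_NC = 2.5 Å, contact cutoff 4 Å
between heavy atoms.

**Dihedral strengths.** ε_BB and ε_SC are not fixed constants of the
model family; this implementation uses the standard normalisation for
such models: the total dihedral strength is half the total (unscaled)
contact strength, split so each backbone dihedral is twice as strong as
each sidechain dihedral.  The resolved values are recorded in the
header of every serialised forcefield file.

**Contact enumeration and exclusions.** Contacts are heavy-atom pairs
within 4 Å, excluding pairs inside one residue, pairs in
sequence-adjacent residues of the same chain, and pairs already
appearing in a bonded term.  Excluded volume applies to every remaining
heavy-atom pair.  `find_contacts` is verified against an O(N²)
brute-force oracle with identical exclusions.

**Group rescaling.** Contact depths are multiplied by group-pair
factors reflecting the translocation setup: substrate(tRNA/mRNA)–
ribosome 0.6, SSU head–body 0.3, SSU–LSU 0.3 within 20 Å of the core
point (default: whole-complex centre of mass) and 0.1 outside, EF-G 0.6;
contacts within a group are unscaled.  Scaling is applied exactly once —
contact sets carry a `scaled` flag and a second application is an error.

**Multi-basin construction.** `merge_basins` appends the endpoint
conformation's unique contacts (width from the endpoint geometry,
depth ε₀ × a global weight multiplier, then group scaling); contacts
present in both conformations keep the starting-basin width so the
start remains a true minimum.  The weight multiplier is the single
knob that deepens the endpoint basin; the forward-swivel experiment
varies it over {1.0, 1.5, 2.0}.

**Degenerate geometry.** Angle and torsion terms whose *reference*
geometry is within 0.1 rad of collinear are dropped at build time:
their reference values are ill-defined and their gradients cusp-like,
which stalls minimisation and corrupts dynamics. This is the
"regularize" branch of the degenerate-geometry contract; the synthetic
generators also avoid building collinear strands in the first place.

## Dynamics

BAOAB Langevin integration with uniform unit masses (element masses
available by configuration), Maxwell–Boltzmann velocity initialisation
from the run seed, friction in inverse reduced time (default 1.0), no
periodic boundary.  One force evaluation per step; a numba-compiled
kernel evaluates the same terms as the readable numpy reference
implementation and the two are cross-checked to 10⁻¹⁰ in the tests.
Identical seed, config and forcefield replay bit-identically: all noise
is drawn from one `numpy` PCG64 generator in fixed-size blocks.

Correctness anchors: on a harmonic dimer at T = 0.5 the bond-length
variance matches T/ε_r = 0.01 Å² and the kinetic energy per degree of
freedom matches T/2 (checked to 10% and 5% over ≥10⁶ steps); at T = 0
the total energy decays monotonically.

Minimisation is iterative steepest descent (gradient direction) with
Barzilai–Borwein secant step lengths and an energy-decrease safeguard;
plain fixed-step descent stalls on the stiffness contrast between
ε_r = 50 bonds and 0.3-scaled interface contacts.

## Measurements

* **Swivel/tilt**: align the frame to the reference over the body core
  (Kabsch), take the residual head rotation (reference head onto the
  aligned frame head), and split it by quaternion swing–twist about the
  reference plane normal: the twist angle is the swivel (signed,
  positive in the translocation direction fixed by the plane-atom
  order), the swing magnitude is the tilt.  Pure-swivel and pure-tilt
  constructions are recovered exactly; composed rotations to ±0.2°.
* **Body rotation**: angle between the body plane normal in the
  reference and in the frame after aligning on the large-subunit core.
* **RMSF**: √⟨(r_i − ⟨r_i⟩)²⟩ per atom after per-frame alignment.  (The
  mean-squared form is sometimes written for this quantity; the square
  root is what "RMSF" plots show and what this package computes.)
* **Helical axis**: sliding windows of 4 consecutive backbone P atoms;
  the local axis direction comes from the double difference of
  successive bond vectors (exact for an ideal helix) and the axis point
  from an algebraic circle fit in the normal plane.  This is a
  deliberately simple, equivariant approximation to full helicoidal
  analysis (Curves+-style); it does not produce groove or base-pair
  step parameters.
* **Hinge localization**: Savitzky–Golay smoothing (window 5, order 2)
  followed by peaks of the discrete second derivative — the points
  where the displacement profile bends upward most sharply.  This one
  detector covers the V-vertex, two-basin and body-aligned
  knee/inflection readings of "hinge".
* **Landscapes**: 2-D histograms over two reaction coordinates;
  occupancy normalised to the modal bin; ΔG* = −ln P in units of kT
  with k_B T = 1 at the simulation temperature; empty bins are masked
  (NaN).  Default bin width 0.5 (degrees or Å).
* **Transit times**: first frame at which the swivel series reaches a
  destination threshold (PRE 0°, 10°, INT2 16°, INT3 22.6°, POST 0°
  for the reverse direction, 13° reverse intermediate); mean ± sample
  SD (n−1) across trajectories; non-reaching trajectories are flagged
  and excluded from the mean.  State labels use a ±1° hysteresis band
  to avoid chatter.  "Percent faster" is computed from the ratio of
  means with first-order error propagation.

## Synthetic fixtures: what they emulate, what they do not

`make_hinge_dumbbell` builds an 84-atom stand-in for the SSU
architecture: two 36-atom jittered-lattice plates ("body", "head";
lattice constant 3.6 Å so bonded and contact neighbours sit at the
same distance) joined by two zigzag hinge strands near the rotation
axis.  The endpoint conformation rotates the head rigidly by the
planted swivel (default 22.6°, the full forward-swivel endpoint) about
the measurement-plane normal, plus an optional tilt about an in-plane
axis — so angle round trips are exact by construction and any residual
is measurement error.  The plate rim re-registers onto neighbouring
lattice sites under the default swivel, giving the endpoint basin a
set of unique contacts for the weight multiplier to act on, while
contacts near the axis survive rotation and act as the pivot.

The forward-swivel experiment (`riboswivel.experiments`) runs 40 seeds
per weight at T = 0.5, friction 0.2 (underdamped, chosen for sampling
efficiency; the thermostat flavour does not enter the stationary
distribution), 10⁵ steps with frames every 500, and records the first
frame reaching 21° (~93% of the planted endpoint swivel, i.e. arrival
*into* the endpoint basin rather than a grazing touch).  Trajectories
that never arrive are censored at the horizon and counted at the
horizon frame in the reported mean; censoring counts are reported
alongside.  These problem sizes keep the whole experiment to a few
minutes; they are ~10⁵× smaller in aggregate than a production
translocation study, so the experiment demonstrates the *qualitative*
mechanism (deeper endpoint basin ⇒ faster forward swivel,
monotonically in the weight) and makes no quantitative contact with
ribosome transit times.

What the toys do **not** emulate: real rRNA sequence and secondary
structure, the tRNA/mRNA/EF-G ligands and their group scalings (the
dumbbell exercises only the head/body groups), solvent and ion
effects, and the ~2×10⁵-atom scale of the real complex.  Passing tests
show the machinery is correct and the two-basin mechanism behaves as
designed — not that variant ribosomes swivel faster.

`make_mini_duplex` / `make_kinked_duplex` provide ideal helices with a
known axis (straight along z, or two arms meeting at a chosen bend) for
the axis and hinge machinery.  `make_fastq_pools` plants variant
frequencies, flank sequences (defaults are non-periodic 10-mers so
flank self-overlap cannot shift the match), constant phred 38 with an
optional contamination rate of single low-quality bases, and writes the
expected enrichments to a truth table.  All generators are
bit-reproducible under a fixed seed.

## Enrichment conventions

Paired-end mates are processed independently and a variant is counted
once per read.  Phred encoding is Sanger (offset 33); `N` bases carry
phred 0 and always fail the filter inside the extracted span.  The
quality rule covers the flanks plus the variable region by default
(whole-read scope by configuration).  The first flank occurrence is
used; reverse-orientation search is off (directional library).
Variants absent from the input pool have undefined enrichment and are
flagged rather than ranked by a pseudo-count.

## Numerical choices and limitations

* PDB I/O goes through biotite; coordinates round-trip at the format's
  3-decimal precision; the highest-occupancy altloc conformer is kept.
* Kabsch superposition rejects <3 points and rank-deficient (collinear)
  point sets instead of silently returning an arbitrary rotation.
* Tilt is reported as the non-negative swing magnitude; the sign
  convention for swivel comes from the plane-atom order.
* Residue numbering follows the source file; measurement targets are
  resolved from explicit (chain, residue, atom) triples in a
  measurement config, never guessed from labels.
* The bonded-term enumeration derives from residue templates
  (ribonucleotides, amino acids, and the 3-atom synthetic residue);
  structures with other residue types need a template registered first.
* The integrator is not symplectic-exact at dt = 0.002 for the stiffest
  modes (ω dt ≈ 0.02); the equipartition checks bound the resulting
  bias well below the tolerances used.
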