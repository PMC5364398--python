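# Methods

This note records the models, conventions, defaults and numerical choices
behind `dntpore`, and what the synthetic-data validation does and does not
demonstrate.

## System and coordinate conventions

The package analyses a membrane-spanning DNA nanotube (DNT): six B-DNA
duplexes connected into a tube, inserted through a phosphatidylcholine (PC)
bilayer, optionally carrying rings ("bands") of ethylated backbone residues
that anchor the tube in the hydrophobic bilayer core.

* All internal lengths are nm and times ps; PDB input (Å) is converted on
  read.
* z is the bilayer normal. The origin z = 0 is the centre of mass of the
  lipid phosphate (PO4) particles, recomputed per frame, so analyses do not
  assume a centred or non-drifting input. Membrane-free systems fall back to
  the DNT centre of mass.
* Boxes are orthorhombic. Minimum-image displacements are applied inside
  distance computations; stored coordinates are never rewrapped.
* Particles and frames are 0-based internally; file formats keep their
  native 1-based serials on write.
* The analysis window is trailing: `analysis_window(traj, T)` keeps frames
  with t ≥ t_end − T, both endpoint frames included, so a span sampled every
  Δt yields T/Δt + 1 frames.

## Role dialects

Analyses address particles by semantic role (DNA backbone/base, ethyl,
lipid NC3/PO4/glycerol/sn1/sn2 tails, water, Na⁺, Cl⁻). A `RoleDialect`
maps `(residue name, atom name)` pairs to roles; two ship with the package
(`cg-martini`, `at-charmm-like`). Unknown names raise an error listing every
unmapped pair — silent misclassification would corrupt density profiles —
with an opt-in flag to map unknowns to `OTHER`. In the MARTINI POPC naming
the unsaturated "A" chain is sn-2 and the "B" chain sn-1; tail bead indices
become `tail_position` 1–4.

Probe radii for pore profiling are part of the dialect: 0.26 nm for regular
CG beads, 0.23 nm for the small bead class, and a per-element van-der-Waals
table for atomistic names. These are package defaults, chosen once.

## Tube model builder

The scaffold places `n_helices` parallel duplex axes on the vertices of a
regular hexagon of side `spacing_d` (default 2.0 nm; the hexagon circumradius
equals its side, so axes are also 2.0 nm from the tube centre). Each duplex
is one backbone pseudo-particle per nucleotide on an ideal B-DNA helical
path: radius 1.0 nm, rise 0.34 nm/bp, twist 34.3°/bp, 144° phase offset
between the two strands. With the defaults, adjacent duplex surfaces touch
(gap = d − 2r = 0) and the largest axis-centred sphere clearing all duplexes
has radius d − r = 1.0 nm — the open-lumen radius the pore profiler should
report for the ideal tube.

Groove assignment is geometric: the minor groove is the ±60° window about
the bisector of the 144° inter-strand gap, the major groove the remainder.
This rule is a declared convention; no analysis depends on sequence.

Hydrophobic band layouts (`1-ring`, `2-adjacent`, `2-distal`, `6-band`,
`7-band`, `full-coverage`) flag outward-facing backbone residues in axial
rings centred at tube mid-height (rings are 1 bp wide, 3 bp apart by
default; `2-distal` splits symmetrically, exact only to the half-bp
discretization). Flagged residues emit additional ETHYL beads offset 0.2 nm
radially outward.

The elastic-network specification connects residue pairs within a cutoff
inside each duplex, with rest lengths equal to build-time distances.
`soft` mode uses k = 100 kJ mol⁻¹ nm⁻²; `stiff` uses 1000 kJ mol⁻¹ nm⁻²
(the soft value is the literature one; the stiff default is this package's
choice). Junction restraints between duplexes are supplied as explicit
pairs — strand routing at the junctions is metadata, not sequence
bookkeeping.

## Synthetic data generator

The generator emulates the *statistical* structure of coarse-grained
simulations so that every analysis can be validated by parameter recovery;
it is not dynamics. Defaults mirror the simulated study conditions: an
18 × 18 × 25 nm box, two leaflets of templated 12-bead PC lipids
(NC3–PO4–GL1/GL2 plus two 4-bead tails), a six-duplex tube, NaCl
electrolyte, frames every 50 ps.

* **Thinning.** Leaflet phosphate separation follows
  h(r) = h0 − A·exp(−(r − r_wall)/λ) outside the tube wall, with defaults
  h0 = 4.0 nm, A = 0.8 nm, λ = 1.0 nm — an exponential stand-in for the
  observed local thinning (decaying to ~5 % by 3λ ≈ 2 nm from the wall).
* **Tail order.** Every tail bond makes the exact polar angle whose order
  parameter equals the target S (cos²θ = (2S+1)/3; default S = 0.5) with a
  random azimuth, so the generated S is exact up to thermal jitter.
* **Ions.** The lumen cylinder holds a deterministic cation:anion split
  realising the requested ratio (default 14); the bulk holds neutral Na/Cl
  pairs, so any net asymmetry is the lumen's.
* **Dynamics stand-ins.** Frames add i.i.d. Gaussian jitter (default
  0.05 nm) to the rigid template; tube tilt may fluctuate per frame. SMD
  traces are entry/exit Gaussian force bumps (centred where the pulled COM
  crosses the bilayer faces, width 1 nm in COM-z) over a COM advancing at
  10 nm μs⁻¹, plus white noise. Displacement traces decay exponentially with
  time constant `relax_time/3` (relax) or drift with superimposed diffusion
  (exit). Residence fixtures draw bound/unbound durations from exponentials
  per bead kind and groove.

Everything is driven by one seed; identical parameters and seed give
bit-identical trajectories, and every generated parameter is recorded in a
ground-truth mapping.

**What recovery tests show.** Passing recovery proves the estimators are
correct and unbiased under known geometry, leaflet separation, orientational
order and composition. It does not validate behaviour absent from the
generator: lipid flip-flop and exchange, water structure, electrostatics,
correlated fluctuations, or non-exponential thinning shapes.

## Membrane profiles

* **Pore axis.** The axis direction is the gyration-tensor eigenvector of
  *all* DNT particles whose eigenvalue is most separated from the other two
  (the tube is rotationally symmetric, so this is the symmetry axis whether
  the tube is prolate or squat; restricting a tilted tube to a horizontal
  z-slab would shear the segment and bias the tensor, which is why the
  direction uses the whole tube). The anchor is the COM of the DNT particles
  inside the transmembrane z-window (default ±2 nm). Planar or isotropic
  particle sets raise a degenerate-axis error.
* **Radial densities.** Cylindrical shells 0.1 nm wide and 4 nm long
  (approximately the membrane thickness) around the pore axis; density is
  count/(π(r₂²−r₁²)L) averaged over frames, so Σ density·volume equals the
  mean in-cylinder count exactly — asserted on every run.
* **Thickness.** Upper minus lower leaflet mean phosphate z per shell,
  leaflets split by the per-frame phosphate median plane (flip-flop not
  modelled). Shells missing a leaflet in a frame contribute nothing; never-
  populated shells are NaN, not zero. The alternative nearest-neighbour P–P
  pairing was considered and rejected as noisier at these bead densities.
* **Order parameter.** S = ⟨(3cos²θ−1)/2⟩ over consecutive-tail-bead bond
  vectors versus z, binned on 1 × 1 nm² xy cells at each lipid's phosphate
  xy position. Cells with fewer than 10 bond samples are reported missing
  to avoid noise-dominated estimates.
* **RDF.** Standard minimum-image pair histogram normalised by the ideal-gas
  shell count at the box density of the second set, self-pairs excluded.
* **Ion selectivity.** Time-averaged Na⁺ and Cl⁻ counts inside the lumen
  cylinder (by convention: radius = time-averaged minimum pore radius,
  axial extent = tube length), reported with a binomial 95 % CI on the
  pooled counts; a zero anion count reports an infinite ratio with counts
  attached.

## Pore profiling and conductance

At each z along the axis the profiler maximises the clearance
min_i(|c − pᵢ| − rᵢ) over in-plane sphere centres c (largest inscribed
sphere, HOLE-style). Water and ions are excluded by default; remaining
particles use their dialect probe radii, plus an optional extra probe
radius.

The optimiser is simulated-annealing Monte Carlo: 1000 moves per slice,
proposal step cooling geometrically 0.1 → 0.01 nm with the Metropolis
temperature tied to the step, a fixed per-(frame, slice) seed for
reproducibility, followed by a deterministic pattern-search polish
(8 directions, shrinking steps 0.05 → 0.002 nm, budget-capped). When a
`search_extent` is given, a coarse 0.1 nm grid over that square first ranks
candidate basins and the best few well-separated ones are polished — this
makes the search global over the extent and is what the exhaustive-grid
equivalence tests exercise. Slice centres chain along z (each slice seeded
from its neighbour's centre, HOLE-like) with an independent axis restart
every 10 slices to escape side channels.

Radii are capped at half the smaller lateral box length; capped slices are
flagged open and excluded from means and conductance. Positions are
transformed into axis coordinates per frame, so profiles are invariant
under rigid rotation of the whole system.

Conductance uses the ohmic pore model. `uniform` mode: g = πR²/(ρL) with R
the window-mean radius. `series_integral` mode: 1/g = (ρ/π)·∫dz/R(z)²
evaluated trapezoidally (stable under dz refinement); any zero-radius slice
closes the pore (g = 0 with the closing z flagged). Bundled resistivities:
ρ(KCl 1.0 M) = 8.9 Ω·cm, ρ(KCl 0.3 M) = 27.4 Ω·cm,
ρ(NaCl 0.15 M) = 62 Ω·cm — overridable; the conductivity-proportional-to-
concentration idealisation underlies the 1.0 M/0.3 M ratio of 3.3.

## Dynamics analyses

* **Residence times.** A contact event is a maximal run of frames with the
  bead's minimum distance to the DNA selection ≤ 0.5 nm; runs separated by
  ≤ `gap_tolerance` frames merge. Events are labelled by the groove of the
  nearest DNA particle at first contact. "Perturbed lipids" are defined
  operationally as beads with ≥ 1 event in the window. Discretisation
  truncates each event by up to one frame interval, and the window censors
  long events; recovery tests therefore check orderings (sn2 > sn1), not
  absolute means.
* **Tilt.** Acute angle between the pore axis and z, invariant under axis
  flip; histogrammed in 1° bins.
* **COM displacement.** Δz(t) = group COM minus bilayer COM along z.
  Classification: *relaxed* if |Δz| enters the ±0.3 nm band and stays to
  the end (relaxation time = first frame of the terminal in-band run);
  *exited* if |Δz| exceeds the exit threshold (default: bilayer
  half-thickness + group half-extent + 1 nm) and does not come back;
  otherwise *undecided*. Note that with a 0.3 nm band a trace started at
  small Δz₀ enters the band well before the nominal relaxation time — the
  classification topology, not the absolute time, is the meaningful output.
* **SMD barriers.** The force is smoothed by a centred 5 ns running mean.
  Windows are delimited by the pulled COM crossing the bilayer boundaries:
  the entry window ends at the bilayer centre (containing the full entry
  peak), the exit window starts at the far boundary, past the transmembrane
  plateau and clear of the entry peak's tail. The barrier location is found
  on a 4× more heavily smoothed trace and the height read from the lightly
  smoothed trace at that location; reading at a noise-independent location
  removes the upward bias of taking the maximum of a noisy curve (verified
  unbiased within 2 SE over 20 noisy traces).
* **Force conversion.** 1 kJ mol⁻¹ nm⁻¹ = 10³/(N_A·10⁻²¹) ≈ 1.66054 pN.
* **Partitioned r.m.s.d.** One least-squares (Kabsch) superposition over
  all DNT particles per frame; r.m.s.d. reported separately for particles
  inside and outside the reference transmembrane window. Per-partition fits
  were rejected so the two series share one frame of reference.
* **Membrane deformation.** Per leaflet and lateral x-bin, the COM z of
  lipid particles, sampled at a configurable interval (4 ns matches the
  published presentation); empty bins are NaN.

## Pipeline and reproducibility

`run_pipeline` validates its config against a known-key schema (unknown
keys are rejected), executes stages in order, and writes CSVs (with units
and a config hash in a header comment) plus a manifest holding the config
hash, package version, seed, per-stage wall times and collected warnings.
Identical config + seed reproduces outputs bit for bit; a failing stage
aborts with the stage name, leaving partial outputs and a FAILED marker.

## Problem sizes used in validation

The test suite and acceptance script run desk-scale versions of each
analysis: synthetic systems of 120–400 lipids per leaflet and 3–12 frames,
SMD traces of 2.5 μs at 100 ps sampling, 20-seed Monte-Carlo checks, and
pore profiles over a ±2 nm transmembrane window at dz = 0.2 nm. These sizes
were chosen as the smallest at which the statistical tolerances above are
meaningful.

## Known limitations

* The generator's lipids are rigid templates; no dynamics, electrostatics
  or water structure. Quantities that require microsecond MD (absolute
  barrier heights, real lumen selectivity, real thinning extent) are
  validated only as *recoverable parameters*, not predicted.
* Orthorhombic boxes only; no triclinic support.
* Leaflet assignment by median plane fails for heavily curved or porated
  membranes.
* Conductance omits access resistance and electric-field (PNP/BD)
  transport; it is the geometric ohmic estimate only.
* Atomistic tail `tail_position` assignment relies on a CHARMM-like naming
  heuristic (trailing digits of C2x/C3x names).
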