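# Model and methods

`phagepack` simulates the packaging and ejection of a viral genome,
coarse-grained as a bead-spring polymer, through the pore of a rigid
spherical capsid, with an explicit particle-based (stochastic rotation
dynamics, SRD) solvent.  This note records the model, the parameter
choices, the numerical decisions, and what the package's tests do and do
not demonstrate.

## Polymer model

The chain is N beads of diameter sigma and mass m (both 1 in reduced
units), connected by FENE springs

    U_FENE(r) = -1/2 k R0^2 ln(1 - (r/R0)^2),   k = 30 eps/sigma^2, R0 = 1.5 sigma,

with excluded volume from a purely repulsive truncated-and-shifted
Lennard-Jones potential (cutoff 2^(1/6) sigma, shifted to zero there;
good-solvent conditions).  Bonded pairs are included in the
excluded-volume sum — the standard Kremer–Grest convention — which places
the equilibrium bond length at b ~ 0.97 sigma.  Bending rigidity

    U_bend = kappa (1 - cos theta)

acts on every interior joint.  The default kappa = 10.8 eps is calibrated
(see below) so that the free chain's persistence length is 10 sigma at
T* = 1.  For a charged chain, every bead pair within the cutoff also
interacts through a screened Coulomb (Debye–Hückel) potential

    U_el(r) = T* A exp(-r / lambda_D) / r,   lambda_D = 0.75 sigma,

truncated at 4 lambda_D = 3 sigma.  Writing the prefactor proportional to
T* makes electrostatic forces grow with temperature at fixed screening —
the coupling that drives the charged chain's temperature phenomenology
(packing harder, ejection faster at high T*).  The prefactor A lumps the
Bjerrum length and the squared effective bead charge into a single
effective coupling, set by calibration (below).

## Units

sigma = eps = m = 1; tau = sigma sqrt(m/eps); T* = k_B T / eps with
T* = 1 at 37 degC.  Physical anchors: one force unit = 1.6 pN, the capsid
radius 3.02 sigma = 7.5 nm (so sigma = 2.48 nm, nominally the 2.5 nm
double-helix diameter), eps = k_B T(37 degC) = 4.28 pN nm.  Note the
force anchor is quoted independently; eps/sigma = 1.72 pN differs from it
by ~8% and the package always uses the quoted 1.6 pN for forces.  The
MD-step-to-nanosecond mapping depends on the solvent viscosity and is
exposed only as a nominal, clearly labelled constant.

## Capsid, pore, tail, motor

The capsid is a sphere of radius R = 3.02 sigma centred at the origin,
felt by beads only (the solvent passes freely).  The wall is a linear
repulsive shell of half-width 0.5 sigma and stiffness 400 eps/sigma^2
acting on both sides of the surface: the maximum wall force (200) exceeds
every systematic force in the model (motor 80), so beads cannot be driven
through the wall.  The wall is evaluated at bead centers and additionally
at every bond midpoint (force split between the bond's endpoints):
because a bond can be longer (up to R0 = 1.5 sigma) than the shell is
thick (1 sigma), two beads can otherwise bracket the wall with neither
feeling it, leaving the bond threaded through the capsid — a mechanically
stable, unphysical trap that deadlocks runs.  The midpoint term makes any
crossing unstable.  A cylindrical channel of radius 0.6 sigma along +z
through the shell forms the pore ("one bead at a time"); inside the
channel the radial wall is replaced by a centering force
(300 eps/sigma^2 times the off-axis distance) that keeps the
translocating bead on the axis — without it, chain tension drags channel
beads sideways across the channel boundary, seeding the same threading
topology.  The centering stiffness is set so the sideways exit barrier
exceeds motor-scale tension.

The optional tail is a cylinder of length 6 sigma and radius 0.7 sigma on
the pore axis.  A bead within its axial extent and within sigma/2 of its
wall — on either side, out to radius + sigma/2 — is pulled toward the
axis with force proportional to its distance beyond ``radius - sigma/2``.
This one-sided retention both confines the filing chain and actively
guides a segment arriving at the tube onto its axis; with a plain
two-sided wall instead, the sharp bend the outside coil must make at the
tail tip is an absolute barrier and tail feeding deadlocks at realistic
forces.  The default retention stiffness is 30 eps/sigma^2 (strong enough
to hold the file, gentle enough that a coil bead drifting into the
capture shell is reeled in without slamming into the filed column).

The motor is a constant force of 80 units (128 pN) on every bead within
the capture sphere (radius 1.5 sigma) around the pore mouth.  A captured
bead already inside the capsid is pulled toward the capsid center; a
captured bead still outside is pulled toward the mouth — along the wall
surface if it sits beside the opening, down into the pore once over it.
All rules coincide (force along the inward pore axis) for a bead at the
mouth.  Two geometry defaults differ from the most literal reading of the
model sketch, both config-exposed:

* capture radius 1.5 sigma, not 1.0: with a 1.0-sigma capture sphere and
  ~0.97-sigma bonds, the bead following a captured one sits just outside
  the capture region and packing stalls in ~10^5-step stretches waiting
  for diffusion (a dead zone the real motor, which grips the polymer
  continuously, does not have); it also leaves a single captured bead to
  drag the whole tail-filed column, which deadlocks tail feeding;
* the toward-the-mouth feed direction for outside beads: a purely
  center-directed force on a bead captured beside the opening is exactly
  opposed by the wall normal, pinning it against the shell (and pumping
  energy through the force discontinuities) instead of feeding it.

## SRD solvent

Point particles of mass 1/gamma fill a periodic cube (edge 16 sigma at
full scale), gamma = 5 per cell, cell size a = 1 sigma.  Every
Delta t_SRD = 20 MD steps the solvent streams ballistically and one
collision step rotates every particle's velocity — solvent and beads
together, mass-weighted — by 130 degrees about a random per-cell axis
around the cell's center-of-mass velocity, after a random grid shift
(Galilean invariance).  Collisions conserve momentum and kinetic energy
per cell exactly; beads couple to the fluid only through them.  With
hydrodynamics off, every solvent velocity is redrawn from the
Maxwell–Boltzmann distribution after each collision, erasing the
correlations that transmit hydrodynamic interactions while leaving all
equilibrium statistics unchanged.  Parameters follow standard practice
for this solvent.  Polymer beads
are wrapped into the periodic box for cell assignment only; their
dynamics use absolute coordinates.

Temperature control: the solvent is initialized at exactly T*.  Pure SRD
conserves energy, but the motor performs of order 80 * 2N eps of work per
packing run — comparable to the bath's kinetic energy at tractable box
sizes — so by default a gentle Berendsen rescale of the solvent velocity
fluctuations (time constant 10 collisions, momentum-conserving) drains
that heat each collision step.  `thermostat: none` recovers the strictly
conservative scheme and is used by the conservation tests.

## Integration

Velocity Verlet at dt = 0.005 tau for the beads, interleaved with the
SRD schedule above (a fused compiled loop; a pure-NumPy reference path is
tested against it).  With conservative forces only, the total energy
shows no secular drift: it oscillates in a bounded band (~3e-4 relative
for a 20-bead chain), and the fitted linear trend over 1e4 steps is below
1e-4 relative — the symplectic-integrator sense in which "drift" is
asserted by the tests.  All randomness flows from one
`numpy.random.Generator` per replicate; replicate seeds derive from the
master seed via `SeedSequence.spawn`.  Runs are bit-for-bit reproducible
for a fixed (config, seed, build).

## Protocols

Packing: bead 1 is placed just inside the pore, the rest threaded
single-file out through the pore (and tail) and continued as a
Boltzmann-statistics coil; the system equilibrates with bead 1 pinned and
the motor off, then the motor switches on until all N beads are inside
the capsid or the step budget (`max_steps`) runs out ("timeout", mirrored
by the spike at the budget edge in ejection-time histograms).

Ejection: from a fully packed state, the chain end nearest the pore is
pulled out by a slow steered extraction (0.06-sigma displacements of the
pinned end bead followed by short relaxations) to just outside the pore —
or outside the tail mouth, when present, with the trailing beads
necessarily filing through the tail: a 6-sigma tail cannot be jumped by a
1.5-sigma-max bond — then re-equilibrated with that bead pinned, and
released with the motor off until capsid and tail are empty.  Packed
initial states are produced by running packing first, at T* = 1.0
regardless of the ejection temperature: packing of the charged chain does
not complete at high T*, so a common, reliable preparation temperature is
used for all ejection conditions.  Thermal re-entry through the pore is
allowed (no ratchet).

Ensembles: independent replicates with derived seeds; mean +/- SEM
occupancy curves on the union time grid with last observation carried
forward (a completed packing run contributes N thereafter; a completed
ejection run 0); event-time lists report completed runs, with timeouts
kept as an explicit terminal bin.

## Calibrations

Bending constant: `calibrate_bending_rigidity` bisects kappa, measuring
the persistence length at each iterate from free-chain Langevin sampling
(equilibrium conformational statistics do not depend on solvent dynamics,
so no SRD bath is needed).  The fit is weighted log-linear least squares
of <cos theta(s)> over s in [1, 15] bonds (weights corr * sqrt(n_pairs),
i.e. inverse variance of log corr), which keeps the estimator from being
dominated by the noisy large-s tail.  Sampling uses many short
independent trajectories, each started from an exact Boltzmann draw of
the ideal worm-like chain (inverse-CDF of exp(kappa cos theta / T*)) with
clashes rejected: orientational decorrelation within one trajectory takes
~1.4e4 MD steps, so independent starts are much cheaper than one long
run.  The calibrated default is
kappa = 10.8 eps; re-measuring l_p with it reproduces the 10-sigma target
within a few percent (the acceptance suite performs this measurement).  The single-joint check against the
exact average coth(kappa/T*) - T*/kappa is meaningful with excluded
volume on because at this stiffness the 1-3 distance never comes inside
the WCA cutoff.

Charge prefactor: A is calibrated against the qualitative criterion that
tailless charged packing completes reliably at T* = 1.0 but is frustrated
at T* = 1.2.  The default (A = 12) is the value at which the charged
chain shows the full qualitative phenomenology at the package's scaled
reference conditions; the frustration comparison itself uses A = 24
(below), where the stall onset is sharp.

## Scaled-down study conditions

The full-size experiments (N = 100, R = 3.02 sigma, box 16 sigma, 100
replicates, ~2e6-step budgets) are cluster-scale.  The package's
qualitative-ordering tests (tests/study.py) run a scaled system chosen to
preserve the physics that drives each ordering:

* N = 40 beads, box 12 sigma, dt = 0.004 tau, 8-10 replicates with
  paired seeds, 3e4-step equilibration;
* capsid radius 2.25 sigma, preserving the packing fraction
  (40 / (8 * 2.25^3) = 0.44 ~ the full-scale 0.45): electrostatic and
  entropic frustration near full packing — the mechanism behind the
  temperature effects — scales with the packing fraction, not the bead
  count;
* tail geometry unchanged (6 x 0.7 sigma);
* per-comparison motor forces.  At N = 40 the 80-unit motor overwhelms
  every free-energy difference (the chain feeds in one continuous pull),
  so each comparison uses a drive scaled to keep its mechanism
  rate-limiting, as it is at full scale: the neutral tail-vs-tailless
  pair runs at motor 12 (entropy-limited feed), the standard comparisons
  at motor 20, and the electrostatic-frustration pair at motor 20 with
  A = 24 (stall onset between T* = 1.0 and 1.2);
* ejection initial states are prepared once per replicate seed and shared
  across the ejection conditions that start from them (paired seeds), a
  variance-reduction choice that leaves the compared conditions identical
  except for the variable under test;
* comparisons use trajectory-averaged statistics (mean completion times
  with timeouts at the budget; paired per-replicate slowness areas for
  the hydrodynamics contrast), which are far less noisy than single
  event times at this scale.

What passing these tests shows: the implementation reproduces the
direction of each reported effect (temperature orderings for packing and
ejection, tail speedup of packing, tail slowdown of ejection,
hydrodynamics dependence, tail-induced interior ordering) under the
scaled conditions.  What they do not show: quantitative agreement with
the full-scale curves, which no desk-scale run can provide.

The synthetic-data layer of this package is the protocol module itself
(all inputs are generated programmatically); it emulates the study's
initial conditions, not any external data set.

## Known limitations

* No torsional/twist energy (its effect on packing free energy is small),
  no explicit counterions, no friction model for the pore, no
  temperature-dependent pore conformations.
* Geometry forces act on bead centers; the wall/channel construction
  above prevents bond-through-wall topologies by design rather than by
  bond-wall collision detection.
* The outside coil can extend beyond the periodic solvent box; beads are
  folded into the box for collision bookkeeping, so hydrodynamic
  correlations for far-outside segments are approximate.
* The Berendsen thermostat acts on the solvent only; driven beads run
  slightly warm (a few percent at default settings) during packing.
* Event-time distributions at reduced scale are wide and bimodal (an
  initially-threaded chain can feed in one pull), so ordering tests
  compare seed-averaged means over matched seeds.
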