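# Methods

This note documents the models, conventions and numerical choices behind
`lidmap`, and what the synthetic fixtures do and do not establish about real
trajectories.

## Geometry and units

Coordinates and cutoffs are in Å everywhere; file-native nm (GRO, XTC) is
converted at the I/O boundary.  Only orthorhombic boxes are supported —
bilayer slabs are the target geometry — and triclinic input is rejected with
an explicit error.  All distance cutoffs are inclusive (≤), and periodic
distances use the minimum-image convention applied per axis.

Bead roles are resolved by name with a shipped Martini-style default table
(BB → protein backbone, SC\* → side chain, NC3/PO4/inositol-phosphate beads →
head group, GL1/GL2 → glycerol linker, C\*A/C\*B/D\*A → acyl chain, W → solvent,
NA/CL → ion); a user-supplied species → {name → role} table overrides the
defaults, and an unresolvable name is an error naming the bead.  Residue
numbering from input files is preserved verbatim (author numbering), with
0-based bead indices internally.

## Contacts

A residue–species contact exists in a frame when any bead of the requested
lipid part (head, acyl, or either) belonging to that species lies within the
cutoff (default 7 Å) of a backbone bead of the residue.  Contacts are counted
once per residue–species–frame, never per lipid molecule, so the profile is a
fraction of simulation time in [0, 1].  "any" is defined as the union of the
head and acyl bead sets, which makes `fraction(any)` exactly the per-frame
union of head/acyl contact events (a tested identity).  An equilibration
offset (default 0 frames) discards the start of the trajectory before
averaging.

The membrane-bound flag is a declared convention, since "bound" has no unique
definition: a frame is raw-bound when ≥ `min_residues` (default 5) residues
have a head-group contact, and the flag is debounced by a run-length state
machine — a run of ≥ `dwell_frames` (default 5) consecutive raw-bound frames
switches the state to bound from the start of that run, and symmetrically for
leaving.  All three parameters are config-exposed and echoed in output
headers.  Bound fraction can be reported against total time or against bound
time (state populations use the latter); callers choose the normalisation.

## Density and enrichment maps

Maps are 2D (xy) histograms of one reference bead per lipid (default PO4) on
a grid of ~1 Å bins tiling the box footprint exactly (bin width is the box
length divided by the rounded bin count, so the grid always covers the box).
Beads are wrapped into the box before binning, which makes the conservation
law exact: grid sum × n_frames = bead observations.  Optional centering
translates each frame so a selection's xy centre of geometry sits at the box
centre (with wrapping) before binning; because the original analyses do not
state whether maps were protein-centred, the centering mode is always
recorded in the map's metadata sidecar.

Enrichment is E = 100·(ρ − ρ̄)/ρ̄ with ρ̄ the mean over the full footprint (an
option restricts ρ̄ to observed bins); the output mean is zero by
construction.  Maps from independent realizations with identical grids can be
averaged before the enrichment transform.

## RMSF

Each frame is superposed by a least-squares (Kabsch) rotation+translation of
the alignment selection; the mean structure is built from a first pass
aligned on frame 0, then all frames are re-aligned onto that mean and
RMSF(r) is the root time-mean squared displacement of the residue's backbone
bead about its time-mean position.  Collinear alignment selections are
rejected (the rotation is underdetermined).  The default alignment set is all
backbone beads; for anchored proteins the transmembrane segment is the
natural choice and can be passed explicitly.

## Orientation states

The rigid domain's pose is reduced to where the inward membrane normal (from
the lower leaflet toward the protein side, i.e. −z in the intracellular
geometry used throughout) pierces the domain's unit sphere: with R the
Kabsch rotation mapping the reference selection onto the frame, the normal in
body axes is v = B·Rᵀn̂, giving latitude 90° − arccos(v_z) and longitude
atan2(v_y, v_x).

Body axes default to the principal axes of the reference selection (sign
fixed deterministically: first axis toward the highest-index bead's
hemisphere, second toward the lowest-index bead's, third completing the
right-handed triad); user axes override.  Note one consequence of the
definition that is easy to get backwards: spinning the whole frame about the
*world* normal changes neither angle (the piercing point lies on the rotation
axis), whereas spinning about the *body* polar axis shifts longitude only.
Both behaviours are tested.

State extraction smooths the (longitude, latitude) population histogram of
bound frames with a Gaussian (default σ = 10°, periodic in longitude,
reflected in latitude; the grid is not area-weighted, an acceptable bias away
from the poles where states of interest lie).  Local maxima closer together
than the assignment radius (default 30°) merge, the stronger peak winning and
exact ties keeping the lower flat bin index.  Bound frames are assigned to
the nearest surviving peak within the radius by great-circle distance
(correct near the poles, unlike Euclidean angle differences); peaks whose
population falls below `min_peak_mass` (default 0.02) are dropped and their
frames reassigned among the survivors.  States are numbered by descending
population; populations plus unassigned mass sum to 1 over bound frames, and
zero states is a valid outcome.  Representative frames minimise the angular
distance to the state centre, ties to the smallest frame index.

## Experimental analyses

* CSP: √(ΔδH² + (α·ΔδN)²) with the standard amide ¹⁵N scaling α = 0.154
  (config-exposed); residues unobserved in either table are omitted and
  listed.
* Intensity ratios I/I₀ per titration point; peaks that disappear relative to
  the reference are reported as ratio 0 with a vanished flag.  Ratios are
  invariant to a global spectrometer gain.
* SCS: observed minus random-coil shift; the random-coil table is an input
  (pre-corrected for pH/temperature), no neighbour correction is applied.
* R₂: joint least-squares fit of I(t) = I₀·e^(−R₂t) over all replicates,
  initialised from a log-space linear regression on positive intensities and
  refined by nonlinear least squares (tolerances 1e-12); standard errors from
  the fit curvature; a negative fitted rate is flagged, not raised; an exactly
  constant curve returns R₂ = 0.
* NMR–contact correlation: Pearson r over residues shared between a
  per-residue series and a contact column, two-sided p from the t transform
  with n−2 degrees of freedom, R² = r² by definition.  The correlation is
  computed on whatever series the caller supplies; using I/I₀ gives the
  negative-r convention (signal falls where contacts are frequent), using
  ΔI = 1 − I/I₀ flips the sign.  The selector (series kind, species, part) is
  recorded in the result.
* MRE: [θ]_MRW = θ_mdeg·MRW/(10·l_cm·c_mg/mL) with MRW = M/(N_res − 1);
  difference spectra report the wavelength of the negative minimum, or none
  when the difference is flat or non-negative.
* Line scans: mean fluorescence over the membrane section divided by the
  intracellular mean.

## Synthetic fixtures: what they emulate and what they do not

The generators plant known values for every estimator so the analysis chain
can be validated as a round trip.  Lipids are 3-bead caricatures (PO4 head +
two acyl beads) on a jittered lattice at a fixed area per lipid (default
65 Å², xy jitter SD 0.8 Å); leaflets sit at fixed z (lower heads 80 Å, upper
118 Å in a 200 Å box).  Species counts per leaflet are exact
(largest-remainder rounding).  The default lower-leaflet composition is
80:10:10 POPC:POPS:PIP2 under a pure-POPC upper leaflet, the mixed-anionic
plasma-membrane model standard for intracellular juxtamembrane studies.

Radial enrichment of one species plants a disc in which the expected species
count is fold × (areal density × disc area) — using the disc *area* rather
than the in-disc lattice-site count keeps the planted density unbiased under
lattice discretisation — drawn as integer part plus a Bernoulli remainder.
Because a single realization holds only a few enriched lipids inside a 15 Å
disc, the planted fold is recovered by averaging density grids over many
independent realizations (2000 in the acceptance run), not frames of one
topology.  Species assignment without enrichment uses a seeded site
permutation with PIP2 occupying a prefix, so raising the PIP2 fraction at a
fixed seed only adds PIP2 sites; this makes the concentration-doubling
monotonicity of per-residue PIP2 contacts hold deterministically.

The protein is a bead chain: a rigid sub-domain (Gaussian blob, SD 4 Å) posed
per frame from a scheduled orientation state (small rotational jitter,
default 3°), plus tail residues pinned to the head groups on schedules that
hit planted per-residue contact fractions exactly (Bresenham spacing over
bound frames).  Planted contacts pin to the nearest head of a designated
species (default POPC) so that species' contact column equals the planted
fraction; `contact_species=None` pins to the nearest head of any species,
which keeps the protein geometry independent of leaflet composition (used by
the monotonicity test).  Bound/unbound segments are instantaneous (no
diffusion-limited approach), so first-binding-time semantics are exact;
unbound segments sit 40 Å below the leaflet.  Orientation-state populations
are laid out in blocks (default 20 frames) with largest-remainder counts, so
planted populations are exact to block resolution; the non-state remainder is
a diffuse background of orientations kept ≥45° from every planted centre.
Randomness is a single seeded generator per invocation with per-molecule
sub-streams, so the fixtures are bit-reproducible and adding lipids does not
perturb the protein's randomness.

NMR titrations model I/I₀ = 1 − s·f + ε with Gaussian ε whose SD is solved in
closed form so the expected sample Pearson correlation with the contact
fraction equals the target (σ = |s|·σ_f·√(1/r² − 1)); ratios are left
unclipped, so large noise can push individual ratios slightly below zero — a
deliberate fixture artifact that keeps the planted correlation exact.  Decay
fixtures are I₀·e^(−R₂t)·(1+ε) at the standard eight-delay list
(0–339.2 ms) in triplicate.

What passing these tests shows: the estimators are unbiased and correctly
normalised on data whose generative process matches their assumptions, at the
stated tolerances.  What they do not show: robustness to real-trajectory
features absent from the fixtures — lipid diffusion and exchange, membrane
undulations and curvature, protein conformational change within the "rigid"
domain, correlated noise in NMR intensities, or force-field realism of any
kind.  The fixtures are caricatures by design.

## Problem sizes and defaults in the shipped runs

The test suite and the acceptance script use 60–80 Å boxes (~50–100 lipids
per leaflet), 300–1000-frame trajectories for binding/contact recovery,
10 000 bound frames for state-population recovery (block size 20 makes the
planted populations exact to 0.002), 2000 bilayer realizations for the
enrichment fold, 200 seeds for the planted correlation and 100 for the
relaxation rate.  These sizes were chosen as the smallest at which the
planted values are recovered well inside their tolerances (±0.01 bound
fraction, ±0.02 state populations, ±10% enrichment, ±0.05 contact fractions,
±0.03 mean correlation, 5% rate error in ≥95% of seeds); the whole
acceptance run completes in well under a minute on one CPU.

## Known limitations

* Orthorhombic boxes only; no curvature, thickness or residence-time
  analyses; no 3D voxel densities.
* The orientation histogram is binned in (longitude, latitude) without
  solid-angle weighting; near-polar states would be over-smoothed.
* Leaflet assignment is static (first frame) and by head-bead z only; lipid
  flip-flop is not tracked.
* Contact counting is O(residues × lipid beads) per frame with dense NumPy
  distance matrices — fine for coarse-grained systems up to a few thousand
  beads, not tuned for atomistic system sizes.
* The CSP formula and the bound-state criterion are declared conventions of
  this package (both config-exposed), not values taken from any single
  experimental protocol.
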