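# lidmap

Analysis toolkit for coarse-grained simulations of peripheral and single-pass
membrane proteins — in particular intrinsically disordered juxtamembrane
regions (lipid interaction domains, LIDs) and kinase complexes binding to
anionic bilayers containing PI(4,5)P₂ — together with the solution-NMR and CD
analyses used to cross-validate such simulations against experiment.

Intended users are structural biophysicists who run bead-resolution (Martini-
style) bilayer simulations and want the standard downstream readouts as a
tested, scriptable library rather than one-off trajectory scripts.

## What it computes

**Protein–lipid contact profiles.** For each protein residue *r* and lipid
species *s*, the fraction of simulation time a contact exists,

&nbsp;&nbsp;&nbsp;&nbsp;f(r, s) = (1/F) Σ_t 1[ min distance(BB_r, beads_s(part)) ≤ 7 Å ],

with the lipid split into head-group and acyl-chain beads, distances under the
minimum-image convention, and the 7 Å cutoff inclusive.  Residue–residue maps
report the time-averaged minimum bead distance with close (≤4 Å) and
no-contact (≥6 Å) masks.

**Lipid density and enrichment maps.** xy-plane densities of a reference bead
(default PO4) on a 1 Å grid; the enrichment score per bin is
E = 100·(ρ − ρ̄)/ρ̄, the percent deviation from the leaflet-average density
(mean exactly zero by construction).

**Membrane-bound orientation states.** The pose of a rigid domain is reduced
to the geographic coordinates (latitude, longitude) of the inward membrane
normal in the domain's body frame, obtained per frame from the least-squares
(Kabsch) rotation onto the reference.  A smoothed 2D population histogram
over bound frames yields orientation states (local maxima) with populations
as fractions of total bound time, representative frames, and per-state
contact profiles.

**Binding statistics.** A debounced per-frame bound flag (≥5 residues in
head-group contact, 5-frame dwell) gives bound fraction ("saturation"), first
binding time and event counts.

**Experimental readouts.** Amide CSPs (√(ΔδH² + (0.154·ΔδN)²)), titration
intensity ratios I/I₀ with vanished-peak flags, secondary chemical shifts,
single-exponential R₂ fits, mean-residue ellipticity and CD difference
spectra with their negative minimum, fluorescence line-scan membrane/
intracellular ratios, and the Pearson correlation (r, p, R² = r²) between any
per-residue NMR series and a contact profile.

**Synthetic fixtures.** `lidmap.synthetic` generates two-leaflet bead
bilayers (e.g. 80:10:10 POPC:POPS:PIP2 lower leaflets, optional radial
enrichment of one species), scheduled protein trajectories with planted bound
fractions, orientation states and per-residue contact fractions, and NMR
titrations/decays with planted correlations and rates — every analysis above
is validated by recovering these planted values.

File I/O (GRO/PDB structures, XTC/DCD trajectories) goes through MDAnalysis;
coordinates are Å throughout.

## Worked example

```python
import numpy as np
from lidmap import (BilayerSpec, ProteinScheduleSpec, make_bilayer,
                    make_protein_trajectory, detect_bound_frames, bound_statistics,
                    residue_lipid_contact_fractions, make_nmr_titration,
                    intensity_profile, nmr_contact_correlation)
from lidmap.synthetic import NMRSpec

bspec = BilayerSpec(box_xy=(60.0, 60.0))          # 80:10:10 POPC:POPS:PIP2 lower leaflet
top, frame = make_bilayer(bspec, seed=1)
pspec = ProteinScheduleSpec(bound_fraction=0.97,  # planted 97% membrane-bound time
                            planted_contact_fractions=(1.0, 0.5, 0.0))
traj, truth = make_protein_trajectory(top, frame, pspec, n_frames=1000, seed=1,
                                      bilayer_spec=bspec)

bound = detect_bound_frames(traj, cutoff=7.0, min_residues=5, dwell_frames=5)
frac, first, events = bound_statistics(bound)
print(f"bound fraction: {frac:.3f}   first binding: {first:.0f} ps   events: {events}")

profile = residue_lipid_contact_fractions(traj, part="head", cutoff=7.0)
col = profile.column("POPC")
rows = {int(r): i for i, r in enumerate(profile.residue_seq)}
for r in truth.planted_residue_seqs:
    print(f"residue {r}: planted {truth.contact_fractions[r]:.2f}  recovered {col[rows[r]]:.3f}")

tser = make_nmr_titration(profile, NMRSpec(target_r=-0.55, slope=0.8), seed=1)
ratios = intensity_profile(tser)[-1]               # I/I0 at 25x molar excess
res = nmr_contact_correlation(ratios, profile, species="POPC")
print(f"Pearson r = {res.r:.2f}, p = {res.p:.1e}, R^2 = {res.r_squared:.2f}, n = {res.n}")
```

Output:

```
bound fraction: 0.970   first binding: 15 ps   events: 1
residue 27: planted 1.00  recovered 0.970
residue 28: planted 0.50  recovered 0.485
residue 29: planted 0.00  recovered 0.000
Pearson r = -0.62, p = 3.3e-04, R^2 = 0.39, n = 29
```

The detector recovers the planted 97% saturation exactly.  Planted contact
fractions are fractions of *bound* time, so over all frames they appear
scaled by the bound fraction (1.00 → 0.97, 0.50 → 0.485).  The single-seed
correlation (−0.62) scatters around the planted −0.55 with the sampling error
expected at n ≈ 30; averaging over seeds converges to the planted value.

A command-line interface mirrors the library (`lidmap synth | contacts |
density | orient | states | rmsf | fit-r2 | titrate | nmr-compare | cd`);
each subcommand writes result tables plus a JSON run manifest.

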