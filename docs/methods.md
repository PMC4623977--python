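# Methods

## Scope and model

`pmdmembrane` implements the analysis layer of probe-based MD for
membrane-bound proteins plus the force-field override that makes such
simulations possible. It does not run dynamics: inputs are a PDB topology,
DCD/XTC trajectories with orthorhombic periodic boxes, and a selection
config naming the probe residue (with its central carbon and hydroxyl
oxygen), lipid residues, phosphate atom and lipid-tail CHARMM types.
Triclinic boxes are rejected explicitly; minimum-image distances are
computed per frame with that frame's box and no trajectory unwrapping,
since probes diffuse freely across boundaries.

Because PDB files carry no CHARMM atom types, type labels come from a
sidecar table (residue name + atom name → type) shipped for POPC/POPS acyl
chains, isopropanol and the synthetic reduced residues, and extendable
through the config. Leaflets are assigned per lipid by the sign of its
mean phosphate z against the bilayer midplane (mean of all phosphate z);
the bilayer normal is taken as the box z axis throughout — no director
fitting, matching the flat-bilayer geometry the method targets.

## NBFIX repulsion protocol

The probe–lipid override is pair-specific: only the probe's *central
carbon* type against the lipid tail methylene type `CTL2` by default, with
well depth ε = 0.01 kcal/mol and pair minimum-energy distance
R_min = 7 Å. Larger distances (10 Å) wall the probe off from the bilayer
surface entirely; smaller ones (4 Å) let it through — 7 Å is the balance
that still lets probes reach the protein's membrane-facing side. The
emitter writes the CHARMM convention (`TYPE_A TYPE_B -ε R_min`), treats
"minimum inter-particle distance" as the pair R_min (not R_min/2), and
offers `halve_rmin` for dialects expecting the half distance. The probe
central-carbon type is a required user input (CG311 is the natural choice
for CGenFF isopropanol); no force-field fact is invented on the user's
behalf. Extending the target set beyond `CTL2` (e.g. terminal `CTL3`
methyls) is a config choice, not the default.

## Occupancy statistic

R_i sums the switching kernel w(d) = 1/(1 + α·d^n) over frames and probes,
with d the minimum-image distance from protein heavy atom i ("protein
atom" always means heavy atoms; hydrogens are excluded) to the nearest
heavy atom of each probe, scaled by 250/(N_frames·N_probes). Defaults
n = 20, α = 1e-17 give w(6 Å) ≈ 0.9647 and w(8 Å) ≈ 0.0798. The sum
nominally runs over all probes; for speed, probes whose minimum distance
exceeds a cutoff are skipped. The cutoff default is 30 Å, where
w < 3×10⁻¹³ — chosen so the truncation stays below 1e-9 of any R_i even
after the 250-fold scale (at 12 Å the kernel is still 2.6×10⁻⁵, far too
large to drop). Correctness is defined against a no-cutoff triple-loop
oracle with explicit 27-cell image enumeration, and the cutoff is
configurable or disabled entirely.

ΔR_i = R_ix − R_iy is formed on the atoms present in both runs and only
when both profiles used identical kernel parameters (different scales are
not comparable). σ for hotspot calling is the population standard
deviation of ΔR over those atoms — the population the ±2σ threshold is
drawn against — and the multiplier is configurable.

## Grids

*Proximal maps*: a probe contributes all four heavy atoms in a frame iff
its minimum heavy-atom distance to the protein is ≤ 4 Å; counts are
time-averaged per 1 Å³ voxel. Conversion to free energy is Boltzmann
inversion, G = −k_B·T·ln(ρ/ρ_ref) at T = 310 K
(k_B·T = 0.616 kcal/mol). The reference density is supplied by the caller
(bulk probe density is the natural choice); empty voxels carry a +5
kcal/mol cap sentinel rather than +∞, and all values are clipped at the
cap. This normalization is this package's design choice for the
density→energy step; with any fixed ρ_ref it shifts all voxels uniformly,
so isosurface *shapes* are robust to the choice.

*Concentration maps*: probe heavy-atom counts on a hexahedral mesh
(default 0.37 Å spacing) normalized by voxel volume, frame count, the 4
heavy atoms per probe, and C0 = 1 M = 1/1660.3 molecule/Å³. Voxels are
half-open (`floor` binning); atoms exactly on the upper grid edge are
dropped with a logged count. The identity Σ c·V·C0 = mean probe
equivalents per frame holds to machine precision and is asserted in tests.
The 7-point smoothing averages each node with its six face neighbours;
out-of-bounds neighbours contribute zero while the divisor stays 7 (the
literal reading of the averaging formula — interior mass is conserved,
boundary nodes leak), with a renormalizing variant available by flag.
Smoothing may be applied before thresholding an isosurface; both raw and
smoothed grids are exportable.

*Alignment*: Kabsch least-squares superposition of each frame onto a
reference (frame index or external coordinates) using a fit selection
minus exclusions; the rigid transform is applied to all atoms, so
distance-based statistics are provably unchanged (asserted numerically).
For Ras-like proteins the conventional exclusions are the flexible switch
regions (residues ~25–40 and ~57–75) and the termini; the package takes
these as config rather than hard-coding residue ranges.

## Orientation order parameters

Against the membrane normal: cos θ between each probe's central-carbon →
hydroxyl-oxygen vector and +z, accumulated into z-bins of the probe's
heavy-atom centre of mass; empty bins are NaN (distinct from a genuine
⟨cos θ⟩ = 0), and zero-length C→O vectors are skipped with a logged count.
Against the protein surface: for atoms with R_i ≥ 0.24, the average over
frames and over probes in contact (minimum heavy-atom distance ≤ 6 Å —
the full-weight range of the switching kernel) of cos θ_r between the
probe C→O vector and the unit vector from the protein centre (unweighted
geometric centre of the configured selection, per frame) to the atom.
Positive means the hydroxyl points away from the surface, i.e. an apolar
contact patch.

## Bilayer metrics

Area per lipid is Lx·Ly/N per leaflet per frame ("both" averages the two
leaflets), reported mean ± sample SD over frames; thickness is the
absolute difference of leaflet mean phosphate z. With a protein occupying
part of one leaflet the plain Lx·Ly/N is an approximation — the package
reports it as such and leaves corrections to the user. Both metrics are
invariant under rigid z-translation.

## Convergence and errors

The per-frame occupancy R_i(k) is the single-frame kernel sum; its frame
average equals the whole-trajectory R_i exactly, which ties the time
series to the headline statistic. R_ave(k) averages over atoms whose
whole-run R_i exceeds 0.05 (catching essentially every atom with non-zero
occupancy; including zero-R atoms would only rescale the curve), with the
atom set frozen over the series and a running mean attached. BSE(b) is the
standard deviation of non-overlapping b-frame block means divided by
√(number of blocks); BSE(1) is exactly the naive SEM. The default block
schedule is powers of two up to a quarter of the series. The saturation
fit a0(1 − a1 exp(−a2 b)) is solved by least squares, initialized at
a0 = max BSE, a1 = 1 − BSE(1)/a0, a2 = 1/median(b); it is flagged
unconverged when the optimizer fails or a0 exceeds twice the largest
observed BSE (the flat-curve pathology of uncorrelated data), in which
case per-atom uncertainties fall back to the maximum observed BSE — a
conservative substitute. The uncertainty of a difference is the plain sum
δ(ΔR_i) = a0_x + a0_y, deliberately conservative rather than in
quadrature.

## Synthetic ground truth

The generator builds a two-leaflet lattice of 3-bead pseudo-lipids
(phosphate marker at ±19 Å from the midplane, two CTL2-labelled tail
beads), a rigid protein bead lattice resting on the upper leaflet, and
rigid 4-heavy-atom probes whose non-central atoms sit in the forward
hemisphere of the C→O axis — so a radially planted probe's nearest atom to
the target bead is always its central carbon and the planted distance is
exact. Contact plants pin a probe at a chosen distance/orientation from a
chosen bead in explicit frames or per-frame Bernoulli draws; paired runs
differ only in planted probabilities. Water is bookkept, not instantiated
(default 20 waters per probe, recorded in the ground truth and the PDB
header): no analysis touches water positions, and omitting tens of
thousands of dummy atoms keeps fixtures tiny.

Free probes are placed uniformly in the solvent region *distal* to the
protein (across the bilayer, ≥ ~35 Å away) by default, where the kernel
weight is < 1e-13 — this makes the planted expectations exact rather than
"dominant": a 2 Å stand-off would leave free probes wandering within the
kernel's full-weight range and contribute a background occupancy of order
1, the same size as a small planted signal. Proximal placement with a
configurable exclusion radius remains available for density-profile and
orientation fixtures where background presence is the point. Expected
occupancies account for every plant's contribution to every protein bead
(from the constructed geometry), and both expectation (true p) and
realization (drawn frequency) are recorded, so estimator error and
sampling scatter can be separated.

What the fixtures deliberately do not emulate: thermal protein/lipid
motion, probe–probe interactions, water structure, correlated frame-to-
frame dynamics (plants are iid across frames unless given explicit frame
sets). Passing tests therefore certify the estimators — selection logic,
kernel arithmetic, periodic-image handling, normalizations, error
propagation — not force-field realism; real bilayer perturbation
measurements (area-per-lipid and thickness shifts) require
microsecond-scale all-atom MD and are outside what desk-scale fixtures
can or should reproduce.

## Problem sizes

Test fixtures use 4–12 protein beads, 4–20 probes, 16–208 lipids per
leaflet and 10–2,000 frames; the planted-recovery study uses 10 probes ×
2,000 frames with contact probabilities {1.0, 0.5, 0.1} on beads isolated
30 Å apart (beyond the kernel range) so each bead's expected occupancy is
exactly 250·p/10. These sizes give sub-percent sampling error on every
planted statistic while the whole suite runs in seconds.

## Known limitations

Orthorhombic boxes only. PSF/PRMTOP topologies are not parsed (PDB +
sidecar types instead). The surface-orientation estimator loops per
retained atom and per contact event, which is fine for hotspot-sized atom
sets but not for whole-proteome sweeps. Grid bounds default to the axis-
aligned span of the largest box; systems drifting far outside their box
should be wrapped or given explicit bounds. The BSE saturation fit is
ill-posed on uncorrelated series by construction — the flagged fallback,
not the fit, is the supported answer there.
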