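# Methods

This note records the models implemented in `helixswitch`, the
parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions used throughout.

## Peptides and numbering

All operations work in author numbering.  The two built-in peptides are
the Trop2 cytosolic tail, Thr298–Leu323 (26 residues, N-acetylated,
with an optional phosphate flag on Ser303), and the transmembrane
helix Ala275–Ile297 (23 residues).  Phosphoserine is represented as a
flag on `S` (residue name `SEP` in structures), not as an extra letter,
so sequence-level operations are phospho-agnostic unless they
explicitly take a phosphate charge.

The charge census counts R and K as basic and D and E as acidic.
Histidine is counted as "other": at pH 7.4 the imidazole is mostly
neutral, and neither built-in peptide contains His, so the printed
census (nine basic, four acidic) is unaffected either way.  Span
fractions are rounded half-up to integer percent — the convention
under which a nine-residue helix in a 26-mer is 35%.

## CD processing

Raw ellipticity θ (mdeg) is converted to mean residue ellipticity with
the standard normalization [θ] = θ / (10 · c(M) · N · l(cm)), giving
deg cm² dmol⁻¹; concentrations are entered in mM and converted
internally.  Fractional helicity is the classical two-state estimator
at 222 nm with coil and helix references +640 and −42 500
deg cm² dmol⁻¹.  Values of f_H outside [0, 1] are clamped with a
warning rather than rejected, because real baselines can overshoot the
references.  No multi-component deconvolution is attempted.

Minima are reported on the MRE spectrum with a default 5 nm window: a
grid point is a minimum if it is strictly the lowest within ±2.5 nm,
and points whose window is truncated by the grid edge are ineligible.
Positions are reported at the nearest grid point (0.5 nm grid by
default).

The synthetic spectra are mixtures f·B_helix + (1−f)·B_coil of two
Gaussian-shaped bases calibrated so that B_coil has its minimum at
198 nm with B_coil(222) = +640, and B_helix has minima at 208 and
222 nm with B_helix(222) = −42 500.  Only those facts are contractual;
the widths and depths elsewhere are cosmetic.  Because the 222 nm value
of the mixture equals the two-state model exactly, the
generate → subtract blank → normalize → estimate chain is an exact
round trip at zero noise (tested to 1e−9).

## Ensemble statistics

**Superposition and precision.**  Rigid superposition is the
least-squares (Kabsch) fit with a proper rotation; selections with
fewer than three atoms or collinear geometry are rejected.  RMSD to
the mean coordinates follows the usual one-pass refinement: superpose
all models on model 1 over the selection, average coordinates,
re-superpose each model onto the mean, report mean ± sd of the
per-model RMSDs.  Further mean-structure iterations change test cases
by less than 1e−6 Å.  For an ensemble of n models with isotropic
per-atom jitter σ, the expected RMSD is σ√3·√((n−1)/n); the jittered
generator reproduces this within a few percent and the test tolerance
is 10%.

**Secondary structure.**  A deterministic dihedral-window assigner is
used instead of a full STRIDE/DSSP re-implementation: α (label H)
requires ≥ 4 consecutive residues with φ within −57 ± 40° and ψ within
−47 ± 40°; 3₁₀ (label G) requires ≥ 3 consecutive residues within
−49 ± 30° / −26 ± 30° among residues not already α.  Terminal residues
without both dihedrals are coil.  This is sufficient to reproduce
span-level statements on synthetic ground truth; it is not a
hydrogen-bond-based assignment and will disagree with STRIDE on
distorted real structures.

**Ramachandran regions.**  Classification uses four nested classes on
a 10° grid.  The maps are built programmatically: explicit core
rectangles for the α, β/extended and (at the `additional` level)
left-handed-α basins, grown by periodic binary dilation — one 10° shell
for `additional`, two more for `generous`.  Dilation guarantees
nesting by construction.  Glycine uses a point-symmetric map, proline
a φ-restricted one; pre-proline is not special-cased.  The percentages
over any set of residues always sum to 100.

**Salt bridges.**  A bridge exists in a model iff the minimum distance
between a basic-group nitrogen (Arg NH1/NH2/NE, Lys NZ) and an
acidic-group oxygen (Glu OE1/OE2, Asp OD1/OD2, phosphoserine
O1P/O2P/O3P) is ≤ 4.0 Å (configurable).  Reports give the per-model
presence and ensemble frequency, sorted descending, with ties included
in the "most frequent" query.  Hydrophobic clusters are connected
components (≥ 3 residues) of the side-chain contact graph at 5 Å among
a configurable residue-type set; serine is included by default because
short-peptide packing analyses count Ser side chains, but the set is a
parameter precisely because that usage is debatable.

**Restraints.**  Distance restraints use the whitespace-column upper
distance limit dialect (`res resname atom  res resname atom  upper`),
torsions a five-column range file; both 1-based author numbering.
Classification by sequence separation: intra |i−j| = 0, sequential 1,
medium 2–4, long ≥ 5 — the standard convention; published tables that
print "< 5" and "> 5" leave |i−j| = 5 formally unassigned and it is
placed in long-range here.  A distance violation requires the model
distance to exceed the bound plus the tolerance (boundary inclusive;
defaults 0.2 Å and 5° match the usual ensemble acceptance thresholds);
torsion windows are compared circularly, so ranges wrapping through
±180° work.

**CSP.**  Combined amide perturbations use
Δδ = √(ΔδH² + (0.14·ΔδN)²); the ¹⁵N scale is a parameter.  Residues
present in only one peak table are reported as missing, duplicates are
an error.

## Transmembrane dimer geometry

Helices are reduced to backbone (BB) and side-chain (SC) beads.  The
axis of a helix is the principal direction of 4-residue sliding-window
BB centroids (windowing suppresses the helical ripple; a raw-PCA mode
is available), oriented N→C.  With a 100°/residue twist the 4-residue
window does not cancel the ripple exactly, which leaves a ≈ 0.05°
residual tilt on ideal geometry — visible as medians of −27.08° where
−27° was programmed, well inside all stated tolerances.  At 1 Å
independent bead noise the fitted direction is within 3° of truth in
the RMS sense over repeated draws; this is close to the information
limit of 23 noisy beads on a 33 Å helix, so individual draws can
exceed 3°.

Interhelical distance is the distance between fitted-axis centroids
projected onto the membrane plane (normal defaults to the box z axis).
Projection makes the constructed 50 Å initial separation exact and
removes vertical drift.

The crossing angle is signed: magnitude is the angle between axis
directions folded to ≤ 90°, sign is the chirality of the dihedral
axis A → line of closest approach → axis B, with negative meaning
right-handed packing (the common convention for TM pairs).  Exactly
parallel axes return 0.  The definition is symmetric in A and B and
flips sign under reflection.

Encounter is the first frame whose minimum inter-helix bead distance
drops to the contact cutoff (default 6 Å — a coarse-grained bead
scale); dimer intervals are maximal contact runs lasting at least the
persistence (default 10 frames), tolerating single-frame gaps.  Both
defaults are analysis parameters, not facts about any particular
simulation, and are CLI-tunable.  The crossing-angle series is
evaluated only inside dimer intervals; its distribution summary uses
5° bins on (−90°, 90°], Gaussian smoothing over ≈ 3 bins, and counts
modes as local maxima above 10% of the global maximum.

Motif contact profiles record, per frame, the distance from each
five-valine side-chain bead on one helix to the centroid of the
opposite motif, in both directions.  A frame is "symmetric" when the
two directional patterns agree within 2 Å for every motif residue.
The interface check reports the fraction of dimer frames whose single
closest inter-helix SC–SC contact has both residues inside the motif.

## The rigid-body dimerization surrogate

The trajectory generator is kinematic, not dynamic: no forces, lipids
or solvent.  It exists to give the analyses known ground truth with
the phenomenology of a coarse-grained dimerization run.  Defaults
mirror the simulated study conditions at desk scale: two ideal
23-residue helices perpendicular to the membrane in a 100 × 100 Å
patch, 50 Å apart, diffusing laterally (reflective walls, 1 Å/frame
steps, kept out of contact range) until a programmed encounter frame,
then held as a rigid dimer.  500 frames stand in for microsecond-scale
trajectories; the analysis cost is linear in frames and nothing in the
geometry depends on the count.

The docked geometry is built so its ground truth is exact: the two
axes are tilted ±θ/2 about the interhelical (closest-approach) line
using the same sign convention the analysis measures, so the
programmed crossing angle is recovered identically; helix B is the
180° rotation of helix A about the central membrane normal, making the
motif orientation exactly C2-symmetric; and the dock is centered on
the motif's axial position so the crossing point — and therefore the
closest contact — falls at the five-valine motif.  Scheduled axial
rotations of helix B break the C2 symmetry on cue (asymmetric
episodes), an axial offset moves the contact to the termini, and
optional isotropic bead noise is added last.  The truth sidecar
records the encounter frame, per-frame true angle and orientation
class.

What the surrogate does not emulate: force-driven association
kinetics, reversible dissociation, helix flexing, lipid interactions,
or rotational diffusion of the docked dimer.  Passing the recovery
tests therefore demonstrates the correctness of the geometric
analyses, not anything about the energetics of real TM dimerization.

## Synthetic ensembles and their limits

The peptide builder places N/CA/C/O with ideal bond geometry from a
per-span (φ, ψ) plan (coil default (−120°, 120°), ω = 180°), one CB
per non-glycine residue, and a single charged-group pseudo-atom along
the CA→CB direction for Arg/Lys/Glu/Asp/phosphoSer at a
residue-specific radius.  Full rotamers are deliberately out of scope;
one interaction center per side chain is enough for the contact-based
analyses tested.  Caps are emitted as ACE/NME residues and excluded
from dihedral statistics.

The jitter generator displaces every atom independently
(model 1 stays unperturbed).  This reproduces RMSD-to-mean statistics
exactly but is a poor model of dihedral-level variation: independent
0.5 Å atomic noise (a third of a bond length) scrambles φ/ψ far more
than the correlated, bond-preserving variation of real conformer
ensembles.  Dihedral-based summaries (secondary structure,
Ramachandran) should therefore be read from the clean or lightly
jittered (≤ 0.1 Å) models, and the acceptance script does exactly
that.  Published ensemble validation numbers (ensemble RMSDs of
1.8–3.9 Å, ~85% most-favored) arise from correlated backbone motion
that the jitter model does not attempt to reproduce — which is why
those numbers are checked against closed forms on synthetic truth, not
against the published table.

Restraint generation samples heavy-atom pairs within a cutoff and sets
each upper bound to the true distance plus a slack (≥ 0), so the
source model satisfies its own restraint list by construction.  Quota
mode emits exactly the requested per-class counts, taking the shortest
candidates deterministically, and raises when the geometry cannot
supply a class (e.g. long-range restraints from a straight helix at a
small cutoff; the acceptance script uses a 9 Å cutoff, where
|i−j| ≥ 5 backbone pairs of an α-helix become available).

## Reproducibility

Every stochastic operation takes an explicit integer seed and uses
`numpy.random.default_rng`; generators are byte-identical under a
fixed seed (tested on written files).  `scripts/acceptance.py` derives
all of its randomness from `--seed` and regenerates every input at run
time; nothing is read from outside the repository.
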