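# helixswitch

Quantitative structural analyses of the membrane-proximal regions of the
tumor marker protein Trop2: the 26-residue cytosolic tail (Trop2IC,
residues 298–323), whose conformation is switched by phosphorylation of
Ser303, and the 23-residue transmembrane helix (Trop2TM, residues
275–297), which dimerizes through a five-valine motif.  The package is
aimed at structural biologists who want the numbers behind such a study
— CD helicity estimates, NMR-ensemble validation statistics, and
coarse-grained dimer-trajectory geometry — as a tested, scriptable
pipeline, with synthetic-data generators standing in for the
spectrometer, NMR, and simulation outputs.

## What it computes

**Sequence arithmetic** (`helixswitch.sequences`): charge census
(basic R/K vs acidic D/E), net charge with phosphate contributions,
span fractions in author numbering, homopolymer motif discovery
(e.g. the VVVVV motif, Val282–Val286).

**CD spectra** (`helixswitch.cd`): blank subtraction, scan averaging,
conversion of the raw signal θ (mdeg) to mean residue ellipticity

    [θ](λ) = θ(λ) / (10 · c · N · l)        [deg cm² dmol⁻¹]

with molar concentration *c*, residue count *N* and path length *l*
(cm); two-state fractional helicity at 222 nm

    f_H = ([θ]₂₂₂ − [θ]_coil) / ([θ]_helix − [θ]_coil)

against the coil/helix references +640 and −42 500 deg cm² dmol⁻¹;
local-minima reporting (coil minimum at 198 nm, helix minima at
208/222 nm).

**NMR-ensemble statistics** (`helixswitch.ensemble`): Kabsch
superposition, RMSD to the mean coordinates, dihedral-window secondary
structure (α-helix H, 3₁₀ G, coil C), four-class Ramachandran
percentages, salt-bridge detection with ensemble frequencies
(acidic O ↔ basic N within 4 Å, phosphate oxygens included),
hydrophobic-cluster detection, peptide-bond ω classification
(cis/trans/twisted), NOE restraint classification by |i−j|
(intra / sequential / medium / long), distance and torsion violation
checks (0.2 Å / 5° tolerances), and combined ¹H/¹⁵N chemical-shift
perturbations Δδ = √(ΔδH² + (0.14·ΔδN)²).

**TM-dimer trajectory geometry** (`helixswitch.tm`): helix-axis fits
from sliding-window bead centroids, membrane-plane interhelical
distance, signed crossing angle in (−90°, 90°] (negative =
right-handed packing), encounter and persistent-dimer detection,
VVVVV-motif contact profiles, symmetric/asymmetric orientation
classification, and crossing-angle distribution summaries (median,
modality).

**Synthetic data** (`helixswitch.synthetic`): ideal peptide builders
from (φ, ψ) plans, Gaussian-jittered conformer ensembles, engineered
salt bridges, exactly calibrated two-state CD spectra, geometrically
satisfied restraint lists (including quota mode reproducing a printed
restraint census), and rigid-body two-helix trajectories with
programmed diffusion, encounter, crossing angle and axial-rotation
episodes.  Every generator is seed-deterministic and emits a
ground-truth sidecar.

## Worked example

```python
from helixswitch.cd import (subtract_blank, to_mean_residue_ellipticity,
                            helicity_from_spectrum)
from helixswitch.sequences import TROP2IC, charge_census, span_fraction
from helixswitch.synthetic import (GeneratorConfig, generate_cd_spectrum,
                                   simulate_rigid_dimerization)
from helixswitch.tm import detect_encounter_and_dimers, angle_distribution_summary

print(charge_census(TROP2IC))          # {'basic': 9, 'acidic': 4, 'other': 13}
print(span_fraction(TROP2IC, 310, 318))  # 35  (percent of the 26-mer)

sample, blank, _ = generate_cd_spectrum(0.29)   # 29% helical peptide in 70% TFE
mre = to_mean_residue_ellipticity(subtract_blank(sample, blank))
print(round(helicity_from_spectrum(mre), 3))    # 0.29

cfg = GeneratorConfig(seed=3, n_frames=500, encounter_frame=120,
                      crossing_angle_deg=-27.0)
traj, _ = simulate_rigid_dimerization(cfg)
timeline = detect_encounter_and_dimers(traj)
summary = angle_distribution_summary(timeline)
print(timeline.encounter_frame, round(summary.median, 1), summary.n_modes)
# 120 -27.1 1
```

The census says the tail is strongly cationic (nine basic vs four
acidic side chains, net +5), the CD round trip recovers the programmed
29% helicity through the full blank-subtraction/normalization chain,
and the trajectory analysis finds the programmed encounter frame and a
unimodal crossing-angle distribution with median −27° — right-handed
helix packing.

The same operations are available from the shell:

```sh
helixswitch seq census --seq "TNRRK(pS)GKYKKVEIKELGELRKEPSL" --start 298
helixswitch synth cd --f-helix 0.29 -o sample.csv
helixswitch cd helicity sample.csv --blank sample.csv.blank.csv
helixswitch synth tm-traj --frames 500 --encounter 120 -o dimer.traj
helixswitch tm analyze dimer.traj --motif 282-286
```

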