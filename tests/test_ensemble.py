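import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from helixswitch.ensemble import (
    assign_secondary_structure,
    backbone_dihedrals,
    check_violations,
    chemical_shift_perturbation,
    classify_noe_restraints,
    detect_hydrophobic_clusters,
    detect_salt_bridges,
    omega_classify,
    ramachandran_summary,
    rmsd_to_mean,
    secondary_structure_spans,
)
from helixswitch.ramachandran import _MAPS, ramachandran_classify
from helixswitch.sequences import TROP2IC, PeptideSeq
from helixswitch.structures import (
    Atom,
    DistanceRestraint,
    RestraintList,
    StructureEnsemble,
    TorsionRestraint,
)
from helixswitch.synthetic import (
    build_ideal_peptide,
    engineer_salt_bridge,
    generate_restraints,
    jitter_ensemble,
)


class TestRmsdToMean:
    def test_identical_models_give_zero(self, helical_ic_model):
        ens = jitter_ensemble(helical_ic_model, 5, 0.0)
        r = rmsd_to_mean(ens)
        assert r.mean == pytest.approx(0.0, abs=1e-12)
        assert r.sd == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_jitter_matches_closed_form(self, jittered_ensemble):
        """Isotropic jitter sigma about a reference: per-coordinate deviation
        from the ensemble mean has variance sigma^2 (1 - 1/n), so the expected
        RMSD is sigma sqrt(3) sqrt((n-1)/n)."""
        sigma, n = 0.5, 20
        assert jittered_ensemble.n_atoms >= 100
        expected = sigma * np.sqrt(3.0) * np.sqrt((n - 1) / n)
        r = rmsd_to_mean(jittered_ensemble)
        assert abs(r.mean - expected) / expected < 0.10

    def test_invariant_under_global_rigid_transform(self, jittered_ensemble):
        R = Rotation.random(random_state=9).as_matrix()
        t = np.array([10.0, -5.0, 3.0])
        moved = jittered_ensemble.with_coords(jittered_ensemble.coords @ R.T + t)
        a = rmsd_to_mean(jittered_ensemble)
        b = rmsd_to_mean(moved)
        assert abs(a.mean - b.mean) < 1e-8
        assert np.allclose(a.per_model, b.per_model, atol=1e-8)

    def test_mirrored_single_atom_displacement(self):
        """One atom at +/- d in two otherwise identical models: each model
        deviates d from the mean on that atom, so RMSD = d / sqrt(k)."""
        rng = np.random.default_rng(2)
        k, d = 200, 1.0
        base = rng.normal(size=(k, 3)) * 5
        m1, m2 = base.copy(), base.copy()
        m1[0, 0] += d
        m2[0, 0] -= d
        atoms = tuple(Atom(i + 1, "ALA", "CA", "C") for i in range(k))
        ens = StructureEnsemble(atoms=atoms, coords=np.stack([m1, m2]))
        r = rmsd_to_mean(ens)
        assert r.per_model[0] == pytest.approx(d / np.sqrt(k), rel=0.02)
        assert r.per_model[1] == pytest.approx(d / np.sqrt(k), rel=0.02)

    def test_empty_selection_rejected(self, helical_ic_model):
        ens = jitter_ensemble(helical_ic_model, 3, 0.1)
        with pytest.raises(ValueError):
            rmsd_to_mean(ens, selection=np.array([], dtype=int))


class TestSecondaryStructure:
    def test_central_helix_span_labeled(self, helical_ic_model):
        ss = assign_secondary_structure(helical_ic_model)
        helix = {r for r, lab in ss.items() if lab == "H"}
        assert helix == set(range(305, 315))

    def test_extended_chain_is_all_coil(self):
        model = build_ideal_peptide(TROP2IC)  # default extended coil
        assert set(assign_secondary_structure(model).values()) == {"C"}

    def test_three_ten_triplet_labeled_G(self):
        model = build_ideal_peptide(TROP2IC, ss_plan=[((300, 302), -49.0, -26.0)])
        ss = assign_secondary_structure(model)
        assert {r for r, lab in ss.items() if lab == "G"} == {300, 301, 302}

    @pytest.mark.parametrize("length", [4, 5, 7, 10])
    def test_alpha_span_exactly_recovered(self, length):
        first = 303
        model = build_ideal_peptide(
            TROP2IC, ss_plan=[((first, first + length - 1), -57.0, -47.0)]
        )
        ss = assign_secondary_structure(model)
        assert {r for r, lab in ss.items() if lab == "H"} == set(
            range(first, first + length)
        )

    def test_spans_compression(self):
        labels = {1: "C", 2: "H", 3: "H", 4: "C"}
        assert secondary_structure_spans(labels) == [
            ("C", 1, 1),
            ("H", 2, 3),
            ("C", 4, 4),
        ]


class TestRamachandran:
    @pytest.mark.parametrize(
        "phi,psi,resname,expected",
        [
            (-60.0, -45.0, "ALA", "most_favored"),  # alpha basin
            (-120.0, 130.0, "ALA", "most_favored"),  # beta basin
            (60.0, -60.0, "ALA", "disallowed"),
            (60.0, 40.0, "ALA", "additional"),  # left-handed alpha
            (60.0, 40.0, "GLY", "most_favored"),
        ],
    )
    def test_classification(self, phi, psi, resname, expected):
        assert ramachandran_classify(phi, psi, resname) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ramachandran_classify(np.nan, 0.0)

    def test_region_maps_are_nested(self):
        for core, additional, generous in _MAPS.values():
            assert np.all(additional[core])
            assert np.all(generous[additional])

    def test_percentages_sum_to_100(self, jittered_ensemble):
        summary = ramachandran_summary(jittered_ensemble)
        assert sum(summary.values()) == pytest.approx(100.0, abs=1e-9)


class TestSaltBridges:
    def _two_residue_ensemble(self, separation):
        atoms = (
            Atom(1, "LYS", "NZ", "N"),
            Atom(2, "GLU", "OE1", "O"),
        )
        coords = np.array([[[0.0, 0, 0], [separation, 0, 0]]])
        return StructureEnsemble(atoms=atoms, coords=coords)

    def test_contact_below_cutoff_detected(self):
        rep = detect_salt_bridges(self._two_residue_ensemble(3.0), cutoff=4.0)
        assert [(b.acidic_res, b.basic_res) for b in rep.bridges] == [(2, 1)]
        assert rep.bridges[0].frequency == 1.0

    def test_contact_beyond_cutoff_absent(self):
        rep = detect_salt_bridges(self._two_residue_ensemble(6.0), cutoff=4.0)
        assert rep.bridges == ()

    def test_engineered_frequency(self, jittered_ensemble):
        ens = engineer_salt_bridge(jittered_ensemble, 310, 301, 3.0, models=range(15))
        ens = engineer_salt_bridge(ens, 310, 301, 9.0, models=range(15, 20))
        rep = detect_salt_bridges(ens, cutoff=4.0)
        freq = {(b.acidic_res, b.basic_res): b.frequency for b in rep.bridges}
        assert freq[(310, 301)] == pytest.approx(0.75)

    def test_frequency_monotone_in_cutoff(self, jittered_ensemble):
        ens = engineer_salt_bridge(jittered_ensemble, 313, 312, 4.5, models=range(10))
        last = {}
        for cutoff in (3.0, 4.0, 5.0, 6.0):
            rep = detect_salt_bridges(ens, cutoff=cutoff)
            freq = {(b.acidic_res, b.basic_res): b.frequency for b in rep.bridges}
            for pair, f in last.items():
                assert freq.get(pair, 0.0) >= f
            last = freq

    def test_most_frequent_reports_ties(self):
        atoms = (
            Atom(1, "LYS", "NZ", "N"),
            Atom(2, "GLU", "OE1", "O"),
            Atom(3, "ARG", "NH1", "N"),
        )
        coords = np.array([[[0.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]]])
        rep = detect_salt_bridges(StructureEnsemble(atoms=atoms, coords=coords))
        assert len(rep.most_frequent()) == 2  # Glu2 bridges both Lys1 and Arg3


class TestHydrophobicClusters:
    def test_engineered_triangle(self, helical_ic_model):
        """Ile311 / Leu314 / Ser322 side chains moved into mutual contact."""
        ens = helical_ic_model
        coords = ens.coords.copy()
        targets = {311: (0.0, 0.0), 314: (3.5, 0.0), 322: (1.75, 3.0)}
        for res, (x, y) in targets.items():
            i = ens.atom_index(res, "CB")
            coords[0, i] = [x, y, 60.0]  # far from everything else
        moved = ens.with_coords(coords)
        clusters = detect_hydrophobic_clusters(moved, contact_cutoff=4.0)
        assert {311, 314, 322} in clusters

    def test_distant_residues_no_cluster(self):
        atoms = tuple(Atom(i, "LEU", n, "C") for i in (1, 5, 9) for n in ("CA", "CB"))
        coords = np.zeros((1, 6, 3))
        coords[0, :, 0] = [0, 0, 20, 20, 40, 40]
        ens = StructureEnsemble(atoms=atoms, coords=coords)
        assert detect_hydrophobic_clusters(ens, contact_cutoff=8.0) == []

    def test_three_contacting_residues_form_one_cluster(self):
        atoms = tuple(
            Atom(i, "VAL", "CB", "C") for i in (1, 3, 5)
        )
        coords = np.array([[[0.0, 0, 0], [4.0, 0, 0], [2.0, 3.4, 0]]])
        ens = StructureEnsemble(atoms=atoms, coords=coords)
        assert detect_hydrophobic_clusters(ens, contact_cutoff=4.1) == [{1, 3, 5}]


class TestOmega:
    def _bond_ensemble(self, omega_deg):
        from helixswitch.geometry import place_atom

        ca1 = np.array([0.0, 0.0, 0.0])
        c1 = np.array([1.52, 0.0, 0.0])
        n2 = place_atom([-1.0, 1.0, 0.0], ca1, c1, 1.33, 116.0, 0.0)
        ca2 = place_atom(ca1, c1, n2, 1.46, 122.0, omega_deg)
        atoms = (
            Atom(1, "ALA", "CA", "C"),
            Atom(1, "ALA", "C", "C"),
            Atom(2, "ALA", "N", "N"),
            Atom(2, "ALA", "CA", "C"),
        )
        return StructureEnsemble(
            atoms=atoms, coords=np.stack([ca1, c1, n2, ca2])[None]
        )

    @pytest.mark.parametrize(
        "omega,expected", [(180.0, "trans"), (0.0, "cis"), (90.0, "twisted")]
    )
    def test_classes(self, omega, expected):
        assert omega_classify(self._bond_ensemble(omega), 1) == expected

    def test_builder_peptide_bonds_are_trans(self, helical_ic_model):
        for r in range(298, 323):
            assert omega_classify(helical_ic_model, r) == "trans"


restraint_strategy = st.builds(
    DistanceRestraint,
    res_i=st.integers(1, 30),
    atom_i=st.just("HA"),
    res_j=st.integers(1, 30),
    atom_j=st.just("HN"),
    upper=st.floats(2.0, 8.0),
)


class TestNoeClassification:
    @pytest.mark.parametrize(
        "sep,cls",
        [(0, "intra"), (1, "sequential"), (3, "medium"), (4, "medium"), (5, "long"), (9, "long")],
    )
    def test_class_boundaries(self, sep, cls):
        r = DistanceRestraint(305, "HN", 305 + sep, "HA", 5.0)
        counts = classify_noe_restraints([r])
        assert counts[cls] == 1
        assert counts["total"] == 1

    def test_table_census(self, full_helix_model):
        rl = generate_restraints(full_helix_model, cutoff=8.0, quotas=(89, 36, 14, 0))
        counts = classify_noe_restraints(rl)
        assert counts == {
            "intra": 89, "sequential": 36, "medium": 14, "long": 0, "total": 139,
        }

    @given(st.lists(restraint_strategy, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_partition_is_exhaustive_and_disjoint(self, restraints):
        counts = classify_noe_restraints(restraints)
        assert (
            counts["intra"] + counts["sequential"] + counts["medium"] + counts["long"]
            == counts["total"]
            == len(restraints)
        )


class TestViolations:
    def _pair_ensemble(self, distance):
        atoms = (Atom(1, "ALA", "HA", "H"), Atom(2, "ALA", "HN", "H"))
        coords = np.array([[[0.0, 0, 0], [distance, 0, 0]]])
        return StructureEnsemble(atoms=atoms, coords=coords)

    def test_boundary_is_inclusive(self):
        rl = RestraintList(distance=(DistanceRestraint(1, "HA", 2, "HN", 5.0),))
        rep = check_violations(self._pair_ensemble(5.2), rl, dist_tol=0.2)
        assert rep.total_violations == 0

    def test_excess_reported(self):
        rl = RestraintList(distance=(DistanceRestraint(1, "HA", 2, "HN", 5.0),))
        rep = check_violations(self._pair_ensemble(5.5), rl, dist_tol=0.2)
        assert rep.per_model[0].distance_violations == 1
        restraint, excess = rep.per_model[0].worst_distance
        assert excess == pytest.approx(0.3)

    def test_unresolvable_restraint_skipped_with_warning(self, helical_ic_model):
        rl = RestraintList(distance=(DistanceRestraint(305, "HZ9", 306, "HN", 5.0),))
        with pytest.warns(UserWarning):
            rep = check_violations(helical_ic_model, rl)
        assert rep.skipped_restraints == 1

    def test_generated_restraints_are_satisfied(self, full_helix_model):
        rl = generate_restraints(full_helix_model, cutoff=7.0, slack=0.3,
                                 torsion_halfwidth=20.0)
        ens = jitter_ensemble(full_helix_model, 1, 0.0)
        rep = check_violations(ens, rl)
        assert rep.total_violations == 0
        assert rep.skipped_restraints == 0

    def test_torsion_violation_circular(self, full_helix_model):
        # phi of the helix is -57; a window on the far side of the circle
        # (170..179 deg) must be flagged even with wrap-around comparison
        rl = RestraintList(
            torsion=(TorsionRestraint(310, "PHI", 170.0, 179.0),)
        )
        rep = check_violations(full_helix_model, rl, torsion_tol=5.0)
        assert rep.per_model[0].torsion_violations == 1
        # and a window wrapping through 180 that contains -57 must pass
        rl_ok = RestraintList(
            torsion=(TorsionRestraint(310, "PHI", 100.0, -30.0),)
        )
        assert check_violations(full_helix_model, rl_ok).total_violations == 0


class TestCsp:
    def _table(self, residues, dh, dn):
        return pd.DataFrame({"residue": residues, "dH_ppm": dh, "dN_ppm": dn})

    def test_identical_tables_zero(self):
        t = self._table([1, 2, 3], [8.1, 8.2, 8.3], [118, 119, 120])
        out = chemical_shift_perturbation(t, t)
        assert np.allclose(out["delta_ppm"], 0.0)

    def test_pure_proton_shift(self):
        a = self._table([1], [8.0], [118.0])
        b = self._table([1], [8.1], [118.0])
        out = chemical_shift_perturbation(a, b)
        assert out["delta_ppm"].iloc[0] == pytest.approx(0.1)

    def test_hand_evaluated_combination(self):
        a = self._table([5], [8.00], [118.0])
        b = self._table([5], [8.03], [118.5])
        out = chemical_shift_perturbation(a, b, nitrogen_scale=0.14)
        assert out["delta_ppm"].iloc[0] == pytest.approx(
            np.sqrt(0.03**2 + (0.14 * 0.5) ** 2), abs=1e-12
        )

    def test_duplicate_residue_rejected(self):
        a = self._table([1, 1], [8.0, 8.1], [118, 119])
        with pytest.raises(ValueError):
            chemical_shift_perturbation(a, a)

    def test_unmatched_residue_flagged_missing(self):
        a = self._table([1, 2], [8.0, 8.1], [118, 119])
        b = self._table([1], [8.0], [118])
        out = chemical_shift_perturbation(a, b)
        assert bool(out.loc[out["residue"] == 2, "missing"].iloc[0])
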