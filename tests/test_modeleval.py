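import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from conftest import random_rotation
from zfdock.fixtures import make_mismatched_decoy, perturb_coordinates
from zfdock.modeleval import (
    ScoreRecord,
    bsa,
    classify_wrap_around,
    enumerate_contacts,
    fnat,
    irmsd,
    kabsch_superpose,
    parse_haddock_scores,
    population_table,
    relative_sasa,
    rescore_and_rank,
    sasa,
)
from zfdock.structures import Atom, Chain, Residue, Structure


def _single_atom_complex(separation):
    prot = Chain(
        id="A",
        residues=[Residue("ALA", 1, "protein", [Atom("CA", "C", np.zeros(3))])],
        role="protein",
    )
    dna = Chain(
        id="D",
        residues=[Residue("DG", 1, "dna", [Atom("C1'", "C", np.array([separation, 0.0, 0.0]))])],
        role="dna",
    )
    return Structure(chains=[prot, dna])


class TestContacts:
    @pytest.mark.parametrize("sep,expected", [(4.9, 1), (5.1, 0)])
    def test_cutoff_boundary(self, sep, expected):
        assert len(enumerate_contacts(_single_atom_complex(sep))) == expected

    def test_far_apart_empty(self, wrapped_structure):
        prot = wrapped_structure.chains_with_role("protein")[0]
        dna = wrapped_structure.chains_with_role("dna")[0]
        moved = Structure(chains=[prot, dna]).copy()
        for r in moved.chains_with_role("protein")[0].residues:
            for a in r.atoms:
                a.coords = a.coords + np.array([100.0, 0.0, 0.0])
        assert len(enumerate_contacts(moved)) == 0

    def test_matches_brute_force(self, wrapped_structure):
        got = enumerate_contacts(wrapped_structure).pairs
        prot = wrapped_structure.chains_with_role("protein")[0]
        dna = wrapped_structure.chains_with_role("dna")[0]
        expected = set()
        for rp in prot.polymer_residues():
            xp = rp.heavy_coords()
            for rd in dna.polymer_residues():
                d = np.linalg.norm(xp[:, None] - rd.heavy_coords()[None], axis=-1)
                if d.min() <= 5.0:
                    expected.add((rp.seq_id, rd.seq_id))
        assert got == expected


class TestFnat:
    def test_identity_is_one(self, wrapped_structure):
        assert fnat(wrapped_structure, wrapped_structure) == 1.0

    def test_far_model_is_zero(self, wrapped_structure):
        moved = wrapped_structure.copy()
        for r in moved.chains_with_role("protein")[0].residues:
            for a in r.atoms:
                a.coords = a.coords + np.array([100.0, 0.0, 0.0])
        assert fnat(moved, wrapped_structure) == 0.0

    def test_displaced_domain_matches_counted_fraction(self, wrapped, rng):
        s, truth = wrapped
        decoy = s.copy()
        span = truth.domains[2].span
        for r in decoy.chains_with_role("protein")[0].residues:
            if span[0] <= r.seq_id <= span[1]:
                for a in r.atoms:
                    a.coords = a.coords + np.array([0.0, 0.0, 200.0])
        native = enumerate_contacts(s).pairs
        surviving = {p for p in native if not span[0] <= p[0] <= span[1]}
        assert fnat(decoy, s) == pytest.approx(len(surviving) / len(native))

    def test_monotone_under_contact_deletion(self, wrapped, rng):
        s, truth = wrapped
        f_full = fnat(s, s)
        decoy = make_mismatched_decoy(s, truth, 2, 140.0)
        f_less = fnat(decoy, s)
        assert f_less < f_full

    def test_contactless_reference_raises(self):
        ref = _single_atom_complex(50.0)
        with pytest.raises(ValueError, match="F_nat"):
            fnat(ref, ref)


def grid_oracle_rmsd(A, B, seed=0, n=4000):
    """Independent superposition oracle: rotation sampling + local refinement."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)

    def cost_rot(R):
        return np.sqrt(np.mean(np.sum((A @ R.T - B) ** 2, axis=-1)))

    rots = Rotation.random(n, random_state=seed)
    costs = [cost_rot(r.as_matrix()) for r in rots]
    best = rots[int(np.argmin(costs))].as_rotvec()
    res = minimize(lambda v: cost_rot(Rotation.from_rotvec(v).as_matrix()), best,
                   method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    return res.fun


class TestKabsch:
    def test_identity_zero(self, rng):
        pts = rng.uniform(-5, 5, (8, 3))
        _, _, rmsd = kabsch_superpose(pts, pts)
        assert rmsd < 1e-12

    def test_rigid_transform_zero(self, rng):
        pts = rng.uniform(-5, 5, (10, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ Rz.T + np.array([5.0, 0.0, 0.0])
        R, t, rmsd = kabsch_superpose(pts, moved)
        assert rmsd < 1e-6
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matches_rotation_grid_oracle(self, rng):
        for trial in range(3):
            A = rng.uniform(-5, 5, (10, 3))
            B = rng.uniform(-5, 5, (10, 3))
            _, _, rmsd = kabsch_superpose(A, B)
            assert rmsd == pytest.approx(grid_oracle_rmsd(A, B, seed=trial), abs=1e-3)

    def test_improper_reflection_rejected(self, rng):
        pts = rng.uniform(-5, 5, (10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        R, _, _ = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_degenerate_collinear_flagged(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch_superpose(line, line + 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestIrmsd:
    def test_identity_zero(self, wrapped_structure):
        assert irmsd(wrapped_structure, wrapped_structure) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_zero(self, wrapped_structure, rng):
        R = random_rotation(rng)
        moved = wrapped_structure.transform(R, rng.uniform(-20, 20, 3))
        assert irmsd(moved, wrapped_structure) == pytest.approx(0.0, abs=1e-6)

    def test_perturbed_matches_independent_computation(self, wrapped_structure):
        model = perturb_coordinates(wrapped_structure, 0.5, seed=42)
        got = irmsd(model, wrapped_structure)
        # independent route: collect the same interface atoms, superpose with scipy
        from zfdock.modeleval import _interface_residues, _split_complex

        iface = _interface_residues(wrapped_structure, 10.0)
        rp, rd = _split_complex(wrapped_structure)
        mp, md = _split_complex(model)
        ref, mod = [], []
        for role, sid in sorted(iface):
            rres = (rp if role == "protein" else rd).residue(sid)
            mres = (mp if role == "protein" else md).residue(sid)
            matoms = {a.name: a for a in mres.heavy_atoms()}
            for a in rres.heavy_atoms():
                ref.append(a.coords)
                mod.append(matoms[a.name].coords)
        ref = np.array(ref) - np.mean(ref, axis=0)
        mod = np.array(mod) - np.mean(mod, axis=0)
        rot, ssd = Rotation.align_vectors(ref, mod, return_sensitivity=False)[0], None
        expected = np.sqrt(np.mean(np.sum((rot.apply(mod) - ref) ** 2, axis=-1)))
        assert got == pytest.approx(expected, abs=1e-6)


class TestSasa:
    def test_isolated_carbon_closed_form(self):
        s = Structure(
            chains=[Chain("A", [Residue("ALA", 1, "protein", [Atom("CA", "C", np.zeros(3))])], "protein")]
        )
        assert sasa(s) == pytest.approx(4 * np.pi * 3.1**2, rel=1e-6)

    def test_far_atoms_additive(self):
        atoms = [
            Residue("ALA", 1, "protein", [Atom("CA", "C", np.zeros(3))]),
            Residue("ALA", 2, "protein", [Atom("CA", "C", np.array([100.0, 0, 0]))]),
        ]
        s = Structure(chains=[Chain("A", atoms, "protein")])
        assert sasa(s) == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=1e-6)

    def test_caged_atom_buried(self):
        from zfdock.modeleval import _sphere_points

        cage = _sphere_points(60) * 2.8
        residues = [Residue("ALA", 1, "protein", [Atom("CA", "C", np.zeros(3))])]
        for i, c in enumerate(cage, start=2):
            residues.append(Residue("ALA", i, "protein", [Atom("CA", "C", c)]))
        s = Structure(chains=[Chain("A", residues, "protein")])
        coords = np.vstack([np.zeros(3), cage])
        from zfdock.modeleval import _sasa_atoms

        areas = _sasa_atoms(coords, ["C"] * len(coords), 1.4, 960)
        assert areas[0] < 1.0  # central atom essentially fully occluded

    def test_unknown_element_listed(self):
        s = Structure(
            chains=[Chain("A", [Residue("HEM", 1, "protein", [Atom("FE", "Fe", np.zeros(3))])], "protein")]
        )
        with pytest.raises(ValueError, match="Fe"):
            sasa(s)

    def test_relative_sasa_bounds(self, wrapped_structure):
        prot = Structure(chains=[wrapped_structure.chains_with_role("protein")[0]])
        rel = relative_sasa(prot)
        assert all(0.0 <= v <= 1.0 + 1e-9 for v in rel.values())


class TestBsa:
    def test_separated_chains_zero(self):
        s = _single_atom_complex(100.0)
        assert bsa(s) == pytest.approx(0.0, abs=0.5)

    def test_positive_on_wrapped_fixture(self, wrapped_structure):
        value = bsa(wrapped_structure)
        assert value > 0.0


class TestWrapClassifier:
    def test_wrapped_fixture_true(self, wrapped):
        s, truth = wrapped
        wrap, cov = classify_wrap_around(s, truth.axis, truth.domains)
        assert wrap
        assert cov >= 240.0

    def test_one_sector_false(self, wrapped):
        from zfdock.fixtures import DecoyConfig, make_wrapped_complex

        s, truth = make_wrapped_complex(DecoyConfig(azimuths=(0.0, 25.0, 50.0)))
        wrap, cov = classify_wrap_around(s, truth.axis, truth.domains)
        assert not wrap
        assert cov < 180.0

    def test_rotated_domain_false_with_violations(self, wrapped):
        from zfdock.restraints import air_energy, build_pairwise_airs

        s, truth = wrapped
        decoy = make_mismatched_decoy(s, truth, 3, 150.0)
        wrap, _ = classify_wrap_around(decoy, truth.axis, truth.domains)
        assert not wrap
        airs = build_pairwise_airs(truth.true_pairs())
        _, recs = air_energy(airs, decoy)
        dom3 = [r for r in recs if r["domain_index"] == 3]
        assert all(r["violation"] > 0 for r in dom3)
        assert all(r["violation"] == 0 for r in recs if r["domain_index"] != 3)

    def test_rigid_invariance(self, wrapped, rng):
        from zfdock.axisgeom import fit_helix_axis

        s, truth = wrapped
        wrap0, cov0 = classify_wrap_around(s, truth.axis, truth.domains)
        R = random_rotation(rng)
        moved = s.transform(R, rng.uniform(-30, 30, 3))
        axis = fit_helix_axis(moved)
        wrap1, cov1 = classify_wrap_around(moved, axis, truth.domains)
        assert wrap0 == wrap1
        assert cov0 == pytest.approx(cov1, abs=1.0)

    def test_no_contacts_false_zero(self, wrapped):
        s, truth = wrapped
        moved = s.copy()
        for r in moved.chains_with_role("protein")[0].residues:
            for a in r.atoms:
                a.coords = a.coords + np.array([200.0, 0.0, 0.0])
        wrap, cov = classify_wrap_around(moved, truth.axis, truth.domains)
        assert (wrap, cov) == (False, 0.0)


class TestScores:
    def test_filelist_parsing(self, tmp_path):
        (tmp_path / "file.list").write_text(
            '"PREVIT:complex_1w.pdb" { -241.91 }\n'
            '"PREVIT:complex_2w.pdb" { -238.62 }\n'
            '"PREVIT:complex_3w.pdb" { -189.02 }\n'
        )
        recs = parse_haddock_scores(tmp_path / "file.list")
        assert [r.model_id for r in recs] == ["complex_1w", "complex_2w", "complex_3w"]
        assert recs[0].haddock_score == pytest.approx(-241.91)

    def test_remark_parsing(self, tmp_path):
        p = tmp_path / "m1.pdb"
        p.write_text(
            "REMARK energies: Evdw=-45.2, Eelec=-967.8, Edesolv=12.1, Eair=8.5, BSA=2780.3\n"
            "REMARK HADDOCKscore=-238.62\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        (rec,) = parse_haddock_scores(p)
        assert rec.e_vdw == pytest.approx(-45.2)
        assert rec.e_inter == pytest.approx(-967.8 - 45.2)
        assert rec.haddock_score == pytest.approx(-238.62)
        assert rec.e_desolv == pytest.approx(12.1)

    def test_empty_dir_raises(self, tmp_path):
        with pytest.raises(ValueError):
            parse_haddock_scores(tmp_path)

    def test_rank_ordering_and_topn(self):
        recs = [
            ScoreRecord("m1", haddock_score=-10.0),
            ScoreRecord("m2", haddock_score=-5.0),
            ScoreRecord("m3", haddock_score=-20.0),
        ]
        ranked = rescore_and_rank(recs, n=10)
        assert [r.model_id for r, _ in ranked] == ["m3", "m1", "m2"]
        top1 = rescore_and_rank(recs, n=1)
        assert len(top1) == 1 and top1[0][0].model_id == "m3"

    def test_stable_ties(self):
        recs = [ScoreRecord(f"m{i}", haddock_score=-7.0) for i in range(5)]
        ranked = rescore_and_rank(recs, n=5)
        assert [r.model_id for r, _ in ranked] == [f"m{i}" for i in range(5)]

    def test_weighted_rescoring_missing_component(self):
        recs = [ScoreRecord("m1", e_vdw=-40.0)]
        with pytest.raises(ValueError, match="e_elec"):
            rescore_and_rank(recs, weights={"e_vdw": 0.2, "e_elec": 1.0})

    def test_weighted_rescore_reproduces_parsed_order(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(8):
            e_vdw, e_elec = rng.uniform(-100, 0, 2)
            score = 0.2 * e_vdw + 1.0 * e_elec
            recs.append(ScoreRecord(f"m{i}", e_vdw=e_vdw, e_elec=e_elec, haddock_score=score))
        by_parsed = [r.model_id for r, _ in rescore_and_rank(recs, n=8)]
        by_weights = [
            r.model_id
            for r, _ in rescore_and_rank(recs, weights={"e_vdw": 0.2, "e_elec": 1.0}, n=8)
        ]
        assert by_parsed == by_weights


class TestPopulations:
    def test_two_separated_clusters(self):
        rng = np.random.default_rng(11)
        low = rng.uniform(0, 5, 12)
        high = rng.uniform(200, 220, 8)
        recs = [ScoreRecord(f"m{i}", haddock_score=0.0) for i in range(20)]
        e_air = {f"m{i}": v for i, v in enumerate(np.concatenate([low, high]))}
        _, pops = population_table(recs, e_air)
        assert len(pops) == 2
        assert sorted(p["count"] for p in pops) == [8, 12]

    def test_single_tight_cluster(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0, 8, 15)
        recs = [ScoreRecord(f"m{i}", haddock_score=0.0) for i in range(15)]
        _, pops = population_table(recs, {f"m{i}": v for i, v in enumerate(vals)})
        assert len(pops) == 1
        assert pops[0]["count"] == 15

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            population_table([], {})

    def test_id_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            population_table([ScoreRecord("m1")], {"m2": 1.0})
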