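"""Solenoid geometry metrics: superposition, helix parameters, stagger,
H-bond candidates and buried area, with independent oracles."""

import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import biotite.structure as struc
from curlinkit.geometry import (
    GeometryError,
    assemble_model,
    buried_area_per_repeat,
    consecutive_repeat_rmsd,
    geometry_report,
    hbond_candidates_per_repeat,
    measure_stagger,
    read_structure,
    repeat_helix_params,
    superpose,
    write_pdb,
)
from curlinkit.synthetic import SolenoidSpec, generate_solenoid_coords


def _random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(1 << 16)))).as_matrix()
    t = rng.normal(0, 50, 3)
    return R, t


def _transformed_copy(model, R, t):
    return model.transformed(R, t)


class TestSuperpose:
    def test_recovers_known_transform(self, rng):
        P = rng.normal(0, 10, (40, 3))
        R, t = _random_rigid(rng)
        Q = P @ R.T + t
        R2, t2, rmsd = superpose(P, Q)
        assert rmsd < 1e-9
        assert np.allclose(R2, R, atol=1e-9)
        assert np.allclose(t2, t, atol=1e-8)

    def test_matches_biotite_oracle(self, rng):
        """Independent least-squares oracle on noisy <=50-atom instances."""
        for _ in range(10):
            n = int(rng.integers(5, 51))
            P = rng.normal(0, 10, (n, 3))
            Q = P @ _random_rigid(rng)[0].T + rng.normal(0, 1, (n, 3))
            _, _, rmsd = superpose(P, Q)
            _, transform = struc.superimpose(Q.astype(float), P.astype(float))
            fitted = transform.apply(P.astype(np.float64)[None])[0] \
                if hasattr(transform, "apply") else None
            ref = struc.rmsd(Q, fitted) if fitted is not None else None
            assert rmsd == pytest.approx(float(ref), abs=1e-6)

    def test_reflection_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        Q = P * np.array([-1.0, 1.0, 1.0])    # mirror image
        R, _, rmsd = superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert rmsd > 0.1                     # cannot be absorbed


class TestConsecutiveRMSD:
    def test_noiseless_is_zero(self):
        model = generate_solenoid_coords(SolenoidSpec(n_repeats=5))
        mean, sd = consecutive_repeat_rmsd(model)
        assert mean == pytest.approx(0.0, abs=1e-5)

    def test_matches_bruteforce_pairwise_oracle(self):
        """Noisy model: per-pair RMSDs recomputed independently."""
        model = generate_solenoid_coords(
            SolenoidSpec(n_repeats=6, noise_sd=0.1, seed=4))
        mean, sd = consecutive_repeat_rmsd(model)
        ref = []
        for a, b in zip(range(5), range(1, 6)):
            ca = model.mainchain_coords(a)
            cb = model.mainchain_coords(b)
            keys = sorted(set(ca) & set(cb))
            P = np.array([ca[k] for k in keys])
            Q = np.array([cb[k] for k in keys])
            fitted, _ = struc.superimpose(Q, P)[1].apply(P[None]), None
            ref.append(float(struc.rmsd(Q, struc.superimpose(Q, P)[0])))
        assert mean == pytest.approx(float(np.mean(ref)), abs=1e-6)
        assert sd == pytest.approx(float(np.std(ref, ddof=1)), abs=1e-6)

    def test_single_repeat_rejected(self):
        model = generate_solenoid_coords(SolenoidSpec(n_repeats=2))
        model.res_repeat[model.res_repeat == 1] = -1
        with pytest.raises(GeometryError):
            consecutive_repeat_rmsd(model)


class TestHelixParams:
    GRID = [(rise, twist, noise)
            for rise in (4.5, 4.8, 5.1)
            for twist in (-2.0, 0.0, 2.0)
            for noise in (0.0, 0.2)]

    @pytest.mark.parametrize("rise,twist,noise", GRID)
    def test_parameter_recovery_grid(self, rise, twist, noise):
        hand = "left" if twist < 0 else ("right" if twist > 0 else "left")
        model = generate_solenoid_coords(SolenoidSpec(
            n_repeats=15, rise_per_repeat=rise, twist_per_repeat=twist,
            handedness=hand, noise_sd=noise, seed=7))
        h = repeat_helix_params(model)
        assert h.rise == pytest.approx(rise, rel=0.02)
        assert h.twist == pytest.approx(twist, abs=0.1)

    def test_fine_twist_recovery(self):
        model = generate_solenoid_coords(SolenoidSpec(
            n_repeats=15, twist_per_repeat=1.333, handedness="right"))
        h = repeat_helix_params(model)
        assert h.twist == pytest.approx(1.333, abs=1e-3)
        assert h.handedness == "right"

    @pytest.mark.parametrize("hand", ["left", "right"])
    def test_zero_twist_handedness_from_winding(self, hand):
        model = generate_solenoid_coords(SolenoidSpec(
            n_repeats=5, handedness=hand))
        assert repeat_helix_params(model).handedness == hand

    def test_rigid_motion_invariance(self, rng):
        model = generate_solenoid_coords(SolenoidSpec(
            n_repeats=8, twist_per_repeat=1.0, handedness="right",
            noise_sd=0.05, seed=3))
        R, t = _random_rigid(rng)
        moved = _transformed_copy(model, R, t)
        h0, h1 = repeat_helix_params(model), repeat_helix_params(moved)
        assert h1.rise == pytest.approx(h0.rise, abs=1e-4)
        assert h1.twist == pytest.approx(h0.twist, abs=1e-4)
        assert h1.handedness == h0.handedness
        r0 = consecutive_repeat_rmsd(model)[0]
        r1 = consecutive_repeat_rmsd(moved)[0]
        assert r1 == pytest.approx(r0, abs=1e-5)
        assert measure_stagger(moved) == pytest.approx(
            measure_stagger(model), abs=1e-4)
        assert hbond_candidates_per_repeat(moved) == \
            hbond_candidates_per_repeat(model)

    def test_mirror_flips_handedness_and_twist(self):
        model = generate_solenoid_coords(SolenoidSpec(
            n_repeats=10, twist_per_repeat=1.5, handedness="right"))
        mirrored = model.transformed(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))
        h0, h1 = repeat_helix_params(model), repeat_helix_params(mirrored)
        assert h1.twist == pytest.approx(-h0.twist, abs=1e-4)
        assert {h0.handedness, h1.handedness} == {"left", "right"}
        # scalar metrics preserved under reflection
        assert consecutive_repeat_rmsd(mirrored)[0] == pytest.approx(
            consecutive_repeat_rmsd(model)[0], abs=1e-5)
        assert measure_stagger(mirrored) == pytest.approx(
            measure_stagger(model), abs=1e-4)
        assert hbond_candidates_per_repeat(mirrored) == \
            hbond_candidates_per_repeat(model)

    def test_zero_translation_rejected(self):
        model = generate_solenoid_coords(SolenoidSpec(n_repeats=3))
        # collapse all repeats onto the first
        per = model.atoms.array_length() // 3
        c = model.atoms.coord.copy()
        c[per:2 * per] = c[:per]
        c[2 * per:] = c[:per]
        model.atoms.coord = c
        with pytest.raises(GeometryError):
            repeat_helix_params(model)


class TestStagger:
    @pytest.mark.parametrize("stagger", [0.0, 2.4])
    def test_recovers_construction(self, stagger):
        model = generate_solenoid_coords(SolenoidSpec(
            n_repeats=6, stagger=stagger))
        assert measure_stagger(model) == pytest.approx(stagger, abs=1e-4)

    def test_needs_sheet_map(self):
        model = generate_solenoid_coords(SolenoidSpec(n_repeats=3))
        model.res_sheet[:] = "unmapped"
        with pytest.raises(GeometryError):
            measure_stagger(model)


def _bruteforce_hbonds(model, cutoff=3.5):
    """Direct O(n^2) enumeration with the declared counting rule."""
    arr = model.atoms
    idx = model.atom_residue_index()
    polar = np.flatnonzero(np.isin(arr.element, ("N", "O")))
    count = 0
    for ii, i in enumerate(polar):
        for j in polar[ii + 1:]:
            ri, rj = int(idx[i]), int(idx[j])
            if ri == rj:
                continue
            d = np.linalg.norm(arr.coord[i] - arr.coord[j])
            if d > cutoff:
                continue
            if abs(ri - rj) == 1:
                lo, hi = (i, j) if ri < rj else (j, i)
                if arr.atom_name[lo] == "C" and arr.atom_name[hi] == "N":
                    continue
                if model.res_sheet[ri] == model.res_sheet[rj]:
                    continue
            count += 1
    return count / len(model.full_repeat_ids)


class TestHbonds:
    def test_matches_bruteforce_enumeration(self):
        model = generate_solenoid_coords(SolenoidSpec(n_repeats=4))
        assert hbond_candidates_per_repeat(model) == pytest.approx(
            _bruteforce_hbonds(model))

    def test_parallel_ladder_pairings(self):
        """Two stacked strands at H-bond register: every O(i)-N(i) rung pair
        plus the diagonal O(i)-N(i+1) contact, enumerated by hand."""
        from curlinkit.synthetic import _strand_residue
        res = []
        for k in range(2):               # two rungs, 4.8 A apart
            for i in range(5):
                res.append(_strand_residue(0.0, i * 3.3, k * 4.8, 1.0, None))
        coords = np.array([xyz for r in res for _, _, xyz in r])
        names = np.array([n for r in res for n, _, _ in r])
        elements = np.array([e for r in res for _, e, _ in r])
        res_index = np.repeat(np.arange(10), 4)
        model = assemble_model(
            coords, names, elements, res_index,
            repeat_of=np.repeat([0, 1], 5),
            motif_pos=np.tile(np.arange(1, 6), 2),
            sheet_of=np.array(["sheet1"] * 10, dtype=object))
        got = hbond_candidates_per_repeat(model)
        assert got == pytest.approx(_bruteforce_hbonds(model))
        # distant pairs contribute nothing under a shrunken cutoff
        assert hbond_candidates_per_repeat(model, cutoff=0.5) == 0.0

    def test_no_polar_atoms_warns(self):
        coords = np.array([[0.0, 0, 0], [0, 0, 4.8]])
        model = assemble_model(
            coords, np.array(["CA", "CA"]), np.array(["C", "C"]),
            np.array([0, 1]), repeat_of=np.array([0, 1]),
            motif_pos=np.array([1, 1]),
            sheet_of=np.array(["sheet1", "sheet1"], dtype=object))
        with pytest.warns(UserWarning):
            assert hbond_candidates_per_repeat(model) == 0.0


class TestBuriedArea:
    def test_far_sheets_bury_nothing(self):
        model = generate_solenoid_coords(SolenoidSpec(
            n_repeats=4, sheet_spacing=100.0))
        assert buried_area_per_repeat(model).per_repeat == pytest.approx(
            0.0, abs=1.0)

    def test_monotone_in_sheet_spacing(self):
        areas = [buried_area_per_repeat(
            generate_solenoid_coords(SolenoidSpec(n_repeats=5, sheet_spacing=s))
        ).per_repeat for s in (8, 10, 12, 16, 20)]
        assert areas[0] > areas[1] > areas[2] >= 0.0  # strict while positive
        assert areas[2] == pytest.approx(0.0, abs=1.0)
        assert areas[3] == pytest.approx(0.0, abs=1.0)

    def test_conventions_reported(self):
        model = generate_solenoid_coords(SolenoidSpec(n_repeats=4))
        out = buried_area_per_repeat(model, probe_radius=1.4, point_number=300)
        assert out.probe_radius == 1.4
        assert out.point_number == 300
        assert out.approximate                        # pseudo-CB only


class TestStructureIO:
    def test_pdb_round_trip_preserves_metrics(self, tmp_path):
        model = generate_solenoid_coords(SolenoidSpec(
            n_repeats=4, twist_per_repeat=1.0, handedness="right"))
        path = tmp_path / "solenoid.pdb"
        write_pdb(model, path)
        n_res = len(model.res_repeat)
        ranges = [(k * 23, (k + 1) * 23) for k in range(4)]
        loaded = read_structure(path, repeat_ranges=ranges)
        assert loaded.n_residues == n_res
        h0, h1 = repeat_helix_params(model), repeat_helix_params(loaded)
        assert h1.rise == pytest.approx(h0.rise, abs=1e-2)
        assert h1.twist == pytest.approx(h0.twist, abs=1e-2)
        assert measure_stagger(loaded) == pytest.approx(
            measure_stagger(model), abs=1e-2)

    def test_missing_atoms_reported(self, tmp_path):
        model = generate_solenoid_coords(SolenoidSpec(n_repeats=3))
        path = tmp_path / "truncated.pdb"
        write_pdb(model, path)
        lines = [l for l in path.read_text().splitlines()
                 if not (l.startswith("ATOM") and " O  " in l and " 5 " in l)]
        (tmp_path / "t2.pdb").write_text("\n".join(lines) + "\n")
        loaded = read_structure(tmp_path / "t2.pdb",
                                repeat_ranges=[(k * 23, (k + 1) * 23)
                                               for k in range(3)])
        assert any("O" in missing for _, missing in loaded.missing_atoms)

    def test_unparseable_file_rejected(self, tmp_path):
        bad = tmp_path / "junk.pdb"
        bad.write_text("this is not a structure\n")
        from curlinkit.geometry import FormatError
        with pytest.raises((FormatError, GeometryError, Exception)):
            model = read_structure(bad, repeat_ranges=[(0, 23)])
            repeat_helix_params(model)

    def test_annotation_length_mismatch(self, tmp_path):
        from curlinkit.geometry import AlignmentError
        from curlinkit.mining import annotate_sequence
        from curlinkit.synthetic import SequenceSpec, generate_curlin_sequence
        model = generate_solenoid_coords(SolenoidSpec(n_repeats=3))
        path = tmp_path / "m.pdb"
        write_pdb(model, path)
        seq, _ = generate_curlin_sequence(SequenceSpec(n_repeats=10, seed=1))
        ann = annotate_sequence("x", seq)      # 230 residues != 69
        with pytest.raises(AlignmentError):
            read_structure(path, annotation=ann)


class TestGeometryReport:
    def test_report_matches_generator_spec(self):
        model = generate_solenoid_coords(SolenoidSpec(n_repeats=6))
        rep = geometry_report(model)
        assert rep.rise_per_repeat == pytest.approx(4.8, abs=1e-3)
        assert rep.stagger == pytest.approx(2.4, abs=1e-3)
        assert rep.handedness == "left"
        assert rep.mean_consecutive_rmsd < 1e-4
        assert rep.conventions["sasa_probe_radius"] == 1.4
        d = rep.to_dict()
        assert set(d) >= {"rise_per_repeat", "twist_per_repeat", "stagger",
                          "hbond_per_repeat", "buried_area_per_repeat"}
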