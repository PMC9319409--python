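"""Lattice construction, CoMFA/CoMSIA field evaluation, matrix filtering."""

import numpy as np
import pytest

from fieldqsar import (
    AlignedMolecule,
    Atom,
    FieldGrid,
    FieldSettings,
    assign_atom_params,
    build_descriptor_matrix,
    build_grid,
    comfa_fields,
    comsia_at_points,
    comsia_fields,
    compute_field_blocks,
    write_dx,
)
from fieldqsar.grid_fields import COULOMB_CONSTANT, DegenerateMatrixError, FieldBlock


def _mol(atoms, bonds=()):
    return assign_atom_params(AlignedMolecule("m", atoms, list(bonds)))


def _point_grid(point):
    return FieldGrid(origin=tuple(point), spacing=1.0, npoints=(1, 1, 1))


class TestBuildGrid:
    def test_single_atom_margins(self, single_carbon):
        grid = build_grid([single_carbon], spacing=2.0, margin=4.0)
        assert grid.origin == (-4.0, -4.0, -4.0)
        assert grid.npoints == (5, 5, 5)

    def test_two_atom_extent(self):
        mol = _mol([Atom("C", (0, 0, 0), 0.0), Atom("C", (10, 0, 0), 0.0)])
        grid = build_grid([mol], spacing=2.0, margin=4.0)
        xs = grid.points()[:, 0]
        assert xs.min() == -4.0 and xs.max() == 14.0

    def test_deterministic_over_series(self, series35):
        mols, _, _ = series35
        g1 = build_grid(mols)
        g2 = build_grid(mols)
        assert g1 == g2

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_grid([])

    def test_point_order_x_fastest(self):
        grid = FieldGrid((0.0, 0.0, 0.0), 1.0, (2, 2, 2))
        pts = grid.points()
        np.testing.assert_allclose(pts[0], [0, 0, 0])
        np.testing.assert_allclose(pts[1], [1, 0, 0])  # x index varies first
        np.testing.assert_allclose(pts[2], [0, 1, 0])
        np.testing.assert_allclose(pts[4], [0, 0, 1])


class TestComfaFields:
    def test_far_probe_fields_vanish(self, single_carbon):
        grid = _point_grid((300.0, 0.0, 0.0))
        steric, elec, excluded = comfa_fields(single_carbon, grid)
        assert abs(steric[0]) < 1e-6 and abs(elec[0]) < 1e-6
        assert not excluded[0]

    def test_probe_on_atom_center_capped(self, single_carbon):
        steric, _, excluded = comfa_fields(single_carbon, _point_grid((0.0, 0.0, 0.0)))
        assert steric[0] == pytest.approx(30.0)
        assert excluded[0]

    def test_lj_minimum_equals_minus_epsilon_star(self, single_carbon):
        settings = FieldSettings()
        r_star = single_carbon.atoms[0].vdw_radius + settings.probe_radius
        eps_star = np.sqrt(single_carbon.atoms[0].well_depth * settings.probe_well_depth)
        steric, _, _ = comfa_fields(single_carbon, _point_grid((r_star, 0.0, 0.0)), settings)
        assert steric[0] == pytest.approx(-eps_star, rel=1e-10)

    def test_electrostatic_distance_dependent_dielectric(self):
        mol = _mol([Atom("C", (0, 0, 0), 0.1)])
        _, elec, _ = comfa_fields(mol, _point_grid((4.0, 0.0, 0.0)))
        # 332.0636 * 0.1 / (eps(r)=r * r) at r=4
        assert elec[0] == pytest.approx(COULOMB_CONSTANT * 0.1 / 16.0, rel=1e-10)

    def test_truncation_bound_holds_everywhere(self, series35):
        mols, _, _ = series35
        grid = build_grid(mols[:5], spacing=1.0, margin=2.0)
        for mol in mols[:5]:
            steric, elec, _ = comfa_fields(mol, grid)
            assert np.abs(steric).max() <= 30.0 + 1e-12
            assert np.abs(elec).max() <= 30.0 + 1e-12

    def test_translation_covariance(self, methane):
        grid = build_grid([methane], spacing=2.0, margin=3.0)
        steric, elec, _ = comfa_fields(methane, grid)
        shift = np.array([3.0, -2.0, 5.0])
        moved = AlignedMolecule(
            "m2",
            [Atom(a.element, tuple(np.array(a.position) + shift), a.partial_charge,
                  a.vdw_radius, a.well_depth, a.steric_weight, a.hydrophobicity,
                  a.is_donor, a.is_acceptor) for a in methane.atoms],
            methane.bonds,
        )
        grid2 = FieldGrid(tuple(np.array(grid.origin) + shift), grid.spacing, grid.npoints)
        steric2, elec2, _ = comfa_fields(moved, grid2)
        np.testing.assert_allclose(steric, steric2, atol=1e-8)
        np.testing.assert_allclose(elec, elec2, atol=1e-8)


class TestComsiaFields:
    def test_probe_at_atom_center(self, single_carbon):
        vals = comsia_at_points(single_carbon, [(0.0, 0.0, 0.0)], ["comsia_S"])
        assert vals["comsia_S"][0] == pytest.approx(-single_carbon.atoms[0].steric_weight)

    def test_two_atom_hand_summed_gaussian(self):
        mol = _mol([Atom("C", (0, 0, 0), 0.1), Atom("O", (2, 0, 0), -0.3)], [(0, 1)])
        point = np.array([1.0, 1.0, 0.0])
        vals = comsia_at_points(mol, [point], ["comsia_S", "comsia_E"])
        d2 = [2.0, 2.0]
        w_s = [1.70 ** 3, 1.52 ** 3]
        w_e = [0.1, -0.3]
        expect_s = -sum(w * np.exp(-0.3 * d) for w, d in zip(w_s, d2))
        expect_e = -sum(w * np.exp(-0.3 * d) for w, d in zip(w_e, d2))
        assert vals["comsia_S"][0] == pytest.approx(expect_s, rel=1e-12)
        assert vals["comsia_E"][0] == pytest.approx(expect_e, rel=1e-12)

    def test_rigid_rotation_invariance(self, methane, rng):
        from scipy.spatial.transform import Rotation

        pts = rng.uniform(-3, 3, size=(20, 3))
        ref = comsia_at_points(methane, pts)
        R = Rotation.random(random_state=11).as_matrix()
        rotated = AlignedMolecule(
            "r",
            [Atom(a.element, tuple(R @ np.array(a.position)), a.partial_charge,
                  a.vdw_radius, a.well_depth, a.steric_weight, a.hydrophobicity,
                  a.is_donor, a.is_acceptor) for a in methane.atoms],
            methane.bonds,
        )
        rot = comsia_at_points(rotated, pts @ R.T)
        for kind in ref:
            np.testing.assert_allclose(ref[kind], rot[kind], atol=1e-8)

    def test_additivity_over_fragments(self, rng):
        a1 = [Atom("C", (0, 0, 0), 0.2), Atom("N", (1.4, 0, 0), -0.4)]
        a2 = [Atom("O", (5, 1, 0), -0.3), Atom("C", (6, 0, 1), 0.1)]
        whole = _mol(a1 + a2, [(0, 1), (2, 3)])
        f1, f2 = _mol(a1, [(0, 1)]), _mol(a2, [(0, 1)])
        pts = rng.uniform(-2, 8, size=(15, 3))
        vw = comsia_at_points(whole, pts)
        v1 = comsia_at_points(f1, pts)
        v2 = comsia_at_points(f2, pts)
        for kind in vw:
            np.testing.assert_allclose(vw[kind], v1[kind] + v2[kind], atol=1e-10)

    def test_smoothness_under_grid_refinement(self, methane):
        # doubling resolution: coarse-lattice values reappear identically and
        # neighbours vary continuously (no caps/jumps)
        coarse = FieldGrid((-3.0, -3.0, -3.0), 2.0, (4, 4, 4))
        fine = FieldGrid((-3.0, -3.0, -3.0), 1.0, (7, 7, 7))
        vc = comsia_fields(methane, coarse, kinds=["comsia_S"])["comsia_S"]
        vf = comsia_fields(methane, fine, kinds=["comsia_S"])["comsia_S"]
        grid_c = vc.reshape(4, 4, 4)
        grid_f = vf.reshape(7, 7, 7)
        np.testing.assert_allclose(grid_c, grid_f[::2, ::2, ::2], atol=1e-12)
        steps = np.abs(np.diff(grid_f, axis=2))
        assert steps.max() < np.abs(vf).max()  # no discontinuous jumps

    def test_unknown_kind_named_in_error(self, methane):
        with pytest.raises(ValueError, match="comsia_X"):
            comsia_at_points(methane, [(0, 0, 0)], ["comsia_X"])


class TestDescriptorMatrix:
    def test_constant_fields_are_degenerate(self, single_carbon):
        mols = []
        for i in range(5):
            m = AlignedMolecule(f"m{i}", single_carbon.atoms, single_carbon.bonds, 5.0 + i)
            mols.append(m)
        grid = build_grid(mols, spacing=2.0, margin=4.0)
        with pytest.raises(DegenerateMatrixError):
            build_descriptor_matrix(mols, grid, ["comsia_S"])

    def test_excluded_electrostatic_imputed_with_column_mean(self):
        grid = FieldGrid((0.0, 0.0, 0.0), 1.0, (2, 1, 1))
        vals = np.array([[4.0, 9.0], [8.0, 9.0], [12.0, 9.0], [16.0, 9.0], [29.0, 9.0]])
        excl = np.zeros_like(vals, dtype=bool)
        excl[4, 0] = True
        steric = np.tile(np.linspace(0, 40, 5)[:, None], (1, 2))  # keeps col sd high
        blocks = {
            "comfa_steric": FieldBlock("comfa_steric", steric, grid),
            "comfa_electrostatic": FieldBlock("comfa_electrostatic", vals, grid, excluded=excl),
        }
        mols = [AlignedMolecule(f"m{i}", [Atom("C", (0, 0, 0), 0.0)], pic50=5.0 + i)
                for i in range(5)]
        dm = build_descriptor_matrix(
            mols, grid, ["comfa_steric", "comfa_electrostatic"], blocks=blocks
        )
        elec_cols = dm.X[:, dm.col_kind == "comfa_electrostatic"]
        assert elec_cols[4, 0] == pytest.approx(np.mean([4.0, 8.0, 12.0, 16.0]))

    def test_variance_filter_matches_brute_force(self, small_series):
        mols, _, _ = small_series
        grid = build_grid(mols)
        settings = FieldSettings()
        blocks = compute_field_blocks(mols, grid, ["comsia_S"], settings)
        dm = build_descriptor_matrix(mols, grid, ["comsia_S"], settings, blocks=blocks)
        sd = blocks["comsia_S"].values.std(axis=0)
        np.testing.assert_array_equal(dm.mask, sd >= settings.sigma_min_comsia)

    def test_surviving_columns_near_substitution_sites(self, series35):
        from fieldqsar.synthetic_data import _SCAFFOLD_ATOMS, _SITES

        mols, _, _ = series35
        grid = build_grid(mols)
        dm = build_descriptor_matrix(mols, grid, ["comsia_S"])
        sd = dm.X.std(axis=0)
        top = dm.grid.points()[dm.col_point[np.argsort(sd)[-10:]]]
        sites = np.array([_SCAFFOLD_ATOMS[i][1] for i, _ in _SITES])
        for pt in top:
            assert np.min(np.linalg.norm(sites - pt, axis=1)) < 7.0


def test_dx_export_roundtrip(tmp_path, single_carbon):
    grid = FieldGrid((-2.0, -2.0, -2.0), 2.0, (3, 2, 2))
    vals = comsia_fields(single_carbon, grid, kinds=["comsia_S"])["comsia_S"]
    path = tmp_path / "field.dx"
    write_dx(path, vals, grid)
    text = path.read_text()
    assert "counts 3 2 2" in text
    data = []
    started = False
    for line in text.splitlines():
        if line.startswith("object 3"):
            started = True
            continue
        if started:
            if line.startswith("attribute"):
                break
            data.extend(float(v) for v in line.split())
    # DX stores z-fastest; undo to recover the package's x-fastest order
    arr = np.array(data).reshape(3, 2, 2).transpose(2, 1, 0).ravel()
    np.testing.assert_allclose(arr, vals, rtol=1e-5)
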