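import numpy as np
import pytest

from gjqsar.compound_table import DataError
from gjqsar.field_qsar import (
    DEFAULT_MAP_CUTOFF,
    DEFAULT_PROBE,
    AlignedMolecule,
    Atom,
    GridSpec,
    PlsModel,
    apply_cutoff,
    build_grid,
    compute_mif,
    export_coefficient_map,
    fit_pls,
    mif_matrix,
    pls_predict,
    read_aligned_sdf,
    select_components_loo,
    truncate_extremes,
    write_dx,
)


def _mol(coords, charges=None, cid=1, rmin=3.8, epsilon=0.107):
    charges = charges if charges is not None else [0.0] * len(coords)
    atoms = tuple(
        Atom("C", float(x), float(y), float(z), charge=float(q), rmin=rmin, epsilon=epsilon)
        for (x, y, z), q in zip(coords, charges)
    )
    return AlignedMolecule(cid=cid, atoms=atoms)


class TestBuildGrid:
    def test_single_atom_default_box(self):
        grid = build_grid([_mol([(0, 0, 0)])], step=1.0, outgap=5.0)
        assert grid.dims == (11, 11, 11)
        assert grid.origin == (-5.0, -5.0, -5.0)

    def test_zero_outgap_degenerate_box(self):
        grid = build_grid([_mol([(0, 0, 0)])], step=1.0, outgap=0.0)
        assert grid.dims == (1, 1, 1)

    def test_two_atoms_along_x(self):
        grid = build_grid([_mol([(0, 0, 0), (4, 0, 0)])], step=1.0, outgap=5.0)
        assert grid.dims == (15, 11, 11)

    def test_box_covers_molecules_with_outgap(self, rng):
        mols = [_mol(rng.normal(size=(5, 3)), cid=i) for i in range(3)]
        grid = build_grid(mols, step=1.0, outgap=5.0)
        coords = np.vstack([m.coords() for m in mols])
        lo = np.array(grid.origin)
        hi = lo + (np.array(grid.dims) - 1) * grid.step
        assert np.all(coords.min(axis=0) - 5.0 >= lo - 1e-9)
        # dims rounding may trim less than one step from the far side
        assert np.all(hi >= coords.max(axis=0) + 5.0 - grid.step)

    def test_points_order_x_fastest(self):
        grid = GridSpec(origin=(0.0, 0.0, 0.0), step=1.0, dims=(2, 2, 2), outgap=0.0)
        pts = grid.points()
        np.testing.assert_array_equal(pts[0], [0, 0, 0])
        np.testing.assert_array_equal(pts[1], [1, 0, 0])
        np.testing.assert_array_equal(pts[2], [0, 1, 0])
        np.testing.assert_array_equal(pts[4], [0, 0, 1])


class TestComputeMif:
    def test_zero_charge_electrostatic_is_zero(self):
        mol = _mol([(0, 0, 0), (1.5, 0, 0)])
        grid = build_grid([mol], step=1.0, outgap=5.0)
        f = compute_mif(mol, grid, "electrostatic")
        np.testing.assert_array_equal(f.values, 0.0)

    def test_lj_minimum_identity(self):
        # probe at the combined minimum-energy distance sees -combined depth
        mol = _mol([(0, 0, 0)], rmin=4.0, epsilon=0.107)
        rc = (4.0 + DEFAULT_PROBE.rmin) / 2.0
        eps_c = np.sqrt(0.107 * DEFAULT_PROBE.epsilon)
        grid = GridSpec(origin=(rc, 0.0, 0.0), step=1.0, dims=(1, 1, 1), outgap=0.0)
        f = compute_mif(mol, grid, "steric_vdw")
        assert f.values[0] == pytest.approx(-eps_c, rel=1e-12)

    def test_lj_at_twice_minimum_distance(self):
        mol = _mol([(0, 0, 0)], rmin=4.0, epsilon=0.2)
        rc = (4.0 + DEFAULT_PROBE.rmin) / 2.0
        eps_c = np.sqrt(0.2 * DEFAULT_PROBE.epsilon)
        grid = GridSpec(origin=(2 * rc, 0.0, 0.0), step=1.0, dims=(1, 1, 1), outgap=0.0)
        f = compute_mif(mol, grid, "steric_vdw")
        expected = eps_c * (2.0**-12 - 2.0 * 2.0**-6)
        assert f.values[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-0.0310 * eps_c, abs=1e-4 * eps_c)

    def test_electrostatic_linear_in_charges(self, rng):
        coords = rng.normal(size=(4, 3))
        q = rng.uniform(-0.5, 0.5, size=4)
        grid = build_grid([_mol(coords)], step=2.0, outgap=4.0)
        f1 = compute_mif(_mol(coords, q), grid, "electrostatic")
        f2 = compute_mif(_mol(coords, 2 * q), grid, "electrostatic")
        np.testing.assert_allclose(f2.values, 2 * f1.values, rtol=1e-12)

    def test_fields_decay_at_padded_corners(self):
        # Coulomb decays only as 1/r (1/r^2 for this neutral pair), so a
        # sub-1e-3 kcal/mol bound needs a few hundred Angstrom of padding
        mol = _mol([(0, 0, 0), (1, 0.5, -0.5)], charges=[0.3, -0.3])
        grid = build_grid([mol], step=100.0, outgap=400.0)
        for probe in ("steric_vdw", "electrostatic"):
            f = compute_mif(mol, grid, probe)
            nx, ny, nz = grid.dims
            corner_idx = [0, nx - 1, nx * ny - 1, nx * ny * nz - 1]
            assert np.all(np.abs(f.values[corner_idx]) < 1e-3)

    def test_fields_shrink_with_distance(self):
        mol = _mol([(0, 0, 0), (1, 0.5, -0.5)], charges=[0.3, -0.3])
        near = build_grid([mol], step=2.0, outgap=4.0)
        far = build_grid([mol], step=2.0, outgap=20.0)
        for probe in ("steric_vdw", "electrostatic"):
            near_max = np.abs(compute_mif(mol, near, probe).values).max()
            f = compute_mif(mol, far, probe)
            nx, ny, nz = far.dims
            corners = np.abs(f.values[[0, nx - 1, nx * ny - 1, nx * ny * nz - 1]])
            assert np.all(corners < 0.05 * near_max)

    def test_coincident_node_clamped_and_logged(self, caplog):
        mol = _mol([(0, 0, 0)])
        grid = GridSpec(origin=(0.0, 0.0, 0.0), step=1.0, dims=(2, 1, 1), outgap=0.0)
        with caplog.at_level("WARNING"):
            f = compute_mif(mol, grid, "steric_vdw")
        assert f.values[0] == 30.0
        assert f.truncated_mask[0]
        assert "coincide" in caplog.text

    def test_deterministic(self):
        mol = _mol([(0.3, -0.2, 1.0)], charges=[0.25])
        grid = build_grid([mol], step=1.0, outgap=5.0)
        a = compute_mif(mol, grid, "electrostatic")
        b = compute_mif(mol, grid, "electrostatic")
        np.testing.assert_array_equal(a.values, b.values)


class TestTruncateExtremes:
    def _field(self, values, probe="steric_vdw"):
        n = len(values)
        grid = GridSpec(origin=(0.0, 0.0, 0.0), step=1.0, dims=(n, 1, 1), outgap=0.0)
        from gjqsar.field_qsar import MifField

        return MifField(
            grid=grid,
            probe=probe,
            values=np.asarray(values, dtype=float),
            truncated_mask=np.zeros(n, dtype=bool),
        )

    def test_within_bounds_identity(self):
        f = truncate_extremes(self._field([1.0, -5.0, 20.0]), steric_max=30.0)
        np.testing.assert_array_equal(f.values, [1.0, -5.0, 20.0])
        assert not f.truncated_mask.any()

    def test_steric_clamp_upper_only(self):
        f = truncate_extremes(self._field([1e6, -50.0]), steric_max=30.0)
        assert f.values[0] == 30.0
        assert f.values[1] == -50.0  # no lower steric bound
        np.testing.assert_array_equal(f.truncated_mask, [True, False])

    def test_electrostatic_symmetric_clamp(self):
        f = truncate_extremes(
            self._field([-25.0, 25.0, 3.0], probe="electrostatic"), elec_abs_max=10.0
        )
        np.testing.assert_array_equal(f.values, [-10.0, 10.0, 3.0])
        np.testing.assert_array_equal(f.truncated_mask, [True, True, False])

    def test_nonpositive_bound_rejected(self):
        with pytest.raises(DataError):
            truncate_extremes(self._field([1.0]), steric_max=0.0)


class TestFitPls:
    def test_rank_one_recovery_single_component(self, rng):
        # all predictor columns share one latent direction; activity linear
        # in one column is then recovered exactly by a single component
        t = rng.normal(size=6)
        loadings = rng.normal(size=10)
        X = np.outer(t, loadings)
        y = 2.0 * X[:, 3] + 1.0
        model, stats = fit_pls(X, y, n_components=1)
        assert stats.r2 == pytest.approx(1.0, abs=1e-10)

    def test_full_components_match_ols(self, rng):
        X = rng.normal(size=(5, 4))
        y = rng.normal(size=5)
        model, _ = fit_pls(X, y, n_components=4)
        ones = np.column_stack([X, np.ones(5)])
        beta, *_ = np.linalg.lstsq(ones, y, rcond=None)
        ols_fitted = ones @ beta
        pls_fitted = [pls_predict(model, X[i]) for i in range(5)]
        np.testing.assert_allclose(pls_fitted, ols_fitted, atol=1e-8)

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(8, 12))
        y = rng.normal(size=8)
        perm = rng.permutation(12)
        m1, _ = fit_pls(X, y, n_components=3)
        m2, _ = fit_pls(X[:, perm], y, n_components=3)
        f1 = [pls_predict(m1, X[i]) for i in range(8)]
        f2 = [pls_predict(m2, X[i, perm]) for i in range(8)]
        np.testing.assert_allclose(f1, f2, atol=1e-10)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(DataError):
            fit_pls(rng.normal(size=(5, 4)), rng.normal(size=5), n_components=5)

    def test_too_few_molecules_rejected(self, rng):
        with pytest.raises(DataError):
            fit_pls(rng.normal(size=(2, 4)), rng.normal(size=2), n_components=1)


class TestPlsPredict:
    @pytest.fixture
    def trained(self, rng):
        X = rng.normal(size=(7, 9))
        y = rng.normal(size=7)
        model, _ = fit_pls(X, y, n_components=3)
        return X, y, model

    def test_training_vector_gives_fitted_value(self, trained):
        X, y, model = trained
        fitted = (X - model.x_mean) @ model.coefficients + model.y_mean
        for i in range(len(y)):
            assert pls_predict(model, X[i]) == pytest.approx(fitted[i], abs=1e-12)

    def test_mean_field_gives_mean_activity(self, trained):
        X, y, model = trained
        assert pls_predict(model, X.mean(axis=0)) == pytest.approx(
            y.mean(), abs=1e-10
        )

    def test_length_mismatch_rejected(self, trained):
        _, _, model = trained
        with pytest.raises(DataError):
            pls_predict(model, np.zeros(5))

    def test_held_out_recovery_low_noise(self):
        from gjqsar.synthetic import SyntheticSpec, gen_aligned_molecules

        spec = SyntheticSpec(seed=11, n_molecules=10, field_noise_sd=0.01)
        mols, acts, grid, hotspots = gen_aligned_molecules(spec)
        X = mif_matrix(mols, grid)
        model, _ = fit_pls(X[:-1], acts[:-1], n_components=3)
        pred = pls_predict(model, X[-1])
        clean = sum(w * X[-1, i] for i, w in hotspots)
        assert abs(pred - clean) < 2 * max(0.02, np.std(acts) * 0.5)


class TestCoefficientMaps:
    def test_default_cutoff_value(self):
        assert DEFAULT_MAP_CUTOFF == 0.0002

    def test_cutoff_thresholding(self):
        vals = np.array([5e-4, -5e-4, 1e-4, -1e-4])
        out = apply_cutoff(vals, 0.0002)
        np.testing.assert_array_equal(out, [5e-4, -5e-4, 0.0, 0.0])

    def test_cutoff_above_max_zeroes_all(self):
        out = apply_cutoff(np.array([1e-4, -2e-4]), cutoff=1.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_export_writes_per_probe_and_sign(self, tmp_path, rng):
        grid = GridSpec(origin=(0.0, 0.0, 0.0), step=1.0, dims=(3, 3, 3), outgap=0.0)
        n = grid.n_points
        model = PlsModel(
            n_components=1,
            coefficients=rng.normal(scale=1e-3, size=2 * n),
            x_mean=np.zeros(2 * n),
            y_mean=0.0,
        )
        written = export_coefficient_map(model, grid, tmp_path)
        assert set(written) == {
            "steric_vdw_positive",
            "steric_vdw_negative",
            "electrostatic_positive",
            "electrostatic_negative",
        }
        for path in written.values():
            text = path.read_text()
            assert "object 1 class gridpositions counts 3 3 3" in text
            assert "items 27 data follows" in text

    def test_dx_round_trip_ordering(self, tmp_path):
        grid = GridSpec(origin=(0.0, 0.0, 0.0), step=1.0, dims=(2, 3, 4), outgap=0.0)
        vals = np.arange(grid.n_points, dtype=float)
        path = tmp_path / "map.dx"
        write_dx(grid, vals, path)
        lines = path.read_text().splitlines()
        start = next(i for i, l in enumerate(lines) if "data follows" in l) + 1
        data = []
        for line in lines[start:]:
            if line.startswith("attribute"):
                break
            data.extend(float(v) for v in line.split())
        # dx stores x slowest; invert to our x-fastest layout
        nx, ny, nz = grid.dims
        back = np.asarray(data).reshape(nx, ny, nz).transpose(2, 1, 0).ravel()
        np.testing.assert_allclose(back, vals)


class TestSdfInput:
    def test_read_synthetic_sdf(self, tmp_path):
        pytest.importorskip("rdkit")
        from click.testing import CliRunner

        from gjqsar.cli import cli

        runner = CliRunner()
        out = tmp_path / "sim"
        result = runner.invoke(
            cli, ["simulate", "molecules", "--seed", "3", "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        mols = read_aligned_sdf(out / "molecules.sdf", charges_csv=out / "charges.csv")
        from gjqsar.synthetic import SyntheticSpec, gen_aligned_molecules

        ref, _, _, _ = gen_aligned_molecules(SyntheticSpec(seed=3))
        assert len(mols) == len(ref)
        for got, want in zip(mols, ref):
            assert got.cid == want.cid
            np.testing.assert_allclose(got.coords(), want.coords(), atol=5e-4)
            np.testing.assert_allclose(got.charges(), want.charges(), atol=1e-9)
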