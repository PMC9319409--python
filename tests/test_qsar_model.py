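"""PLS fitting, LOO cross-validation, bootstrap and field-combination search."""

import numpy as np
import pytest

from fieldqsar import (
    FieldSettings,
    SeriesSpec,
    bootstrap_r2,
    build_descriptor_matrix,
    build_grid,
    compute_field_blocks,
    field_combination_search,
    fit_pls,
    generate_series,
    loo_q2,
)
from fieldqsar.grid_fields import COMSIA_KINDS
from fieldqsar.qsar_model import PLSModel, RankError


@pytest.fixture(scope="module")
def planted_matrix():
    """Descriptor matrix + activities from a small noiseless planted series."""
    mols, acts, truth = generate_series(SeriesSpec(n_compounds=16, noise_sigma=0.0, seed=5))
    grid = build_grid(mols)
    dm = build_descriptor_matrix(mols, grid, ["comsia_S", "comsia_H"])
    return dm, acts.pic50


class TestFitPLS:
    def test_rank_one_design_exact_fit(self, rng):
        t = rng.standard_normal(15)
        p = rng.standard_normal(8)
        X = np.outer(t, p)
        y = 2.0 + 3.0 * t
        model = fit_pls(X, y, 1)
        assert model.rss < 1e-10
        assert model.r2 == pytest.approx(1.0, abs=1e-12)

    def test_permuted_activity_not_perfectly_fit(self, rng):
        X = rng.standard_normal((20, 50))
        y = rng.permutation(np.linspace(5, 9, 20))
        model = fit_pls(X, y, 6)
        assert model.r2 < 1.0

    def test_components_equal_to_n_rejected(self, rng):
        X = rng.standard_normal((6, 10))
        y = rng.standard_normal(6)
        with pytest.raises(RankError):
            fit_pls(X, y, 6)

    def test_zero_variance_activity_rejected(self, rng):
        X = rng.standard_normal((10, 5))
        with pytest.raises(ValueError):
            fit_pls(X, np.full(10, 7.0), 2)

    def test_stored_coefficients_reproduce_stored_r2(self, planted_matrix):
        dm, y = planted_matrix
        model = fit_pls(dm, y, 3)
        yhat = model.predict_rows(dm.X)
        rss = float(((y - yhat) ** 2).sum())
        ss = float(((y - y.mean()) ** 2).sum())
        assert 1 - rss / ss == pytest.approx(model.r2, abs=1e-10)

    def test_matches_sklearn_pls(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.standard_normal((18, 12))
        y = rng.standard_normal(18)
        ours = fit_pls(X, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y.reshape(-1, 1))
        np.testing.assert_allclose(
            ours.predict_rows(X), ref.predict(X).ravel(), atol=1e-8
        )

    def test_see_and_f_definitions(self, rng):
        X = rng.standard_normal((20, 7))
        y = rng.standard_normal(20)
        m = fit_pls(X, y, 2)
        dof = 20 - 2 - 1
        assert m.see == pytest.approx(np.sqrt(m.rss / dof), rel=1e-12)
        assert m.f_value == pytest.approx((m.r2 / 2) / ((1 - m.r2) / dof), rel=1e-12)

    def test_wide_rank_one_matrix_stops_cleanly(self):
        X = np.outer(np.arange(8.0), np.ones(30))
        y = np.arange(8.0)
        with pytest.raises(RankError):
            fit_pls(X, y, 3)


class TestLOO:
    def test_equals_explicit_refit_loop(self, planted_matrix):
        dm, y = planted_matrix
        res = loo_q2(dm, y, max_components=3)
        # independent oracle: n explicit refits per component count
        from fieldqsar.qsar_model import _block_scales

        Xs = dm.X / _block_scales(dm.X, dm.col_kind)
        n = len(y)
        for a in range(1, 4):
            press = 0.0
            for i in range(n):
                keep = np.arange(n) != i
                m = fit_pls(Xs[keep], y[keep], a)
                press += float((y[i] - m.predict_rows(Xs[i][None, :])[0]) ** 2)
            q2 = 1 - press / float(((y - y.mean()) ** 2).sum())
            assert res.q2[a - 1] == pytest.approx(q2, abs=1e-12)

    def test_noiseless_planted_model_recovered(self):
        mols, acts, _ = generate_series(SeriesSpec(noise_sigma=0.0, seed=1))
        grid = build_grid(mols)
        dm = build_descriptor_matrix(mols, grid, ["comsia_S", "comsia_H"])
        res = loo_q2(dm, acts.pic50)
        assert res.q2_onc > 0.9

    def test_q2_below_r2(self, planted_matrix):
        dm, y = planted_matrix
        res = loo_q2(dm, y, max_components=4)
        for a in range(1, 5):
            assert res.q2[a - 1] <= fit_pls(dm, y, a).r2 + 1e-12

    def test_permutation_null_rarely_scores(self, rng):
        X = rng.standard_normal((20, 40))
        y = np.linspace(5, 9, 20)
        hits = 0
        n_perm = 100
        for _ in range(n_perm):
            res = loo_q2(X, rng.permutation(y), max_components=4)
            hits += res.q2_onc <= 0.3
        assert hits >= 95

    def test_pure_noise_columns_do_not_inflate_q2(self, rng):
        mols, acts, _ = generate_series(SeriesSpec(seed=9))
        grid = build_grid(mols)
        dm = build_descriptor_matrix(mols, grid, ["comsia_S", "comsia_H"])
        base = loo_q2(dm, acts.pic50, max_components=3).q2_onc
        assert base > 0.5  # the property is about a meaningful model
        diffs = []
        for rep in range(20):
            noise = rng.standard_normal(dm.X.shape) * dm.X.std()
            aug = np.hstack([dm.X, noise])
            diffs.append(loo_q2(aug, acts.pic50, max_components=3).q2_onc - base)
        assert max(diffs) <= 0.05

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            loo_q2(rng.standard_normal((3, 5)), np.arange(3.0))

    def test_sep_definition(self, planted_matrix):
        dm, y = planted_matrix
        res = loo_q2(dm, y, max_components=2)
        n = len(y)
        for a in (1, 2):
            assert res.sep[a - 1] == pytest.approx(
                np.sqrt(res.press[a - 1] / (n - a - 1)), rel=1e-12
            )


class TestBootstrap:
    def test_perfect_fit_gives_one_and_zero(self, rng):
        t = rng.standard_normal(12)
        X = np.outer(t, rng.standard_normal(5))
        y = 1.5 * t + 4.0
        bs_r2, bs_sd, _ = bootstrap_r2(X, y, 1, n_boot=30, seed=1)
        assert bs_r2 == pytest.approx(1.0, abs=1e-10)
        assert bs_sd == pytest.approx(0.0, abs=1e-10)

    def test_deterministic_under_fixed_seed(self, planted_matrix):
        dm, y = planted_matrix
        a = bootstrap_r2(dm.X, y, 2, n_boot=25, seed=42)
        b = bootstrap_r2(dm.X, y, 2, n_boot=25, seed=42)
        assert a == b

    def test_sd_shrinks_as_noise_is_halved(self):
        # stochastic monotonicity: compare seed-averaged BS-SD as the
        # generator's noise is halved twice
        means = []
        for sigma in (1.0, 0.5, 0.25):
            sds = []
            for seed in (11, 12, 13):
                mols, acts, _ = generate_series(SeriesSpec(noise_sigma=sigma, seed=seed))
                grid = build_grid(mols)
                dm = build_descriptor_matrix(mols, grid, ["comsia_S", "comsia_H"])
                _, bs_sd, _ = bootstrap_r2(dm, acts.pic50, 2, n_boot=100, seed=2)
                sds.append(bs_sd)
            means.append(np.mean(sds))
        assert means[0] > means[1] > means[2]


class TestCombinationSearch:
    def test_single_candidate_single_row(self, small_series):
        mols, acts, _ = small_series
        grid = build_grid(mols)
        df = field_combination_search(mols, grid, ["comsia_S"], acts.pic50)
        assert len(df) == 1
        assert df.iloc[0]["combination"] == "comsia_S"

    def test_all_31_combinations_enumerated(self, series35, split35):
        mols, acts, _ = series35
        train_ids, _ = split35
        by_id = {m.id: m for m in mols}
        train = [by_id[c] for c in train_ids]
        y = np.array([acts.lookup(c) for c in train_ids])
        grid = build_grid(mols)
        df = field_combination_search(train, grid, COMSIA_KINDS, y)
        assert len(df) == 31
        # ranking: q2 descending, ties toward fewer fields then components
        assert df["q2"].is_monotonic_decreasing

    def test_planted_structure_recovered(self, series35, split35):
        mols, acts, _ = series35
        train_ids, _ = split35
        by_id = {m.id: m for m in mols}
        train = [by_id[c] for c in train_ids]
        y = np.array([acts.lookup(c) for c in train_ids])
        grid = build_grid(mols)
        df = field_combination_search(train, grid, COMSIA_KINDS, y)
        top = set(df.iloc[0]["combination"].split("+"))
        assert {"comsia_S", "comsia_H"} <= top


class TestPersistence:
    def test_json_roundtrip_preserves_predictions(self, planted_matrix, tmp_path):
        dm, y = planted_matrix
        model = fit_pls(dm, y, 2)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PLSModel.from_json(path)
        np.testing.assert_allclose(
            back.predict_rows(dm.X), model.predict_rows(dm.X), atol=1e-12
        )
        assert back.field_kinds == model.field_kinds
        assert back.template.grid == dm.grid

    def test_wrong_column_count_rejected(self, planted_matrix):
        dm, y = planted_matrix
        model = fit_pls(dm, y, 2)
        with pytest.raises(ValueError, match="columns"):
            model.predict_rows(np.zeros((1, dm.p + 3)))


def test_field_contributions_sum_to_100(planted_matrix):
    dm, y = planted_matrix
    model = fit_pls(dm, y, 3)
    total = sum(model.field_contributions.values())
    assert total == pytest.approx(100.0, abs=1e-9)
    assert set(model.field_contributions) == {"comsia_S", "comsia_H"}
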