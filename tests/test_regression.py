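"""Design construction and per-parcel OLS against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svocortex.design import DesignError, build_design
from svocortex.regression import fit_lobe, fit_parcel, results_table


def normal_equations_oracle(X, y, j):
    """Explicit (X'X)^-1 X'y solve with textbook t-statistic for column j."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    s2 = resid @ resid / (n - k)
    se = np.sqrt(s2 * xtx_inv[j, j])
    t = beta[j] / se
    p = 2 * stats.t.sf(abs(t), n - k)
    return beta, t, p


def random_design(rng, n=30, model="angle"):
    profiles = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "angle_deg": rng.uniform(90, 270, n),
            "w_self": rng.uniform(-0.5, 0.5, n),
            "w_other": rng.uniform(-0.5, 0.5, n),
        }
    )
    demo = pd.DataFrame(
        {
            "participant_id": profiles["participant_id"],
            "age": rng.normal(24, 2, n),
            "gender": rng.integers(0, 2, n),
        }
    )
    hemi = pd.Series(rng.uniform(2, 3, n), index=profiles["participant_id"])
    return build_design(profiles, demo, hemi, model=model), profiles, demo, hemi


class TestBuildDesign:
    def test_angle_model_shape(self, rng):
        X, *_ = random_design(rng, n=194)
        assert X.shape == (194, 5)
        assert list(X.columns) == ["const", "svo_angle", "age", "gender", "avg_thickness"]

    def test_weights_model_columns(self, rng):
        X, *_ = random_design(rng, n=40, model="weights")
        assert X.shape[1] == 6
        assert {"w_self", "w_other", "age"} <= set(X.columns)

    def test_weights_model_age_droppable(self, rng):
        _, profiles, demo, hemi = random_design(rng, n=40, model="weights")
        X = build_design(profiles, demo, hemi, model="weights", include_age=False)
        assert "age" not in X.columns and X.shape[1] == 5

    def test_rank_deficiency_names_column(self, rng):
        _, profiles, demo, hemi = random_design(rng, n=30)
        demo = demo.assign(gender=1)  # constant gender, collinear with intercept
        with pytest.raises(DesignError, match="gender"):
            build_design(profiles, demo, hemi, model="angle")

    def test_subject_mismatch_rejected(self, rng):
        _, profiles, demo, hemi = random_design(rng, n=30)
        with pytest.raises(DesignError, match="demographics"):
            build_design(profiles, demo.iloc[:-1], hemi, model="angle")

    def test_undefined_angle_rejected(self, rng):
        _, profiles, demo, hemi = random_design(rng, n=30)
        profiles.loc[0, "angle_deg"] = np.nan
        with pytest.raises(DesignError):
            build_design(profiles, demo, hemi, model="angle")


class TestFitParcel:
    def test_noiseless_recovery(self, rng):
        X, *_ = random_design(rng, n=50)
        coef = np.array([2.5, 0.002, -0.01, 0.05, 0.3])
        y = X.to_numpy() @ coef
        res = fit_parcel(y, X, "svo_angle")
        assert np.allclose(res.params.to_numpy(), coef, atol=1e-10)
        assert np.abs(res.resid).max() < 1e-10

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            X, *_ = random_design(rng, n=int(rng.integers(20, 60)))
            y = rng.normal(2.5, 0.3, len(X))
            res = fit_parcel(y, X, "svo_angle")
            j = list(X.columns).index("svo_angle")
            beta, t, p = normal_equations_oracle(X, y, j)
            assert np.allclose(res.params.to_numpy(), beta, atol=1e-8)
            assert res.t_stat["svo_angle"] == pytest.approx(t, abs=1e-8)
            assert res.p_uncorrected["svo_angle"] == pytest.approx(p, abs=1e-8)

    def test_frisch_waugh_residualisation(self, rng):
        # t for the variable of interest equals the t from regressing the
        # residualised outcome on the residualised predictor (df matched)
        X, *_ = random_design(rng, n=40)
        y = rng.normal(2.5, 0.3, 40)
        res = fit_parcel(y, X, "svo_angle")
        Z = X.drop(columns="svo_angle").to_numpy()
        x = X["svo_angle"].to_numpy()
        proj = Z @ np.linalg.lstsq(Z, np.column_stack([x, y]), rcond=None)[0]
        x_res, y_res = x - proj[:, 0], y - proj[:, 1]
        beta = (x_res @ y_res) / (x_res @ x_res)
        resid = y_res - beta * x_res
        df = len(y) - X.shape[1]
        t = beta / np.sqrt((resid @ resid / df) / (x_res @ x_res))
        assert res.t_stat["svo_angle"] == pytest.approx(t, abs=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        X, *_ = random_design(rng, n=60)
        y = rng.normal(2.5, 0.3, 60)
        res = fit_parcel(y, X, "svo_angle")
        Xu = X.to_numpy() / np.linalg.norm(X.to_numpy(), axis=0)
        assert np.abs(Xu.T @ res.resid).max() < 1e-8

    def test_beta_std_invariant_to_affine_rescaling(self, rng):
        X, *_ = random_design(rng, n=50)
        y = rng.normal(2.5, 0.3, 50)
        base = fit_parcel(y, X, "svo_angle").beta_std["svo_angle"]
        scaled_y = fit_parcel(1000 * y + 7, X, "svo_angle").beta_std["svo_angle"]
        X2 = X.copy()
        X2["svo_angle"] = X2["svo_angle"] / 57.3 - 2.0
        scaled_x = fit_parcel(y, X2, "svo_angle").beta_std["svo_angle"]
        assert base == pytest.approx(scaled_y, abs=1e-10)
        assert base == pytest.approx(scaled_x, abs=1e-10)

    def test_too_few_subjects_rejected(self, rng):
        X, *_ = random_design(rng, n=30)
        with pytest.raises(ValueError):
            fit_parcel(rng.normal(size=6), X.iloc[:6], "svo_angle")


class TestFitLobe:
    def _matrix(self, rng, atlas, lobe="occipital", hemi="left", n=30):
        from svocortex.atlas import thickness_from_frame

        cols = atlas.all_columns()
        idx = pd.Index([f"P{i}" for i in range(n)], name="participant_id")
        df = pd.DataFrame(rng.uniform(1.5, 4.5, (n, len(cols))), index=idx, columns=cols)
        return thickness_from_frame(df, atlas).subset(atlas.columns(hemi, lobe))

    def test_occipital_yields_12_results(self, rng, atlas):
        X, *_ = random_design(rng, n=30)
        mat = self._matrix(rng, atlas)
        mat = type(mat)(values=mat.values.set_axis(X.index), hemi_average=mat.hemi_average)
        results = fit_lobe(mat, X, "svo_angle", atlas=atlas)
        assert len(results) == 12
        ids = [r.parcel_id for r in results]
        assert ids == sorted(ids) and set(ids) == set(atlas.lobe_ids("occipital"))
        tab = results_table(results)
        assert (tab["lobe"] == "occipital").all()
        assert (tab["hemisphere"] == "left").all()

    def test_row_order_invariance(self, rng, atlas):
        X, *_ = random_design(rng, n=30)
        mat = self._matrix(rng, atlas)
        vals = mat.values.set_axis(X.index)
        mat = type(mat)(values=vals, hemi_average=mat.hemi_average)
        r1 = fit_lobe(mat, X, "svo_angle", atlas=atlas)
        perm = np.random.default_rng(1).permutation(len(X))
        Xp = X.iloc[perm]
        r2 = fit_lobe(mat, Xp, "svo_angle", atlas=atlas)
        for a, b in zip(r1, r2):
            assert a.t_stat["svo_angle"] == pytest.approx(b.t_stat["svo_angle"], abs=1e-10)

    def test_identical_outcomes_identical_results(self, rng, atlas):
        X, *_ = random_design(rng, n=30)
        mat = self._matrix(rng, atlas)
        vals = mat.values.set_axis(X.index)
        col0 = vals.columns[0]
        vals = vals.assign(**{c: vals[col0] for c in vals.columns})
        mat = type(mat)(values=vals, hemi_average=mat.hemi_average)
        results = fit_lobe(mat, X, "svo_angle", atlas=atlas)
        ts = {r.t_stat["svo_angle"] for r in results}
        assert len(ts) == 1
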