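"""Design-matrix structure and OLS fitting for the three LFER variants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mcflfer as m
from mcflfer.models import ColumnInfo, lstsq_rank_revealing


class TestDesignStructure:
    @pytest.mark.parametrize("variant,ncols", [
        ("single", 6), ("crossed", 540), ("nested", 105),
    ])
    def test_column_counts_on_full_design(self, full_obs, variant, ncols):
        design = m.build_design(full_obs, m.ModelSpec(variant=variant))
        assert design.shape == (9990, ncols)

    def test_unpopulated_cells_contribute_no_columns(self, full_obs):
        sub = full_obs.subset(
            ~(
                (full_obs.data["mwf"] == "MO")
                & (full_obs.data["mwf_conc"] == 0.05)
            ).to_numpy()
        )
        nested = m.build_design(sub, m.ModelSpec("nested"))
        crossed = m.build_design(sub, m.ModelSpec("crossed"))
        assert nested.shape[1] == 14 * 7
        assert crossed.shape[1] == 84 * 6

    def test_each_row_activates_exactly_one_block(self, full_obs):
        design = m.build_design(full_obs, m.ModelSpec("crossed"))
        meta = design.row_meta
        i = meta.index[
            (meta["mwf"] == "MO") & (meta["mwf_conc"] == 0.05)
            & (meta["solute_conc"] == 0.05)
        ][0]
        row = design.matrix[i]
        nz_cells = {design.columns[j].cell for j in np.nonzero(row)[0]}
        assert nz_cells == {("MO", 0.05, 0.05)}
        icol = design.columns.index(ColumnInfo("intercept", ("MO", 0.05, 0.05)))
        assert row[icol] == 1.0

    def test_block_orthogonality(self, descriptors):
        """Cross-product matrix is block-diagonal over treatment cells."""
        obs, _ = m.generate(m.default_config(seed=3, solute_ids=tuple(range(1, 9)),
                                             dropout=0.0, replicates=1))
        design = m.build_design(obs, m.ModelSpec("nested"))
        xtx = design.matrix.T @ design.matrix
        cell_order = design.cells()
        cells = np.array([cell_order.index(c.cell) for c in design.columns])
        off_block = xtx[np.not_equal.outer(cells, cells)]
        assert np.abs(off_block).max() == 0.0


class TestFitOLS:
    def test_noiseless_linear_response_fits_exactly(self):
        obs, truth = m.generate(m.default_config(seed=5, noise_sd=0.0))
        design = m.build_design(obs, m.ModelSpec("nested"))
        fit = m.fit_ols(design, obs.data["log_k"].to_numpy())
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert np.abs(fit.residuals).max() < 1e-8

    def test_intercept_only_design(self):
        core = lstsq_rank_revealing(np.ones((3, 1)), np.array([1.0, 2.0, 3.0]))
        assert core.beta[0] == pytest.approx(2.0)
        assert core.sse == pytest.approx(2.0)  # r2 = 0 about the mean

    def test_crossed_estimates_match_independent_per_cell_regressions(self, default_obs):
        """Block orthogonality: the joint 540-column fit reproduces 90
        separate 6-parameter regressions (brute-force oracle)."""
        design = m.build_design(default_obs, m.ModelSpec("crossed"))
        y = default_obs.data["log_k"].to_numpy()
        fit = m.fit_ols(design, y)
        merged = default_obs.merged()
        checked = 0
        for cell in design.cells():
            mask = (
                (merged["mwf"] == cell[0]) & (merged["mwf_conc"] == cell[1])
                & (merged["solute_conc"] == cell[2])
            ).to_numpy()
            Xc = np.column_stack(
                [np.ones(mask.sum())]
                + [merged.loc[mask, d].to_numpy() for d in ("E", "S", "A", "B", "V")]
            )
            beta_c, *_ = np.linalg.lstsq(Xc, y[mask], rcond=None)
            joint = [
                fit.get(d, cell)["estimate"]
                for d in ("intercept", "E", "S", "A", "B", "V")
            ]
            np.testing.assert_allclose(joint, beta_c, rtol=1e-8)
            checked += 1
        assert checked == 90

    def test_affine_equivariance(self, default_obs):
        """Adding c to every response shifts intercepts by c, slopes not."""
        design = m.build_design(default_obs, m.ModelSpec("nested"))
        y = default_obs.data["log_k"].to_numpy()
        f0 = m.fit_ols(design, y)
        f1 = m.fit_ols(design, y + 2.5)
        is_int = np.array([c.descriptor == "intercept" for c in design.columns])
        np.testing.assert_allclose(f1.coef[is_int], f0.coef[is_int] + 2.5, atol=1e-8)
        np.testing.assert_allclose(f1.coef[~is_int], f0.coef[~is_int], atol=1e-8)

    def test_adj_r2_bounded_by_r2(self, default_obs):
        for variant in ("single", "crossed", "nested"):
            design = m.build_design(default_obs, m.ModelSpec(variant))
            fit = m.fit_ols(design, default_obs.data["log_k"].to_numpy())
            assert fit.adj_r2 <= fit.r2

    def test_rank_deficient_column_dropped_and_reported(self, descriptors):
        """A cell whose solutes all share A = 0 cannot estimate the A slope."""
        zero_a = tuple(
            int(s) for s in descriptors.loc[descriptors["A"] == 0, "solute_id"]
        )[:10]
        obs, _ = m.generate(m.default_config(
            seed=9, solute_ids=zero_a, dropout=0.0,
        ))
        design = m.build_design(obs, m.ModelSpec("nested"))
        fit = m.fit_ols(design, obs.data["log_k"].to_numpy())
        dropped = {c.descriptor for c in fit.dropped_columns}
        assert dropped == {"A"}
        assert len(fit.dropped_columns) == 15  # one per (MWF, conc) block
        assert np.isnan(fit.get("A", ("MO", 0.05))["estimate"])

    def test_too_few_rows_is_estimability_error(self, descriptors):
        obs, _ = m.generate(m.default_config(
            seed=2, solute_ids=(1, 2, 3), replicates=1, dropout=0.0,
            solute_concs=(0.01,), mwfs=("MO",), mwf_concs=(0.05,),
        ))
        design = m.build_design(obs, m.ModelSpec("single"))
        with pytest.raises(m.EstimabilityError):
            m.fit_ols(design, obs.data["log_k"].to_numpy())

    def test_ci_brackets_estimate(self, default_obs):
        design = m.build_design(default_obs, m.ModelSpec("nested"))
        fit = m.fit_ols(design, default_obs.data["log_k"].to_numpy())
        ret = fit.retained_idx
        assert (fit.ci_low[ret] < fit.coef[ret]).all()
        assert (fit.coef[ret] < fit.ci_high[ret]).all()


class TestPerCell:
    def test_skips_cells_with_insufficient_df(self, descriptors):
        obs, _ = m.generate(m.default_config(
            seed=4, solute_ids=(1, 2, 3, 4, 5, 6), replicates=1, dropout=0.0,
            mwfs=("MO",), mwf_concs=(0.05,), solute_concs=(0.01, 5.0),
        ))
        per = m.fit_per_cell(obs)
        assert not per.fits
        assert all("insufficient df" in reason for _, reason in per.skipped)

    def test_recovers_generating_coefficients_within_3_se(self):
        """Parameter recovery for separate per-cell fits (the generating
        crossed model has constant slopes within each cell)."""
        nested = m.default_truth()
        from mcflfer.simulate import crossed_truth_from_nested
        cfg = m.default_config(
            seed=21, dropout=0.0, variant="crossed",
            coefficients=crossed_truth_from_nested(nested),
            noise_sd=0.15,
        )
        obs, truth = m.generate(cfg)
        per = m.fit_per_cell(obs)
        assert len(per.fits) == 90
        coef_map = {"intercept": "beta0", "E": "beta1", "S": "beta2",
                    "A": "beta3", "B": "beta4", "V": "beta5"}
        n_checked = n_within = 0
        tt = truth.coefficients
        for cell, fit in per.fits.items():
            row = tt[(tt["mwf"] == cell[0]) & (tt["mwf_conc"] == cell[1])
                     & (tt["solute_conc"] == cell[2])].iloc[0]
            for d, beta in coef_map.items():
                got = fit.get(d)
                n_checked += 1
                n_within += abs(got["estimate"] - row[beta]) <= 3 * got["se"]
        assert n_within / n_checked >= 0.95

    def test_coef_table_shape(self, default_obs):
        per = m.fit_per_cell(default_obs)
        cell, fit = next(iter(per.fits.items()))
        tab = fit.coef_table()
        assert list(tab.columns) == ["cell", "descriptor", "estimate", "se",
                                     "ci_low", "ci_high"]
        assert len(tab) == 6


class TestPredict:
    def test_training_rows_reproduce_fitted_values(self, default_obs):
        design = m.build_design(default_obs, m.ModelSpec("nested"))
        y = default_obs.data["log_k"].to_numpy()
        fit = m.fit_ols(design, y)
        pred = m.predict(fit, default_obs)
        np.testing.assert_allclose(pred, fit.fitted, atol=1e-10)

    def test_unseen_solute_in_populated_cell_is_finite(self, default_obs):
        keep = default_obs.data["solute_id"] != 1
        train = default_obs.subset(keep.to_numpy())
        test = default_obs.subset((~keep).to_numpy())
        design = m.build_design(train, m.ModelSpec("nested"))
        fit = m.fit_ols(design, train.data["log_k"].to_numpy())
        pred = m.predict(fit, test)
        assert np.isfinite(pred).all()

    def test_hand_computed_dot_product(self, default_obs, descriptors):
        design = m.build_design(default_obs, m.ModelSpec("single"))
        y = default_obs.data["log_k"].to_numpy()
        fit = m.fit_ols(design, y)
        row = default_obs.data.iloc[0]
        sol = m.solute_record(descriptors, int(row["solute_id"]))
        by_hand = (
            fit.get("intercept")["estimate"]
            + fit.get("E")["estimate"] * sol.E + fit.get("S")["estimate"] * sol.S
            + fit.get("A")["estimate"] * sol.A + fit.get("B")["estimate"] * sol.B
            + fit.get("V")["estimate"] * sol.V
        )
        assert m.predict(fit, default_obs)[0] == pytest.approx(by_hand, rel=1e-10)

    def test_row_in_absent_cell_flagged_nan(self, default_obs):
        in_mo005 = (
            (default_obs.data["mwf"] == "MO") & (default_obs.data["mwf_conc"] == 0.05)
        ).to_numpy()
        train = default_obs.subset(~in_mo005)
        test = default_obs.subset(in_mo005)
        design = m.build_design(train, m.ModelSpec("nested"))
        fit = m.fit_ols(design, train.data["log_k"].to_numpy())
        pred = m.predict(fit, test)
        assert np.isnan(pred).all()


@given(st.integers(0, 2**20))
def test_lstsq_core_matches_numpy_on_full_rank_problems(seed):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(30), rng.normal(size=(30, 5))])
    y = rng.normal(size=30)
    core = lstsq_rank_revealing(X, y)
    ref, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(core.beta, ref, rtol=1e-8, atol=1e-10)
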