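import numpy as np
import pandas as pd
import pytest

from dige_mm import (
    COEFFICIENTS,
    DesignTable,
    Group,
    SimulationConfig,
    SpotClass,
    bh_adjust,
    count_significant,
    design_matrix,
    fit_spot_models,
    replace_zeros,
    significant_molecules,
    simulate_experiment,
    standard_workflow,
    visualize_adjust,
    normalize,
)
from dige_mm.io import ValidationError
from dige_mm.tmm import NormalizationResult

import oracles
from conftest import make_annotation, make_design


def norm_stub(sample, ips, gel_ids):
    sample = np.asarray(sample, float)
    return NormalizationResult(
        spot_ids=[f"s{i}" for i in range(sample.shape[0])],
        gel_ids=list(gel_ids),
        library_sizes={},
        tmm_factors={},
        reference={},
        normalized_log2={"sample": sample, "ips": np.asarray(ips, float)},
    )


class TestDesignMatrix:
    def test_coding_and_rank(self, small_design):
        x = design_matrix(small_design, small_design.gel_ids)
        xd = np.column_stack([np.ones(len(small_design.gel_ids)), x])
        assert np.linalg.matrix_rank(xd) == 5
        for gel, row in zip(small_design.gel_ids, x):
            grp = small_design.group_of(gel)
            assert row[0] == (grp in (Group.SCB, Group.SCB_AG))
            assert row[1] == (grp in (Group.DCB, Group.DCB_AG))
            assert row[2] == (grp is Group.SCB_AG)
            assert row[3] == (grp is Group.DCB_AG)

    def test_empty_group_named_in_error(self):
        design = DesignTable({"g1": Group.control, "g2": Group.SCB})
        with pytest.raises(ValidationError, match="SCB_AG"):
            design_matrix(design, design.gel_ids)


class TestFit:
    def test_noise_free_recovery_is_exact(self, small_design):
        """sample = IPS + 1 on the SCB arm recovers fluid_SCB = 1 exactly."""
        gel_ids = small_design.gel_ids
        rng = np.random.default_rng(0)
        ips = rng.normal(10, 1, size=(3, len(gel_ids)))
        bump = np.array(
            [
                1.0 if small_design.group_of(g) in (Group.SCB, Group.SCB_AG) else 0.0
                for g in gel_ids
            ]
        )
        res = fit_spot_models(norm_stub(ips + bump, ips, gel_ids), small_design)
        for spot in res.spot_ids:
            row = res.coefficient_frame("fluid_SCB").loc[spot]
            assert row["estimate"] == pytest.approx(1.0, abs=1e-12)
            assert row["fold_change"] == 2.0 ** row["estimate"]
            for coef in ("fluid_DCB", "additive_SCB_AG", "additive_DCB_AG"):
                assert res.coefficient_frame(coef).loc[spot, "estimate"] == pytest.approx(
                    0.0, abs=1e-12
                )

    def test_matches_reml_mixed_model(self, small_design):
        """Closed-form fit equals generic REML (statsmodels MixedLM) per spot."""
        MixedLM = pytest.importorskip("statsmodels.regression.mixed_linear_model").MixedLM
        gel_ids = small_design.gel_ids
        n = len(gel_ids)
        rng = np.random.default_rng(1)
        x = design_matrix(small_design, gel_ids)
        sample = rng.normal(10, 1, (6, n))
        ips = sample - rng.normal(0.3, 0.5, (6, n)) - (x @ [0.5, -0.4, 0.2, 0.1])
        res = fit_spot_models(norm_stub(sample, ips, gel_ids), small_design)

        groups_num = np.arange(n)
        g_ind = np.zeros((n, 5))
        for i, g in enumerate(gel_ids):
            g_ind[i, list(Group).index(small_design.group_of(g))] = 1.0
        exog = np.column_stack(
            [
                np.vstack([g_ind, g_ind]),
                np.concatenate([np.ones(n), np.zeros(n)]),
                np.vstack([x, np.zeros_like(x)]),
            ]
        )
        for i, spot in enumerate(res.spot_ids):
            endog = np.concatenate([sample[i], ips[i]])
            fit = MixedLM(endog, exog, groups=np.concatenate([groups_num] * 2)).fit(
                reml=True, method="lbfgs"
            )
            for k, coef in enumerate(COEFFICIENTS):
                got = res.coefficient_frame(coef).loc[spot]
                assert got["estimate"] == pytest.approx(fit.fe_params[6 + k], abs=1e-8)
                # SEs agree up to the optimizer tolerance of the generic fitter
                assert got["se"] == pytest.approx(fit.bse_fe[6 + k], rel=1e-3)

    def test_estimates_equal_difference_ols_exactly(self, sim_null):
        matrix, design, ann, _ = sim_null
        norm = normalize(replace_zeros(matrix), ann)
        res = fit_spot_models(norm, design)
        x = design_matrix(design, norm.gel_ids)
        expected = oracles.diff_ols_reference(
            norm.normalized_log2["sample"], norm.normalized_log2["ips"], x
        )
        got = np.column_stack(
            [res.coefficient_frame(c)["estimate"].to_numpy() for c in COEFFICIENTS]
        )
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_q_at_least_p_and_count_monotonicity(self, sim_default):
        matrix, design, ann, _ = sim_default
        res = fit_spot_models(normalize(replace_zeros(matrix), ann), design)
        ok = res.table["q"].notna()
        assert (res.table.loc[ok, "q"] >= res.table.loc[ok, "p"] - 1e-15).all()
        for coef in COEFFICIENTS:
            n_p = len(res.significant_spots(coef, 0.05, "p"))
            n_q = len(res.significant_spots(coef, 0.05, "q"))
            assert n_q <= n_p

    def test_pairwise_mode_estimates_same_contrasts(self, sim_null):
        matrix, design, ann, _ = sim_null
        norm = normalize(replace_zeros(matrix), ann)
        wald = fit_spot_models(norm, design, tests="wald")
        pw = fit_spot_models(norm, design, tests="pairwise")
        for coef in COEFFICIENTS:
            a = wald.coefficient_frame(coef)["estimate"]
            b = pw.coefficient_frame(coef)["estimate"]
            np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)


class TestBH:
    def test_single_p(self):
        np.testing.assert_array_equal(bh_adjust([0.03]), [0.03])

    def test_stepup_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValidationError):
            bh_adjust([np.nan])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_stepup_oracle_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 200))
        q = bh_adjust(p)
        np.testing.assert_allclose(q, oracles.bh_stepup_reference(p), rtol=0, atol=0)
        sm = pytest.importorskip("statsmodels.stats.multitest")
        np.testing.assert_allclose(q, sm.multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_stable_under_input_order(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestCounting:
    def test_empty_results_count_zero(self, small_design):
        gel_ids = small_design.gel_ids
        rng = np.random.default_rng(2)
        ips = rng.normal(10, 1, (4, len(gel_ids)))
        sample = ips + rng.normal(0, 0.1, ips.shape)
        res = fit_spot_models(norm_stub(sample, ips, gel_ids), small_design)
        ann = make_annotation(res.spot_ids, [SpotClass.cellular] * 4)
        counts = count_significant(res, ann, alpha=1e-12, measure="p")
        assert all(v["n_spots"] == 0 for v in counts["per_coefficient"].values())

    def test_unique_id_dedup_and_unidentified_exclusion(self, small_design):
        gel_ids = small_design.gel_ids
        x = design_matrix(small_design, gel_ids)
        rng = np.random.default_rng(3)
        ips = rng.normal(10, 0.5, (3, len(gel_ids)))
        sample = ips + 5.0 * x[:, 0][None, :] + rng.normal(0, 0.05, ips.shape)
        res = fit_spot_models(norm_stub(sample, ips, gel_ids), small_design)
        ann = make_annotation(
            res.spot_ids,
            [SpotClass.cellular] * 3,
            accessions=["A", "A", None],
        )
        counts = count_significant(res, ann, alpha=0.05, measure="p")
        assert counts["per_coefficient"]["fluid_SCB"]["n_spots"] == 3
        assert counts["per_coefficient"]["fluid_SCB"]["n_unique_ids"] == 1
        assert "fluid_SCB&fluid_DCB" in counts["overlap"]

    def test_unknown_coefficient_rejected(self, sim_null):
        matrix, design, ann, _ = sim_null
        res = fit_spot_models(normalize(replace_zeros(matrix), ann), design)
        with pytest.raises(ValidationError, match="interaction"):
            count_significant(res, ann, coefficients=["interaction"])


class TestVisualizeAdjust:
    def test_zero_intercepts_identity(self, small_design):
        gel_ids = small_design.gel_ids
        norm = norm_stub(
            np.tile(np.arange(len(gel_ids), dtype=float), (2, 1)),
            np.tile(np.arange(len(gel_ids), dtype=float), (2, 1)),
            gel_ids,
        )
        res = fit_spot_models(norm, small_design)
        res.random_intercepts = np.zeros_like(res.random_intercepts)
        out = visualize_adjust(norm, res)
        np.testing.assert_array_equal(out["sample"], norm.normalized_log2["sample"])

    def test_adjustment_preserves_contrasts_and_flattens_ips(self, small_design):
        gel_ids = small_design.gel_ids
        rng = np.random.default_rng(5)
        base = rng.normal(10, 1, (40, 1))
        b_g = rng.normal(0, 1.0, (1, len(gel_ids)))
        sample = base + b_g + rng.normal(0, 0.1, (40, len(gel_ids)))
        ips = base + b_g + rng.normal(0, 0.1, (40, len(gel_ids)))
        norm = norm_stub(sample, ips, gel_ids)
        res = fit_spot_models(norm, small_design)
        adjusted = visualize_adjust(norm, res)
        # within each group, adjusted IPS column means become near-constant
        # (between-group level differences belong to the fixed effects)
        groups = np.array([small_design.group_of(g).name for g in gel_ids])
        def within_group_spread(col_means):
            return np.mean(
                [col_means[groups == g].std() for g in np.unique(groups)]
            )
        before = within_group_spread(norm.normalized_log2["ips"].mean(axis=0))
        after = within_group_spread(adjusted["ips"].mean(axis=0))
        assert after < 0.1 * before
        # within-gel differences (the contrast information) are untouched
        np.testing.assert_allclose(
            adjusted["sample"] - adjusted["ips"],
            norm.normalized_log2["sample"] - norm.normalized_log2["ips"],
            atol=1e-12,
        )


class TestStandardWorkflow:
    def test_single_gel_per_group_is_error(self):
        from dige_mm import SpotMatrix

        design = make_design((1, 1, 1, 1, 1))
        rng = np.random.default_rng(4)
        m = SpotMatrix(
            [f"s{i}" for i in range(10)],
            design.gel_ids,
            rng.lognormal(5, 1, (10, 5)),
            rng.lognormal(5, 1, (10, 5)),
        )
        with pytest.raises(ValidationError, match=">=2 gels"):
            standard_workflow(m, design)

    def test_schema_matches_main_pipeline(self, sim_default):
        matrix, design, ann, _ = sim_default
        std = standard_workflow(matrix, design)
        main = fit_spot_models(normalize(replace_zeros(matrix), ann), design)
        assert list(std.table.columns) == list(main.table.columns)
        assert sorted(std.table["coefficient"].unique()) == sorted(COEFFICIENTS)
        assert len(std.table) == len(main.table)


def test_significant_molecules_signs():
    cfg = SimulationConfig(seed=12)
    matrix, design, ann, truth = simulate_experiment(cfg)
    res = fit_spot_models(normalize(replace_zeros(matrix), ann), design)
    molecules = significant_molecules(res, ann, "fluid_SCB", alpha=0.01)
    assert molecules and all(s in (-1, 1) for s in molecules.values())
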