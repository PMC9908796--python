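"""Stage-1 trial analysis: REML, H2, BLUPs, grids, correlations, ANOVA."""

import numpy as np
import pandas as pd
import pytest

from envgblup.trials import (
    PhenoGrid,
    TrialModel,
    assemble_pheno_grid,
    broad_sense_h2,
    cluster_environments_pheno,
    correlation_summary,
    env_correlation,
    gxe_anova,
)


def _rcbd(rng, n_lines=40, n_reps=3, s2g=3.0, s2e=1.0, rep_effects=None):
    """Balanced randomised-complete-block phenotypes with known truth."""
    g = rng.normal(0, np.sqrt(s2g), n_lines)
    if rep_effects is None:
        rep_effects = rng.normal(0, 1, n_reps)
    rows = []
    for j in range(n_reps):
        for i in range(n_lines):
            rows.append(
                {
                    "line": f"L{i:03d}",
                    "replicate": f"r{j}",
                    "value": 10 + rep_effects[j] + g[i]
                    + rng.normal(0, np.sqrt(s2e)),
                }
            )
    return pd.DataFrame(rows), g


class TestBroadSenseH2:
    @pytest.mark.parametrize(
        "s2g,s2e,expect", [(3, 1, 0.75), (0, 5, 0.0), (1.2, 0.3, 0.8)]
    )
    def test_values(self, s2g, s2e, expect):
        assert broad_sense_h2(s2g, s2e) == pytest.approx(expect)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            broad_sense_h2(-1, 1)


class TestTrialModel:
    def test_balanced_rcbd_matches_shrinkage_oracle(self, rng):
        # balanced RCBD: BLUP_i = (s2g / (s2g + s2e/r)) (ybar_i - ybar)
        plots, _ = _rcbd(rng, n_lines=60, n_reps=3)
        fit = TrialModel(plots).fit()
        r = 3
        shrink = fit.sigma2_g / (fit.sigma2_g + fit.sigma2_e / r)
        line_means = plots.groupby("line")["value"].mean()
        expect = shrink * (line_means - line_means.mean())
        np.testing.assert_allclose(
            fit.blups.sort_index(), expect.sort_index(), atol=1e-6
        )

    def test_reml_matches_bruteforce_grid(self, rng):
        plots, _ = _rcbd(rng, n_lines=20, n_reps=2)
        model = TrialModel(plots)
        y, X, Z = model._design()
        grid = np.linspace(-6, 6, 4001)
        nlls = [model._reml_nll(g, y, X, Z) for g in grid]
        brute = np.exp(grid[int(np.argmin(nlls))])
        fit = model.fit()
        assert abs(fit.sigma2_g / fit.sigma2_e - brute) < 1e-3 * max(1, brute)

    def test_variance_recovery_over_seeds(self):
        # 100 lines x 2 reps, s2g=3, s2e=1: mean estimates within 25% relative
        est_g, est_e = [], []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            plots, _ = _rcbd(rng, n_lines=100, n_reps=2, s2g=3.0, s2e=1.0)
            fit = TrialModel(plots).fit()
            est_g.append(fit.sigma2_g)
            est_e.append(fit.sigma2_e)
        assert abs(np.mean(est_g) - 3.0) / 3.0 < 0.25
        assert abs(np.mean(est_e) - 1.0) / 1.0 < 0.25

    def test_no_genetic_variance_shrinks_blups_to_zero(self, rng):
        plots, _ = _rcbd(rng, n_lines=40, n_reps=3, s2g=0.0, s2e=1.0)
        fit = TrialModel(plots).fit()
        assert np.abs(fit.blups).max() < 0.25
        assert fit.H2 < 0.2

    def test_unreplicated_passes_raw_through(self):
        plots = pd.DataFrame(
            {"line": ["a", "b", "c"], "value": [1.0, 2.0, 6.0]}
        )
        fit = TrialModel(plots).fit()
        assert fit.H2 is None
        assert not fit.replicated
        np.testing.assert_allclose(fit.blups.to_numpy(), [-2.0, -1.0, 3.0])

    def test_constant_values_raise(self):
        plots = pd.DataFrame(
            {"line": ["a", "b"] * 2, "replicate": ["r1"] * 2 + ["r2"] * 2,
             "value": [5.0] * 4}
        )
        with pytest.raises(ValueError, match="zero variance"):
            TrialModel(plots).fit()


class TestPhenoGrid:
    def test_assemble_with_overlap(self):
        grid = assemble_pheno_grid(
            {
                "E1": pd.Series({"a": 1.0, "b": 2.0}),
                "E2": pd.Series({"b": 3.0}),
                "E3": pd.Series({"a": 4.0}),
            }
        )
        assert grid.values.shape == (2, 3)
        assert grid.n_observed == 4
        assert (~grid.mask).to_numpy().sum() == 2

    def test_duplicate_record_raises(self):
        s = pd.Series([1.0, 2.0], index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_pheno_grid({"E1": s})

    def test_masked_cell_conservation(self, small_dataset):
        grid = small_dataset.pheno
        n_cells = len(grid.line_ids) * len(grid.environment_ids)
        assert n_cells - grid.n_observed == (~grid.mask).to_numpy().sum()

    def test_long_roundtrip(self, small_dataset):
        grid = small_dataset.pheno
        back = PhenoGrid.from_long(grid.to_long(), trait=grid.trait)
        # lines unobserved everywhere have no long-format record
        observed_rows = grid.values.dropna(how="all")
        pd.testing.assert_frame_equal(
            back.values.sort_index(axis=0).sort_index(axis=1),
            observed_rows.sort_index(axis=0).sort_index(axis=1),
            check_names=False,
        )


class TestEnvCorrelation:
    def test_identical_columns_give_unit_r(self, rng):
        col = pd.Series(rng.normal(size=20), index=[f"l{i}" for i in range(20)])
        grid = assemble_pheno_grid({"E1": col, "E2": col.copy()})
        corr = env_correlation(grid, min_overlap=10)
        assert corr.r.loc["E1", "E2"] == pytest.approx(1.0)

    def test_small_overlap_undefined(self, rng):
        a = pd.Series(rng.normal(size=12), index=[f"l{i}" for i in range(12)])
        b = pd.Series(rng.normal(size=2), index=["l0", "l1"])
        grid = assemble_pheno_grid({"E1": a, "E2": b})
        corr = env_correlation(grid, min_overlap=10)
        assert np.isnan(corr.r.loc["E1", "E2"])
        assert corr.n_overlap.loc["E1", "E2"] == 2

    def test_affine_rescaling_invariance(self, small_dataset):
        grid = small_dataset.pheno
        corr1 = env_correlation(grid, min_overlap=3).r
        scaled = PhenoGrid(values=grid.values * 3.0 + 7.0, trait=grid.trait)
        corr2 = env_correlation(scaled, min_overlap=3).r
        pd.testing.assert_frame_equal(corr1, corr2, atol=1e-12)
        np.testing.assert_allclose(corr1, corr1.T, atol=1e-12)

    def test_summary_on_constructed_correlations(self, rng):
        # three environments built so r(E1,E2) ~ 0.9 and the others ~ 0
        n = 400
        base = rng.normal(size=n)
        idx = [f"l{i}" for i in range(n)]
        grid = assemble_pheno_grid(
            {
                "E1": pd.Series(base + 0.3 * rng.normal(size=n), index=idx),
                "E2": pd.Series(base + 0.3 * rng.normal(size=n), index=idx),
                "E3": pd.Series(rng.normal(size=n), index=idx),
            }
        )
        summary = correlation_summary(env_correlation(grid), threshold=0.5)
        assert summary["n_pairs"] == 3
        assert summary["fraction_above"] == pytest.approx(1 / 3)
        assert summary["max"] > 0.85


class TestGxEAnova:
    def _fixture(self):
        # 2 lines x 2 envs x 2 reps, cell means [[1,-1],[-1,1]], no within-cell spread
        rows = []
        means = {("g1", "e1"): 1, ("g1", "e2"): -1,
                 ("g2", "e1"): -1, ("g2", "e2"): 1}
        for (g, e), m in means.items():
            for rep in ("r1", "r2"):
                rows.append({"line": g, "environment": e, "replicate": rep,
                             "value": float(m)})
        return pd.DataFrame(rows)

    def test_hand_anova_on_crossed_fixture(self):
        table = gxe_anova(self._fixture())
        assert table.loc["genotype", "SS"] == pytest.approx(0.0, abs=1e-10)
        assert table.loc["environment", "SS"] == pytest.approx(0.0, abs=1e-10)
        assert table.loc["G x E", "SS"] == pytest.approx(8.0)

    def test_location_invariance(self):
        df = self._fixture()
        t1 = gxe_anova(df)
        df2 = df.assign(value=df["value"] + 100.0)
        t2 = gxe_anova(df2)
        np.testing.assert_allclose(t1["SS"], t2["SS"], atol=1e-8)

    def test_ss_additivity(self, rng):
        rows = []
        for g in range(4):
            for e in range(3):
                for rep in range(2):
                    rows.append({"line": f"g{g}", "environment": f"e{e}",
                                 "replicate": f"r{rep}",
                                 "value": float(rng.normal())})
        df = pd.DataFrame(rows)
        table = gxe_anova(df)
        total = ((df["value"] - df["value"].mean()) ** 2).sum()
        assert table["SS"].sum() == pytest.approx(total, abs=1e-8)

    def test_single_obs_per_cell_flags_interaction(self, rng):
        rows = [
            {"line": f"g{g}", "environment": f"e{e}",
             "value": float(rng.normal())}
            for g in range(3) for e in range(3)
        ]
        with pytest.warns(UserWarning, match="confounded"):
            table = gxe_anova(pd.DataFrame(rows))
        assert np.isnan(table.loc["G x E", "F"])

    def test_incomplete_table_raises(self):
        df = self._fixture().iloc[:-2]
        with pytest.raises(ValueError, match="subset"):
            gxe_anova(df)


class TestClusterPheno:
    def test_two_blocks_recovered(self, rng):
        from scipy.cluster.hierarchy import fcluster

        n = 200
        idx = [f"l{i}" for i in range(n)]
        b1, b2 = rng.normal(size=n), rng.normal(size=n)
        cols = {}
        for j in range(3):
            cols[f"A{j}"] = pd.Series(b1 + 0.3 * rng.normal(size=n), index=idx)
        for j in range(3):
            cols[f"B{j}"] = pd.Series(b2 + 0.3 * rng.normal(size=n), index=idx)
        corr = env_correlation(assemble_pheno_grid(cols))
        Z, labels = cluster_environments_pheno(corr)
        groups = fcluster(Z, t=2, criterion="maxclust")
        by_label = dict(zip(labels, groups))
        assert len({by_label[f"A{j}"] for j in range(3)}) == 1
        assert len({by_label[f"B{j}"] for j in range(3)}) == 1
        assert by_label["A0"] != by_label["B0"]

    def test_identity_correlation_merges_at_height_one(self):
        from envgblup.trials import EnvCorrelation

        ids = ["a", "b", "c"]
        corr = EnvCorrelation(
            environment_ids=ids,
            r=pd.DataFrame(np.eye(3), index=ids, columns=ids),
            n_overlap=pd.DataFrame(99, index=ids, columns=ids),
        )
        Z, _ = cluster_environments_pheno(corr)
        assert Z.shape == (2, 4)
        np.testing.assert_allclose(Z[:, 2], 1.0, atol=1e-12)

    def test_undefined_pair_raises(self, rng):
        a = pd.Series(rng.normal(size=12), index=[f"l{i}" for i in range(12)])
        b = pd.Series(rng.normal(size=3), index=["l0", "l1", "l2"])
        corr = env_correlation(assemble_pheno_grid({"E1": a, "E2": b}),
                               min_overlap=10)
        with pytest.raises(ValueError, match="E1"):
            cluster_environments_pheno(corr)
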