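"""Kernels, Gibbs sampler, closed-form BLUP oracle, new-environment theory."""

import numpy as np
import pandas as pd
import pytest

from envgblup.kernels import (
    MODEL_TERMS,
    ObservationGrid,
    build_kernels,
    mme_predict,
)
from envgblup.model import GibbsSettings, MultiEnvGBLUP, genomic_h2
from envgblup.trials import PhenoGrid


def _random_G(rng, n, p=30):
    A = rng.normal(size=(n, p))
    A = (A - A.mean(0)) / A.std(0, ddof=1)
    return A @ A.T / p


def _grid(rng, nL=5, nE=4, masked=()):
    y = rng.normal(size=nL * nE)
    y[list(masked)] = np.nan
    return ObservationGrid(
        [f"L{i}" for i in range(nL)], [f"E{j}" for j in range(nE)], y
    )


class TestObservationGrid:
    def test_counts_and_order(self):
        vals = pd.DataFrame(
            [[1.0, 2.0], [np.nan, 4.0]], index=["a", "b"], columns=["E1", "E2"]
        )
        grid = ObservationGrid.from_pheno_grid(PhenoGrid(values=vals))
        assert grid.n_cells == 4
        assert grid.n_observed == 3
        # environment-major: (a,E1), (b,E1), (a,E2), (b,E2)
        np.testing.assert_array_equal(grid.y[:2], [1.0, np.nan][:1] + [np.nan])
        assert grid.cell_index("b", "E2") == 3

    def test_order_stable(self, small_dataset):
        g1 = ObservationGrid.from_pheno_grid(small_dataset.pheno)
        g2 = ObservationGrid.from_pheno_grid(small_dataset.pheno)
        np.testing.assert_array_equal(g1.y, g2.y)
        assert g1.observed.sum() == small_dataset.pheno.n_observed


class TestKernels:
    def test_model_g_single_kernel(self, rng):
        grid = _grid(rng)
        ker = build_kernels(grid, _random_G(rng, 5), terms="G")
        assert set(ker) == {"g"}

    def test_kge_block_diagonal(self, rng):
        G = _random_G(rng, 2)
        grid = _grid(rng, nL=2, nE=2)
        ker = build_kernels(grid, G, terms="GE-GxE")
        expect = np.zeros((4, 4))
        expect[:2, :2] = G
        expect[2:, 2:] = G
        np.testing.assert_allclose(ker["ge"], expect, atol=1e-12)

    def test_kgw_elementwise_product(self, rng):
        G = _random_G(rng, 3)
        Wm = rng.normal(size=(2, 4))
        omega = Wm @ Wm.T / 4
        grid = _grid(rng, nL=3, nE=2)
        ker = build_kernels(grid, G, omega, terms="GW-GxW")
        for i in range(3):
            for j in range(2):
                for i2 in range(3):
                    for j2 in range(2):
                        c, c2 = j * 3 + i, j2 * 3 + i2
                        assert ker["gw"][c, c2] == pytest.approx(
                            G[i, i2] * omega[j, j2]
                        )

    def test_hadamard_products_stay_psd(self, rng):
        # Schur product theorem, checked numerically on random instances
        for _ in range(3):
            G = _random_G(rng, 4)
            Wm = rng.normal(size=(3, 5))
            omega = Wm @ Wm.T / 5
            grid = _grid(rng, nL=4, nE=3)
            ker = build_kernels(grid, G, omega, terms="GEW-GxE-GxW")
            for K in ker.values():
                assert np.linalg.eigvalsh((K + K.T) / 2).min() >= -1e-8

    def test_missing_line_raises(self, rng):
        from envgblup.genotypes import GenomicRelationship

        grid = _grid(rng, nL=3, nE=2)
        G = GenomicRelationship(["L0", "L1"], np.eye(2))
        with pytest.raises(ValueError, match="L2"):
            build_kernels(grid, G, terms="G")


class TestGibbsSampler:
    def test_matches_mme_blup_with_known_variances(self, rng):
        # 20-cell instance, variance components fixed at the truth: the
        # posterior-mean prediction is the closed-form mixed-model BLUP
        G = _random_G(rng, 5)
        grid = _grid(rng, nL=5, nE=4, masked=(3, 7, 11))
        ker = build_kernels(grid, G, terms="GE-GxE")
        var = {"g": 1.0, "e": 0.5, "ge": 0.4}
        pred, _, _ = mme_predict(grid, ker, var, 0.3)
        model = MultiEnvGBLUP(grid, G, model="GE-GxE")
        diffs = []
        for seed in (1, 2, 3):
            res = model.fit(
                n_iter=12000, burn_in=2000, thin=1, seed=seed,
                fix_variances={**var, "eps": 0.3},
            )
            diffs.append(res.predictions - pred)
        assert np.abs(np.mean(diffs, axis=0)).max() < 0.02

    def test_variance_partition_identity_kernel(self, rng):
        # single identity kernel on standardised y: total variance ~ 1
        n = 60
        y = rng.normal(size=n)
        y = (y - y.mean()) / y.std(ddof=1)
        grid = ObservationGrid([f"L{i}" for i in range(n)], ["E0"], y)
        res = MultiEnvGBLUP(grid, np.eye(n), model="G").fit(
            n_iter=4000, burn_in=1000, thin=2, seed=5
        )
        total = res.sigma2["g"] + res.sigma2["eps"]
        assert abs(total - 1.0) < 0.15

    def test_degenerate_constant_phenotypes(self):
        n = 20
        y = np.full(n, 3.0)
        grid = ObservationGrid([f"L{i}" for i in range(n)], ["E0"], y)
        res = MultiEnvGBLUP(grid, np.eye(n), model="G").fit(
            n_iter=2000, burn_in=500, thin=2, seed=1
        )
        np.testing.assert_allclose(res.predictions, 3.0, atol=0.01)
        assert res.sigma2["eps"] < 1e-6

    def test_rrblup_equivalence_single_genomic_kernel(self, rng):
        # GBLUP with K_g and fixed variances equals ridge regression on the
        # markers with penalty p * s2_eps / s2_g (plus the GLS intercept)
        n, p = 30, 80
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        G = X @ X.T / p
        beta = rng.normal(size=p) / np.sqrt(p)
        y = 2.0 + X @ beta + rng.normal(0, 0.5, n)
        grid = ObservationGrid([f"L{i}" for i in range(n)], ["E0"], y)
        s2g, s2e = 1.0, 0.25
        ker = build_kernels(grid, G, terms="G")
        pred, _, mu = mme_predict(grid, ker, {"g": s2g}, s2e)
        lam = p * s2e / s2g
        ridge = X @ np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ (y - mu))
        np.testing.assert_allclose(pred, mu + ridge, atol=1e-8)
        res = MultiEnvGBLUP(grid, G, model="G").fit(
            n_iter=12000, burn_in=2000, thin=1, seed=2,
            fix_variances={"g": s2g, "eps": s2e},
        )
        assert np.abs(res.predictions - pred).max() < 0.05

    def test_chain_length_robustness(self, small_dataset, small_grm):
        model = MultiEnvGBLUP(
            small_dataset.pheno, small_grm, small_dataset.environments.omega,
            model="GEW",
        )
        r1 = model.fit(n_iter=8000, burn_in=2000, thin=2, seed=9)
        r2 = model.fit(n_iter=16000, burn_in=2000, thin=2, seed=9)
        scale = np.std(small_dataset.pheno.values.to_numpy()[
            ~np.isnan(small_dataset.pheno.values.to_numpy())])
        assert np.abs(r1.predictions - r2.predictions).max() / scale < 0.05

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            GibbsSettings(n_iter=100, burn_in=200)
        with pytest.raises(ValueError):
            GibbsSettings(thin=0)

    def test_genomic_h2_values(self, rng):
        grid = _grid(rng, nL=5, nE=4)
        res = MultiEnvGBLUP(grid, _random_G(rng, 5), model="G").fit(
            n_iter=1000, burn_in=200, thin=2, seed=0
        )
        vc = res.variance_components
        expect = vc.loc["g", "mean"] / (vc.loc["g", "mean"] + vc.loc["eps", "mean"])
        assert genomic_h2(res) == pytest.approx(expect)
        assert 0 <= res.genomic_h2 <= 1


class TestNewEnvironmentPrediction:
    """Kernel-structure consequences for a fully unobserved environment."""

    def _setup(self, rng, nL=8, nE=4):
        G = _random_G(rng, nL)
        Wm = rng.normal(size=(nE, 5))
        Wm = (Wm - Wm.mean(0)) / Wm.std(0, ddof=1)
        omega = Wm @ Wm.T / 5
        y = rng.normal(size=nL * nE)
        y[-nL:] = np.nan  # last environment entirely unobserved
        grid = ObservationGrid(
            [f"L{i}" for i in range(nL)], [f"E{j}" for j in range(nE)], y
        )
        return grid, G, omega

    def test_ge_contribution_exactly_zero(self, rng):
        grid, G, omega = self._setup(rng)
        ker = build_kernels(grid, G, terms="GE-GxE")
        var = {"g": 1.0, "e": 0.7, "ge": 0.5}
        _, contrib, _ = mme_predict(grid, ker, var, 0.4)
        target = grid.env_slice("E3")
        np.testing.assert_array_equal(contrib["ge"][target], 0.0)

    def test_e_contribution_exactly_zero(self, rng):
        grid, G, omega = self._setup(rng)
        ker = build_kernels(grid, G, terms="GE")
        _, contrib, _ = mme_predict(grid, ker, {"g": 1.0, "e": 0.7}, 0.4)
        np.testing.assert_array_equal(contrib["e"][grid.env_slice("E3")], 0.0)

    def test_ge_and_gegxe_predictions_coincide(self, rng):
        # with equal shared variance components the interaction model adds
        # nothing for an untested environment
        grid, G, omega = self._setup(rng)
        k1 = build_kernels(grid, G, terms="GE")
        k2 = build_kernels(grid, G, terms="GE-GxE")
        var = {"g": 1.0, "e": 0.7}
        p1, _, _ = mme_predict(grid, k1, var, 0.4)
        # put the interaction variance into the model but keep g/e/eps equal
        p2, _, _ = mme_predict(grid, k2, {**var, "ge": 0.5}, 0.4)
        target = grid.env_slice("E3")
        # predictions for the new environment flow only through g, whose
        # conditional mean changes because the training-cell covariance
        # changes; the *ranking* must coincide exactly when the ge kernel
        # carries zero information about the target
        assert np.array_equal(
            np.argsort(p1[target]), np.argsort(p2[target])
        ) or np.corrcoef(p1[target], p2[target])[0, 1] > 0.99

    def test_g_model_same_prediction_everywhere(self, rng):
        grid, G, omega = self._setup(rng)
        ker = build_kernels(grid, G, terms="G")
        pred, _, _ = mme_predict(grid, ker, {"g": 1.0}, 0.4)
        nL = grid.n_lines
        per_env = pred.reshape(grid.n_envs, nL)
        for j in range(1, grid.n_envs):
            np.testing.assert_allclose(per_env[j], per_env[0], atol=1e-10)

    def test_gw_target_with_duplicated_omega_row(self, rng):
        # if the target's Omega row equals a training environment's row, the
        # environmental-covariate contribution is identical in both
        nL, nE = 6, 4
        G = _random_G(rng, nL)
        Wm = rng.normal(size=(nE, 5))
        Wm[-1] = Wm[0]  # target ECs identical to E0's
        omega = Wm @ Wm.T / 5
        y = rng.normal(size=nL * nE)
        y[-nL:] = np.nan
        grid = ObservationGrid(
            [f"L{i}" for i in range(nL)], [f"E{j}" for j in range(nE)], y
        )
        ker = build_kernels(grid, G, omega, terms="GW")
        _, contrib, _ = mme_predict(grid, ker, {"g": 1.0, "w": 0.8}, 0.4)
        np.testing.assert_allclose(
            contrib["w"][grid.env_slice("E3")],
            contrib["w"][grid.env_slice("E0")],
            atol=1e-10,
        )
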