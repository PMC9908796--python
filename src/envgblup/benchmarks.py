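"""Reference computations exercising the whole pipeline on synthetic data.

These routines generate data at fixed study conditions, run the package's
own estimators, and return the summary quantities a user would quote:
variance-component recovery error, sampler-vs-closed-form agreement, and
cross-validation scheme comparisons.  They are shared by the test suite and
the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .crossval import run_cv_loeo, run_cv_ran, run_cv_sel
from .genotypes import compute_grm, impute_and_standardize
from .kernels import ObservationGrid, build_kernels, mme_predict
from .model import GibbsSettings, MultiEnvGBLUP
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "gibbs_vs_blup_gap",
    "variance_recovery",
    "cv_scheme_comparison",
]


def gibbs_vs_blup_gap(seed: int = 0, n_seeds: int = 3) -> float:
    """Max |Gibbs - closed-form BLUP| prediction gap on a 20-cell instance.

    Variance components are fixed at the truth so the sampler's posterior
    mean converges to the mixed-model-equation BLUP; the returned gap is the
    seed-averaged maximum absolute difference over all 20 cells.
    """
    rng = np.random.default_rng(seed)
    nL, nE = 5, 4
    A = rng.normal(size=(nL, 12))
    G = A @ A.T / 12
    y = rng.normal(size=nL * nE)
    y[[3, 7, 11]] = np.nan
    grid = ObservationGrid(
        [f"L{i}" for i in range(nL)], [f"E{j}" for j in range(nE)], y
    )
    ker = build_kernels(grid, G, terms="GE-GxE")
    var = {"g": 1.0, "e": 0.5, "ge": 0.4}
    pred, _, _ = mme_predict(grid, ker, var, 0.3)
    model = MultiEnvGBLUP(grid, G, model="GE-GxE")
    diffs = []
    for k in range(n_seeds):
        res = model.fit(
            n_iter=20_000, burn_in=2_000, thin=1, seed=seed + 100 + k,
            fix_variances={**var, "eps": 0.3},
        )
        diffs.append(res.predictions - pred)
    return float(np.abs(np.mean(diffs, axis=0)).max())


#: recovery study conditions: main-effects (GEW) generative regime with
#: equal unit variances, 200 lines x 10 environments, fully observed
RECOVERY_CONFIG = dict(
    n_lines=200,
    n_markers=300,
    n_envs=10,
    core_fraction=1.0,
    ec_effect_noise=1.0,  # e is i.i.d. in this regime; only w is EC-mediated
    variances={"g": 1.0, "e": 1.0, "w": 1.0, "ge": 0.0, "gw": 0.0, "eps": 1.0},
)

RECOVERY_SETTINGS = GibbsSettings(n_iter=3_000, burn_in=1_000, thin=2)


def variance_recovery(seed: int = 0, n_seeds: int = 5) -> pd.DataFrame:
    """Recover the GEW variance components from their own generative model.

    Returns a table of true values, seed-averaged posterior means and
    relative errors for sigma2_g, sigma2_e, sigma2_w and sigma2_eps.
    """
    cfg0 = RECOVERY_CONFIG
    estimates: dict[str, list[float]] = {t: [] for t in ("g", "e", "w", "eps")}
    for k in range(n_seeds):
        cfg = SimulationConfig(
            seed=seed + 1000 + k,
            allocation_range=(cfg0["n_lines"], cfg0["n_lines"]),
            **cfg0,
        )
        ds = simulate_dataset(cfg)
        G = compute_grm(
            impute_and_standardize(ds.genotypes), ds.genotypes.line_ids
        )
        model = MultiEnvGBLUP(
            ds.pheno, G, ds.environments.omega, model="GEW"
        )
        res = model.fit(
            GibbsSettings(
                n_iter=RECOVERY_SETTINGS.n_iter,
                burn_in=RECOVERY_SETTINGS.burn_in,
                thin=RECOVERY_SETTINGS.thin,
                seed=seed + 2000 + k,
            )
        )
        for t in estimates:
            estimates[t].append(res.sigma2[t])
    rows = []
    for t in estimates:
        true = cfg0["variances"]["eps" if t == "eps" else t]
        mean = float(np.mean(estimates[t]))
        rows.append(
            {
                "term": t,
                "true": true,
                "estimate": mean,
                "relative_error": abs(mean - true) / true,
            }
        )
    return pd.DataFrame(rows).set_index("term")


#: CV study conditions: sparse unbalanced allocation, environment main
#: effects dominating the genetic variance, EC-transferable structure (w,
#: gw) present so training-set composition matters
CV_CONFIG = dict(
    n_lines=60,
    n_markers=200,
    n_envs=10,
    core_fraction=0.3,
    variances={"g": 1.0, "e": 3.0, "w": 0.5, "ge": 0.2, "gw": 0.8, "eps": 0.5},
)

CV_SETTINGS = GibbsSettings(n_iter=2_000, burn_in=500, thin=3)


def cv_scheme_comparison(
    seed: int = 0,
    n_ran_replicates: int = 8,
    models_schemes: tuple[str, ...] = ("GW-GxW",),
    models_baseline: tuple[str, ...] = ("G", "GE"),
) -> dict[str, float]:
    """Compare CV-RAN, CV-SEL and CV-LOEO and the G vs GE baseline.

    Runs the three untested-environment designs with an EC-aware model
    (training-set composition can only matter when information transfers
    through Omega) and, on the same data, CV-RAN with the G and GE models.
    Returns mean predictive abilities per scheme and model.
    """
    cfg = SimulationConfig(seed=seed + 5000, **CV_CONFIG)
    ds = simulate_dataset(cfg)
    G = compute_grm(
        impute_and_standardize(ds.genotypes), ds.genotypes.line_ids
    )
    W = ds.environments.W
    omega = ds.environments.omega
    out: dict[str, float] = {}
    ran = run_cv_ran(
        ds.pheno, G, list(models_schemes), omega=omega,
        n_replicates=n_ran_replicates, seed=seed, settings=CV_SETTINGS,
    )
    sel = run_cv_sel(
        ds.pheno, G, list(models_schemes), W, omega=omega, seed=seed,
        settings=CV_SETTINGS,
    )
    loeo = run_cv_loeo(
        ds.pheno, G, list(models_schemes), omega=omega, seed=seed,
        settings=CV_SETTINGS,
    )
    out["pa_cv_ran"] = float(ran["r"].mean())
    out["pa_cv_sel"] = float(sel["r"].mean())
    out["pa_cv_loeo"] = float(loeo["r"].mean())
    base = run_cv_ran(
        ds.pheno, G, list(models_baseline), omega=omega,
        n_replicates=n_ran_replicates, seed=seed + 1, settings=CV_SETTINGS,
    )
    for m in models_baseline:
        out[f"pa_cv_ran_{m}"] = float(base.loc[base["model"] == m, "r"].mean())
    return out
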