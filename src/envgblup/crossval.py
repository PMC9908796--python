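"""Cross-validation schemes for untested environments and untested lines.

Four designs are implemented over a sparse line x environment phenotype
grid:

* CV-RAN: each target environment predicted from 4 environments sampled at
  random among the rest; 50 replicates by default.
* CV-SEL: the 4 training environments nearest the target in (standardised)
  environmental-covariate space; one run per target.
* CV-LOEO: leave one environment out, training on all the others.
* LOO-lines: leave one line out everywhere; predictive ability reported both
  per line (across environments) and per environment (across the assembled
  left-out lines).

Predictive ability is the Pearson correlation between predictions and the
adjusted phenotypes in the validation set.  Model comparison works on
Fisher-z transformed abilities (one-way ANOVA + Tukey HSD with a compact
letter display), with means back-transformed to r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenomicRelationship
from .kernels import ObservationGrid
from .model import GibbsSettings, MultiEnvGBLUP
from .trials import PhenoGrid
from .weather import ECMatrix, OmegaKernel, build_omega, select_training_envs

__all__ = [
    "predictive_ability",
    "fisher_z",
    "fisher_z_inverse",
    "run_cv_ran",
    "run_cv_sel",
    "run_cv_loeo",
    "run_cv_lines",
    "compare_models",
]


def predictive_ability(predicted, observed) -> float:
    """Pearson correlation between predictions and adjusted phenotypes.

    Sign is preserved (negative abilities are real results).  Fewer than 3
    pairs or a constant vector leaves the value undefined (NaN, with a
    warning).
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "predictive ability undefined (fewer than 3 pairs or constant vector)",
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def fisher_z(r: float) -> float:
    """Variance-stabilising transform Z = 0.5 [ln(1 + r) - ln(1 - r)].

    |r| >= 1 is clamped to 1 - 1e-6 (with a warning) so perfect
    correlations stay finite.
    """
    r = float(r)
    if abs(r) >= 1:
        warnings.warn("|r| >= 1 clamped before the Fisher transform", stacklevel=2)
        r = np.sign(r) * (1 - 1e-6)
    return float(np.arctanh(r))


def fisher_z_inverse(z: float) -> float:
    """Back-transform a Fisher z value to a correlation."""
    return float(np.tanh(z))


@dataclass
class _DataBundle:
    pheno: PhenoGrid
    G: GenomicRelationship | np.ndarray
    omega: OmegaKernel | None
    W: ECMatrix | None


def _subgrid(pheno: PhenoGrid, train_envs: list[str], target_env: str) -> ObservationGrid:
    """Grid over training environments plus the fully masked target."""
    cols = list(train_envs) + [target_env]
    sub = pheno.values[cols].copy()
    sub[target_env] = np.nan
    # PhenoGrid forbids empty environments; build the cell grid directly
    grid = ObservationGrid(
        line_ids=list(sub.index),
        environment_ids=cols,
        y=sub.to_numpy(dtype=float).T.reshape(-1),
    )
    return grid


def _fit_and_score(
    bundle: _DataBundle,
    model: str,
    train_envs: list[str],
    target_env: str,
    settings: GibbsSettings,
) -> tuple[float, int]:
    assert target_env not in train_envs, "leakage: target in training set"
    grid = _subgrid(bundle.pheno, train_envs, target_env)
    fit = MultiEnvGBLUP(grid, bundle.G, bundle.omega, model=model).fit(settings)
    pred = fit.predictions_for(target_env)
    obs = bundle.pheno.values[target_env]
    ok = obs.notna()
    r = predictive_ability(pred[ok], obs[ok])
    return r, int(ok.sum())


def _result_row(trait, scheme, model, target, replicate, r, n_test, train_envs):
    return {
        "trait": trait,
        "scheme": scheme,
        "model": model,
        "target": target,
        "replicate": replicate,
        "r": r,
        "z": fisher_z(r) if np.isfinite(r) else np.nan,
        "n_test": n_test,
        "training_envs": ",".join(train_envs),
    }


def _derive_seed(master: int, *labels) -> int:
    """Deterministic per-run seed below 2**31 from a master seed and labels."""
    h = master & 0x7FFFFFFF
    for lab in labels:
        for ch in str(lab):
            h = (h * 31 + ord(ch)) & 0xFFFFFFFF
    return h & 0x7FFFFFFF


def run_cv_ran(
    pheno: PhenoGrid,
    G,
    models: list[str],
    omega: OmegaKernel | None = None,
    n_train_envs: int = 4,
    n_replicates: int = 50,
    seed: int = 0,
    settings: GibbsSettings | None = None,
) -> pd.DataFrame:
    """Random-training-environment cross-validation.

    For each target environment and replicate, ``n_train_envs`` environments
    are sampled uniformly without replacement from the remaining ones; each
    model is fitted on their cells only and scored on the target.
    """
    envs = pheno.environment_ids
    if len(envs) < n_train_envs + 1:
        raise ValueError(
            f"need at least {n_train_envs + 1} environments, have {len(envs)}"
        )
    settings = settings or GibbsSettings()
    rows = []
    for target in envs:
        others = [e for e in envs if e != target]
        rng = np.random.default_rng(_derive_seed(seed, "ran", target))
        for rep in range(n_replicates):
            train = sorted(rng.choice(others, size=n_train_envs, replace=False))
            for model in models:
                run_settings = GibbsSettings(
                    n_iter=settings.n_iter, burn_in=settings.burn_in,
                    thin=settings.thin, prior_df=settings.prior_df,
                    seed=_derive_seed(seed, "ran", target, rep, model),
                )
                r, n_test = _fit_and_score(
                    _DataBundle(pheno, G, omega, None), model, train, target,
                    run_settings,
                )
                rows.append(
                    _result_row(pheno.trait, "CV-RAN", model, target, rep, r,
                                n_test, train)
                )
    return pd.DataFrame(rows)


def run_cv_sel(
    pheno: PhenoGrid,
    G,
    models: list[str],
    W: ECMatrix,
    omega: OmegaKernel | None = None,
    n_train_envs: int = 4,
    seed: int = 0,
    settings: GibbsSettings | None = None,
) -> pd.DataFrame:
    """EC-nearest-environment cross-validation (one run per target)."""
    settings = settings or GibbsSettings()
    if omega is None:
        omega = build_omega(W)
    rows = []
    for target in pheno.environment_ids:
        train = select_training_envs(target, W, k=n_train_envs)
        for model in models:
            run_settings = GibbsSettings(
                n_iter=settings.n_iter, burn_in=settings.burn_in,
                thin=settings.thin, prior_df=settings.prior_df,
                seed=_derive_seed(seed, "sel", target, model),
            )
            r, n_test = _fit_and_score(
                _DataBundle(pheno, G, omega, W), model, train, target,
                run_settings,
            )
            rows.append(
                _result_row(pheno.trait, "CV-SEL", model, target, 0, r,
                            n_test, train)
            )
    return pd.DataFrame(rows)


def run_cv_loeo(
    pheno: PhenoGrid,
    G,
    models: list[str],
    omega: OmegaKernel | None = None,
    seed: int = 0,
    settings: GibbsSettings | None = None,
) -> pd.DataFrame:
    """Leave-one-environment-out: train on every remaining environment."""
    envs = pheno.environment_ids
    if len(envs) < 3:
        raise ValueError("need at least 3 environments")
    settings = settings or GibbsSettings()
    rows = []
    for target in envs:
        train = [e for e in envs if e != target]
        for model in models:
            run_settings = GibbsSettings(
                n_iter=settings.n_iter, burn_in=settings.burn_in,
                thin=settings.thin, prior_df=settings.prior_df,
                seed=_derive_seed(seed, "loeo", target, model),
            )
            r, n_test = _fit_and_score(
                _DataBundle(pheno, G, omega, None), model, train, target,
                run_settings,
            )
            rows.append(
                _result_row(pheno.trait, "CV-LOEO", model, target, 0, r,
                            n_test, train)
            )
    return pd.DataFrame(rows)


def run_cv_lines(
    pheno: PhenoGrid,
    G,
    models: list[str],
    omega: OmegaKernel | None = None,
    lines: list[str] | None = None,
    seed: int = 0,
    settings: GibbsSettings | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-line-out over the fully observed lines.

    Each eligible line is masked in every environment in turn and predicted
    from all remaining cells.  Returns (per-line table, per-environment
    table); the per-environment ability is computed across the assembled
    left-out predictions of all lines.
    """
    settings = settings or GibbsSettings()
    eligible = pheno.common_lines()
    if lines is None:
        lines = eligible
    else:
        dropped = [l for l in lines if l not in eligible]
        if dropped:
            warnings.warn(
                f"lines not observed in all environments excluded: {dropped}",
                stacklevel=2,
            )
        lines = [l for l in lines if l in eligible]
    if not lines:
        raise ValueError("no fully observed lines to leave out")
    envs = pheno.environment_ids
    line_rows = []
    assembled: dict[str, pd.DataFrame] = {
        m: pd.DataFrame(index=lines, columns=envs, dtype=float) for m in models
    }
    for line in lines:
        masked = pheno.values.copy()
        masked.loc[line, :] = np.nan
        grid = ObservationGrid(
            line_ids=list(masked.index),
            environment_ids=envs,
            y=masked.to_numpy(dtype=float).T.reshape(-1),
        )
        for model in models:
            run_settings = GibbsSettings(
                n_iter=settings.n_iter, burn_in=settings.burn_in,
                thin=settings.thin, prior_df=settings.prior_df,
                seed=_derive_seed(seed, "loo", line, model),
            )
            fit = MultiEnvGBLUP(grid, G, omega, model=model).fit(run_settings)
            pred = fit.predictions_frame().loc[line]
            obs = pheno.values.loc[line]
            assembled[model].loc[line] = pred
            r = predictive_ability(pred.to_numpy(), obs.to_numpy())
            line_rows.append(
                {
                    "trait": pheno.trait, "scheme": "LOO-LINES", "model": model,
                    "target": line, "level": "line", "r": r,
                    "z": fisher_z(r) if np.isfinite(r) else np.nan,
                    "n_test": int(obs.notna().sum()),
                }
            )
    env_rows = []
    for model in models:
        for env in envs:
            pred = assembled[model][env]
            obs = pheno.values.loc[lines, env]
            r = predictive_ability(pred.to_numpy(), obs.to_numpy())
            env_rows.append(
                {
                    "trait": pheno.trait, "scheme": "LOO-LINES", "model": model,
                    "target": env, "level": "environment", "r": r,
                    "z": fisher_z(r) if np.isfinite(r) else np.nan,
                    "n_test": int(obs.notna().sum()),
                }
            )
    return pd.DataFrame(line_rows), pd.DataFrame(env_rows)


# -- model comparison ------------------------------------------------------


def _compact_letter_display(
    groups: list[str], not_different: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; groups with no
    shared letter differ.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            if frozenset((a, b)) in not_different:
                continue
            # significant pair: split every set containing both
            split = []
            for s in letter_sets:
                if a in s and b in s:
                    split.extend([s - {a}, s - {b}])
                else:
                    split.append(s)
            # absorb duplicates and proper subsets
            letter_sets = [
                s for k, s in enumerate(split)
                if s and not any(
                    (s < o) or (s == o and k > m) for m, o in enumerate(split)
                )
            ]
    # every group must carry at least one letter
    for g in groups:
        if not any(g in s for s in letter_sets):
            letter_sets.append({g})
    # deterministic letter order: by first group appearance
    letter_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for s, letter in zip(letter_sets, letters):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def compare_models(cv: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """ANOVA + Tukey HSD comparison of models per (trait, target).

    Works on Fisher-z values with model as the single factor.  Needs at
    least two models and two replicates per model.  Returns one row per
    (trait, target, model) with the back-transformed mean ability, the ANOVA
    F and p, and the compact Tukey letter.
    """
    from scipy import stats as sps
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    out = []
    for (trait, target), sub in cv.groupby(["trait", "target"]):
        sub = sub.dropna(subset=["z"])
        models = list(dict.fromkeys(sub["model"]))
        if len(models) < 2:
            raise ValueError(f"{trait}/{target}: need at least two models")
        counts = sub.groupby("model").size()
        if (counts < 2).any():
            raise ValueError(
                f"{trait}/{target}: need at least two replicates per model "
                "for a within-group variance"
            )
        groups = [sub.loc[sub["model"] == m, "z"].to_numpy() for m in models]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            f_stat, p_val = 0.0, 1.0
            nd = {frozenset((a, b)) for i, a in enumerate(models)
                  for b in models[i + 1:]}
        else:
            f_stat, p_val = sps.f_oneway(*groups)
            tuk = pairwise_tukeyhsd(
                sub["z"].to_numpy(), sub["model"].to_numpy(), alpha=alpha
            )
            nd = set()
            res = pd.DataFrame(
                tuk.summary().data[1:], columns=tuk.summary().data[0]
            )
            for _, row in res.iterrows():
                if not row["reject"]:
                    nd.add(frozenset((row["group1"], row["group2"])))
        letters = _compact_letter_display(models, nd)
        for m in models:
            z_mean = float(np.mean(sub.loc[sub["model"] == m, "z"]))
            out.append(
                {
                    "trait": trait,
                    "target": target,
                    "model": m,
                    "z_mean": z_mean,
                    "r_mean": fisher_z_inverse(z_mean),
                    "anova_F": float(f_stat),
                    "anova_p": float(p_val),
                    "letters": letters[m],
                }
            )
    return pd.DataFrame(out)
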