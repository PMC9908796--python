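"""Stage-1 trial analysis and phenotype assembly.

Each field trial is analysed separately with the linear mixed model
``y = Xb + Zu + e`` where replicates are fixed, genotypes random
(u ~ N(0, sigma2_g I)) and residuals i.i.d.  Variance components are
estimated by REML, profiling the ratio gamma = sigma2_g / sigma2_e on a
log grid with a bounded refinement.  Broad-sense heritability is
H2 = sigma2_g / (sigma2_g + sigma2_e) and line BLUPs are the conditional
means of the genotype effects, used as adjusted phenotypes downstream.

Unreplicated trials (one plot per line) cannot separate the two variances;
their raw values are passed through unchanged and H2 is reported undefined,
which is standard practice for such designs.

The module also assembles the line x environment adjusted-phenotype grid,
computes pairwise-complete between-environment correlations, the two-way
genotype x environment ANOVA, and phenotype-based environment clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "TrialModel",
    "TrialResults",
    "PhenoGrid",
    "EnvCorrelation",
    "broad_sense_h2",
    "assemble_pheno_grid",
    "env_correlation",
    "correlation_summary",
    "gxe_anova",
    "cluster_environments_pheno",
]


def broad_sense_h2(sigma2_g: float, sigma2_e: float) -> float:
    """Broad-sense heritability sigma2_g / (sigma2_g + sigma2_e)."""
    if sigma2_g < 0 or sigma2_e < 0:
        raise ValueError("variance components must be non-negative")
    if sigma2_g == 0 and sigma2_e == 0:
        raise ValueError("both variance components are zero")
    return sigma2_g / (sigma2_g + sigma2_e)


@dataclass
class TrialResults:
    """REML fit of a single trial: variance components, H2 and line BLUPs."""

    sigma2_g: float
    sigma2_e: float
    H2: float | None
    blups: pd.Series  # genotype effect per line (deviation from trial mean)
    replicated: bool
    trait: str | None = None

    def adjusted_phenotypes(self) -> pd.Series:
        """Per-line adjusted values used as the stage-2 response."""
        return self.blups

    def summary(self) -> str:
        h2 = "undefined" if self.H2 is None else f"{self.H2:.3f}"
        lines = [
            "Single-trial mixed model (genotype random, replicate fixed)",
            f"  lines: {len(self.blups)}   replicated: {self.replicated}",
            f"  sigma2_g: {self.sigma2_g:.4g}   sigma2_e: {self.sigma2_e:.4g}",
            f"  H2: {h2}",
        ]
        return "\n".join(lines)


class TrialModel:
    """Per-trial mixed model with genotype random and replicate fixed.

    Parameters
    ----------
    plots : DataFrame with columns ``line``, ``value`` and optionally
        ``replicate``.  One row per plot.
    """

    def __init__(self, plots: pd.DataFrame, trait: str | None = None):
        plots = plots.copy()
        if "replicate" not in plots.columns:
            plots["replicate"] = "r1"
        missing = {"line", "value"} - set(plots.columns)
        if missing:
            raise ValueError(f"plot table missing columns: {sorted(missing)}")
        if plots.duplicated(["line", "replicate"]).any():
            raise ValueError("duplicate (line, replicate) plot records")
        if plots["line"].nunique() < 2:
            raise ValueError("need at least 2 lines")
        if not np.isfinite(plots["value"]).all():
            raise ValueError("non-finite phenotype values")
        self.plots = plots
        self.trait = trait
        self.lines = sorted(plots["line"].unique())
        self.replicated = plots["line"].value_counts().max() > 1

    # -- REML machinery ----------------------------------------------------

    def _design(self):
        y = self.plots["value"].to_numpy(dtype=float)
        Z = pd.get_dummies(
            pd.Categorical(self.plots["line"], categories=self.lines)
        ).to_numpy(dtype=float)
        reps = sorted(self.plots["replicate"].unique())
        X = pd.get_dummies(
            pd.Categorical(self.plots["replicate"], categories=reps)
        ).to_numpy(dtype=float)
        # full-rank fixed design: intercept + rep contrasts
        X = np.column_stack([np.ones(len(y)), X[:, 1:]])
        return y, X, Z

    @staticmethod
    def _reml_nll(log_gamma: float, y, X, Z) -> float:
        """Negative restricted log-likelihood profiled over sigma2_e.

        gamma = sigma2_g / sigma2_e; V0 = I + gamma ZZ'.
        """
        gamma = np.exp(log_gamma)
        n, p = X.shape
        V0 = np.eye(n) + gamma * (Z @ Z.T)
        c, lower = np.linalg.cholesky(V0), True
        logdet_V0 = 2 * np.sum(np.log(np.diag(c)))
        Vi = np.linalg.inv(V0)
        XtViX = X.T @ Vi @ X
        sign, logdet_X = np.linalg.slogdet(XtViX)
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        quad = r @ Vi @ r
        if quad <= 0:
            return np.inf
        return 0.5 * (logdet_V0 + logdet_X + (n - p) * np.log(quad))

    def fit(self) -> TrialResults:
        if np.ptp(self.plots["value"].to_numpy()) == 0:
            raise ValueError("all phenotype values identical: zero variance")
        if not self.replicated:
            # variances not separable without replication: pass raw data on
            raw = self.plots.set_index("line")["value"].reindex(self.lines)
            return TrialResults(
                sigma2_g=float("nan"),
                sigma2_e=float("nan"),
                H2=None,
                blups=raw - raw.mean(),
                replicated=False,
                trait=self.trait,
            )
        y, X, Z = self._design()
        n, p = X.shape
        grid = np.linspace(-8, 8, 33)
        vals = [self._reml_nll(g, y, X, Z) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            self._reml_nll,
            bounds=(g0 - 1.0, g0 + 1.0),
            args=(y, X, Z),
            method="bounded",
            options={"xatol": 1e-8},
        )
        gamma = float(np.exp(res.x))
        V0 = np.eye(n) + gamma * (Z @ Z.T)
        Vi = np.linalg.inv(V0)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        P0y = Vi @ r
        sigma2_e = float(r @ P0y / (n - p))
        sigma2_g = gamma * sigma2_e
        # BLUP: u = sigma2_g Z' V^-1 r with V = sigma2_e V0, so u = gamma Z' V0^-1 r
        u = gamma * (Z.T @ P0y)
        blups = pd.Series(u, index=self.lines)
        return TrialResults(
            sigma2_g=sigma2_g,
            sigma2_e=sigma2_e,
            H2=broad_sense_h2(sigma2_g, sigma2_e),
            blups=blups,
            replicated=True,
            trait=self.trait,
        )


# -- phenotype grid --------------------------------------------------------


@dataclass
class PhenoGrid:
    """Line x environment adjusted phenotypes for one trait; NaN = untested."""

    values: pd.DataFrame  # index: line ids, columns: environment ids
    trait: str = "trait"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate line ids in phenotype grid")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate environment ids in phenotype grid")
        if (self.values.notna().sum(axis=0) == 0).any():
            empty = list(self.values.columns[self.values.notna().sum(axis=0) == 0])
            raise ValueError(f"environments with no observations: {empty}")

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def environment_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed mask."""
        return self.values.notna()

    @property
    def n_observed(self) -> int:
        return int(self.values.notna().to_numpy().sum())

    def common_lines(self) -> list[str]:
        """Lines observed in every environment."""
        return list(self.values.index[self.values.notna().all(axis=1)])

    def to_long(self) -> pd.DataFrame:
        long = (
            self.values.rename_axis("line")
            .reset_index()
            .melt(id_vars="line", var_name="environment", value_name="value")
            .dropna(subset=["value"])
        )
        long.insert(2, "trait", self.trait)
        return long[["line", "environment", "trait", "value"]]

    @classmethod
    def from_long(cls, long: pd.DataFrame, trait: str | None = None) -> "PhenoGrid":
        df = long.copy()
        if trait is not None and "trait" in df.columns:
            df = df[df["trait"] == trait]
        if df.duplicated(["line", "environment"]).any():
            raise ValueError("duplicate (line, environment) records")
        wide = df.pivot(index="line", columns="environment", values="value")
        return cls(values=wide, trait=trait or "trait")


def assemble_pheno_grid(
    per_env: dict[str, pd.Series], trait: str = "trait"
) -> PhenoGrid:
    """Combine per-environment adjusted phenotypes into a sparse grid.

    ``per_env`` maps environment id (location x year x season) to a Series of
    adjusted values indexed by line id.  Cells without a record are masked.
    """
    frames = {}
    for env, series in per_env.items():
        if series.index.duplicated().any():
            dup = list(series.index[series.index.duplicated()])
            raise ValueError(f"duplicate line records in environment {env!r}: {dup}")
        frames[env] = series
    wide = pd.DataFrame(frames)
    return PhenoGrid(values=wide, trait=trait)


# -- between-environment correlation ---------------------------------------


@dataclass
class EnvCorrelation:
    environment_ids: list[str]
    r: pd.DataFrame  # env x env Pearson correlations, NaN where undefined
    n_overlap: pd.DataFrame  # shared observed lines per pair


def env_correlation(grid: PhenoGrid, min_overlap: int = 10) -> EnvCorrelation:
    """Pairwise-complete Pearson correlations between environment columns.

    Pairs with fewer than ``min_overlap`` shared lines are left undefined.
    """
    if min_overlap < 3:
        raise ValueError("min_overlap must be at least 3")
    vals = grid.values
    mask = vals.notna().astype(int)
    n_overlap = mask.T @ mask
    r = vals.corr(method="pearson", min_periods=min_overlap)
    r = r.mask(n_overlap < min_overlap)
    np.fill_diagonal(r.values, 1.0)
    return EnvCorrelation(
        environment_ids=list(vals.columns), r=r, n_overlap=n_overlap
    )


def correlation_summary(corr: EnvCorrelation, threshold: float = 0.5) -> dict:
    """Summary of the upper-triangle correlations: count, fraction above a
    threshold, and the extremes.  Undefined pairs are excluded."""
    r = corr.r.to_numpy()
    iu = np.triu_indices_from(r, k=1)
    vals = r[iu]
    vals = vals[~np.isnan(vals)]
    return {
        "n_pairs": int(vals.size),
        "fraction_above": float(np.mean(vals > threshold)) if vals.size else np.nan,
        "max": float(vals.max()) if vals.size else np.nan,
        "min": float(vals.min()) if vals.size else np.nan,
    }


# -- genotype x environment ANOVA ------------------------------------------


def gxe_anova(data: pd.DataFrame) -> pd.DataFrame:
    """Two-way genotype x environment analysis of variance.

    ``data`` is long format with columns ``line``, ``environment``, ``value``
    and optionally ``replicate``.  The line x environment table must be
    complete (subset to common lines first).  With a single observation per
    cell the interaction is confounded with the residual: its sum of squares
    is reported but the F test is flagged unavailable (NaN).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = data.rename(columns={"line": "G", "environment": "E", "value": "y"}).copy()
    cell_counts = df.groupby(["G", "E"], observed=True).size().unstack()
    if cell_counts.isna().any().any() or (cell_counts == 0).any().any():
        raise ValueError(
            "incomplete genotype x environment table; subset to lines observed "
            "in all environments before the ANOVA"
        )
    replicated = (cell_counts > 1).all().all()
    if replicated:
        model = ols("y ~ C(G) + C(E) + C(G):C(E)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        table = table.rename(
            index={"C(G)": "genotype", "C(E)": "environment",
                   "C(G):C(E)": "G x E", "Residual": "residual"}
        )
    else:
        model = ols("y ~ C(G) + C(E)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        table = table.rename(
            index={"C(G)": "genotype", "C(E)": "environment", "Residual": "G x E"}
        )
        # one observation per cell: interaction == residual, no F test for it
        table.loc["G x E", ["F", "PR(>F)"]] = np.nan
        warnings.warn(
            "single observation per cell: G x E confounded with residual, "
            "no F test for the interaction",
            stacklevel=2,
        )
    table = table.rename(columns={"sum_sq": "SS", "PR(>F)": "p"})
    return table


# -- environment clustering on phenotypic correlation ----------------------


def cluster_environments_pheno(corr: EnvCorrelation):
    """Average-linkage hierarchical clustering of environments on d = 1 - r.

    Returns (linkage matrix in scipy format, leaf labels).
    """
    r = corr.r.to_numpy(dtype=float)
    if np.isnan(r).any():
        bad = [
            (corr.environment_ids[i], corr.environment_ids[j])
            for i, j in zip(*np.where(np.isnan(r)))
            if i < j
        ]
        raise ValueError(f"undefined correlations for pairs: {bad}")
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    Z = linkage(squareform(d, checks=False), method="average")
    return Z, list(corr.environment_ids)
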