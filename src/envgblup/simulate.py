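"""Synthetic multi-environment trial data with known ground truth.

The generator emulates the data a sparse multi-environment rice trial
produces: biallelic SNP genotypes for an inbred-line panel, environmental
covariates per environment (optionally backed by a daily weather series),
an unbalanced line x environment allocation mask with a core set of lines
observed everywhere, and phenotypes from the reaction-norm generative model

    y_ij = mu + g_i + e_j + w_ij + ge_ij + gw_ij + eps_ij

with each component rescaled so its realised variance over observed cells
hits the configured target exactly:

* g_i: additive marker effects on the centred standardised genotypes,
* e_j: environment main effect, a linear function of the ECs plus noise so
  that EC distance predicts environmental similarity,
* w_ij = w_j: EC-driven environmental effect with covariance Omega = WW'/q,
* ge_ij: i.i.d. line x environment deviation - deliberately *not* mediated
  by ECs, so it cannot transfer to an unobserved environment,
* gw_ij: marker x EC interaction, X A W'/sqrt(p q), whose cell covariance is
  exactly G (x) Omega and which *does* transfer through Omega,
* eps_ij: i.i.d. noise.

The ge/gw separation mirrors the two interaction kernel classes of the
prediction models and is what makes untested-environment behaviour testable.
All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .genotypes import HapMapRecord, MarkerMatrix, impute_and_standardize
from .trials import PhenoGrid
from .weather import EC_COVARIATES, PHASES, ECMatrix, OmegaKernel, build_omega

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedEnvironments",
    "simulate_genotypes",
    "genotypes_to_hapmap_records",
    "simulate_environments",
    "simulate_daily_weather",
    "make_sparse_mask",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults describe a mid-sized sparse multi-environment trial: 150 inbred
    lines genotyped at 500 SNPs, 10 environments described by 8 ECs, 35-100%
    of the panel allocated per environment with a 30% core tested everywhere.
    Variance targets put the environment main effect above the genetic
    variance (as multi-environment yield trials typically show), with
    moderate EC-mediated structure and interactions.
    """

    n_lines: int = 150
    n_markers: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    het_rate: float = 0.02
    n_envs: int = 10
    n_ecs: int = 8
    ec_correlation: float = 0.3
    ec_effect_noise: float = 0.3  # share of env-effect variance not EC-driven
    variances: dict[str, float] = field(
        default_factory=lambda: {
            "g": 1.0, "e": 2.0, "w": 0.5, "ge": 0.3, "gw": 0.3, "eps": 0.5,
        }
    )
    allocation_range: tuple[int, int] | None = None  # default (0.35 n, n)
    core_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        if any(v < 0 for v in self.variances.values()):
            raise ValueError("variance targets must be non-negative")
        if self.allocation_range is None:
            self.allocation_range = (
                max(2, int(round(0.35 * self.n_lines))), self.n_lines
            )
        lo, hi = self.allocation_range
        if not 1 <= lo <= hi <= self.n_lines:
            raise ValueError("invalid allocation range")


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    inject_qc_failures: dict[str, float] | None = None,
) -> MarkerMatrix:
    """Draw inbred-panel genotypes on the {0, 0.5, 1} scale.

    Minor-allele frequencies are uniform on ``config.maf_range``; each line is
    homozygous except for a small heterozygote rate.  ``inject_qc_failures``
    maps {"missing", "maf", "het"} to fractions of extra markers violating
    the corresponding QC filter (appended after the regular markers, with ids
    prefixed ``BAD``), used to test the filtering stage.
    """
    rng = rng or np.random.default_rng(config.seed)
    nL, nM = config.n_lines, config.n_markers
    freqs = rng.uniform(*config.maf_range, size=nM)
    values = (rng.random((nL, nM)) < freqs).astype(float)
    het = rng.random((nL, nM)) < config.het_rate
    values[het] = 0.5
    # a QC-filtered panel is polymorphic; redraw the occasional fixed column
    for j in range(nM):
        while np.ptp(values[:, j]) == 0:
            col = (rng.random(nL) < freqs[j]).astype(float)
            col[rng.random(nL) < config.het_rate] = 0.5
            values[:, j] = col
    line_ids = [f"L{i:03d}" for i in range(nL)]
    marker_ids = [f"M{j:04d}" for j in range(nM)]
    if inject_qc_failures:
        extras, extra_ids = [], []
        n_bad = {k: int(round(v * nM)) for k, v in inject_qc_failures.items()}
        for j in range(n_bad.get("missing", 0)):
            col = (rng.random(nL) < 0.3).astype(float)
            col[rng.choice(nL, size=int(0.4 * nL), replace=False)] = np.nan
            extras.append(col)
            extra_ids.append(f"BADMISS{j:03d}")
        for j in range(n_bad.get("maf", 0)):
            col = np.zeros(nL)
            col[rng.choice(nL, size=1)] = 1.0  # singleton: MAF ~ 1/n
            extras.append(col)
            extra_ids.append(f"BADMAF{j:03d}")
        for j in range(n_bad.get("het", 0)):
            col = (rng.random(nL) < 0.3).astype(float)
            col[rng.random(nL) < 0.5] = 0.5
            extras.append(col)
            extra_ids.append(f"BADHET{j:03d}")
        if extras:
            values = np.column_stack([values, np.column_stack(extras)])
            marker_ids = marker_ids + extra_ids
    return MarkerMatrix(line_ids=line_ids, marker_ids=marker_ids, values=values)


def genotypes_to_hapmap_records(
    m: MarkerMatrix, rng: np.random.Generator | None = None
) -> list[HapMapRecord]:
    """Express a numeric genotype matrix as HapMap records (random allele pairs)."""
    rng = rng or np.random.default_rng(0)
    records = []
    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    for j, mid in enumerate(m.marker_ids):
        major, minor = pairs[rng.integers(len(pairs))]
        calls: list[str | None] = []
        for v in m.values[:, j]:
            if np.isnan(v):
                calls.append(None)
            elif v == 0.0:
                calls.append(major + major)
            elif v == 1.0:
                calls.append(minor + minor)
            else:
                calls.append("".join(sorted((major, minor))))
        records.append(
            HapMapRecord(
                marker_id=mid,
                alleles=(major, minor),
                chromosome=str(1 + j % 12),
                position=1 + j,
                calls=calls,
            )
        )
    return records


@dataclass
class SimulatedEnvironments:
    """ECs and the EC-linked environment main effects."""

    ec_raw: pd.DataFrame  # environments x raw EC values
    W: ECMatrix  # standardised
    omega: OmegaKernel
    env_effects: pd.Series  # un-rescaled main effect per environment
    ec_loadings: np.ndarray


def simulate_environments(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedEnvironments:
    """Draw EC vectors and EC-linked environment main effects.

    ECs come from a multivariate normal with exchangeable correlation
    ``config.ec_correlation``.  Environment main effects are a linear
    function of the ECs plus independent noise with variance share
    ``config.ec_effect_noise`` - so nearby environments in EC space have
    similar main effects, the assumption EC-guided training-set selection
    relies on.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    nE, q = config.n_envs, config.n_ecs
    rho = config.ec_correlation
    cov = np.full((q, q), rho) + (1 - rho) * np.eye(q)
    raw = rng.multivariate_normal(np.zeros(q), cov, size=nE)
    env_ids = [f"E{j:02d}" for j in range(nE)]
    cols = [f"EC{k:02d}" for k in range(q)]
    ec_raw = pd.DataFrame(raw, index=env_ids, columns=cols)
    sd = ec_raw.std(axis=0, ddof=1)
    W = ECMatrix(W=(ec_raw - ec_raw.mean(axis=0)) / sd)
    omega = build_omega(W)
    loadings = rng.normal(size=q) / np.sqrt(q)
    signal = W.W.to_numpy() @ loadings
    tau = config.ec_effect_noise
    if tau >= 1.0:
        # pure i.i.d. main effects, no EC linkage
        effects = rng.normal(size=nE)
    elif tau > 0:
        sig_sd = signal.std(ddof=1) if nE > 1 else 1.0
        noise = rng.normal(size=nE) * sig_sd * np.sqrt(tau / (1 - tau))
        effects = signal + noise
    else:
        effects = signal
    return SimulatedEnvironments(
        ec_raw=ec_raw,
        W=W,
        omega=omega,
        env_effects=pd.Series(effects, index=env_ids),
        ec_loadings=loadings,
    )


def simulate_daily_weather(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    season_days: int = 120,
    start: date = date(2019, 6, 1),
) -> tuple[pd.DataFrame, dict]:
    """Emit a daily weather table per environment plus phenology windows.

    Window means of the directly emitted covariates are exact by
    construction (within-window noise is recentred), so re-aggregating the
    series through the EC pipeline reproduces the drawn targets; the derived
    covariates (TR via TMIN/TMAX, VPD, PET) follow from the emitted series.
    Returns (daily table, {env: PhenologyWindows}).
    """
    from .weather import PhenologyWindows

    rng = rng or np.random.default_rng(config.seed + 2)
    env_ids = [f"E{j:02d}" for j in range(config.n_envs)]
    frames, windows = [], {}
    for env in env_ids:
        transplant = start + timedelta(days=int(rng.integers(0, 20)))
        ef = transplant + timedelta(days=int(rng.integers(50, 70)))
        lf = ef + timedelta(days=int(rng.integers(10, 30)))
        harvest = lf + timedelta(days=int(rng.integers(25, 40)))
        win = PhenologyWindows(env, transplant, ef, lf, harvest)
        windows[env] = win
        days = pd.date_range(transplant, harvest, freq="D")
        n = len(days)
        # per-phase target means for the base series
        tm_mean = rng.uniform(22, 30)
        tr_mean = rng.uniform(6, 12)
        dpt_mean = tm_mean - rng.uniform(3, 8)
        pp_mean = rng.uniform(0, 12)
        apar_mean = rng.uniform(80, 140)
        cpar_mean = apar_mean + rng.uniform(10, 40)

        def phase_series(target_by_phase, noise_sd, floor=None):
            vals = np.empty(n)
            phases = win.phase_of(pd.Series(days))
            for ph in PHASES:
                m = (phases == ph).to_numpy()
                x = rng.normal(0.0, noise_sd, int(m.sum()))
                x -= x.mean()  # exact window mean
                vals[m] = target_by_phase[ph] + x
            if floor is not None:
                vals = np.maximum(vals, floor)
            return vals

        def targets(mean, spread):
            return {ph: mean + rng.uniform(-spread, spread) for ph in PHASES}

        tm = phase_series(targets(tm_mean, 2.0), 0.8)
        tr = phase_series(targets(tr_mean, 2.0), 0.5, floor=2.0)
        dpt = phase_series(targets(dpt_mean, 1.5), 0.6)
        pp = phase_series(targets(pp_mean, 3.0), 1.0, floor=0.0)
        apar = phase_series(targets(apar_mean, 15.0), 5.0, floor=0.0)
        cpar = np.maximum(phase_series(targets(cpar_mean, 15.0), 5.0), apar)
        frames.append(
            pd.DataFrame(
                {
                    "environment": env,
                    "date": days,
                    "TMIN": tm - tr / 2,
                    "TMAX": tm + tr / 2,
                    "TM": tm,
                    "DPT": np.minimum(dpt, tm - tr / 2),
                    "RH": np.clip(rng.normal(75, 8, n), 0, 100),
                    "PP": pp,
                    "APAR": apar,
                    "CPAR": cpar,
                }
            )
        )
    return pd.concat(frames, ignore_index=True), windows


def make_sparse_mask(
    n_lines: int,
    n_envs: int,
    allocation_range: tuple[int, int],
    seed: int = 0,
    core_fraction: float = 0.3,
) -> pd.DataFrame:
    """Unbalanced line x environment allocation with a common core.

    Per-environment line counts are uniform on ``allocation_range``; a core
    of ``core_fraction`` of the lines is observed in every environment
    (emulating the common checks of a sparse-testing design).
    """
    rng = np.random.default_rng(seed)
    lo, hi = allocation_range
    if not 1 <= lo <= hi <= n_lines:
        raise ValueError("invalid allocation range")
    n_core = int(round(core_fraction * n_lines))
    if n_core > lo:
        raise ValueError(
            f"core size {n_core} exceeds the minimum allocation {lo}"
        )
    line_ids = [f"L{i:03d}" for i in range(n_lines)]
    env_ids = [f"E{j:02d}" for j in range(n_envs)]
    core = rng.choice(n_lines, size=n_core, replace=False)
    mask = np.zeros((n_lines, n_envs), dtype=bool)
    mask[core, :] = True
    others = np.setdiff1d(np.arange(n_lines), core)
    for j in range(n_envs):
        n_alloc = int(rng.integers(lo, hi + 1))
        extra = rng.choice(others, size=n_alloc - n_core, replace=False)
        mask[extra, j] = True
    return pd.DataFrame(mask, index=line_ids, columns=env_ids)


@dataclass
class SimulationTruth:
    """Generative-model ground truth for one phenotype draw."""

    mu: float
    marker_effects: np.ndarray
    genetic_values: pd.Series  # g_i per line
    env_effects: pd.Series  # e_j per environment (rescaled)
    w_effects: pd.Series  # w_j per environment (rescaled)
    ec_loadings: np.ndarray
    ge: pd.DataFrame  # line x environment
    gw: pd.DataFrame
    realized_variances: dict[str, float]


def _rescale(component: np.ndarray, mask: np.ndarray, target: float) -> np.ndarray:
    """Scale a component so its variance over observed cells equals target."""
    if target == 0:
        return np.zeros_like(component)
    obs = component[mask]
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate component: zero variance before rescaling")
    return component * np.sqrt(target) / sd


def simulate_phenotypes(
    genotypes: MarkerMatrix,
    environments: SimulatedEnvironments,
    config: SimulationConfig,
    mask: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    mu: float = 0.0,
) -> tuple[PhenoGrid, SimulationTruth]:
    """Draw phenotypes from the reaction-norm generative model.

    Components are rescaled so realised variances over observed cells equal
    the configured targets exactly, which pins the ground truth recovery
    tests compare against.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    v = config.variances
    if all(val == 0 for val in v.values()):
        raise ValueError("all variance targets are zero")
    X = impute_and_standardize(genotypes)
    nL = len(genotypes.line_ids)
    env_ids = environments.W.environment_ids
    nE = len(env_ids)
    if mask is None:
        mask_arr = np.ones((nL, nE), dtype=bool)
    else:
        mask_arr = mask.loc[genotypes.line_ids, env_ids].to_numpy()

    p = X.shape[1]
    Wm = environments.W.W.to_numpy()
    q = Wm.shape[1]

    beta = rng.normal(size=p) / np.sqrt(p)
    g_line = X @ beta
    g = np.tile(g_line[:, None], (1, nE))
    g = _rescale(g, mask_arr, v["g"]) if v["g"] > 0 else np.zeros_like(g)

    e_env = environments.env_effects.to_numpy()
    e = np.tile(e_env[None, :], (nL, 1))
    e = _rescale(e, mask_arr, v["e"]) if v["e"] > 0 else np.zeros_like(e)

    gamma = rng.normal(size=q) / np.sqrt(q)
    w_env = Wm @ gamma
    w = np.tile(w_env[None, :], (nL, 1))
    w = _rescale(w, mask_arr, v["w"]) if v["w"] > 0 else np.zeros_like(w)

    ge = rng.normal(size=(nL, nE))
    ge = _rescale(ge, mask_arr, v["ge"]) if v["ge"] > 0 else np.zeros_like(ge)

    A = rng.normal(size=(p, q))
    gw = X @ A @ Wm.T / np.sqrt(p * q)  # cell covariance G (x) Omega
    gw = _rescale(gw, mask_arr, v["gw"]) if v["gw"] > 0 else np.zeros_like(gw)

    eps = rng.normal(size=(nL, nE))
    eps = _rescale(eps, mask_arr, v["eps"]) if v["eps"] > 0 else np.zeros_like(eps)

    total = mu + g + e + w + ge + gw + eps
    values = pd.DataFrame(
        np.where(mask_arr, total, np.nan),
        index=genotypes.line_ids,
        columns=env_ids,
    )
    realized = {
        name: float(comp[mask_arr].var(ddof=1)) if v[name] > 0 else 0.0
        for name, comp in
        [("g", g), ("e", e), ("w", w), ("ge", ge), ("gw", gw), ("eps", eps)]
    }
    truth = SimulationTruth(
        mu=mu,
        marker_effects=beta,
        genetic_values=pd.Series(g[:, 0], index=genotypes.line_ids),
        env_effects=pd.Series(e[0, :], index=env_ids),
        w_effects=pd.Series(w[0, :], index=env_ids),
        ec_loadings=environments.ec_loadings,
        ge=pd.DataFrame(ge, index=genotypes.line_ids, columns=env_ids),
        gw=pd.DataFrame(gw, index=genotypes.line_ids, columns=env_ids),
        realized_variances=realized,
    )
    return PhenoGrid(values=values, trait="simulated"), truth


@dataclass
class SimulatedDataset:
    """Everything a full pipeline run needs, with ground truth attached."""

    config: SimulationConfig
    genotypes: MarkerMatrix
    environments: SimulatedEnvironments
    mask: pd.DataFrame
    pheno: PhenoGrid
    truth: SimulationTruth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a coherent genotype/EC/mask/phenotype bundle from one seed."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    environments = simulate_environments(config, rng)
    mask = make_sparse_mask(
        config.n_lines,
        config.n_envs,
        config.allocation_range,
        seed=config.seed + 17,
        core_fraction=config.core_fraction,
    )
    pheno, truth = simulate_phenotypes(genotypes, environments, config, mask, rng)
    return SimulatedDataset(
        config=config,
        genotypes=genotypes,
        environments=environments,
        mask=mask,
        pheno=pheno,
        truth=truth,
    )
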