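"""Environmental characterisation from daily weather.

Daily weather per environment (TMIN, TMAX, TM, DPT, RH, PP, APAR, CPAR) is
augmented with three derived variables:

* temperature range TR = TMAX - TMIN,
* vapour pressure deficit VPD = (es(TMIN) + es(TMAX))/2 - es(DPT), with the
  Tetens saturation curve es(T) = 0.61078 exp(17.27 T / (T + 237.3)) kPa,
* potential evapotranspiration PET by Hargreaves-Samani,
  0.0023 (TM + 17.8) sqrt(TR) Ra / lambda, with extraterrestrial radiation Ra
  from latitude and day of year (FAO-56) and lambda = 2.45 MJ kg^-1.

Eight covariates (PP, DPT, PET, VPD, TM, TR, APAR, CPAR) are then averaged
over the three phenology windows (vegetative, reproductive, ripening) giving
24 window-specific environmental covariates per environment.  Their
column-standardised matrix W defines the environmental kernel
Omega = W W' / q.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

__all__ = [
    "EC_COVARIATES",
    "PHASES",
    "PhenologyWindows",
    "ECMatrix",
    "OmegaKernel",
    "derive_daily_variables",
    "infer_phenology_windows",
    "aggregate_ecs",
    "standardize_ecs",
    "build_omega",
    "cluster_environments_ec",
    "select_training_envs",
    "ec_table_to_long",
    "ec_table_from_long",
]

logger = logging.getLogger(__name__)

#: the eight covariates carried into the prediction models
EC_COVARIATES = ("PP", "DPT", "PET", "VPD", "TM", "TR", "APAR", "CPAR")

#: phase codes: vegetative, reproductive, ripening, whole season
PHASES = ("VE", "RE", "RI")

LAMBDA_MJ_PER_KG = 2.45  # latent heat of vaporisation
SOLAR_CONSTANT = 0.0820  # MJ m^-2 min^-1


def tetens_es(temp_c):
    """Saturation vapour pressure (kPa) at temperature ``temp_c`` (Celsius)."""
    temp_c = np.asarray(temp_c, dtype=float)
    return 0.61078 * np.exp(17.27 * temp_c / (temp_c + 237.3))


def extraterrestrial_radiation(latitude_deg: float, day_of_year) -> np.ndarray:
    """Daily extraterrestrial radiation Ra (MJ m^-2 d^-1), FAO-56 eq. 21."""
    j = np.asarray(day_of_year, dtype=float)
    phi = np.deg2rad(latitude_deg)
    dr = 1 + 0.033 * np.cos(2 * np.pi * j / 365)
    delta = 0.409 * np.sin(2 * np.pi * j / 365 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1, 1))
    return (
        24 * 60 / np.pi
        * SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )


def derive_daily_variables(daily: pd.DataFrame, latitude: float) -> pd.DataFrame:
    """Add TR, VPD and PET columns to a daily weather table.

    ``daily`` needs columns ``date``, ``TMIN``, ``TMAX``, ``TM``, ``DPT``.
    VPD and PET are floored at zero.
    """
    if not -60 <= latitude <= 60:
        raise ValueError("latitude outside [-60, 60]")
    df = daily.copy()
    if (df["TMAX"] < df["TMIN"]).any():
        bad = df.loc[df["TMAX"] < df["TMIN"], "date"].tolist()
        raise ValueError(f"TMAX < TMIN on days: {bad}")
    df["TR"] = df["TMAX"] - df["TMIN"]
    es_mean = (tetens_es(df["TMIN"]) + tetens_es(df["TMAX"])) / 2.0
    df["VPD"] = np.maximum(es_mean - tetens_es(df["DPT"]), 0.0)
    doy = pd.to_datetime(df["date"]).dt.dayofyear
    ra = extraterrestrial_radiation(latitude, doy)
    pet = 0.0023 * (df["TM"] + 17.8) * np.sqrt(df["TR"]) * ra / LAMBDA_MJ_PER_KG
    df["PET"] = np.maximum(pet, 0.0)
    return df


@dataclass
class PhenologyWindows:
    """Growth-phase date intervals for one environment.

    Days are assigned: vegetative before the earliest flowering date,
    reproductive from earliest to latest flowering (inclusive), ripening
    after the latest flowering up to harvest.
    """

    environment_id: str
    transplant: date
    earliest_flowering: date
    latest_flowering: date
    harvest: date

    def phase_of(self, days: pd.Series) -> pd.Series:
        d = pd.to_datetime(days).dt.date
        phase = pd.Series("RI", index=days.index)
        phase[d < self.earliest_flowering] = "VE"
        phase[(d >= self.earliest_flowering) & (d <= self.latest_flowering)] = "RE"
        return phase

    def n_days(self) -> dict[str, int]:
        total = (self.harvest - self.transplant).days + 1
        ve = (self.earliest_flowering - self.transplant).days
        re = (self.latest_flowering - self.earliest_flowering).days + 1
        ri = total - ve - re
        return {"VE": ve, "RE": re, "RI": ri}


def infer_phenology_windows(
    environment_id: str,
    transplant_date: date,
    dtf_values,
    harvest_date: date,
    seeding_date: date,
) -> PhenologyWindows:
    """Derive phase windows from flowering dates.

    Days-to-flowering are counted from seeding; the reproductive phase spans
    the earliest to the latest flowering date across the panel.  Degenerate
    zero-length vegetative or ripening phases are widened to one day.
    """
    dtf = np.asarray(list(dtf_values), dtype=float)
    if dtf.size == 0:
        raise ValueError("no days-to-flowering values")
    earliest = seeding_date + timedelta(days=int(np.min(dtf)))
    latest = seeding_date + timedelta(days=int(np.max(dtf)))
    if not (transplant_date <= earliest <= latest <= harvest_date):
        raise ValueError(
            f"{environment_id}: ordering transplant <= earliest flowering <= "
            f"latest flowering <= harvest violated "
            f"({transplant_date}, {earliest}, {latest}, {harvest_date})"
        )
    if earliest == transplant_date:
        warnings.warn(
            f"{environment_id}: zero-length vegetative phase widened to 1 day",
            stacklevel=2,
        )
        earliest = earliest + timedelta(days=1)
        latest = max(latest, earliest)
    if latest == harvest_date:
        warnings.warn(
            f"{environment_id}: zero-length ripening phase widened to 1 day",
            stacklevel=2,
        )
        latest = latest - timedelta(days=1)
        earliest = min(earliest, latest)
    return PhenologyWindows(
        environment_id=environment_id,
        transplant=transplant_date,
        earliest_flowering=earliest,
        latest_flowering=latest,
        harvest=harvest_date,
    )


def aggregate_ecs(
    daily: pd.DataFrame,
    windows: dict[str, PhenologyWindows],
    covariates: tuple[str, ...] = EC_COVARIATES,
    whole_season: bool = False,
) -> pd.DataFrame:
    """Average daily covariates within each phenology window.

    ``daily`` has one row per environment-day with an ``environment`` column.
    Returns an environment x "COV_PHASE" table (24 columns for the default
    8 covariates x 3 phases); with ``whole_season`` a "COV_WS" column per
    covariate is added.
    """
    missing = set(covariates) - set(daily.columns)
    if missing:
        raise ValueError(f"daily table lacks covariates: {sorted(missing)}")
    rows = {}
    for env, sub in daily.groupby("environment"):
        if env not in windows:
            raise ValueError(f"no phenology windows for environment {env!r}")
        win = windows[env]
        d = pd.to_datetime(sub["date"]).dt.date
        in_season = (d >= win.transplant) & (d <= win.harvest)
        sub = sub[in_season]
        if sub.empty:
            raise ValueError(f"{env}: no daily records within the season window")
        phases = win.phase_of(sub["date"])
        row = {}
        for cov in covariates:
            for ph in PHASES:
                sel = sub.loc[phases.values == ph, cov]
                if sel.empty:
                    raise ValueError(f"{env}: empty {ph} window")
                row[f"{cov}_{ph}"] = float(sel.mean())
            if whole_season:
                row[f"{cov}_WS"] = float(sub[cov].mean())
        rows[env] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


@dataclass
class ECMatrix:
    """Environments x covariates standardised EC matrix (the W of Omega)."""

    W: pd.DataFrame  # index: environment ids; columns: covariate labels

    @property
    def environment_ids(self) -> list[str]:
        return list(self.W.index)

    @property
    def covariate_ids(self) -> list[str]:
        return list(self.W.columns)

    def subset(self, environments: list[str]) -> "ECMatrix":
        missing = set(environments) - set(self.W.index)
        if missing:
            raise ValueError(f"environments absent from EC matrix: {sorted(missing)}")
        return ECMatrix(W=self.W.loc[environments])


def standardize_ecs(raw: pd.DataFrame) -> ECMatrix:
    """Column z-scores (n-1 denominator) of a raw environment x EC table.

    Constant columns carry no between-environment information and are dropped
    with a logged warning.
    """
    if len(raw) < 3:
        raise ValueError("need at least 3 environments to standardise ECs")
    sd = raw.std(axis=0, ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        logger.warning("dropping constant EC columns: %s", constant)
    keep = raw.loc[:, sd > 0]
    W = (keep - keep.mean(axis=0)) / keep.std(axis=0, ddof=1)
    return ECMatrix(W=W)


@dataclass
class OmegaKernel:
    """Environmental relationship kernel Omega = WW'/q."""

    environment_ids: list[str]
    Omega: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Omega, index=self.environment_ids, columns=self.environment_ids
        )


def build_omega(W: ECMatrix) -> OmegaKernel:
    """Environmental kernel Omega = W W' / q over environments.

    Dividing by the number of covariate columns q keeps the diagonal near 1,
    on the same scale as the genomic relationship matrix.
    """
    q = len(W.covariate_ids)
    if q == 0:
        raise ValueError("EC matrix has no covariate columns")
    mat = W.W.to_numpy(dtype=float)
    omega = mat @ mat.T / q
    omega = (omega + omega.T) / 2
    return OmegaKernel(environment_ids=W.environment_ids, Omega=omega)


def ec_table_to_long(ecs: pd.DataFrame) -> pd.DataFrame:
    """Wide environment x "COV_PHASE" table to long (environment, covariate,
    phase, value) records."""
    long = (
        ecs.rename_axis("environment")
        .reset_index()
        .melt(id_vars="environment", var_name="label", value_name="value")
    )
    parts = long["label"].str.rsplit("_", n=1, expand=True)
    long["covariate"], long["phase"] = parts[0], parts[1]
    return long[["environment", "covariate", "phase", "value"]]


def ec_table_from_long(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`ec_table_to_long`."""
    df = long.copy()
    df["label"] = df["covariate"] + "_" + df["phase"]
    wide = df.pivot(index="environment", columns="label", values="value")
    wide.index.name = None
    wide.columns.name = None
    return wide.sort_index()


def _phase_columns(W: ECMatrix, phase: str) -> pd.DataFrame:
    if phase == "all":
        return W.W
    valid = {"WS": "whole season", "VE": "vegetative", "RE": "reproductive",
             "RI": "ripening"}
    if phase not in valid:
        raise ValueError(f"unknown phase {phase!r}; use one of {list(valid)} or 'all'")
    cols = [c for c in W.W.columns if c.endswith(f"_{phase}")]
    if not cols:
        raise ValueError(f"no EC columns for phase {phase!r}")
    return W.W[cols]


def cluster_environments_ec(W: ECMatrix, phase: str = "all"):
    """Average-linkage clustering of environments on Euclidean EC distance.

    ``phase`` selects the column block ("WS", "VE", "RE", "RI" or "all").
    Returns (scipy linkage matrix, leaf labels).
    """
    block = _phase_columns(W, phase)
    Z = linkage(pdist(block.to_numpy(dtype=float)), method="average")
    return Z, list(block.index)


def select_training_envs(
    target_env: str, W: ECMatrix, k: int = 4, phase: str = "all"
) -> list[str]:
    """The k environments nearest the target in (standardised) EC space.

    Euclidean distance, ascending; exact ties broken lexicographically.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if target_env not in W.W.index:
        raise ValueError(f"target environment {target_env!r} not in EC matrix")
    block = _phase_columns(W, phase)
    others = [e for e in block.index if e != target_env]
    if k > len(others):
        raise ValueError(f"k={k} exceeds the {len(others)} candidate environments")
    t = block.loc[target_env].to_numpy(dtype=float)
    dists = {
        e: float(np.linalg.norm(block.loc[e].to_numpy(dtype=float) - t))
        for e in others
    }
    ranked = sorted(others, key=lambda e: (dists[e], e))
    return ranked[:k]
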