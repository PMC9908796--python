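"""Observation grid and random-effect kernels for the multi-environment models.

Cells are ordered environment-major: cell index c = j * n_lines + i for line
i in environment j.  With that ordering the kernels over the full grid are
Kronecker products:

* K_g  = J_E (x) G          (genotype main effect, J_E all-ones)
* K_e  = I_E (x) J_L        (environment main effect)
* K_w  = Omega (x) J_L      (environmental-covariate effect)
* K_ge = K_g o K_e = I_E (x) G       (genotype x environment)
* K_gw = K_g o K_w = Omega (x) G     (genotype x covariate)

where o is the Hadamard (elementwise) product; each is symmetric PSD by the
Schur product theorem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenomicRelationship
from .trials import PhenoGrid
from .weather import OmegaKernel

__all__ = [
    "MODEL_TERMS",
    "MODEL_NAMES",
    "ObservationGrid",
    "build_kernels",
    "mme_predict",
]

#: model names exactly as used in the field, mapped to their random terms
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "G": ("g",),
    "GE": ("g", "e"),
    "GW": ("g", "w"),
    "GEW": ("g", "e", "w"),
    "GE-GxE": ("g", "e", "ge"),
    "GW-GxW": ("g", "w", "gw"),
    "GEW-GxE-GxW": ("g", "e", "w", "ge", "gw"),
}

MODEL_NAMES = tuple(MODEL_TERMS)


@dataclass
class ObservationGrid:
    """Full line x environment cell grid with an observed mask.

    ``cells`` is implicit: environment-major order over (line_ids,
    environment_ids).  ``y`` holds phenotypes at observed cells and NaN at
    masked (prediction) cells.
    """

    line_ids: list[str]
    environment_ids: list[str]
    y: np.ndarray  # length n_lines * n_envs, NaN where unobserved

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.n_cells,):
            raise ValueError("y length does not match the cell grid")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_envs(self) -> int:
        return len(self.environment_ids)

    @property
    def n_cells(self) -> int:
        return self.n_lines * self.n_envs

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.y)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def cell_index(self, line: str, env: str) -> int:
        return self.environment_ids.index(env) * self.n_lines + self.line_ids.index(line)

    def env_slice(self, env: str) -> slice:
        j = self.environment_ids.index(env)
        return slice(j * self.n_lines, (j + 1) * self.n_lines)

    def cells_frame(self) -> pd.DataFrame:
        """(line, environment, y, observed) in cell order."""
        lines = np.tile(self.line_ids, self.n_envs)
        envs = np.repeat(self.environment_ids, self.n_lines)
        return pd.DataFrame(
            {"line": lines, "environment": envs, "y": self.y,
             "observed": self.observed}
        )

    @classmethod
    def from_pheno_grid(cls, pheno: PhenoGrid) -> "ObservationGrid":
        vals = pheno.values.to_numpy(dtype=float)
        return cls(
            line_ids=pheno.line_ids,
            environment_ids=pheno.environment_ids,
            y=vals.T.reshape(-1),  # environment-major
        )


def _check_psd(K: np.ndarray, name: str, tol: float = 1e-8) -> None:
    evals = np.linalg.eigvalsh((K + K.T) / 2)
    if evals.min() < -tol * max(1.0, evals.max()):
        raise ValueError(f"kernel {name} is not PSD (min eigenvalue {evals.min():.3g})")


def build_kernels(
    grid: ObservationGrid,
    G: GenomicRelationship | np.ndarray | None,
    omega: OmegaKernel | np.ndarray | None = None,
    terms: tuple[str, ...] | str = "G",
    check_psd: bool = True,
) -> dict[str, np.ndarray]:
    """Build the cell-level kernels needed by a model's random terms.

    ``terms`` may be a model name ("GE-GxE") or an explicit tuple of terms.
    G must cover every line of the grid (in order); Omega every environment,
    and is only required when "w" or "gw" terms are present.
    """
    if isinstance(terms, str):
        if terms not in MODEL_TERMS:
            raise ValueError(
                f"unknown model {terms!r}; expected one of {MODEL_NAMES}"
            )
        terms = MODEL_TERMS[terms]
    nL, nE = grid.n_lines, grid.n_envs

    G_mat = None
    if any(t in terms for t in ("g", "ge", "gw")):
        if G is None:
            raise ValueError("G matrix required for g/ge/gw terms")
        if isinstance(G, GenomicRelationship):
            missing = set(grid.line_ids) - set(G.line_ids)
            if missing:
                raise ValueError(f"lines absent from G: {sorted(missing)}")
            G_mat = G.to_frame().loc[grid.line_ids, grid.line_ids].to_numpy()
        else:
            G_mat = np.asarray(G, dtype=float)
            if G_mat.shape != (nL, nL):
                raise ValueError("G shape does not match the grid's lines")

    O_mat = None
    if any(t in terms for t in ("w", "gw")):
        if omega is None:
            raise ValueError("Omega required for w/gw terms")
        if isinstance(omega, OmegaKernel):
            missing = set(grid.environment_ids) - set(omega.environment_ids)
            if missing:
                raise ValueError(f"environments absent from Omega: {sorted(missing)}")
            O_mat = (
                omega.to_frame()
                .loc[grid.environment_ids, grid.environment_ids]
                .to_numpy()
            )
        else:
            O_mat = np.asarray(omega, dtype=float)
            if O_mat.shape != (nE, nE):
                raise ValueError("Omega shape does not match the grid's environments")

    JE = np.ones((nE, nE))
    JL = np.ones((nL, nL))
    IE = np.eye(nE)
    builders = {
        "g": lambda: np.kron(JE, G_mat),
        "e": lambda: np.kron(IE, JL),
        "w": lambda: np.kron(O_mat, JL),
        "ge": lambda: np.kron(IE, G_mat),
        "gw": lambda: np.kron(O_mat, G_mat),
    }
    kernels = {}
    for t in terms:
        if t not in builders:
            raise ValueError(f"unknown random term {t!r}")
        K = builders[t]()
        if check_psd:
            _check_psd(K, t)
        kernels[t] = K
    return kernels


def mme_predict(
    grid: ObservationGrid,
    kernels: dict[str, np.ndarray],
    variances: dict[str, float],
    sigma2_eps: float,
) -> tuple[np.ndarray, dict[str, np.ndarray], float]:
    """Closed-form BLUP of every cell given known variance components.

    Solves the mixed-model (GLS) equations directly: with
    C = sum_k sigma2_k K_k and V = C[obs, obs] + sigma2_eps I,
    mu_hat = (1' V^-1 y) / (1' V^-1 1) and the conditional mean of each
    random term at all cells is sigma2_k K_k[:, obs] V^-1 (y - mu_hat).

    Returns (predictions over all cells, per-term contributions, mu_hat).
    This is the deterministic oracle the Gibbs sampler is checked against,
    and makes kernel-structure arguments (e.g. a fully unobserved
    environment receives exactly zero genotype-x-environment contribution)
    directly inspectable.
    """
    obs = grid.observed
    y = grid.y[obs]
    C_obs = sum(variances[k] * kernels[k][np.ix_(obs, obs)] for k in kernels)
    V = C_obs + sigma2_eps * np.eye(obs.sum())
    Vinv_y = np.linalg.solve(V, y)
    ones = np.ones(obs.sum())
    Vinv_1 = np.linalg.solve(V, ones)
    mu = float(ones @ Vinv_y / (ones @ Vinv_1))
    resid = np.linalg.solve(V, y - mu)
    contributions = {
        k: variances[k] * kernels[k][:, obs] @ resid for k in kernels
    }
    pred = mu + sum(contributions.values())
    return pred, contributions, mu
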