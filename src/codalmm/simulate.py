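"""Synthetic multilevel compositional data with the model's exact structure.

The generator draws, per subject, a random-intercept vector b0i ~ MVN(0, G)
and, per occasion, a residual vector eps_ij ~ MVN(0, E); the olr coordinate
vector is X beta + b0i + eps_ij and behaviours are its inverse olr closed to
kappa.  Default parameters emulate the Life on Holidays cohort the method
was demonstrated on: 241 children measured on 5 occasions across two school
years, a 4-part composition (sleep, SB, LPA, MVPA; kappa = 1440 min/day),
fixed effects, G and E set to the published model estimates.  Covariate
distributions (zBMI standard normal; income middle/high/low with
probabilities 0.5/0.3/0.2) are this package's own choice, as no empirical
distributions are published.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import OCCASION_COL, SUBJECT_COL
from .simplex import OlrBasis, SbpSignMatrix, basis_from_sbp

__all__ = ["SimulationParams", "simulate", "make_fixture", "loh_basis", "loh_params"]

PART_LABELS = ("sleep", "SB", "LPA", "MVPA")


def loh_basis() -> OlrBasis:
    """The worked example's balance basis: z1 sleep vs waking behaviours,
    z2 SB vs active behaviours, z3 LPA vs MVPA."""
    S = SbpSignMatrix(
        np.array([[1, -1, -1, -1], [0, 1, -1, -1], [0, 0, 1, -1]]), PART_LABELS
    )
    return basis_from_sbp(S)


def alt_basis() -> OlrBasis:
    """A different SBP over the same parts, for basis-invariance checks:
    z1 passive (sleep+SB) vs active (LPA+MVPA), z2 sleep vs SB,
    z3 LPA vs MVPA."""
    S = SbpSignMatrix(
        np.array([[1, 1, -1, -1], [1, -1, 0, 0], [0, 0, 1, -1]]), PART_LABELS
    )
    return basis_from_sbp(S)


# Published fixed effects of the worked example, by (term, coordinate).
LOH_BETA = {
    "Intercept": (0.83, 0.94, 0.93),
    "T2": (0.01, 0.01, -0.01),
    "T3": (0.09, 0.22, 0.21),
    "T4": (0.03, 0.09, 0.01),
    "T5": (0.04, 0.12, 0.05),
    "zBMI": (0.01, 0.003, 0.05),
    "income_high": (-0.001, 0.01, -0.07),
    "income_low": (0.03, 0.10, 0.03),
}


def _cov_from_sd_corr(sd, corr_pairs):
    sd = np.asarray(sd, dtype=float)
    R = sd.size
    C = np.eye(R)
    for (i, j), rho in corr_pairs.items():
        C[i, j] = C[j, i] = rho
    return C * np.outer(sd, sd)


# Published covariance estimates: G sds 0.11/0.29/0.22 with correlations
# rho12=0.75, rho13=0.64, rho23=0.49; E sds 0.12/0.24/0.26 with correlations
# rho12=0.68, rho13=0.64, rho23=0.64.
LOH_G = _cov_from_sd_corr([0.11, 0.29, 0.22], {(0, 1): 0.75, (0, 2): 0.64, (1, 2): 0.49})
LOH_E = _cov_from_sd_corr([0.12, 0.24, 0.26], {(0, 1): 0.68, (0, 2): 0.64, (1, 2): 0.64})


@dataclass
class SimulationParams:
    """Everything needed to draw one longitudinal compositional dataset."""

    basis: OlrBasis
    beta: dict[str, tuple[float, ...]]
    G: np.ndarray
    E: np.ndarray
    n_subjects: int = 241
    occasions: tuple[str, ...] = ("T1", "T2", "T3", "T4", "T5")
    income_probs: dict[str, float] = field(
        default_factory=lambda: {"middle": 0.5, "high": 0.3, "low": 0.2}
    )
    with_covariates: bool = True
    missingness: float = 0.0
    kappa: float = 1440.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        R = self.basis.D - 1
        for name, M in (("G", self.G), ("E", self.E)):
            if M.shape != (R, R):
                raise ValueError(f"{name} must be {R}x{R}")
            if np.linalg.eigvalsh(M).min() < 0:
                raise ValueError(f"{name} must be positive semi-definite")
        if abs(sum(self.income_probs.values()) - 1.0) > 1e-12:
            raise ValueError("income probabilities must sum to 1")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")


def loh_params(**overrides) -> SimulationParams:
    """Study-condition defaults: 241 subjects x 5 occasions, published
    beta/G/E truth, 4-part composition closed to 1440 min/day."""
    kw = dict(basis=loh_basis(), beta=dict(LOH_BETA), G=LOH_G.copy(), E=LOH_E.copy())
    kw.update(overrides)
    return SimulationParams(**kw)


@dataclass
class SimulationTruth:
    params: SimulationParams
    random_intercepts: pd.DataFrame   # subject x coordinate
    linear_predictor: np.ndarray      # (n_rows, R) fixed-effect part


def simulate(params: SimulationParams) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw a long-format dataset; returns (table, hidden truth record)."""
    rng = np.random.default_rng(params.seed)
    R = params.basis.D - 1
    n = params.n_subjects
    occs = list(params.occasions)
    subjects = [f"s{i + 1:04d}" for i in range(n)]

    if params.with_covariates:
        zbmi = rng.standard_normal(n)
        cats = list(params.income_probs)
        income = rng.choice(cats, size=n, p=[params.income_probs[c] for c in cats])
    b0 = rng.multivariate_normal(np.zeros(R), params.G, size=n, method="cholesky")

    rows = []
    eta_rows = []
    for i, s in enumerate(subjects):
        for j, occ in enumerate(occs):
            eta = np.asarray(params.beta["Intercept"], dtype=float).copy()
            if occ != occs[0] and occ in params.beta:
                eta = eta + np.asarray(params.beta[occ])
            if params.with_covariates:
                eta = eta + zbmi[i] * np.asarray(params.beta.get("zBMI", np.zeros(R)))
                key = f"income_{income[i]}"
                if key in params.beta:
                    eta = eta + np.asarray(params.beta[key])
            eps = rng.multivariate_normal(np.zeros(R), params.E, method="cholesky")
            z = eta + b0[i] + eps
            w = np.exp(params.basis.contrast @ z)
            beh = params.kappa * w / w.sum()
            row = {SUBJECT_COL: s, OCCASION_COL: occ}
            row.update(dict(zip(params.basis.part_labels, beh)))
            if params.with_covariates:
                row["zBMI"] = zbmi[i]
                row["income"] = income[i]
            rows.append(row)
            eta_rows.append(eta)
    table = pd.DataFrame(rows)
    if params.missingness > 0:
        # MCAR dropout per occasion, but never a subject's first occasion,
        # so every subject stays in the sample
        drop = rng.random(len(table)) < params.missingness
        drop &= (table[OCCASION_COL] != occs[0]).to_numpy()
        table = table[~drop].reset_index(drop=True)
        eta_rows = [e for e, d in zip(eta_rows, drop) if not d]
    truth = SimulationTruth(
        params=params,
        random_intercepts=pd.DataFrame(
            b0, index=subjects, columns=params.basis.coordinate_names
        ),
        linear_predictor=np.asarray(eta_rows),
    )
    return table, truth


def make_fixture(name: str, seed: int = 0) -> pd.DataFrame:
    """Canned seeded scenarios used across the test-suite and examples.

    tiny            6 subjects x 3 occasions, no covariates (oracle checks)
    loh_like        full study conditions (241 x 5, published truth)
    null_effects    all time effects zero (type-I error studies)
    diagonal_truth  G and E diagonal (likelihood-ratio calibration)
    """
    if name == "tiny":
        p = loh_params(
            n_subjects=6, occasions=("T1", "T2", "T3"), with_covariates=False,
            seed=seed,
        )
    elif name == "loh_like":
        p = loh_params(seed=seed)
    elif name == "null_effects":
        beta = dict(LOH_BETA)
        for t in ("T2", "T3", "T4", "T5"):
            beta[t] = (0.0, 0.0, 0.0)
        p = loh_params(beta=beta, seed=seed)
    elif name == "diagonal_truth":
        p = loh_params(G=np.diag(np.diag(LOH_G)), E=np.diag(np.diag(LOH_E)), seed=seed)
    else:
        raise ValueError(f"unknown fixture {name!r}")
    table, _ = simulate(p)
    return table
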