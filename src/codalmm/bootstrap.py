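"""Non-parametric cases bootstrap at the subject level.

Whole subjects (level-2 units) are resampled with replacement — all of a
subject's occasions travel together, preserving the within-subject
dependence — the model is refit on each replicate, and any scalar or vector
functional of the fit is recorded.  Intervals are empirical percentile
intervals; per-part intervals for a predicted composition are marginal, not
joint, and their endpoints need not themselves form a composition.

Determinism: the master seed spawns one independent substream per replicate
(`numpy.random.SeedSequence.spawn`), so results do not depend on execution
order or on how replicates are distributed over workers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .data import SUBJECT_COL, compute_olr, stack
from .fit import FitResult, fit_cmrlmm
from .model import ModelSpec

logger = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "cases_bootstrap", "percentile_interval"]


@dataclass
class BootstrapResult:
    replicates: np.ndarray      # (B_converged, k)
    level: float
    B: int
    seed: int
    n_failed: int
    labels: list[str]

    @property
    def unreliable(self) -> bool:
        return self.n_failed > 0.05 * self.B

    def interval(self, level: float | None = None) -> pd.DataFrame:
        lo, hi = percentile_interval(self.replicates, level or self.level)
        return pd.DataFrame({"label": self.labels, "lower": lo, "upper": hi})


def percentile_interval(
    replicates: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical percentile interval per column (type-7/linear quantiles)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be strictly between 0 and 1")
    reps = np.atleast_2d(np.asarray(replicates, dtype=float))
    if reps.shape[0] < 2:
        raise ValueError("need at least two converged replicates")
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(reps, alpha, axis=0, method="linear")
    hi = np.quantile(reps, 1.0 - alpha, axis=0, method="linear")
    return lo, hi


def cases_bootstrap(
    long_table: pd.DataFrame,
    spec: ModelSpec,
    quantity: Callable[[FitResult], np.ndarray],
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    labels: list[str] | None = None,
    kappa: float = 1440.0,
) -> BootstrapResult:
    """Subject-level cases bootstrap of any functional of the fit.

    ``quantity`` maps a FitResult to a scalar or 1-d vector (e.g. the parts
    of a predicted composition).  Resampled subjects receive fresh
    identifiers so that a subject drawn twice counts as two independent
    grouping units.  Replicates that fail to converge (or on which
    ``quantity`` raises) are dropped and counted; more than 5% failures
    flags the result as unreliable.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be strictly between 0 and 1")
    if B < 2:
        raise ValueError("need at least 2 replicates")
    subjects = long_table[SUBJECT_COL].unique()
    by_subject = {s: df for s, df in long_table.groupby(SUBJECT_COL, sort=False)}
    streams = np.random.SeedSequence(seed).spawn(B)
    rows = []
    n_failed = 0
    for b, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        draw = rng.choice(subjects, size=len(subjects), replace=True)
        pieces = []
        for k, s in enumerate(draw):
            piece = by_subject[s].copy()
            piece[SUBJECT_COL] = f"bs{k:05d}"
            pieces.append(piece)
        resampled = pd.concat(pieces, ignore_index=True)
        try:
            stacked = stack(compute_olr(resampled, spec.basis))
            fit = fit_cmrlmm(stacked, spec, kappa=kappa)
            if not fit.converged:
                raise RuntimeError("replicate fit did not converge")
            rows.append(np.atleast_1d(np.asarray(quantity(fit), dtype=float)))
        except Exception as exc:  # noqa: BLE001 - replicate failures are data
            n_failed += 1
            logger.warning("bootstrap replicate %d dropped: %s", b, exc)
    if not rows:
        raise RuntimeError("all bootstrap replicates failed")
    reps = np.vstack(rows)
    if labels is None:
        labels = [f"q{k + 1}" for k in range(reps.shape[1])]
    result = BootstrapResult(
        replicates=reps, level=level, B=B, seed=seed,
        n_failed=n_failed, labels=list(labels),
    )
    if result.unreliable:
        logger.warning(
            "%d of %d bootstrap replicates failed; intervals unreliable",
            n_failed, B,
        )
    return result
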