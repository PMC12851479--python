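"""Aitchison-geometry primitives and orthonormal log-ratio (olr) bases.

A D-part composition lives on the simplex: only the ratios between its
parts carry information, and any strictly positive vector can be *closed*
(rescaled) to an arbitrary constant ``kappa`` — 1440 min/day, 24 h/day or 1 —
without changing its compositional content.  The two simplex operations,
perturbation (the analogue of addition) and powering (the analogue of scalar
multiplication), together with the olr transformation, turn the simplex into
a (D-1)-dimensional Euclidean space in which ordinary multivariate statistics
apply.

Orthonormal bases are built either from a sequential binary partition (SBP)
sign matrix — each coordinate a "balance" between two groups of parts — or as
pivot coordinates that contrast one part against the geometric mean of the
rest.  All bases of the same parts are related by an orthogonal rotation, so
any statistic that uses the full coordinate vector is basis-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Composition",
    "SbpSignMatrix",
    "OlrBasis",
    "close",
    "perturb",
    "power",
    "inverse",
    "neutral",
    "basis_from_sbp",
    "pivot_basis",
    "olr",
    "olr_inv",
    "clr",
    "change_of_basis",
]

_ORTHO_TOL = 1e-10


class ZeroPartError(ValueError):
    """A compositional part is zero or negative.

    Log-ratio methods are undefined at zero; if your data contain structural
    or rounded zeros, apply a zero-replacement method (e.g. multiplicative or
    model-based imputation from the compositional literature) before analysis.
    """


@dataclass(frozen=True)
class Composition:
    """A strictly positive D-part composition closed to ``kappa``.

    Parts are stored internally closed to 1; ``kappa`` is metadata applied
    when the parts are materialised, which is legitimate because the olr
    transformation is scale invariant.
    """

    parts: np.ndarray  # closed to 1 internally
    labels: tuple[str, ...]
    kappa: float = 1.0

    def __post_init__(self) -> None:
        p = np.asarray(self.parts, dtype=float)
        _check_positive(p, self.labels)
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        object.__setattr__(self, "parts", p / p.sum())
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def D(self) -> int:
        return self.parts.size

    @property
    def values(self) -> np.ndarray:
        """Parts on the ``kappa`` scale (they sum to ``kappa``)."""
        return self.parts * self.kappa

    def with_kappa(self, kappa: float) -> "Composition":
        return Composition(self.parts, self.labels, kappa)

    def __eq__(self, other: object) -> bool:  # compositional equality
        if not isinstance(other, Composition):
            return NotImplemented
        return self.labels == other.labels and np.allclose(
            self.parts, other.parts, rtol=1e-12, atol=0
        )

    def isclose(self, other: "Composition", rtol: float = 1e-9) -> bool:
        return self.labels == other.labels and bool(
            np.allclose(self.parts, other.parts, rtol=rtol)
        )

    def __repr__(self) -> str:
        vals = ", ".join(f"{l}={v:.4g}" for l, v in zip(self.labels, self.values))
        return f"Composition({vals}; kappa={self.kappa:g})"


def _check_positive(parts: np.ndarray, labels: Sequence[str]) -> None:
    if not np.all(np.isfinite(parts)):
        raise ValueError("compositional parts must be finite")
    bad = np.flatnonzero(parts <= 0)
    if bad.size:
        names = ", ".join(str(labels[i]) for i in bad) if len(labels) else str(bad)
        raise ZeroPartError(
            f"part(s) {names} are <= 0; log-ratio analysis requires strictly "
            "positive parts (consider a zero-replacement method)"
        )


def close(raw: Sequence[float], kappa: float, labels: Sequence[str] | None = None) -> Composition:
    """Closure: rescale a positive vector so its parts sum to ``kappa``."""
    raw = np.asarray(raw, dtype=float)
    if labels is None:
        labels = tuple(f"x{i + 1}" for i in range(raw.size))
    return Composition(raw, tuple(labels), kappa)


def _require_same_parts(x: Composition, y: Composition) -> None:
    if x.labels != y.labels:
        raise ValueError(f"part labels differ: {x.labels} vs {y.labels}")


def perturb(x: Composition, y: Composition) -> Composition:
    """Simplex addition: componentwise product, closed to ``x.kappa``."""
    _require_same_parts(x, y)
    return Composition(x.parts * y.parts, x.labels, x.kappa)


def power(alpha: float, x: Composition) -> Composition:
    """Simplex scalar multiplication: componentwise power, closed to ``x.kappa``."""
    if not np.isfinite(alpha):
        raise ValueError("powering constant must be finite")
    return Composition(x.parts ** float(alpha), x.labels, x.kappa)


def inverse(x: Composition) -> Composition:
    """Perturbation inverse: componentwise reciprocal."""
    return Composition(1.0 / x.parts, x.labels, x.kappa)


def neutral(D: int, kappa: float = 1.0, labels: Sequence[str] | None = None) -> Composition:
    """The equal-parts composition [kappa/D, ..., kappa/D], identity of ⊕."""
    if labels is None:
        labels = tuple(f"x{i + 1}" for i in range(D))
    return Composition(np.full(D, 1.0 / D), tuple(labels), kappa)


# ---------------------------------------------------------------------------
# Bases


@dataclass(frozen=True)
class SbpSignMatrix:
    """A sequential binary partition encoded as a (D-1) x D sign matrix.

    Row 1 splits all D parts into a +1 (numerator) and a -1 (denominator)
    group; every later row splits one same-signed block of an earlier row,
    until all blocks are singletons.
    """

    entries: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        S = np.asarray(self.entries, dtype=int)
        object.__setattr__(self, "entries", S)
        object.__setattr__(self, "labels", tuple(self.labels))
        D = len(self.labels)
        if S.shape != (D - 1, D):
            raise ValueError(f"sign matrix must be {(D - 1, D)}, got {S.shape}")
        if not np.isin(S, (-1, 0, 1)).all():
            raise ValueError("sign matrix entries must be in {-1, 0, +1}")
        self._validate_partition(S)

    @staticmethod
    def _validate_partition(S: np.ndarray) -> None:
        D = S.shape[1]
        for j, row in enumerate(S):
            if (row == 1).sum() < 1 or (row == -1).sum() < 1:
                raise ValueError(
                    f"SBP row {j + 1} must have at least one +1 and one -1 part"
                )
        # Row 1 must use every part; each later row's support must equal one
        # same-signed block produced by an earlier row.
        if (S[0] == 0).any():
            raise ValueError("SBP row 1 must assign every part to +1 or -1")
        open_blocks = [frozenset(np.flatnonzero(S[0] == 1)),
                       frozenset(np.flatnonzero(S[0] == -1))]
        for j in range(1, D - 1):
            support = frozenset(np.flatnonzero(S[j] != 0))
            if support not in open_blocks:
                raise ValueError(
                    f"SBP row {j + 1} does not split a block of an earlier row"
                )
            open_blocks.remove(support)
            open_blocks.append(frozenset(np.flatnonzero(S[j] == 1)))
            open_blocks.append(frozenset(np.flatnonzero(S[j] == -1)))
        leftovers = [b for b in open_blocks if len(b) > 1]
        if leftovers:
            raise ValueError("SBP does not reduce all blocks to single parts")


@dataclass(frozen=True)
class OlrBasis:
    """An orthonormal log-ratio basis: D x (D-1) contrast matrix plus labels.

    Column j holds the log-contrast coefficients of coordinate z_j, so
    z = contrast.T @ ln(x) and x = close(exp(contrast @ z), kappa).
    """

    contrast: np.ndarray
    part_labels: tuple[str, ...]
    provenance: str = "custom"
    coordinate_names: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        V = np.asarray(self.contrast, dtype=float)
        object.__setattr__(self, "contrast", V)
        object.__setattr__(self, "part_labels", tuple(self.part_labels))
        D = len(self.part_labels)
        if V.shape != (D, D - 1):
            raise ValueError(f"contrast matrix must be {(D, D - 1)}, got {V.shape}")
        if not np.allclose(V.T @ V, np.eye(D - 1), atol=_ORTHO_TOL):
            raise ValueError("contrast columns are not orthonormal")
        if not np.allclose(V.sum(axis=0), 0.0, atol=_ORTHO_TOL):
            raise ValueError("contrast columns must each sum to zero")
        if self.coordinate_names is None:
            object.__setattr__(
                self, "coordinate_names", tuple(f"z{j + 1}" for j in range(D - 1))
            )
        else:
            object.__setattr__(self, "coordinate_names", tuple(self.coordinate_names))

    @property
    def D(self) -> int:
        return len(self.part_labels)


def basis_from_sbp(sbp: SbpSignMatrix) -> OlrBasis:
    """Balance basis of an SBP: coordinate j contrasts the geometric means of
    the +1 and -1 groups of row j, with the normalising constants that make
    the contrast matrix orthonormal."""
    S = sbp.entries
    D = S.shape[1]
    V = np.zeros((D, D - 1))
    for j, row in enumerate(S):
        p = int((row == 1).sum())
        n = int((row == -1).sum())
        V[row == 1, j] = np.sqrt(n / (p * (p + n)))
        V[row == -1, j] = -np.sqrt(p / (n * (p + n)))
    return OlrBasis(V, sbp.labels, provenance="sbp")


def pivot_basis(labels: Sequence[str], order: Sequence[str] | None = None) -> OlrBasis:
    """Pivot coordinates: z_j contrasts part j against the geometric mean of
    parts j+1..D, in the given ``order`` (defaults to label order).  The first
    coordinate is sqrt(D/(D-1)) times the first clr coordinate."""
    labels = tuple(labels)
    D = len(labels)
    if D < 2:
        raise ValueError("need at least two parts")
    if order is None:
        order = labels
    order = tuple(order)
    if sorted(order) != sorted(labels):
        raise ValueError("order must be a permutation of the part labels")
    rows = []
    for j in range(D - 1):
        row = np.zeros(D, dtype=int)
        row[labels.index(order[j])] = 1
        for k in range(j + 1, D):
            row[labels.index(order[k])] = -1
        rows.append(row)
    basis = basis_from_sbp(SbpSignMatrix(np.array(rows), labels))
    return OlrBasis(basis.contrast, labels, provenance="pivot")


def sbp_from_rows(rows: Sequence[Sequence[int]], labels: Sequence[str]) -> SbpSignMatrix:
    """Build and validate a sign matrix from config-style nested lists."""
    return SbpSignMatrix(np.asarray(rows, dtype=int), tuple(labels))


# ---------------------------------------------------------------------------
# Transformations


def olr(x: Composition, basis: OlrBasis) -> np.ndarray:
    """Orthonormal log-ratio coordinates z = V.T ln(x); scale invariant."""
    if x.labels != basis.part_labels:
        raise ValueError("composition and basis refer to different parts")
    return basis.contrast.T @ np.log(x.parts)


def olr_inv(z: Sequence[float], basis: OlrBasis, kappa: float = 1.0) -> Composition:
    """Inverse olr: close(exp(V z), kappa)."""
    z = np.asarray(z, dtype=float)
    if z.shape != (basis.D - 1,):
        raise ValueError(f"coordinate vector must have length {basis.D - 1}")
    if not np.all(np.isfinite(z)):
        raise ValueError("olr coordinates must be finite")
    return Composition(np.exp(basis.contrast @ z), basis.part_labels, kappa)


def olr_matrix(X: np.ndarray, basis: OlrBasis) -> np.ndarray:
    """Row-wise olr of an (n, D) array of positive parts (scale per row free)."""
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ZeroPartError("all parts must be strictly positive")
    return np.log(X) @ basis.contrast


def clr(x: Composition) -> np.ndarray:
    """Centred log-ratio: ln(parts / geometric mean); sums to zero."""
    lg = np.log(x.parts)
    return lg - lg.mean()


def change_of_basis(z: Sequence[float], from_basis: OlrBasis, to_basis: OlrBasis) -> np.ndarray:
    """Rotate coordinates between two olr bases of the same parts."""
    if from_basis.part_labels != to_basis.part_labels:
        raise ValueError("bases refer to different parts")
    z = np.asarray(z, dtype=float)
    return to_basis.contrast.T @ (from_basis.contrast @ z)
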