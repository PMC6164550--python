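"""Aitchison geometry on the open simplex.

Relative abundances are compositions: equivalence classes of positive
vectors under multiplication by a positive scalar, represented canonically
by their closed (unit-sum) member.  With perturbation (componentwise
product + closure) as addition and powering (componentwise power + closure)
as scalar multiplication the simplex is a real vector space, and the
isometric logratio (ilr) transform is a linear isometry onto
``R^(s-1)``.  Everything downstream — polynomial gradient curves, their
derivatives and integrals, dissimilarity surfaces — is ordinary Euclidean
algebra seen through this isometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Composition",
    "IlrBasis",
    "closure",
    "perturb",
    "power",
    "difference",
    "clr",
    "clr_inv",
    "build_ilr_basis",
    "default_sbp",
    "ilr",
    "ilr_inv",
    "aitchison_norm",
    "aitchison_distance",
]

_CLOSE_TOL = 1e-12
_CLR_SUM_TOL = 1e-8


def _as_positive_vector(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("a composition needs at least two parts in a 1-d vector")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("all parts must be finite and strictly positive")
    return arr


@dataclass(frozen=True)
class Composition:
    """Canonical (unit-sum) representative of a composition.

    Parameters
    ----------
    parts
        Strictly positive vector; closed to unit sum on construction, so
        ``Composition(v)`` and ``Composition(a * v)`` are identical for any
        ``a > 0``.
    labels
        Optional category names, one per part.
    """

    parts: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        arr = _as_positive_vector(self.parts)
        arr = arr / arr.sum()
        object.__setattr__(self, "parts", arr)
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != arr.size:
                raise ValueError("labels length must match number of parts")
            object.__setattr__(self, "labels", labels)

    @property
    def n_parts(self) -> int:
        return self.parts.size

    def isclose(self, other: "Composition", rtol: float = 1e-9) -> bool:
        return self.n_parts == other.n_parts and np.allclose(
            self.parts, other.parts, rtol=rtol, atol=1e-15
        )

    def subcomposition(self, keep: Sequence[str] | Sequence[int]) -> "Composition":
        """Close a subset of parts, selected by label or index."""
        if all(isinstance(k, str) for k in keep):
            if self.labels is None:
                raise ValueError("composition has no labels to select by")
            idx = [self.labels.index(k) for k in keep]
            labels = tuple(keep)
        else:
            idx = [int(k) for k in keep]
            labels = None if self.labels is None else tuple(self.labels[i] for i in idx)
        if len(idx) < 2:
            raise ValueError("a subcomposition needs at least two parts")
        return Composition(self.parts[idx], labels)

    def __repr__(self):
        return f"Composition({np.array2string(self.parts, precision=4)})"


def closure(v, labels=None) -> Composition:
    """Normalise a positive vector to unit sum (the canonical representative)."""
    return Composition(_as_positive_vector(v), labels)


def identity(s: int) -> Composition:
    """The neutral element of perturbation: all parts equal."""
    return Composition(np.full(s, 1.0 / s))


def _check_same_length(a: Composition, b: Composition):
    if a.n_parts != b.n_parts:
        raise ValueError(f"compositions have {a.n_parts} and {b.n_parts} parts")


def perturb(a: Composition, b: Composition) -> Composition:
    """Simplex addition: closure of the componentwise product."""
    _check_same_length(a, b)
    return Composition(a.parts * b.parts, a.labels)


def power(alpha: float, a: Composition) -> Composition:
    """Simplex scalar multiplication: closure of componentwise powers."""
    if not np.isfinite(alpha):
        raise ValueError("powering scalar must be finite")
    # work on the log scale to avoid overflow for large |alpha|
    w = alpha * np.log(a.parts)
    w -= w.max()
    return Composition(np.exp(w), a.labels)


def difference(a: Composition, b: Composition) -> Composition:
    """Simplex subtraction a ⊖ b: closure of componentwise ratios."""
    _check_same_length(a, b)
    return Composition(a.parts / b.parts, a.labels)


def clr(a: Composition) -> np.ndarray:
    """Centred logratio: log of each part over the geometric mean of all parts."""
    lg = np.log(a.parts)
    return lg - lg.mean()


def clr_inv(w, labels=None) -> Composition:
    """Inverse clr.  Input must sum to ~0; small float drift is re-centred."""
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("clr vector must be finite")
    if abs(w.sum()) > _CLR_SUM_TOL:
        raise ValueError(f"clr vector must sum to 0 (got {w.sum():.3g})")
    w = w - w.mean()
    w = w - w.max()
    return Composition(np.exp(w), labels)


@dataclass(frozen=True)
class IlrBasis:
    """Orthonormal logcontrast basis: an s × (s−1) matrix V with
    orthonormal, zero-sum columns.  ilr(a) = Vᵀ clr(a)."""

    contrast_matrix: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        V = np.asarray(self.contrast_matrix, dtype=float)
        if V.ndim != 2 or V.shape[1] != V.shape[0] - 1:
            raise ValueError("contrast matrix must be s x (s-1)")
        if not np.allclose(V.T @ V, np.eye(V.shape[1]), atol=_CLOSE_TOL * V.shape[0] * 100):
            raise ValueError("basis columns must be orthonormal")
        if not np.allclose(V.sum(axis=0), 0.0, atol=1e-10):
            raise ValueError("basis columns must sum to zero (logcontrasts)")
        object.__setattr__(self, "contrast_matrix", V)
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != V.shape[0]:
                raise ValueError("labels length must match number of parts")
            object.__setattr__(self, "labels", labels)

    @property
    def n_parts(self) -> int:
        return self.contrast_matrix.shape[0]

    @property
    def n_coords(self) -> int:
        return self.contrast_matrix.shape[1]


def default_sbp(s: int) -> np.ndarray:
    """Default sequential binary partition: split {1..j} vs {j+1} for
    j = s−1 … 1.  Column j of the resulting basis contrasts the first j
    parts against part j+1."""
    sbp = np.zeros((s - 1, s), dtype=int)
    for row, j in enumerate(range(s - 1, 0, -1)):
        sbp[row, :j] = 1
        sbp[row, j] = -1
    return sbp


def _validate_sbp(sbp: np.ndarray):
    """An SBP is valid when its splits form a hierarchy: starting from the
    full part set, each split bisects exactly one current group."""
    s = sbp.shape[1]
    remaining = list(range(sbp.shape[0]))
    groups = [frozenset(range(s))]
    while remaining:
        for ridx in list(remaining):
            row = sbp[ridx]
            plus = frozenset(np.flatnonzero(row > 0))
            minus = frozenset(np.flatnonzero(row < 0))
            if not plus or not minus:
                raise ValueError(f"SBP row {ridx} has an empty side")
            whole = plus | minus
            if whole in groups:
                groups.remove(whole)
                groups += [g for g in (plus, minus) if len(g) > 1]
                remaining.remove(ridx)
                break
        else:
            raise ValueError("SBP rows do not form a nested partition tree")


def build_ilr_basis(s: int, sbp: np.ndarray | None = None, labels=None) -> IlrBasis:
    """Construct an orthonormal ilr basis from a sequential binary partition.

    ``sbp`` is an (s−1) × s sign matrix; each row codes one split with +1 /
    −1 / 0.  For a split with r parts coded +1 and t coded −1 the balance
    column carries +sqrt(t/(r(r+t))) on the +1 parts and −sqrt(r/(t(r+t)))
    on the −1 parts.  Without ``sbp`` the default partition from
    :func:`default_sbp` is used.
    """
    if s < 2:
        raise ValueError("need at least two parts")
    if sbp is None:
        sbp = default_sbp(s)
    sbp = np.asarray(sbp)
    if sbp.shape != (s - 1, s):
        raise ValueError(f"SBP must be (s-1) x s = {(s - 1, s)}, got {sbp.shape}")
    _validate_sbp(sbp)
    V = np.zeros((s, s - 1))
    for j, row in enumerate(sbp):
        plus = row > 0
        minus = row < 0
        r, t = plus.sum(), minus.sum()
        V[plus, j] = np.sqrt(t / (r * (r + t)))
        V[minus, j] = -np.sqrt(r / (t * (r + t)))
    return IlrBasis(V, labels)


def random_orthonormal_basis(s: int, rng: np.random.Generator) -> IlrBasis:
    """A uniformly random orthonormal logcontrast basis (for invariance tests)."""
    V0 = build_ilr_basis(s).contrast_matrix
    A = rng.standard_normal((s - 1, s - 1))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    return IlrBasis(V0 @ Q)


def ilr(a: Composition, basis: IlrBasis) -> np.ndarray:
    """Isometric logratio coordinates of ``a`` in ``basis``."""
    if a.n_parts != basis.n_parts:
        raise ValueError("composition and basis dimensions do not match")
    return basis.contrast_matrix.T @ clr(a)


def ilr_inv(x, basis: IlrBasis, labels=None) -> Composition:
    """Back-transform ilr coordinates to the simplex (a softmax of V·x)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (basis.n_coords,):
        raise ValueError(
            f"coordinate vector must have length {basis.n_coords}, got {x.shape}"
        )
    w = basis.contrast_matrix @ x
    w -= w.max()
    return Composition(np.exp(w), labels if labels is not None else basis.labels)


def aitchison_norm(a: Composition) -> float:
    """Aitchison norm: Euclidean norm of the clr (equivalently ilr) vector."""
    return float(np.linalg.norm(clr(a)))


def aitchison_distance(a: Composition, b: Composition) -> float:
    """Perturbation-invariant distance ‖a ⊖ b‖ₐ."""
    _check_same_length(a, b)
    return float(np.linalg.norm(clr(a) - clr(b)))
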