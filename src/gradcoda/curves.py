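"""Polynomial simplex-valued curves on an environmental gradient.

A curve of degree d maps a (centred and scaled) gradient position z to the
composition ilr_inv(β₀ + β₁z + … + β_d z^d).  Because ilr is a linear
isometry, evaluation, differentiation and integration reduce to the same
operations on the coefficient vectors; the simplex forms are

    M(z)    = γ₀ ⊕ (z ⊙ γ₁) ⊕ (z² ⊙ γ₂) ⊕ …
    D⊕M(z)  = γ₁ ⊕ (2z ⊙ γ₂) ⊕ …        (degree 2: γ₁ ⊕ (2z ⊙ γ₂))
    mean over [S, D] = (1/(D−S)) ⊙ [ (z⊙γ₀) ⊕ (z²/2⊙γ₁) ⊕ (z³/3⊙γ₂) ]_S^D

with γ_j = ilr_inv(β_j).  For degree ≤ 2 the dissimilarity between expected
compositions factorizes as |z₁−z₂| · ‖γ₁ ⊕ ((z₁+z₂) ⊙ γ₂)‖ₐ, so it vanishes
off the diagonal only when γ₂ is a powering of γ₁ (β₂ = c β₁ in ilr
coordinates), along the counter-diagonal z₁ + z₂ = −1/c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simplex import (
    Composition,
    IlrBasis,
    aitchison_distance,
    aitchison_norm,
    identity,
    ilr,
    ilr_inv,
    power,
)

__all__ = [
    "PolySimplexCurve",
    "curve_eval",
    "curve_derivative",
    "derivative_norm",
    "curve_mean",
    "expected_dissimilarity",
    "collinearity_check",
    "powering_line",
]


@dataclass(frozen=True)
class PolySimplexCurve:
    """Polynomial gradient curve in ilr coordinates.

    Parameters
    ----------
    beta
        (d+1) × (s−1) array; row j is the coefficient vector β_j of z^j.
    basis
        The ilr basis fixing the coordinate system.
    z_center, z_scale
        The affine map from gradient units (e.g. depth in metres) to the
        standardised z the polynomial is written in: z = (depth − center)/scale.
        Defaults to the identity map.
    """

    beta: np.ndarray
    basis: IlrBasis
    z_center: float = 0.0
    z_scale: float = 1.0

    def __post_init__(self):
        beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if not np.all(np.isfinite(beta)):
            raise ValueError("curve coefficients must be finite")
        if beta.shape[0] < 1 or beta.shape[0] > 4:
            raise ValueError("only degrees 0-3 are supported")
        if beta.shape[1] != self.basis.n_coords:
            raise ValueError(
                f"coefficients have {beta.shape[1]} coordinates, basis expects "
                f"{self.basis.n_coords}"
            )
        if self.z_scale <= 0:
            raise ValueError("z_scale must be positive")
        object.__setattr__(self, "beta", beta)

    @property
    def degree(self) -> int:
        return self.beta.shape[0] - 1

    @property
    def n_parts(self) -> int:
        return self.basis.n_parts

    def gamma(self, j: int) -> Composition:
        """The simplex form γ_j = ilr_inv(β_j) of the j-th coefficient."""
        return ilr_inv(self.beta[j], self.basis)

    def to_z(self, depth) -> np.ndarray:
        """Map gradient units to the standardised scale of the polynomial."""
        return (np.asarray(depth, dtype=float) - self.z_center) / self.z_scale

    def coords(self, z: float) -> np.ndarray:
        """ilr coordinates Σ_j β_j z^j at a standardised position z."""
        zp = np.asarray(z, dtype=float) ** np.arange(self.beta.shape[0])
        return zp @ self.beta

    def derivative_coords(self, z: float) -> np.ndarray:
        d = self.degree
        if d == 0:
            return np.zeros(self.basis.n_coords)
        j = np.arange(1, d + 1)
        zp = j * np.asarray(z, dtype=float) ** (j - 1)
        return zp @ self.beta[1:]


def curve_eval(curve: PolySimplexCurve, z: float) -> Composition:
    """Expected composition M(z) = ilr_inv(Σ_j β_j z^j) at standardised z."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return ilr_inv(curve.coords(z), curve.basis)


def curve_derivative(curve: PolySimplexCurve, z: float) -> Composition:
    """Simplex derivative D⊕M(z); a composition, the identity element when
    the curve is constant."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return ilr_inv(curve.derivative_coords(z), curve.basis)


def derivative_norm(curve: PolySimplexCurve, z: float) -> float:
    """Scalar rate of change ‖D⊕M(z)‖ₐ, per unit of standardised z."""
    return float(np.linalg.norm(curve.derivative_coords(z)))


def rate_minimiser(curve: PolySimplexCurve) -> float:
    """Standardised position minimising the rate of change of a quadratic
    curve: z* = −(β₁·β₂)/(2‖β₂‖²)."""
    if curve.degree != 2:
        raise ValueError("closed-form minimiser requires a quadratic curve")
    b1, b2 = curve.beta[1], curve.beta[2]
    n2 = float(b2 @ b2)
    if n2 == 0.0:
        raise ValueError("quadratic coefficient is zero; rate is constant")
    return float(-(b1 @ b2) / (2.0 * n2))


def curve_mean(curve: PolySimplexCurve, S: float, D: float) -> Composition:
    """Mean composition over [S, D] (standardised units):
    ilr_inv( (1/(D−S)) [β₀z + β₁z²/2 + β₂z³/3 + …]_S^D )."""
    if not (np.isfinite(S) and np.isfinite(D)):
        raise ValueError("integration limits must be finite")
    if D <= S:
        raise ValueError("upper limit must exceed lower limit")
    j = np.arange(1, curve.beta.shape[0] + 1)
    anti = curve.beta / j[:, None]  # coefficients of the antiderivative, z^j / j
    zD = D ** j
    zS = S ** j
    x = ((zD - zS) @ anti) / (D - S)
    return ilr_inv(x, curve.basis)


def expected_dissimilarity(curve: PolySimplexCurve, z1: float, z2: float) -> float:
    """Aitchison distance between expected compositions at z₁ and z₂.

    For degree ≤ 2 this equals |z₁−z₂| · ‖β₁ + (z₁+z₂)β₂‖ — the factorized
    form used by the dissimilarity surface; higher degrees fall back to the
    direct distance.
    """
    if not (np.isfinite(z1) and np.isfinite(z2)):
        raise ValueError("positions must be finite")
    if curve.degree <= 2:
        b1 = curve.beta[1] if curve.degree >= 1 else np.zeros(curve.basis.n_coords)
        b2 = curve.beta[2] if curve.degree == 2 else np.zeros(curve.basis.n_coords)
        return float(abs(z1 - z2) * np.linalg.norm(b1 + (z1 + z2) * b2))
    return aitchison_distance(curve_eval(curve, z1), curve_eval(curve, z2))


def collinearity_check(curve: PolySimplexCurve, tol: float = 1e-6) -> dict:
    """Test whether β₂ is a scalar multiple of β₁ (γ₂ a powering of γ₁).

    When it is, the expected dissimilarity vanishes along the
    counter-diagonal z₁ + z₂ = −1/c, so the same expected composition
    recurs at distinct gradient positions.  Returns
    ``{"is_collinear": bool, "c": float | None}`` with c the least-squares
    multiplier (β₁·β₂)/‖β₁‖².
    """
    if curve.degree != 2:
        raise ValueError("collinearity condition is defined for quadratic curves")
    b1, b2 = curve.beta[1], curve.beta[2]
    n1 = float(b1 @ b1)
    if n1 == 0.0:
        raise ValueError("linear coefficient is zero; the condition is undefined")
    n2 = float(np.linalg.norm(b2))
    if n2 == 0.0:
        # degenerate quadratic: really a degree-1 curve, collinear with c = 0
        return {"is_collinear": True, "c": 0.0}
    c = float(b1 @ b2) / n1
    resid = float(np.linalg.norm(b2 - c * b1)) / n2
    return {"is_collinear": resid < tol, "c": c if resid < tol else None}


def powering_line(g: Composition, t_values) -> list[Composition]:
    """The compositional line {t ⊙ g}: in ilr coordinates, the straight line
    through the origin spanned by ilr(g)."""
    if aitchison_norm(g) == 0.0:
        raise ValueError("the identity element spans no line")
    return [power(float(t), g) for t in np.asarray(t_values, dtype=float)]


def reparametrise(
    curve: PolySimplexCurve, new_center: float, new_scale: float
) -> PolySimplexCurve:
    """Re-express the curve's coefficients in a different covariate
    standardisation.  The returned curve is the same map from gradient
    units to compositions; only (z_center, z_scale) and hence β change.
    """
    a = new_scale / curve.z_scale
    b = (new_center - curve.z_center) / curve.z_scale
    lin = np.polynomial.Polynomial([b, a])
    new_beta = np.zeros_like(curve.beta)
    for k in range(curve.beta.shape[1]):
        composed = np.polynomial.Polynomial(curve.beta[:, k])(lin)
        coef = composed.coef
        new_beta[: len(coef), k] = coef
    return PolySimplexCurve(new_beta, curve.basis, new_center, new_scale)


def subcurve(curve: PolySimplexCurve, keep) -> PolySimplexCurve:
    """Restrict a curve to a subcomposition (selected by labels or indices).

    Subcompositional coherence: closing each γ_j to the kept parts yields
    the curve of the closed subcomposition, expressed in the default basis
    of the smaller simplex.
    """
    from .simplex import build_ilr_basis, clr

    gammas = [curve.gamma(j).subcomposition(keep) for j in range(curve.degree + 1)]
    sub_basis = build_ilr_basis(gammas[0].n_parts, labels=gammas[0].labels)
    beta = np.stack([sub_basis.contrast_matrix.T @ clr(g) for g in gammas])
    return PolySimplexCurve(beta, sub_basis, curve.z_center, curve.z_scale)
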