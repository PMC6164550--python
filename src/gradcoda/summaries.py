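"""Posterior summaries of fitted gradient curves.

Each function takes the collection of per-draw expected-composition curves
(from :func:`gradcoda.model.predict_expected_curve`) and a grid of gradient
positions in original units (metres of depth), and reduces the posterior to
the quantities of ecological interest: the pairwise dissimilarity surface,
the rate-of-change profile, the gradient-integrated mean composition, and
ordination scores of observation-specific predictions.  All of them are
invariant to the ilr basis used in fitting, since they are built from
Aitchison norms and distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import PolySimplexCurve
from .simplex import Composition

__all__ = [
    "GridSummary",
    "hpd_interval",
    "dissimilarity_surface",
    "rate_profile",
    "integrated_composition",
    "bray_curtis",
    "adjacent_dissimilarity_profile",
    "pca_scores",
]


@dataclass(frozen=True)
class GridSummary:
    """Pointwise posterior summary along a gradient grid."""

    grid: np.ndarray
    mean: np.ndarray
    hpd_lower: np.ndarray
    hpd_upper: np.ndarray
    level: float

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 1 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not (
            np.all(self.hpd_lower <= self.mean + 1e-12)
            and np.all(self.mean <= self.hpd_upper + 1e-12)
        ):
            raise ValueError("pointwise mean must lie inside the HPD band")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "grid": self.grid,
                "mean": self.mean,
                "lower": self.hpd_lower,
                "upper": self.hpd_upper,
            }
        )


def hpd_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval: the shortest contiguous interval
    containing ``ceil(level * n)`` of the sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for an HPD interval")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    w = int(np.ceil(level * n))
    widths = x[w - 1 :] - x[: n - w + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + w - 1])


def _hpd_bounds_along_axis0(samples: np.ndarray, level: float):
    """Vectorised HPD over axis 0 of an (M, ...) array."""
    shp = samples.shape[1:]
    x = np.sort(samples.reshape(samples.shape[0], -1), axis=0)
    n = x.shape[0]
    w = int(np.ceil(level * n))
    widths = x[w - 1 :, :] - x[: n - w + 1, :]
    i = np.argmin(widths, axis=0)
    cols = np.arange(x.shape[1])
    return x[i, cols].reshape(shp), x[i + w - 1, cols].reshape(shp)


def _stack_curves(curves: list[PolySimplexCurve]):
    first = curves[0]
    beta = np.stack([c.beta for c in curves])
    for c in curves[1:]:
        if (c.z_center, c.z_scale) != (first.z_center, first.z_scale):
            raise ValueError("curves must share the covariate standardisation")
    return beta, first.basis, first.z_center, first.z_scale


def dissimilarity_surface(
    curves: list[PolySimplexCurve], depth_grid, level: float = 0.95
) -> dict:
    """Pairwise Aitchison dissimilarity between expected compositions on a
    gradient grid: posterior-mean matrix and HPD-width matrix.

    Both matrices are symmetric with an exactly zero diagonal (same
    position, same expected composition).  For quadratic curves each entry
    uses the factorized form |z1−z2|·‖β₁+(z1+z2)β₂‖.
    """
    beta, basis, c0, s0 = _stack_curves(curves)
    depth_grid = np.asarray(depth_grid, dtype=float)
    zg = (depth_grid - c0) / s0
    M, d1, K = beta.shape
    if d1 <= 3:
        b1 = beta[:, 1] if d1 >= 2 else np.zeros((M, K))
        b2 = beta[:, 2] if d1 >= 3 else np.zeros((M, K))
        a = np.einsum("mk,mk->m", b1, b1)
        b = 2.0 * np.einsum("mk,mk->m", b1, b2)
        c = np.einsum("mk,mk->m", b2, b2)
        S = zg[:, None] + zg[None, :]
        dz = np.abs(zg[:, None] - zg[None, :])
        norm_sq = (
            a[:, None, None] + b[:, None, None] * S + c[:, None, None] * S * S
        )
        D = dz[None, :, :] * np.sqrt(np.maximum(norm_sq, 0.0))
    else:
        design = zg[:, None] ** np.arange(d1)[None, :]
        coords = np.einsum("gd,mdk->mgk", design, beta)
        diff = coords[:, :, None, :] - coords[:, None, :, :]
        D = np.linalg.norm(diff, axis=-1)
    lo, hi = _hpd_bounds_along_axis0(D, level)
    return {
        "grid": depth_grid,
        "mean": D.mean(axis=0),
        "hpd_width": hi - lo,
        "level": level,
    }


def _derivative_coords(beta: np.ndarray, zg: np.ndarray) -> np.ndarray:
    """(M, G, K) ilr coordinates of the simplex derivative on the grid."""
    M, d1, K = beta.shape
    j = np.arange(1, d1)
    design = j[None, :] * zg[:, None] ** (j - 1)[None, :]  # (G, d)
    return np.einsum("gd,mdk->mgk", design, beta[:, 1:])


def rate_profile(
    curves: list[PolySimplexCurve],
    depth_grid,
    level: float = 0.95,
    per_metre: bool = True,
) -> dict:
    """Posterior profile of the scalar rate of change ‖D⊕M(z)‖ₐ on a grid.

    With ``per_metre`` (default) the chain rule converts the rate from
    per-standardised-z units to per metre of depth.  Returns the pointwise
    ``GridSummary``, the per-draw traces, and each draw's rate-minimising
    depth (closed form z* = −(β₁·β₂)/(2‖β₂‖²) for quadratic curves, grid
    argmin otherwise).
    """
    beta, basis, c0, s0 = _stack_curves(curves)
    depth_grid = np.asarray(depth_grid, dtype=float)
    zg = (depth_grid - c0) / s0
    rates = np.linalg.norm(_derivative_coords(beta, zg), axis=-1)  # (M, G)
    if per_metre:
        rates = rates / s0
    lo, hi = _hpd_bounds_along_axis0(rates, level)
    M, d1, K = beta.shape
    if d1 == 3:
        b1, b2 = beta[:, 1], beta[:, 2]
        n2 = np.einsum("mk,mk->m", b2, b2)
        with np.errstate(divide="ignore", invalid="ignore"):
            zstar = -np.einsum("mk,mk->m", b1, b2) / (2.0 * n2)
        zstar = np.where(n2 > 0, zstar, np.nan)
        minimisers = zstar * s0 + c0
    else:
        minimisers = depth_grid[np.argmin(rates, axis=1)]
    return {
        "summary": GridSummary(depth_grid, rates.mean(axis=0), lo, hi, level),
        "traces": rates,
        "minimiser_depths": minimisers,
    }


def integrated_composition(
    curves: list[PolySimplexCurve], S: float, D: float, level: float = 0.95
) -> dict:
    """Posterior of the mean composition over the gradient interval [S, D]
    (original units).  The simplex integral mean is invariant under the
    affine covariate standardisation, so it is evaluated on the z scale.

    Returns per-category posterior means and HPD intervals of the parts,
    plus the per-draw compositions (rows sum to 1)."""
    if D <= S:
        raise ValueError("upper depth must exceed lower depth")
    beta, basis, c0, s0 = _stack_curves(curves)
    zS, zD = (S - c0) / s0, (D - c0) / s0
    M, d1, K = beta.shape
    j = np.arange(1, d1 + 1)
    anti = beta / j[None, :, None]
    x = np.einsum("d,mdk->mk", zD ** j - zS ** j, anti) / (zD - zS)  # (M, K)
    U = x @ basis.contrast_matrix.T  # (M, s)
    U -= U.max(axis=1, keepdims=True)
    parts = np.exp(U)
    parts /= parts.sum(axis=1, keepdims=True)
    lo, hi = _hpd_bounds_along_axis0(parts, level)
    labels = basis.labels or tuple(f"part_{j}" for j in range(basis.n_parts))
    return {
        "labels": labels,
        "mean": parts.mean(axis=0),
        "hpd_lower": lo,
        "hpd_upper": hi,
        "draws": parts,
        "level": level,
    }


def bray_curtis(a: Composition, b: Composition) -> float:
    """Bray–Curtis dissimilarity Σ|a−b| / Σ(a+b) of closed compositions.

    Included as a contrast: it is not perturbation invariant, so profiles
    built from it can disagree qualitatively with the Aitchison rate."""
    if a.n_parts != b.n_parts:
        raise ValueError("compositions must have the same number of parts")
    return float(
        np.abs(a.parts - b.parts).sum() / (a.parts + b.parts).sum()
    )


def adjacent_dissimilarity_profile(
    curves: list[PolySimplexCurve],
    depth_grid,
    metric: str = "aitchison",
    level: float = 0.95,
) -> GridSummary:
    """Dissimilarity between consecutive grid compositions, per draw.

    Reported at the midpoints of consecutive grid cells.  With the
    Aitchison metric the profile divided by the grid spacing converges to
    the rate profile as the grid is refined; Bray–Curtis gives the
    non-invariant contrast."""
    if metric not in ("aitchison", "bray_curtis"):
        raise ValueError("metric must be 'aitchison' or 'bray_curtis'")
    beta, basis, c0, s0 = _stack_curves(curves)
    depth_grid = np.asarray(depth_grid, dtype=float)
    zg = (depth_grid - c0) / s0
    design = zg[:, None] ** np.arange(beta.shape[1])[None, :]
    coords = np.einsum("gd,mdk->mgk", design, beta)  # (M, G, K)
    if metric == "aitchison":
        prof = np.linalg.norm(np.diff(coords, axis=1), axis=-1)
    else:
        U = coords @ basis.contrast_matrix.T
        U -= U.max(axis=2, keepdims=True)
        P = np.exp(U)
        P /= P.sum(axis=2, keepdims=True)
        prof = 0.5 * np.abs(np.diff(P, axis=1)).sum(axis=-1)
    lo, hi = _hpd_bounds_along_axis0(prof, level)
    mid = 0.5 * (depth_grid[:-1] + depth_grid[1:])
    return GridSummary(mid, prof.mean(axis=0), lo, hi, level)


def pca_scores(scores: np.ndarray) -> dict:
    """First two principal components of observation-specific ilr scores.

    Column-centred PCA via SVD; the sign of each component is fixed so that
    its largest-magnitude loading is positive.  Returns the 2-d coordinates,
    the per-component explained-variance fractions, and the loadings."""
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[0] <= 2:
        raise ValueError("need a matrix with more than two rows")
    Xc = X - X.mean(axis=0)
    U, sing, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = sing**2 / (X.shape[0] - 1)
    explained = var / var.sum()
    n_pc = min(2, Vt.shape[0])
    comps = Vt[:n_pc]
    signs = np.sign(comps[np.arange(n_pc), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    comps = comps * signs[:, None]
    return {
        "scores": Xc @ comps.T,
        "explained_variance_ratio": explained[:n_pc],
        "loadings": comps,
    }
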