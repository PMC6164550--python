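"""Bayesian multinomial regression with an ilr link and logistic-normal
overdispersion.

The observation model for a count vector y_i with total n_i at (centred,
scaled) gradient position z_i is

    y_i  ~ multinomial(n_i, rho_i)
    rho_i = ilr_inv(x_i)
    x_i  = beta_0 + beta_1 z_i + ... + beta_d z_i^d + eps_i
    eps_i ~ N(0, Sigma)

Counts of zero sit naturally in the multinomial support, so no pseudocounts
are ever applied; the linear predictor is back-transformed, never the data.
Fitting is by NUTS over (beta, Sigma, eps) with a non-centred
parameterisation of the per-observation effects and Sigma = L L' given a
weakly-informative prior on the Cholesky factor L (half-normal diagonal,
normal off-diagonal).  All gradients are analytic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .curves import PolySimplexCurve
from .nuts import nuts_sample
from .simplex import IlrBasis, build_ilr_basis

__all__ = [
    "CountTable",
    "PriorSpec",
    "SamplerSpec",
    "ModelSpec",
    "PosteriorDraws",
    "aggregate_taxa",
    "standardize_covariate",
    "fit",
    "predict_expected_curve",
    "clr_bands",
    "still_scores",
    "loo_pointwise",
    "loo_compare",
    "posterior_predictive",
]


@dataclass(frozen=True)
class CountTable:
    """Observations × categories count matrix with one covariate value per
    observation.  Zeros are permitted anywhere; each row total must be ≥ 1."""

    counts: np.ndarray
    covariate: np.ndarray
    category_labels: tuple[str, ...]
    observation_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-d matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        cov = np.asarray(self.covariate, dtype=float)
        if cov.shape != (counts.shape[0],):
            raise ValueError("covariate length must match number of observations")
        labels = tuple(str(x) for x in self.category_labels)
        if len(labels) != counts.shape[1]:
            raise ValueError("category_labels length must match number of columns")
        totals = counts.sum(axis=1)
        if np.any(totals < 1):
            bad = np.flatnonzero(totals < 1)
            raise ValueError(f"rows with zero total counts: {bad.tolist()}")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "covariate", cov)
        object.__setattr__(self, "category_labels", labels)
        if self.observation_ids is not None:
            ids = tuple(str(x) for x in self.observation_ids)
            if len(ids) != counts.shape[0]:
                raise ValueError("observation_ids length mismatch")
            object.__setattr__(self, "observation_ids", ids)

    @property
    def n_obs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def aggregate_taxa(
    raw: CountTable, merge_map: dict[str, str], exclude: list[str] | None = None
) -> CountTable:
    """Merge taxa into groups and drop excluded taxa.

    Excluded taxa's points are removed outright — row totals shrink, nothing
    is redistributed.  Remaining labels must all appear in ``merge_map``;
    output category order follows the order groups first appear in the map.
    """
    exclude = list(exclude or [])
    unknown = [
        lab
        for lab in raw.category_labels
        if lab not in merge_map and lab not in exclude
    ]
    if unknown:
        raise ValueError(f"labels neither merged nor excluded: {unknown}")
    groups: list[str] = []
    for lab in merge_map:
        g = merge_map[lab]
        if g not in groups:
            groups.append(g)
    new_counts = np.zeros((raw.n_obs, len(groups)), dtype=np.int64)
    for j, lab in enumerate(raw.category_labels):
        if lab in exclude:
            continue
        new_counts[:, groups.index(merge_map[lab])] += raw.counts[:, j]
    return CountTable(new_counts, raw.covariate, tuple(groups), raw.observation_ids)


def standardize_covariate(covariate) -> tuple[np.ndarray, float, float]:
    """Centre and scale (sample SD, denominator N−1); returns (z, center, scale)."""
    cov = np.asarray(covariate, dtype=float)
    if np.unique(cov).size < 2:
        raise ValueError("covariate is constant; cannot standardise")
    center = float(cov.mean())
    scale = float(cov.std(ddof=1))
    return (cov - center) / scale, center, scale


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative priors on the ilr scale.

    beta_scale: SD of the normal prior on each regression coefficient.
    re_scale:   scale of the half-normal prior on the diagonal of the
                random-effect Cholesky factor (marginal SD of eps).
    offdiag_scale: SD of the normal prior on its off-diagonal entries.
    """

    beta_scale: float = 5.0
    re_scale: float = 2.0
    offdiag_scale: float = 1.0

    def __post_init__(self):
        if min(self.beta_scale, self.re_scale, self.offdiag_scale) <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class SamplerSpec:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.9
    max_depth: int = 10


@dataclass(frozen=True)
class ModelSpec:
    degree: int = 2
    basis: IlrBasis | None = None  # default basis of the data's dimension
    priors: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerSpec = field(default_factory=SamplerSpec)

    def __post_init__(self):
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")


@dataclass
class PosteriorDraws:
    """Combined posterior draws with everything needed to reproduce
    predictions: the ilr basis, the covariate standardisation and the data."""

    beta: np.ndarray  # (M, degree+1, K)
    chol: np.ndarray  # (M, K, K) lower Cholesky factor of Sigma
    eps: np.ndarray  # (M, N, K) per-observation effects
    basis: IlrBasis
    z: np.ndarray
    z_center: float
    z_scale: float
    data: CountTable
    spec: ModelSpec
    n_chains: int
    diagnostics: dict

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def degree(self) -> int:
        return self.beta.shape[1] - 1

    @property
    def Sigma(self) -> np.ndarray:
        return self.chol @ np.swapaxes(self.chol, 1, 2)


# ---------------------------------------------------------------------------
# log posterior and analytic gradient


class _Posterior:
    def __init__(self, Y, z, V, degree, priors):
        self.Y = Y.astype(float)
        self.n = Y.sum(axis=1).astype(float)
        self.V = V
        self.N, self.s = Y.shape
        self.K = self.s - 1
        self.d1 = degree + 1
        self.P = z[:, None] ** np.arange(self.d1)[None, :]  # (N, d+1)
        self.priors = priors
        self.tril = np.tril_indices(self.K, -1)
        self.n_off = self.tril[0].size
        self.dim = self.d1 * self.K + self.K + self.n_off + self.N * self.K

    def unpack(self, q):
        K, d1, N = self.K, self.d1, self.N
        i = 0
        B = q[i : i + d1 * K].reshape(d1, K)
        i += d1 * K
        ldiag = q[i : i + K]
        i += K
        off = q[i : i + self.n_off]
        i += self.n_off
        eta = q[i:].reshape(N, K)
        L = np.zeros((K, K))
        L[self.tril] = off
        lam = np.exp(ldiag)
        L[np.diag_indices(K)] = lam
        return B, ldiag, lam, off, L, eta

    def logp_and_grad(self, q):
        pr = self.priors
        B, ldiag, lam, off, L, eta = self.unpack(q)
        X = self.P @ B + eta @ L.T  # (N, K)
        U = X @ self.V.T  # (N, s)
        m = U.max(axis=1)
        E = np.exp(U - m[:, None])
        sum_e = E.sum(axis=1)
        lse = m + np.log(sum_e)
        loglik = float(np.sum(self.Y * U) - self.n @ lse)
        logp = (
            loglik
            - 0.5 * np.sum(B * B) / pr.beta_scale**2
            - 0.5 * np.sum(lam * lam) / pr.re_scale**2
            + np.sum(ldiag)  # Jacobian of the log-diagonal parameterisation
            - 0.5 * np.sum(off * off) / pr.offdiag_scale**2
            - 0.5 * np.sum(eta * eta)
        )
        # gradient
        R = self.Y - (self.n / sum_e)[:, None] * E  # (N, s)
        G = R @ self.V  # (N, K)
        gB = self.P.T @ G - B / pr.beta_scale**2
        gL = G.T @ eta  # (K, K) full
        g_ldiag = np.diag(gL) * lam - lam * lam / pr.re_scale**2 + 1.0
        g_off = gL[self.tril] - off / pr.offdiag_scale**2
        g_eta = G @ L - eta
        grad = np.concatenate(
            [gB.ravel(), g_ldiag, g_off, g_eta.ravel()]
        )
        return logp, grad

    def initial_point(self, rng):
        q = 0.1 * rng.standard_normal(self.dim)
        # start the intercept at the smoothed empirical centre
        p = self.Y.sum(axis=0) + 0.5
        p = p / p.sum()
        lg = np.log(p)
        clr0 = lg - lg.mean()
        B0 = self.V.T @ clr0
        q[: self.K] += B0
        # modest initial random-effect scales
        i = self.d1 * self.K
        q[i : i + self.K] = np.log(0.2) + 0.05 * rng.standard_normal(self.K)
        return q


def fit(
    data: CountTable,
    spec: ModelSpec | None = None,
    rhat_gate: float = 1.01,
    on_bad_fit: str = "raise",
) -> PosteriorDraws:
    """Sample the joint posterior of (beta, Sigma, eps) by NUTS.

    ``on_bad_fit`` controls the convergence gate: "raise" aborts when any
    beta component has split-R-hat above ``rhat_gate`` or divergences
    occurred; "warn" records the problem in the diagnostics and continues.
    """
    import arviz as az

    spec = spec or ModelSpec()
    if spec.degree + 1 > data.n_obs:
        raise ValueError("need more observations than polynomial coefficients")
    if on_bad_fit not in ("raise", "warn"):
        raise ValueError("on_bad_fit must be 'raise' or 'warn'")
    basis = spec.basis or build_ilr_basis(
        data.n_categories, labels=data.category_labels
    )
    if basis.n_parts != data.n_categories:
        raise ValueError("basis dimension does not match the count table")
    z, center, scale = standardize_covariate(data.covariate)
    post = _Posterior(data.counts, z, basis.contrast_matrix, spec.degree, spec.priors)

    ss = spec.sampler
    seed_seq = np.random.SeedSequence(ss.seed)
    chain_draws, divergences = [], 0
    for child in seed_seq.spawn(ss.chains):
        rng = np.random.default_rng(child)
        q0 = post.initial_point(rng)
        draws, stats = nuts_sample(
            post.logp_and_grad,
            q0,
            ss.warmup,
            ss.draws,
            rng,
            target_accept=ss.target_accept,
            max_depth=ss.max_depth,
        )
        chain_draws.append(draws)
        divergences += stats.divergences

    K, d1, N = post.K, post.d1, post.N
    all_draws = np.stack(chain_draws)  # (chains, draws, dim)
    beta_c = all_draws[:, :, : d1 * K].reshape(ss.chains, ss.draws, d1, K)

    rhat = az.rhat(az.convert_to_dataset(beta_c))["x"].values
    ess = az.ess(az.convert_to_dataset(beta_c))["x"].values
    diagnostics = {
        "rhat_beta_max": float(np.nanmax(rhat)),
        "ess_beta_min": float(np.nanmin(ess)),
        "divergences": int(divergences),
        "converged": bool(np.nanmax(rhat) <= rhat_gate and divergences == 0),
    }
    if not diagnostics["converged"]:
        msg = (
            f"convergence gate failed: max R-hat {diagnostics['rhat_beta_max']:.4f}, "
            f"{divergences} divergences"
        )
        if on_bad_fit == "raise":
            raise RuntimeError(msg)
        warnings.warn(msg, RuntimeWarning)

    flat = all_draws.reshape(ss.chains * ss.draws, -1)
    M = flat.shape[0]
    beta = flat[:, : d1 * K].reshape(M, d1, K)
    i = d1 * K
    ldiag = flat[:, i : i + K]
    i += K
    off = flat[:, i : i + post.n_off]
    i += post.n_off
    eta = flat[:, i:].reshape(M, N, K)
    chol = np.zeros((M, K, K))
    chol[:, post.tril[0], post.tril[1]] = off
    chol[:, np.arange(K), np.arange(K)] = np.exp(ldiag)
    eps = np.einsum("mnk,mjk->mnj", eta, chol)

    return PosteriorDraws(
        beta=beta,
        chol=chol,
        eps=eps,
        basis=basis,
        z=z,
        z_center=center,
        z_scale=scale,
        data=data,
        spec=spec,
        n_chains=ss.chains,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# posterior products


def predict_expected_curve(draws: PosteriorDraws) -> list[PolySimplexCurve]:
    """One expected-composition curve M(z) per retained posterior draw."""
    return [
        PolySimplexCurve(draws.beta[m], draws.basis, draws.z_center, draws.z_scale)
        for m in range(draws.n_draws)
    ]


def posterior_mean_curve(draws: PosteriorDraws) -> PolySimplexCurve:
    return PolySimplexCurve(
        draws.beta.mean(axis=0), draws.basis, draws.z_center, draws.z_scale
    )


def clr_bands(draws: PosteriorDraws, depth_grid, level: float = 0.95):
    """Pointwise posterior mean and HPD band of clr(M(z)) per category.

    Returns a tidy DataFrame with columns (depth, category, mean, lower,
    upper).  clr values sum to zero across categories at every grid point.
    """
    import pandas as pd

    from .summaries import hpd_interval

    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    depth_grid = np.asarray(depth_grid, dtype=float)
    zg = (depth_grid - draws.z_center) / draws.z_scale
    design = zg[:, None] ** np.arange(draws.degree + 1)[None, :]  # (G, d+1)
    coords = np.einsum("gd,mdk->mgk", design, draws.beta)  # (M, G, K)
    clr_vals = coords @ draws.basis.contrast_matrix.T  # (M, G, s)
    rows = []
    labels = draws.basis.labels or tuple(
        f"part_{j}" for j in range(draws.basis.n_parts)
    )
    for gi, depth in enumerate(depth_grid):
        for j, lab in enumerate(labels):
            samples = clr_vals[:, gi, j]
            lo, hi = hpd_interval(samples, level)
            rows.append((float(depth), lab, float(samples.mean()), lo, hi))
    return pd.DataFrame(rows, columns=["depth", "category", "mean", "lower", "upper"])


def still_scores(draws: PosteriorDraws) -> np.ndarray:
    """Posterior-mean observation-specific ilr predictions (including the
    per-observation effect): row i is E[Σ_j beta_j z_i^j + eps_i]."""
    design = draws.z[:, None] ** np.arange(draws.degree + 1)[None, :]
    mu = np.einsum("nd,mdk->mnk", design, draws.beta)
    return (mu + draws.eps).mean(axis=0)


# ---------------------------------------------------------------------------
# model comparison


def _multinomial_const(Y):
    return gammaln(Y.sum(axis=1) + 1.0) - gammaln(Y + 1.0).sum(axis=1)


def loo_pointwise(
    draws: PosteriorDraws, n_inner: int = 100, seed: int = 0
) -> np.ndarray:
    """Per-draw, per-observation log predictive density with the
    observation effect integrated out by Monte Carlo over fresh
    eps ~ N(0, Sigma_draw) (``n_inner`` samples).  Shape (M, N)."""
    Y = draws.data.counts.astype(float)
    n = Y.sum(axis=1)
    V = draws.basis.contrast_matrix
    const = _multinomial_const(Y)
    design = draws.z[:, None] ** np.arange(draws.degree + 1)[None, :]
    rng = np.random.default_rng(seed)
    M, N = draws.n_draws, draws.data.n_obs
    K = draws.basis.n_coords
    out = np.empty((M, N))
    eta = rng.standard_normal((n_inner, K))
    for m in range(M):
        mu = design @ draws.beta[m]  # (N, K)
        eps = eta @ draws.chol[m].T  # (n_inner, K), shared across observations
        X = mu[None, :, :] + eps[:, None, :]  # (n_inner, N, K)
        U = X @ V.T
        ll = np.einsum("nj,inj->in", Y, U) - n * logsumexp(U, axis=2)
        out[m] = logsumexp(ll, axis=0) - np.log(n_inner) + const
    return out


def _elpd_loo(draws: PosteriorDraws, n_inner: int, seed: int):
    import arviz as az

    ll = loo_pointwise(draws, n_inner=n_inner, seed=seed)
    n_per_chain = draws.n_draws // draws.n_chains
    idata = az.from_dict(
        posterior={
            "beta": draws.beta.reshape(draws.n_chains, n_per_chain, -1)
        },
        log_likelihood={"y": ll.reshape(draws.n_chains, n_per_chain, -1)},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo = az.loo(idata, pointwise=True)
    return loo


def loo_compare(
    fits: dict[str, PosteriorDraws], n_inner: int = 100, seed: int = 0
):
    """PSIS leave-one-out comparison of models fitted to the same data.

    Returns a DataFrame ranked by elpd with columns (elpd, se, delta_elpd,
    delta_se, n_high_pareto_k); delta columns are paired differences from
    the top-ranked model.
    """
    import pandas as pd

    if len(fits) < 2:
        raise ValueError("need at least two fitted models to compare")
    datasets = [f.data for f in fits.values()]
    for other in datasets[1:]:
        if not np.array_equal(other.counts, datasets[0].counts):
            raise ValueError("all models must be fitted to the same data")
    loos = {name: _elpd_loo(f, n_inner, seed) for name, f in fits.items()}
    names = sorted(loos, key=lambda k: loos[k].elpd_loo, reverse=True)
    best_pw = loos[names[0]].loo_i.values
    rows = []
    for name in names:
        l = loos[name]
        pw = l.loo_i.values
        diff = best_pw - pw
        n_obs = pw.size
        rows.append(
            {
                "model": name,
                "elpd": float(l.elpd_loo),
                "se": float(l.se),
                "delta_elpd": float(diff.sum()),
                "delta_se": float(np.sqrt(n_obs * diff.var(ddof=1))),
                "n_high_pareto_k": int((l.pareto_k.values > 0.7).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("model")


def posterior_predictive(
    draws: PosteriorDraws, seed: int = 0, thin: int = 1
) -> dict:
    """Replicate the count table from the fitted model.

    Per retained draw, y_rep_i ~ multinomial(n_i, ilr_inv(x_i)) at the
    observed linear predictor (including eps_i).  Returns the replicate
    array and simple discrepancy summaries (per-category zero frequency and
    maximum count, observed vs replicated)."""
    rng = np.random.default_rng(seed)
    Y = draws.data.counts
    n = draws.data.totals
    V = draws.basis.contrast_matrix
    design = draws.z[:, None] ** np.arange(draws.degree + 1)[None, :]
    idx = np.arange(0, draws.n_draws, thin)
    reps = np.empty((idx.size, *Y.shape), dtype=np.int64)
    for out_m, m in enumerate(idx):
        X = design @ draws.beta[m] + draws.eps[m]
        U = X @ V.T
        P = np.exp(U - logsumexp(U, axis=1)[:, None])
        for i in range(Y.shape[0]):
            reps[out_m, i] = rng.multinomial(n[i], P[i])
    return {
        "y_rep": reps,
        "zero_frequency": {
            "observed": (Y == 0).mean(axis=0),
            "replicated": (reps == 0).mean(axis=(0, 1)),
        },
        "max_count": {
            "observed": Y.max(axis=0),
            "replicated_mean": reps.max(axis=1).mean(axis=0),
        },
    }
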