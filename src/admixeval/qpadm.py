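"""Rank-constrained admixture modeling on a matrix of f4-statistics.

A model of a ``target`` as a k-way mixture of ``sources``, judged against
``references``, is tested through the ``k x (n_R - 1)`` matrix

    X[i, j] = f4(target, source_i; ref_0, ref_j)

If the target's ancestral allele frequencies are a linear combination of the
sources' (weights summing to 1), the rows of the expectation of X are
linearly dependent and X has rank at most ``k - 1``.  The test statistic is
the generalized-least-squares distance between X and the nearest rank-(k-1)
matrix, using the block-jackknife covariance of vec(X) as the metric; it is
referred to a chi-squared distribution with ``n_R - k`` degrees of freedom
(``(m - r)(n - r)`` with m = k rows, n = n_R - 1 columns, r = k - 1).

The admixture weights are the left-null vector of the fitted rank-(k-1)
matrix, normalized to sum to 1; the weight vector w satisfies
``w @ X ~ 0`` because ``sum_i w_i f4(target, source_i; .) =
f4(target, sum_i w_i source_i; .)`` vanishes when the mixture is correct.
Weights outside [0, 1] are reported as estimated, never clamped — they are a
diagnostic in their own right.  A model is *plausible* when P > threshold
and every weight lies in [0, 1].

The single-source case (k = 1) tests whether the target forms a clade with
the source: the 1 x (n_R - 1) row is tested against rank 0 with
``n_R - 1`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from admixeval.fstats import (
    DEFAULT_BLOCK_SIZE,
    F4Vector,
    F4Workspace,
    SitePolicy,
    f4_vector_with_cov,
)
from admixeval.genotype import GenotypeMatrix


@dataclass
class QpAdmModel:
    """Target, ordered sources, and reference ("right") populations."""

    target: str
    sources: list[str]
    references: list[str]

    def __post_init__(self) -> None:
        self.sources = list(self.sources)
        self.references = list(self.references)
        k, n_r = len(self.sources), len(self.references)
        if k < 1:
            raise ValueError("need at least one source")
        overlap = ({self.target} | set(self.sources)) & set(self.references)
        if overlap:
            raise ValueError(f"populations on both sides of the model: {sorted(overlap)}")
        if self.target in self.sources:
            raise ValueError("target cannot be a source")
        if n_r < k + 1:
            raise ValueError(
                f"need at least {k + 1} reference populations for {k} sources, got {n_r}"
            )

    @property
    def k(self) -> int:
        return len(self.sources)

    @property
    def left(self) -> list[str]:
        return [self.target, *self.sources]

    @property
    def all_populations(self) -> list[str]:
        return [*self.left, *self.references]


@dataclass
class QpAdmOptions:
    """Fitting options; the all-snps policy defaults to YES."""

    allsnps: bool = True
    block_size: float = DEFAULT_BLOCK_SIZE
    p_threshold: float = 0.05
    max_iterations: int = 100
    tolerance: float = 1e-10
    #: relative ridge added to a near-singular covariance before inversion
    regularization: float = 1e-10
    #: compute per-weight jackknife standard errors (costs one rank fit per block)
    weight_se: bool = True

    @property
    def policy(self) -> SitePolicy:
        return SitePolicy.ALLSNPS_YES if self.allsnps else SitePolicy.ALLSNPS_NO


@dataclass
class QpAdmFit:
    """Result of a qpAdm model fit."""

    model: QpAdmModel
    weights: np.ndarray
    weight_ses: np.ndarray
    statistic: float
    df: int
    p_value: float
    n_snps_used: float
    plausible: bool
    converged: bool
    policy: SitePolicy
    f4: F4Vector | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def design_quadruples(model: QpAdmModel) -> list[tuple[str, str, str, str]]:
    """Row-major (source-major) list of the f4 quadruples of the design."""
    r0, rest = model.references[0], model.references[1:]
    return [(model.target, s, r0, rj) for s in model.sources for rj in rest]


def build_f4_design(
    G_or_ws: GenotypeMatrix | F4Workspace,
    model: QpAdmModel,
    options: QpAdmOptions | None = None,
) -> F4Vector:
    """The f4 vector (k x (n_R - 1), row-major) with jackknife covariance."""
    options = options or QpAdmOptions()
    return f4_vector_with_cov(
        G_or_ws, design_quadruples(model),
        policy=options.policy, block_size=options.block_size,
    )


# ---------------------------------------------------------------------------
# rank-constrained GLS fit
# ---------------------------------------------------------------------------

def _regularized_inverse(cov: np.ndarray, rel_ridge: float) -> np.ndarray:
    d = cov.shape[0]
    eps = rel_ridge * np.trace(cov) / d
    try:
        return np.linalg.inv(cov + eps * np.eye(d))
    except np.linalg.LinAlgError:
        return np.linalg.pinv(cov + eps * np.eye(d))


def _als_once(x, Cinv, k, n, r, A, B, max_iterations, tolerance):
    I_n, I_k = np.eye(n), np.eye(k)
    obj_prev = np.inf
    converged = False
    obj = np.inf
    for _ in range(max_iterations):
        # B-step: vec(A @ B) = kron(A, I_n) @ vec(B)
        M = np.kron(A, I_n)
        G = M.T @ Cinv
        try:
            b = np.linalg.solve(G @ M, G @ x)
        except np.linalg.LinAlgError:
            b = np.linalg.lstsq(G @ M, G @ x, rcond=None)[0]
        B = b.reshape(r, n)
        # A-step: vec(A @ B) = kron(I_k, B') @ vec(A)
        M = np.kron(I_k, B.T)
        G = M.T @ Cinv
        try:
            a = np.linalg.solve(G @ M, G @ x)
        except np.linalg.LinAlgError:
            a = np.linalg.lstsq(G @ M, G @ x, rcond=None)[0]
        A = a.reshape(k, r)
        resid = x - (A @ B).ravel()
        obj = float(resid @ Cinv @ resid)
        if obj_prev - obj <= tolerance * max(obj_prev, 1.0):
            converged = True
            break
        obj_prev = obj
    return A, B, obj, converged


def _fit_rank_one_of_two(x, Cinv, n):
    """Global rank-1 fit for a 2 x n matrix by profiling out B.

    For a fixed left direction a = (cos t, sin t) the optimal row vector b
    solves a linear GLS system, leaving a smooth 1-D profile objective in t
    which is minimized by a coarse grid plus Brent refinement.  This avoids
    the local minima of alternating least squares and makes the fit exactly
    equivariant under source reordering and reference re-basing.
    """
    from scipy.optimize import minimize_scalar

    P11, P12, P22 = Cinv[:n, :n], Cinv[:n, n:], Cinv[n:, n:]
    x1, x2 = x[:n], x[n:]
    u1 = P11 @ x1 + P12 @ x2
    u2 = P12.T @ x1 + P22 @ x2
    c0 = float(x1 @ u1 + x2 @ u2)
    P12s = P12 + P12.T

    def profile(t):
        a1, a2 = np.cos(t), np.sin(t)
        S = a1 * a1 * P11 + a1 * a2 * P12s + a2 * a2 * P22
        m = a1 * u1 + a2 * u2
        try:
            return c0 - float(m @ np.linalg.solve(S, m))
        except np.linalg.LinAlgError:
            return c0 - float(m @ np.linalg.lstsq(S, m, rcond=None)[0])

    grid = np.linspace(0.0, np.pi, 49)[:-1]
    vals = np.array([profile(t) for t in grid])
    j = int(np.argmin(vals))
    lo, hi = grid[j] - np.pi / 48, grid[j] + np.pi / 48
    res = minimize_scalar(profile, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    t = float(res.x) if res.fun <= vals[j] else grid[j]
    a = np.array([np.cos(t), np.sin(t)])
    S = a[0] ** 2 * P11 + a[0] * a[1] * P12s + a[1] ** 2 * P22
    m = a[0] * u1 + a[1] * u2
    try:
        b = np.linalg.solve(S, m)
    except np.linalg.LinAlgError:
        b = np.linalg.lstsq(S, m, rcond=None)[0]
    E = np.outer(a, b)
    resid = x - E.ravel()
    obj = float(resid @ (Cinv @ resid))
    return E, obj, True


def fit_rank(
    X: np.ndarray,
    cov: np.ndarray,
    r: int,
    max_iterations: int = 100,
    tolerance: float = 1e-10,
    regularization: float = 1e-10,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    n_restarts: int = 8,
) -> tuple[np.ndarray, float, bool]:
    """GLS projection of X onto matrices of rank <= r.

    Minimizes ``vec(X - E)' cov^-1 vec(X - E)`` over ``E = A @ B`` with
    ``A (k x r)``, ``B (r x n)``.  The two-source case (k = 2, r = 1) is
    solved globally by a 1-D profile search; other shapes use alternating
    weighted least squares from the truncated SVD of X (or ``init``) plus
    ``n_restarts`` deterministic random restarts, keeping the best optimum.
    Returns ``(E, objective, converged)``; the objective is the
    likelihood-ratio statistic of the rank constraint.
    """
    X = np.asarray(X, dtype=float)
    k, n = X.shape
    if not 0 <= r <= min(k, n):
        raise ValueError(f"rank {r} outside [0, {min(k, n)}]")
    x = X.ravel()
    Cinv = _regularized_inverse(np.asarray(cov, dtype=float), regularization)
    if r == min(k, n):
        return X.copy(), 0.0, True
    if r == 0:
        return np.zeros_like(X), float(x @ Cinv @ x), True
    if k == 2 and r == 1:
        return _fit_rank_one_of_two(x, Cinv, n)

    if init is None:
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        inits = [(U[:, :r] * S[:r], Vt[:r].copy())]
    else:
        inits = [(init[0].copy(), init[1].copy())]
    rng = np.random.default_rng(1729)
    scale = max(np.abs(X).max(), 1e-300)
    for _ in range(n_restarts):
        inits.append((rng.normal(size=(k, r)) * scale, rng.normal(size=(r, n))))

    best = (None, np.inf, False)
    for A0, B0 in inits:
        A, B, obj, conv = _als_once(x, Cinv, k, n, r, A0, B0,
                                    max_iterations, tolerance)
        if obj < best[1]:
            best = (A @ B, obj, conv)
    return best


def _weights_from_fit(E: np.ndarray) -> np.ndarray:
    """Left-null vector of the fitted matrix, normalized to sum to 1."""
    k = E.shape[0]
    if k == 1:
        return np.array([1.0])
    U, S, Vt = np.linalg.svd(E)
    w = U[:, -1]
    s = w.sum()
    if abs(s) < 1e-12:
        # degenerate null direction orthogonal to 1; report the direction of
        # smallest singular value with unit L1 mass and the sign of the
        # largest component
        s = np.sign(w[np.argmax(np.abs(w))]) * np.abs(w).sum()
    return w / s


def _weighted_jackknife_ses(
    w_hat: np.ndarray, w_loo: np.ndarray, block_weights: np.ndarray
) -> np.ndarray:
    """Weighted delete-one-block jackknife SE per weight component.

    ``w_loo`` has shape (n_blocks, k); ``block_weights`` are the per-block
    site counts (blocks with zero weight are skipped).
    """
    m = np.asarray(block_weights, dtype=float)
    keep = m > 0
    m, w_loo = m[keep], w_loo[keep]
    B = len(m)
    n = m.sum()
    h = n / m
    theta_J = B * w_hat - ((1.0 - m / n)[:, None] * w_loo).sum(axis=0)
    tau = (h[:, None] * w_hat - (h - 1.0)[:, None] * w_loo - theta_J) / np.sqrt(
        h - 1.0
    )[:, None]
    return np.sqrt((tau**2).sum(axis=0) / B)


# ---------------------------------------------------------------------------
# the qpAdm fit
# ---------------------------------------------------------------------------

def qpadm(
    G_or_ws: GenotypeMatrix | F4Workspace,
    model: QpAdmModel,
    options: QpAdmOptions | None = None,
) -> QpAdmFit:
    """Fit a k-source admixture model and test its plausibility.

    Returns the likelihood-ratio statistic of the rank-(k-1) constraint, its
    chi-squared P-value on ``n_R - k`` degrees of freedom, admixture weights
    with delete-one-block jackknife standard errors, and the plausibility
    verdict (P above threshold and all weights in [0, 1]).
    """
    options = options or QpAdmOptions()
    f4vec = build_f4_design(G_or_ws, model, options)
    k, n = model.k, len(model.references) - 1
    X = f4vec.estimates.reshape(k, n)
    r = k - 1

    E, stat, converged = fit_rank(
        X, f4vec.covariance, r,
        max_iterations=options.max_iterations,
        tolerance=options.tolerance,
        regularization=options.regularization,
    )
    df = len(model.references) - k
    if k == 1:
        # The clade statistic is exactly a Hotelling T^2 form (quadratic form
        # of block-jackknife means in their estimated covariance); refer it
        # to its finite-block F distribution rather than the large-block
        # chi-squared limit, which is anticonservative when the number of
        # blocks is not much larger than the dimension.
        n_blocks = int((f4vec.block_counts > 0).sum(axis=1).min())
        if n_blocks > df + 1:
            p_value = float(stats.f.sf(
                stat * (n_blocks - df) / (df * (n_blocks - 1)), df, n_blocks - df
            ))
        else:
            p_value = float(stats.chi2.sf(stat, df))
    else:
        p_value = float(stats.chi2.sf(stat, df))
    weights = _weights_from_fit(E) if r > 0 else np.array([1.0])

    weight_ses = np.full(k, np.nan)
    if options.weight_se and k > 1:
        Cinv_fixed = f4vec.covariance  # same metric for every delete-one fit
        nb = f4vec.block_counts.shape[1]
        block_weights = f4vec.block_counts.mean(axis=0)
        w_loo = np.empty((nb, k))
        init = None
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        init = (U[:, :r] * S[:r], Vt[:r])
        for b in range(nb):
            Xb = f4vec.delete_block(b).reshape(k, n)
            Eb, _, _ = fit_rank(
                Xb, Cinv_fixed, r,
                max_iterations=25, tolerance=1e-9,
                regularization=options.regularization, init=init, n_restarts=1,
            )
            w_loo[b] = _weights_from_fit(Eb)
        weight_ses = _weighted_jackknife_ses(weights, w_loo, block_weights)
    elif k == 1:
        weight_ses = np.array([0.0])

    plausible = bool(
        p_value > options.p_threshold
        and np.all(weights >= 0.0)
        and np.all(weights <= 1.0)
    )
    return QpAdmFit(
        model=model,
        weights=weights,
        weight_ses=weight_ses,
        statistic=stat,
        df=df,
        p_value=p_value,
        n_snps_used=float(f4vec.block_counts.sum(axis=1).mean()),
        plausible=plausible,
        converged=converged,
        policy=options.policy,
        f4=f4vec,
    )


def clade_test(
    G_or_ws: GenotypeMatrix | F4Workspace,
    target: str,
    source: str,
    references: list[str],
    options: QpAdmOptions | None = None,
) -> QpAdmFit:
    """Single-source (k = 1) model: does ``target`` form a clade with
    ``source`` relative to the references?

    Tests the 1 x (n_R - 1) f4 row against rank 0 with ``n_R - 1`` degrees
    of freedom; the weight is trivially 1.
    """
    model = QpAdmModel(target=target, sources=[source], references=list(references))
    return qpadm(G_or_ws, model, options)
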