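"""REML variance-component estimation and the boundary likelihood-ratio test.

Models are linear mixed models on the observed 0/1 disease scale,

    y = X b + u + e            (null: genome-wide component only)
    y = X b + u + w + e        (alternative: plus one regional component)

with Var(u) = G su2, Var(w) = Q sw2, Var(e) = I se2, where G is the
whole-genome GRM and Q a regional GRM.  Estimation is restricted maximum
likelihood: one EM step from the starting values for stability, then
average-information (AI) updates with step-halving, components constrained
at a small positive floor.  The regional variance is tested at its boundary,
so the LRT is referred to a 50-50 mixture of chi-square(0) and chi-square(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.stats import chi2

RESIDUAL = "residual"


class NumericError(RuntimeError):
    """Singular covariance or design encountered during REML."""


@dataclass
class ModelSpec:
    """Phenotype, fixed effects, and named genetic covariance structures.

    ``structures`` lists (name, matrix) pairs for the genetic components;
    the residual identity component is implicit and always last.
    """

    y: np.ndarray
    X: np.ndarray
    structures: list

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValueError("X rows must match length of y")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X is not of full column rank")
        for name, k in self.structures:
            if k.shape != (n, n):
                raise ValueError(f"structure {name!r} has wrong shape")

    @property
    def n(self) -> int:
        return self.y.size

    def component_names(self) -> list:
        return [name for name, _ in self.structures] + [RESIDUAL]

    def kernels(self) -> list:
        return [k for _, k in self.structures] + [np.eye(self.n)]


@dataclass
class VarianceEstimate:
    """One REML fit: components, SEs, log-likelihood, convergence record."""

    names: list
    components: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    constrained: np.ndarray
    trace: list = field(default_factory=list)

    @property
    def phenotypic_variance(self) -> float:
        return float(self.components.sum())

    def component(self, name: str) -> float:
        return float(self.components[self.names.index(name)])

    def ratio(self, name: str) -> float:
        """Variance share of one component, e.g. observed-scale h2."""
        return self.component(name) / self.phenotypic_variance

    def ratio_se(self, name: str) -> float:
        """Delta-method SE of the variance share."""
        i = self.names.index(name)
        s = self.phenotypic_variance
        grad = np.full(len(self.names), -self.components[i] / s**2)
        grad[i] += 1.0 / s
        return float(np.sqrt(grad @ self.cov @ grad))


@dataclass
class LrtResult:
    """Likelihood-ratio test of the regional variance component."""

    loglik_null: float
    loglik_alt: float
    lrt: float
    p_value: float
    optimizer_failure: bool = False


def _build_v(kernels, comps):
    n = kernels[0].shape[0]
    v = np.zeros((n, n))
    for c, k in zip(comps, kernels):
        v += c * k
    return v


def _reml_ll_only(y, X, kernels, comps):
    """Restricted log-likelihood alone (cheap: one Cholesky, no inverse)."""
    v = _build_v(kernels, comps)
    try:
        cho = cho_factor(v, lower=True, check_finite=False)
    except LinAlgError as exc:
        raise NumericError(f"V singular at components {comps}") from exc
    logdet_v = 2.0 * np.log(np.diag(cho[0])).sum()
    vix = cho_solve(cho, X, check_finite=False)
    viy = cho_solve(cho, y, check_finite=False)
    xtvix = X.T @ vix
    try:
        cho_x = cho_factor(xtvix, lower=True, check_finite=False)
    except LinAlgError as exc:
        raise NumericError("X' V^-1 X singular") from exc
    logdet_x = 2.0 * np.log(np.diag(cho_x[0])).sum()
    xtviy = X.T @ viy
    ypy = float(y @ viy - xtviy @ cho_solve(cho_x, xtviy, check_finite=False))
    return -0.5 * (logdet_v + logdet_x + ypy)


def _reml_pieces(y, X, kernels, comps):
    """Log-likelihood plus the gradient/AI ingredients at ``comps``."""
    n = y.size
    v = _build_v(kernels, comps)
    try:
        cho = cho_factor(v, lower=True, check_finite=False)
    except LinAlgError as exc:
        raise NumericError(f"V singular at components {comps}") from exc
    logdet_v = 2.0 * np.log(np.diag(cho[0])).sum()
    vi = cho_solve(cho, np.eye(n), check_finite=False)
    vix = vi @ X
    xtvix = X.T @ vix
    try:
        cho_x = cho_factor(xtvix, lower=True, check_finite=False)
    except LinAlgError as exc:
        raise NumericError("X' V^-1 X singular") from exc
    logdet_x = 2.0 * np.log(np.diag(cho_x[0])).sum()
    p = vi - vix @ cho_solve(cho_x, vix.T, check_finite=False)
    py = p @ y
    ypy = float(y @ py)
    ll = -0.5 * (logdet_v + logdet_x + ypy)
    # score: dl/dc_i = -0.5 (tr(P K_i) - y'P K_i P y)
    kpy = np.column_stack([k @ py for k in kernels])
    tr_pk = np.array([float(np.sum(p * k)) for k in kernels])
    quad = np.array([float(py @ kpy[:, i]) for i in range(len(kernels))])
    grad = -0.5 * (tr_pk - quad)
    pkpy = p @ kpy
    ai = 0.5 * (kpy.T @ pkpy)
    return ll, grad, ai, tr_pk, quad


def reml_loglik(spec: ModelSpec, components: Sequence[float]) -> float:
    """Restricted log-likelihood (constant omitted) at fixed components.

    Returns -1/2 [ log|V| + log|X'V^-1 X| + y'Py ].
    """
    comps = np.asarray(components, dtype=float)
    if (comps < 0).any() or not comps.any():
        raise ValueError("components must be >= 0 and not all zero")
    ll, *_ = _reml_pieces(spec.y, spec.X, spec.kernels(), comps)
    return ll


def fit_reml(
    spec: ModelSpec,
    start: Optional[Sequence[float]] = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    floor_frac: float = 1e-6,
) -> VarianceEstimate:
    """AI-REML fit of all variance components.

    One EM-REML step from the start values, then AI updates with up to ten
    step-halvings whenever the restricted log-likelihood would decrease
    (falling back to an EM step if halving fails).  Components dropping
    below the floor (``floor_frac`` x phenotypic variance) are constrained
    there and flagged.  Convergence: |delta logL| < ``tol``.  On
    non-convergence the best estimate is returned with ``converged=False``;
    no exception is raised.
    """
    y, X = spec.y, spec.X
    kernels = spec.kernels()
    names = spec.component_names()
    n_comp = len(kernels)
    vp = float(np.var(y, ddof=1))
    floor = floor_frac * vp
    if start is None:
        comps = np.full(n_comp, vp / n_comp)
    else:
        comps = np.maximum(np.asarray(start, dtype=float), floor)

    n = y.size
    trace = []
    ll, grad, ai, tr_pk, quad = _reml_pieces(y, X, kernels, comps)
    # one EM step: c_i <- c_i + c_i^2 (y'P K_i P y - tr(P K_i)) / n
    comps = np.maximum(comps + comps**2 * (quad - tr_pk) / n, floor)
    ll, grad, ai, tr_pk, quad = _reml_pieces(y, X, kernels, comps)
    trace.append((0, ll, comps.copy()))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # active-set Newton: components pinned at the floor that still want
        # to decrease are held out of the AI solve, otherwise their large
        # negative gradients drag the free components into a zigzag
        pinned = (comps <= floor * (1 + 1e-9)) & (grad < 0)
        free = ~pinned
        delta = np.zeros(n_comp)
        if free.any():
            ai_f = ai[np.ix_(free, free)]
            try:
                delta[free] = np.linalg.solve(ai_f, grad[free])
            except np.linalg.LinAlgError:
                delta[free] = np.linalg.lstsq(ai_f, grad[free], rcond=None)[0]
        step = 1.0
        accepted = False
        for _ in range(11):  # full step + up to 10 halvings
            cand = np.maximum(comps + step * delta, floor)
            try:
                cand_ll = _reml_ll_only(y, X, kernels, cand)
            except NumericError:
                step *= 0.5
                continue
            if cand_ll >= ll - 1e-10:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # EM fallback step (guaranteed ascent direction)
            cand = np.maximum(comps + comps**2 * (quad - tr_pk) / n, floor)
        res = _reml_pieces(y, X, kernels, cand)
        new_ll = res[0]
        d_ll = new_ll - ll
        comps, (ll, grad, ai, tr_pk, quad) = cand, res
        trace.append((it, ll, comps.copy()))
        if abs(d_ll) < tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(ai)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return VarianceEstimate(
        names=names,
        components=comps,
        se=se,
        cov=cov,
        loglik=ll,
        converged=converged,
        n_iter=it,
        constrained=comps <= floor * (1 + 1e-9),
        trace=trace,
    )


def lrt_regional(
    null_fit: VarianceEstimate,
    alt_fit: VarianceEstimate,
    tol: float = 1e-3,
) -> LrtResult:
    """LRT = -2 ln(L0/L1) for the regional component, with the boundary
    50-50 chi-square(0):chi-square(1) mixture p-value.

    LRT is floored at zero; an alternative log-likelihood materially below
    the null indicates an optimizer failure and is flagged.  LRT = 0 maps
    to p = 0.5 (the mixture's point mass).
    """
    l0, l1 = null_fit.loglik, alt_fit.loglik
    lrt = 2.0 * (l1 - l0)
    failure = lrt < -tol
    lrt = max(0.0, lrt)
    p = 0.5 * float(chi2.sf(lrt, df=1))
    return LrtResult(l0, l1, lrt, p, optimizer_failure=failure)
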