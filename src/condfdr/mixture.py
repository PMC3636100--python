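"""Gaussian mixture models for polygenicity and power analysis.

Univariate two-groups model: a z-score is null with probability pi0 and
drawn from N(0, sigma0_sq); with probability 1 - pi0 it is non-null and
drawn from N(0, sigma0_sq + sigma1_sq) — the non-null score is the null
sampling noise plus an independent zero-mean effect.  The local false
discovery rate at z is the posterior null probability pi0 f0(z) / f(z).

Bivariate four-groups model for two phenotypes: a SNP is null for both
(pi0), non-null only for trait 1 (pi1), only for trait 2 (pi2), or for both
(pi3, the pleiotropic component).  Each component is a zero-mean bivariate
Gaussian: the shared null sampling covariance is diagonal, components 1 and
2 add effect variance only to their own coordinate, and the pleiotropic
component has a free positive-semidefinite 2x2 effect covariance, allowing
correlated cross-trait effects.

Both models are fitted by expectation-maximization on the exact
latent-effect formulation z = u + e (e the null noise, u the effect, zero in
null components), which keeps every M-step closed-form and the observed-data
log-likelihood monotone across iterations.  Fits use multiple random
restarts; z-scores enter as magnitudes mirrored to +/- (the model is
symmetric and sign information is not used).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

DEFAULT_RESTARTS = 5
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 10_000
_VAR_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Two-groups model


@dataclass
class TwoGroupsFit:
    """Parameters of the univariate two-groups scale mixture."""

    pi0: float
    sigma0_sq: float
    sigma1_sq: float
    loglik: float
    n_iter: int = 0
    converged: bool = True
    boundary: bool = False  # pi0 or sigma1_sq at/near the parameter boundary
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0

    @property
    def nonnull_variance(self) -> float:
        return self.sigma0_sq + self.sigma1_sq


def _norm_logpdf(z, var):
    return -0.5 * (np.log(2 * np.pi * var) + z**2 / var)


def two_groups_loglik(z, pi0, sigma0_sq, sigma1_sq) -> float:
    """Observed-data log-likelihood of the two-groups model."""
    z = np.asarray(z, dtype=float)
    comps = np.stack([
        np.log(max(pi0, 1e-320)) + _norm_logpdf(z, sigma0_sq),
        np.log(max(1 - pi0, 1e-320)) + _norm_logpdf(z, sigma0_sq + sigma1_sq),
    ])
    return float(logsumexp(comps, axis=0).sum())


def fit_two_groups(z, init: TwoGroupsFit | None = None, seed: int = 0,
                   restarts: int = DEFAULT_RESTARTS, tol: float = DEFAULT_TOL,
                   max_iter: int = DEFAULT_MAX_ITER) -> TwoGroupsFit:
    """Maximum-likelihood EM fit of the two-groups model.

    Runs ``restarts`` random initializations (plus ``init`` if given) and
    returns the best fit.  Degenerate solutions (sigma1_sq -> 0 or pi0 at a
    boundary) are reported with ``boundary=True`` rather than raised.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("no finite z-scores to fit")
    z2 = z**2
    rng = np.random.default_rng(seed)

    starts: list[tuple[float, float, float]] = []
    if init is not None:
        starts.append((init.pi0, init.sigma0_sq, init.sigma1_sq))
    base_var = float(np.median(z2) / 0.454936423119572)  # robust null variance
    for _ in range(restarts):
        pi0_0 = float(np.clip(rng.uniform(0.8, 0.999), 1e-3, 1 - 1e-3))
        v0_0 = base_var * rng.uniform(0.7, 1.1)
        v1_0 = base_var * rng.uniform(1.5, 10.0)
        starts.append((pi0_0, v0_0, v1_0 - v0_0))

    best: TwoGroupsFit | None = None
    for pi0_0, s0_0, s1_0 in starts:
        fit = _em_two_groups(z2, pi0_0, s0_0, max(s1_0, 1e-3), tol, max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def _em_two_groups(z2, pi0, v0, t1, tol, max_iter) -> TwoGroupsFit:
    """EM on the latent-effect formulation; v0 null variance, t1 effect var."""
    n = z2.size
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        v1 = v0 + t1
        log_r0 = np.log(max(pi0, 1e-320)) - 0.5 * (np.log(2 * np.pi * v0) + z2 / v0)
        log_r1 = np.log(max(1 - pi0, 1e-320)) - 0.5 * (np.log(2 * np.pi * v1) + z2 / v1)
        log_norm = np.logaddexp(log_r0, log_r1)
        ll = float(log_norm.sum())
        trace.append(ll)
        g1 = np.exp(log_r1 - log_norm)
        g0 = 1.0 - g1

        # posterior moments of the latent effect u (non-null component):
        # u | z ~ N(w z / v0 ... ) with w = t1 v0 / (t1 + v0)
        w = t1 * v0 / v1
        m2 = (t1 / v1) ** 2 * z2 + w      # E[u^2 | z, non-null]
        e2_1 = (v0 / v1) ** 2 * z2 + w    # E[(z-u)^2 | z, non-null]

        s_g1 = g1.sum()
        pi0 = float(g0.sum() / n)
        v0 = float((g0 @ z2 + g1 @ e2_1) / n)
        t1 = float((g1 @ m2) / s_g1) if s_g1 > 0 else 0.0
        v0 = max(v0, _VAR_FLOOR)
        t1 = max(t1, 0.0)

        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = ll

    loglik = two_groups_loglik(np.sqrt(z2), pi0, v0, t1)
    # degenerate when indistinguishable from a single zero-mean Gaussian
    ll_single = float(_norm_logpdf(np.sqrt(z2), np.mean(z2)).sum())
    boundary = (t1 < 1e-4 or pi0 < 1e-3 or pi0 > 1 - 1e-6
                or 2 * (loglik - ll_single) < 6.0)
    if boundary:
        logger.info("two-groups fit at parameter boundary (pi0=%.4g, sigma1_sq=%.4g)",
                    pi0, t1)
    return TwoGroupsFit(pi0=pi0, sigma0_sq=v0, sigma1_sq=t1, loglik=loglik,
                        n_iter=it, converged=converged, boundary=boundary,
                        loglik_trace=np.asarray(trace))


def local_fdr(z, fit: TwoGroupsFit):
    """Local false discovery rate pi0 f0(z) / f(z); in (0, 1], symmetric in z,
    non-increasing in |z| when sigma1_sq > 0."""
    z = np.asarray(z, dtype=float)
    log_f0 = np.log(max(fit.pi0, 1e-320)) + _norm_logpdf(z, fit.sigma0_sq)
    log_f1 = np.log(max(fit.pi1, 1e-320)) + _norm_logpdf(z, fit.nonnull_variance)
    out = np.exp(log_f0 - np.logaddexp(log_f0, log_f1))
    if np.ndim(z) == 0:
        return float(out)
    return out


def fdr_cutpoint(fit: TwoGroupsFit, level: float, z_max: float = 50.0,
                 tol: float = 1e-6) -> float:
    """Smallest |z| with local fdr <= level, by bisection.

    Returns ``inf`` when the level is unattainable (local fdr never dips
    below it, e.g. sigma1_sq = 0).
    """
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    if local_fdr(0.0, fit) <= level:
        return 0.0
    if fit.sigma1_sq <= 0 or local_fdr(z_max, fit) > level:
        logger.warning("local fdr never reaches %g; cutpoint unattainable", level)
        return float("inf")
    lo, hi = 0.0, z_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if local_fdr(mid, fit) <= level:
            hi = mid
        else:
            lo = mid
    return hi


def scale_effective_n(fit: TwoGroupsFit, factor: float) -> TwoGroupsFit:
    """Rescale the fit for a hypothetical change in effective sample size.

    The non-null effect variance component scales linearly with effective n
    (chi-square non-centrality grows with sample size) while the null
    sampling variance is unchanged.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return TwoGroupsFit(pi0=fit.pi0, sigma0_sq=fit.sigma0_sq,
                        sigma1_sq=factor * fit.sigma1_sq, loglik=np.nan,
                        n_iter=fit.n_iter, converged=fit.converged,
                        boundary=fit.boundary)


# ---------------------------------------------------------------------------
# Four-groups bivariate model


@dataclass
class FourGroupsFit:
    """Parameters of the bivariate four-groups mixture.

    ``pi`` are the mixing proportions (null/null, trait-1 only, trait-2
    only, both).  ``sigma0_sq`` is the per-trait null sampling variance
    (shared across components), ``sigma1_sq``/``sigma2_sq`` the single-trait
    effect variances, and ``effect_cov3`` the 2x2 PSD effect covariance of
    the pleiotropic component.
    """

    pi: np.ndarray
    sigma0_sq: np.ndarray            # (2,) null variances
    sigma1_sq: float                 # trait-1 effect variance, component 1
    sigma2_sq: float                 # trait-2 effect variance, component 2
    effect_cov3: np.ndarray          # (2, 2) effect covariance, component 3
    loglik: float
    n_iter: int = 0
    converged: bool = True
    boundary: bool = False
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def pi0(self) -> float:
        return float(self.pi[0])

    @property
    def pi3(self) -> float:
        return float(self.pi[3])

    @property
    def rho3(self) -> float:
        """Correlation of the pleiotropic component's non-null effects."""
        v1, v2 = self.effect_cov3[0, 0], self.effect_cov3[1, 1]
        if v1 <= 0 or v2 <= 0:
            return 0.0
        return float(self.effect_cov3[0, 1] / np.sqrt(v1 * v2))

    @property
    def covariances(self) -> list[np.ndarray]:
        """Observed-score covariance of each of the four components."""
        s = np.diag(self.sigma0_sq)
        return [
            s.copy(),
            s + np.diag([self.sigma1_sq, 0.0]),
            s + np.diag([0.0, self.sigma2_sq]),
            s + self.effect_cov3,
        ]


def _bvn_logpdf(z1, z2, cov):
    v1, v2, c = cov[0, 0], cov[1, 1], cov[0, 1]
    det = v1 * v2 - c * c
    det = max(det, 1e-300)
    quad = (v2 * z1**2 - 2 * c * z1 * z2 + v1 * z2**2) / det
    return -0.5 * (2 * np.log(2 * np.pi) + np.log(det) + quad)


def four_groups_loglik(z1, z2, pi, covs) -> float:
    """Observed-data log-likelihood of a four-groups parameterization."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    logs = np.stack([
        np.log(max(float(p), 1e-320)) + _bvn_logpdf(z1, z2, cov)
        for p, cov in zip(pi, covs)
    ])
    return float(logsumexp(logs, axis=0).sum())


def fit_four_groups(z1, z2, init: FourGroupsFit | None = None, seed: int = 0,
                    restarts: int = DEFAULT_RESTARTS, tol: float = DEFAULT_TOL,
                    max_iter: int = DEFAULT_MAX_ITER) -> FourGroupsFit:
    """Maximum-likelihood EM fit of the four-groups bivariate mixture.

    z-scores are paired by SNP.  The component structure (which coordinate a
    component inflates) makes labels identifiable, so no post-hoc relabeling
    is needed; boundary fits (a vanishing component or effect variance) are
    flagged, not raised.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("z1 and z2 must be paired (same length)")
    ok = np.isfinite(z1) & np.isfinite(z2)
    z1, z2 = z1[ok], z2[ok]
    if z1.size == 0:
        raise ValueError("no finite z-score pairs to fit")
    rng = np.random.default_rng(seed)

    starts = []
    if init is not None:
        starts.append((np.asarray(init.pi, dtype=float),
                       np.asarray(init.sigma0_sq, dtype=float),
                       init.sigma1_sq, init.sigma2_sq,
                       np.asarray(init.effect_cov3, dtype=float)))
    base1 = float(np.median(z1**2) / 0.454936423119572)
    base2 = float(np.median(z2**2) / 0.454936423119572)
    for _ in range(restarts):
        raw = rng.uniform(0.5, 1.5, size=3) * np.array([0.01, 0.01, 0.01])
        pi = np.array([1 - raw.sum(), *raw])
        t1 = base1 * rng.uniform(1.0, 8.0)
        t2 = base2 * rng.uniform(1.0, 8.0)
        rho = rng.uniform(-0.3, 0.7)
        cov3 = np.array([[t1, rho * np.sqrt(t1 * t2)],
                         [rho * np.sqrt(t1 * t2), t2]])
        starts.append((pi, np.array([base1, base2]), t1, t2, cov3))

    best: FourGroupsFit | None = None
    for pi, s0, t1, t2, cov3 in starts:
        fit = _em_four_groups(z1, z2, pi.copy(), s0.copy(), t1, t2,
                              cov3.copy(), tol, max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def _em_four_groups(z1, z2, pi, s0, t1, t2, cov3, tol, max_iter) -> FourGroupsFit:
    n = z1.size
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    z1sq, z2sq, z12 = z1**2, z2**2, z1 * z2
    for it in range(1, max_iter + 1):
        covs = [np.diag(s0),
                np.diag(s0) + np.diag([t1, 0.0]),
                np.diag(s0) + np.diag([0.0, t2]),
                np.diag(s0) + cov3]
        logs = np.stack([
            np.log(max(float(p), 1e-320)) + _bvn_logpdf(z1, z2, cov)
            for p, cov in zip(pi, covs)
        ])
        log_norm = logsumexp(logs, axis=0)
        ll = float(log_norm.sum())
        trace.append(ll)
        g = np.exp(logs - log_norm)  # (4, n) responsibilities
        gsum = g.sum(axis=1)

        # E-step latent-effect moments.
        # Component 1: u1 | z1 ~ N(a z1, w1), a = t1/(t1+s1)
        w1 = t1 * s0[0] / (t1 + s0[0]) if t1 > 0 else 0.0
        a1 = t1 / (t1 + s0[0]) if t1 > 0 else 0.0
        Eu1sq_c1 = a1**2 * z1sq + w1
        Ee1sq_c1 = (1 - a1) ** 2 * z1sq + w1
        # Component 2 symmetric in trait 2
        w2 = t2 * s0[1] / (t2 + s0[1]) if t2 > 0 else 0.0
        a2 = t2 / (t2 + s0[1]) if t2 > 0 else 0.0
        Eu2sq_c2 = a2**2 * z2sq + w2
        Ee2sq_c2 = (1 - a2) ** 2 * z2sq + w2
        # Component 3: u | z ~ N(Mz, W), M = T (T + S)^-1, W = T - M T
        S = np.diag(s0)
        TpS = cov3 + S
        det = TpS[0, 0] * TpS[1, 1] - TpS[0, 1] ** 2
        det = max(det, 1e-300)
        inv = np.array([[TpS[1, 1], -TpS[0, 1]],
                        [-TpS[0, 1], TpS[0, 0]]]) / det
        M = cov3 @ inv
        W = cov3 - M @ cov3
        m1 = M[0, 0] * z1 + M[0, 1] * z2
        m2 = M[1, 0] * z1 + M[1, 1] * z2
        Eu1sq_c3 = m1**2 + W[0, 0]
        Eu2sq_c3 = m2**2 + W[1, 1]
        Eu12_c3 = m1 * m2 + W[0, 1]
        Ee1sq_c3 = (z1 - m1) ** 2 + W[0, 0]
        Ee2sq_c3 = (z2 - m2) ** 2 + W[1, 1]

        # M-step
        pi = gsum / n
        s0 = np.array([
            (g[0] @ z1sq + g[1] @ Ee1sq_c1 + g[2] @ z1sq + g[3] @ Ee1sq_c3) / n,
            (g[0] @ z2sq + g[1] @ z2sq + g[2] @ Ee2sq_c2 + g[3] @ Ee2sq_c3) / n,
        ])
        s0 = np.maximum(s0, _VAR_FLOOR)
        t1 = float(g[1] @ Eu1sq_c1 / gsum[1]) if gsum[1] > 1e-12 else t1
        t2 = float(g[2] @ Eu2sq_c2 / gsum[2]) if gsum[2] > 1e-12 else t2
        if gsum[3] > 1e-12:
            c11 = float(g[3] @ Eu1sq_c3 / gsum[3])
            c22 = float(g[3] @ Eu2sq_c3 / gsum[3])
            c12 = float(g[3] @ Eu12_c3 / gsum[3])
            # clamp to PSD (|corr| <= 1) against numerical drift
            bound = np.sqrt(max(c11, _VAR_FLOOR) * max(c22, _VAR_FLOOR))
            c12 = float(np.clip(c12, -0.999 * bound, 0.999 * bound))
            cov3 = np.array([[max(c11, _VAR_FLOOR), c12],
                             [c12, max(c22, _VAR_FLOOR)]])
        t1 = max(t1, _VAR_FLOOR)
        t2 = max(t2, _VAR_FLOOR)

        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = ll

    covs = [np.diag(s0), np.diag(s0) + np.diag([t1, 0.0]),
            np.diag(s0) + np.diag([0.0, t2]), np.diag(s0) + cov3]
    loglik = four_groups_loglik(z1, z2, pi, covs)
    # degenerate when indistinguishable from a single bivariate Gaussian
    cov_mle = np.array([[np.mean(z1sq), np.mean(z12)],
                        [np.mean(z12), np.mean(z2sq)]])
    ll_single = float(_bvn_logpdf(z1, z2, cov_mle).sum())
    boundary = bool(np.any(pi < 1e-6) or t1 < 1e-4 or t2 < 1e-4
                    or cov3[0, 0] < 1e-4 or cov3[1, 1] < 1e-4
                    or 2 * (loglik - ll_single) < 12.0)
    return FourGroupsFit(pi=pi, sigma0_sq=s0, sigma1_sq=t1, sigma2_sq=t2,
                         effect_cov3=cov3, loglik=loglik, n_iter=it,
                         converged=converged, boundary=boundary,
                         loglik_trace=np.asarray(trace))


# ---------------------------------------------------------------------------
# Local fdr from the bivariate fit


def conditional_local_fdr(z1, z2, fit: FourGroupsFit):
    """Posterior probability the SNP is null for trait 1 given (z1, z2):

    (pi0 f0 + pi2 f2) / (pi0 f0 + pi1 f1 + pi2 f2 + pi3 f3).
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    covs = fit.covariances
    logs = np.stack([
        np.log(max(float(p), 1e-320)) + _bvn_logpdf(z1, z2, cov)
        for p, cov in zip(fit.pi, covs)
    ])
    log_null1 = np.logaddexp(logs[0], logs[2])
    out = np.exp(log_null1 - logsumexp(logs, axis=0))
    if np.ndim(z1) == 0 and np.ndim(z2) == 0:
        return float(out)
    return out


def marginal_local_fdr(z1, fit: FourGroupsFit, trait: int = 0):
    """Unconditional (trait-marginal) local fdr from the four-groups fit.

    The trait's marginal is itself a mixture: null with weight pi0 + pi_other
    and variance sigma0_sq, plus two non-null components.
    """
    z1 = np.asarray(z1, dtype=float)
    weights, variances, is_null = _marginal_components(fit, trait)
    logs = np.stack([
        np.log(max(w, 1e-320)) + _norm_logpdf(z1, v)
        for w, v in zip(weights, variances)
    ])
    log_null = logsumexp(logs[is_null], axis=0)
    out = np.exp(log_null - logsumexp(logs, axis=0))
    if np.ndim(z1) == 0:
        return float(out)
    return out


def _marginal_components(fit: FourGroupsFit, trait: int):
    s = float(fit.sigma0_sq[trait])
    if trait == 0:
        weights = [fit.pi[0] + fit.pi[2], fit.pi[1], fit.pi[3]]
        variances = [s, s + fit.sigma1_sq, s + fit.effect_cov3[0, 0]]
    else:
        weights = [fit.pi[0] + fit.pi[1], fit.pi[2], fit.pi[3]]
        variances = [s, s + fit.sigma2_sq, s + fit.effect_cov3[1, 1]]
    is_null = np.array([True, False, False])
    return np.asarray(weights, dtype=float), np.asarray(variances, dtype=float), is_null


# ---------------------------------------------------------------------------
# Power / ROC curves


def power_curve(fit, levels, mode: str = "unconditional", trait: int = 0,
                z_range: float = 15.0, step: float = 0.01):
    """Sensitivity P(local fdr <= level | non-null) over fdr levels.

    For a :class:`TwoGroupsFit` the integration is over the univariate
    non-null density.  For a :class:`FourGroupsFit`, ``mode`` selects the
    unconditional (trait-marginal) local fdr or the conditional local fdr
    using the other trait's z-score; the non-null density is the trait's
    non-null mixture (components where the trait is non-null).  Numeric
    integration on a fixed grid over [-z_range, z_range].
    """
    levels = np.atleast_1d(np.asarray(levels, dtype=float))
    if isinstance(fit, TwoGroupsFit):
        z = np.arange(-z_range, z_range + step / 2, step)
        fdr = local_fdr(z, fit)
        dens = np.exp(_norm_logpdf(z, fit.nonnull_variance))
        total = dens.sum()
        sens = np.array([(dens * (fdr <= lvl)).sum() / total for lvl in levels])
        return list(zip(levels.tolist(), sens.tolist()))

    if not isinstance(fit, FourGroupsFit):
        raise TypeError("fit must be a TwoGroupsFit or FourGroupsFit")

    if mode == "unconditional":
        z = np.arange(-z_range, z_range + step / 2, step)
        fdr = marginal_local_fdr(z, fit, trait=trait)
        weights, variances, _ = _marginal_components(fit, trait)
        nn_w, nn_v = weights[1:], variances[1:]
        dens = sum(w * np.exp(_norm_logpdf(z, v)) for w, v in zip(nn_w, nn_v))
        total = dens.sum()
        sens = np.array([(dens * (fdr <= lvl)).sum() / total for lvl in levels])
        return list(zip(levels.tolist(), sens.tolist()))

    if mode != "conditional":
        raise ValueError("mode must be 'unconditional' or 'conditional'")

    step2d = max(step, 0.05)  # 2-D grid; coarser step keeps integration cheap
    axis = np.arange(-z_range, z_range + step2d / 2, step2d)
    zz1, zz2 = np.meshgrid(axis, axis, indexing="ij")
    if trait == 0:
        fdr = conditional_local_fdr(zz1, zz2, fit)
    else:
        fdr = conditional_local_fdr(zz2, zz1, _swap_traits(fit))
    covs = fit.covariances
    nonnull_idx = (1, 3) if trait == 0 else (2, 3)
    dens = sum(
        float(fit.pi[k]) * np.exp(_bvn_logpdf(zz1, zz2, covs[k]))
        for k in nonnull_idx
    )
    total = dens.sum()
    sens = np.array([(dens * (fdr <= lvl)).sum() / total for lvl in levels])
    return list(zip(levels.tolist(), sens.tolist()))


def _swap_traits(fit: FourGroupsFit) -> FourGroupsFit:
    """View of the fit with the two traits' roles exchanged."""
    swap = np.array([[0, 1], [1, 0]], dtype=float)
    return FourGroupsFit(
        pi=np.array([fit.pi[0], fit.pi[2], fit.pi[1], fit.pi[3]]),
        sigma0_sq=fit.sigma0_sq[::-1].copy(),
        sigma1_sq=fit.sigma2_sq,
        sigma2_sq=fit.sigma1_sq,
        effect_cov3=(swap @ fit.effect_cov3 @ swap),
        loglik=fit.loglik,
    )
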