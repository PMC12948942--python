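"""Trio variance-components estimation (the Trio-GCTA core).

The focal phenotype vector y over n families is modelled as multivariate
normal with covariance

    V = s2_o G_ff + s2_m G_aa + s2_p G_bb
        + s_om (G_fa + G_fa') + s_op (G_fb + G_fb') + s_mp (G_ab + G_ab')
        + s2_e I

where f is the focal role and a, b the two non-focal roles; the G blocks
are empirical cross-role genomic relatedness matrices.  Fixed effects are
profiled out by generalized least squares and the free covariance
parameters are maximized by full maximum likelihood, so AIC/BIC/likelihood
ratio comparisons across the five nested model specifications are on
comparable likelihoods.

The 3x3 genetic covariance block is parameterized through a lower
triangular factor restricted to each specification's free components, so
positive semidefiniteness holds by construction while covariances remain
free in sign; the residual variance is optimized on the log scale.
Optimization is a damped Newton iteration using the average-information
approximation to the Hessian with analytic gradients, restarted from
jittered Haseman-Elston-style moment starts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps

from .grm import GRMSet
from .params import COMPONENT_NAMES, VCParams
from .simulate import focal_slot_roles

__all__ = [
    "ModelSpec",
    "FitOptions",
    "FitResult",
    "ModelComparison",
    "MODEL_NAMES",
    "assemble_covariance",
    "profile_loglik",
    "fit_model",
    "compare_models",
    "summarize_components",
    "run_model_comparison",
    "NonConvergenceError",
]

logger = logging.getLogger(__name__)

MODEL_NAMES = ("FULL", "MO", "FO", "DIRECT", "NULL")

_GRM_CODE = {"offspring": "o", "mother": "m", "father": "p"}

# lower-triangular entries of the genetic factor freed by each model
_FREE_L = {
    "FULL": ((0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)),
    "MO": ((0, 0), (1, 0), (1, 1)),
    "FO": ((0, 0), (2, 0), (2, 2)),
    "DIRECT": ((0, 0),),
    "NULL": (),
}

# canonical components (see params.COMPONENT_NAMES) freed by each model
_FREE_CANON = {
    "FULL": (0, 1, 2, 3, 4, 5, 6),
    "MO": (0, 1, 3, 6),
    "FO": (0, 2, 4, 6),
    "DIRECT": (0, 6),
    "NULL": (6,),
}


class NonConvergenceError(RuntimeError):
    """No optimizer restart converged; carries the best incumbent fit."""

    def __init__(self, message: str, best: "FitResult"):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class ModelSpec:
    """One of the five nested trio models for a given focal role."""

    name: str
    focal_role: str = "offspring"

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")

    @property
    def free_l(self):
        return _FREE_L[self.name]

    @property
    def free_canon(self):
        return _FREE_CANON[self.name]

    @property
    def n_free(self) -> int:
        """Free covariance parameters (fixed effects excluded, constant
        across the five models so rankings are unaffected)."""
        return len(self.free_canon)


@dataclass
class FitOptions:
    restarts: int = 5
    max_iter: int = 200
    rel_tol: float = 1e-8
    grad_tol: float = 1e-4  # scaled by max(1, |loglik|)
    seed: int = 0
    ridge: float = 1e-8


@dataclass
class FitResult:
    spec: ModelSpec
    estimates: VCParams
    loglik: float
    n_free: int
    aic: float
    bic: float
    converged: bool
    n_obs: int
    beta: np.ndarray
    beta_names: list[str]
    variance_shares: dict[str, float]
    r_om: float
    r_op: float
    metadata: dict = field(default_factory=dict)


@dataclass
class ModelComparison:
    fits: dict[str, FitResult]
    lrt_vs_full: dict[str, tuple[float, int, float]]
    selected: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            lrt = self.lrt_vs_full.get(name)
            row = {
                "model": name,
                "loglik": fit.loglik,
                "n_free": fit.n_free,
                "aic": fit.aic,
                "bic": fit.bic,
                "converged": fit.converged,
                "n_obs": fit.n_obs,
                "lrt_stat": lrt[0] if lrt else np.nan,
                "lrt_df": lrt[1] if lrt else np.nan,
                "lrt_p": lrt[2] if lrt else np.nan,
                "selected": name == self.selected,
            }
            row.update(fit.estimates.as_dict())
            row.update({f"share_{k}": v for k, v in fit.variance_shares.items()})
            row["r_om"] = fit.r_om
            row["r_op"] = fit.r_op
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariance assembly


def _component_matrices(
    grms: GRMSet, focal_role: str, needed: set[int] | None = None
) -> list:
    """The seven n x n design matrices multiplying the canonical components,
    with blocks permuted so the focal role carries the direct slot.
    Components outside ``needed`` are left as None (not materialized)."""
    f, a, b = (_GRM_CODE[r] for r in focal_slot_roles(focal_role))
    pairs = [(f, f), (a, a), (b, b), (f, a), (f, b), (a, b)]
    mats: list = [None] * 7
    for c, (r1, r2) in enumerate(pairs):
        if needed is not None and c not in needed:
            continue
        g = grms.block(r1, r2)
        mats[c] = g if c < 3 else g + g.T
    if needed is None or 6 in needed:
        mats[6] = np.eye(grms.n_families)
    return mats


def assemble_covariance(grms: GRMSet, params: VCParams, focal_role: str) -> np.ndarray:
    """Phenotypic covariance V implied by the parameters and GRM blocks.

    If numerical assembly leaves V indefinite, a 1e-8 ridge is added once
    with a logged warning (never silently).
    """
    theta = params.as_array()
    needed = {c for c, t in enumerate(theta) if t != 0.0} | {6}
    mats = _component_matrices(grms, focal_role, needed=needed)
    v = np.zeros((grms.n_families, grms.n_families))
    for t, g in zip(theta, mats):
        if g is not None and t != 0.0:
            v = v + t * g
    try:
        sla.cholesky(v, lower=True, check_finite=False)
    except sla.LinAlgError:
        logger.warning("assembled covariance not positive definite; adding 1e-8 ridge")
        v = v + 1e-8 * np.eye(v.shape[0])
    return v


# ---------------------------------------------------------------------------
# likelihood


def _check_design(x: np.ndarray, names: list[str] | None) -> list[str]:
    names = names or [f"x{j}" for j in range(x.shape[1])]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify offending columns through QR pivoting
        _, r, piv = sla.qr(x, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        tol = (diag.max() if diag.size else 0.0) * max(x.shape) * np.finfo(float).eps
        bad = [
            names[piv[k]]
            for k in range(x.shape[1])
            if k >= diag.size or diag[k] <= tol
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return names


def profile_loglik(
    v: np.ndarray, y: np.ndarray, x: np.ndarray, *, names: list[str] | None = None
) -> tuple[float, np.ndarray]:
    """Gaussian log-likelihood with fixed effects profiled out by GLS.

    Returns (loglik, beta_hat).  V must be positive definite and X full
    column rank (collinear columns are reported by name).
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    _check_design(x, names)
    n = y.size
    cho = sla.cho_factor(v, lower=True, check_finite=False)
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    xv = sla.cho_solve(cho, x, check_finite=False)
    yv = sla.cho_solve(cho, y, check_finite=False)
    beta = np.linalg.solve(x.T @ xv, xv.T @ y)
    r = y - x @ beta
    quad = r @ (yv - xv @ beta)
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    return float(ll), beta


# ---------------------------------------------------------------------------
# fitting machinery


def _unpack(theta: np.ndarray, spec: ModelSpec) -> tuple[np.ndarray, float]:
    """theta -> (3x3 factor L, sigma2_e)."""
    l = np.zeros((3, 3))
    for val, (i, j) in zip(theta[:-1], spec.free_l):
        l[i, j] = val
    return l, float(np.exp(theta[-1]))


def _canon_from(l: np.ndarray, s2e: float) -> np.ndarray:
    sig = l @ l.T
    return np.array([sig[0, 0], sig[1, 1], sig[2, 2], sig[0, 1], sig[0, 2], sig[1, 2], s2e])


def _jacobian(theta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """d(canonical components)/d(theta); rows in COMPONENT_NAMES order."""
    l, s2e = _unpack(theta, spec)
    j = np.zeros((7, theta.size))
    for col, (i, jj) in enumerate(spec.free_l):
        e = np.zeros((3, 3))
        e[i, jj] = 1.0
        ds = e @ l.T + l @ e.T
        j[:, col] = [ds[0, 0], ds[1, 1], ds[2, 2], ds[0, 1], ds[0, 2], ds[1, 2], 0.0]
    j[6, -1] = s2e  # sigma2_e = exp(t)
    return j


_CANON_OF_PAIR = {(0, 0): 0, (1, 1): 1, (2, 2): 2, (0, 1): 3, (0, 2): 4, (1, 2): 5}


def _chain_curvature(theta: np.ndarray, spec: ModelSpec, g_canon: np.ndarray, s2e: float):
    """Second derivative of the canonical components w.r.t. theta, weighted
    by the canonical gradient of the negative log-likelihood.

    For factor entries a=(i,j), b=(k,l): d2 Sigma / da db = [j==l]
    (e_i e_k' + e_k e_i'), contributing -g_canon at component (i,k); for
    the log-residual coordinate, d2 sigma2_e/dt2 = exp(t)."""
    p = theta.size
    h2 = np.zeros((p, p))
    free = spec.free_l
    for a, (i, j) in enumerate(free):
        for b, (k, l) in enumerate(free[: a + 1]):
            if j != l:
                continue
            c = _CANON_OF_PAIR[(min(i, k), max(i, k))]
            val = -(2.0 if i == k else 1.0) * g_canon[c]
            h2[a, b] += val
            if a != b:
                h2[b, a] += val
    h2[-1, -1] += -g_canon[6] * s2e
    return h2


class _Objective:
    """Negative profiled log-likelihood with analytic gradient and AI metric."""

    def __init__(self, spec: ModelSpec, mats: list[np.ndarray], y: np.ndarray, x: np.ndarray):
        self.spec = spec
        self.mats = mats
        self.y = y
        self.x = x
        self.n = y.size
        # reusable n x n buffers: repeated evaluations at n in the
        # thousands are memory-bandwidth bound, so avoid fresh temporaries
        self._v = np.empty((self.n, self.n))
        self._tmp = np.empty((self.n, self.n))
        self._lowmask = np.tril(np.ones((self.n, self.n)))

    def __call__(self, theta: np.ndarray):
        l, s2e = _unpack(theta, self.spec)
        canon = _canon_from(l, s2e)
        v = self._v
        v[:] = 0.0
        np.fill_diagonal(v, s2e)
        for c in self.spec.free_canon:
            if c < 6 and canon[c] != 0.0:
                np.multiply(self.mats[c], canon[c], out=self._tmp)
                v += self._tmp
        try:
            cf = sla.cholesky(v, lower=True, overwrite_a=True, check_finite=False)
        except sla.LinAlgError:
            return np.inf, None, None, None
        logdet = 2.0 * np.log(np.diag(cf)).sum()
        # explicit inverse needed for the trace terms of the gradient
        vi, info = sla.lapack.dpotri(cf, lower=True, overwrite_c=True)
        if info != 0:
            return np.inf, None, None, None
        vi *= self._lowmask  # clear factor remnants above the diagonal
        vi += np.tril(vi, -1).T  # mirror the lower triangle
        xv = vi @ self.x
        beta = np.linalg.solve(self.x.T @ xv, xv.T @ self.y)
        r = self.y - self.x @ beta
        rv = vi @ r
        quad = r @ rv
        ll = -0.5 * (self.n * np.log(2 * np.pi) + logdet + quad)

        free = list(self.spec.free_canon)
        g_canon = np.zeros(7)
        us = np.empty((self.n, len(free)))
        for k, c in enumerate(free):
            gmat = self.mats[c] if c < 6 else None
            if gmat is None:  # identity (residual) component
                tr = np.trace(vi)
                u = rv.copy()
            else:
                tr = float(np.vdot(vi, gmat))
                u = gmat @ rv
            g_canon[c] = -0.5 * tr + 0.5 * (rv @ u)
            us[:, k] = u
        ai_free = 0.5 * (us.T @ vi @ us)
        # embed into the 7-component frame, then chain to theta
        ai = np.zeros((7, 7))
        for k1, c1 in enumerate(free):
            for k2, c2 in enumerate(free):
                ai[c1, c2] = ai_free[k1, k2]
        jac = _jacobian(theta, self.spec)
        grad = -(jac.T @ g_canon)
        # AI metric pulled back through the factor parameterization, plus the
        # exact second-order chain term (the part that keeps curvature alive
        # when a factor entry sits at zero)
        hess = jac.T @ ai @ jac + _chain_curvature(theta, self.spec, g_canon, s2e)
        return -ll, grad, hess, beta


def _he_start(spec: ModelSpec, mats, y, x) -> np.ndarray:
    """Haseman-Elston-style moment start: regress the residual outer
    product on the component design matrices (free components only).

    At large n the normal equations are formed on a family subsample; a
    moment start only needs to land in the right neighbourhood."""
    beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta_ols
    n = y.size
    sub = slice(None) if n <= 800 else slice(0, n, int(np.ceil(n / 800)))
    r_s = r[sub]
    free = list(spec.free_canon)
    k = len(free)
    a = np.empty((k, k))
    rhs = np.empty(k)
    mats_s = [m[sub, sub] if m is not None else None for m in mats]
    for i, c in enumerate(free):
        gi = mats_s[c]
        rhs[i] = r_s @ (gi @ r_s)
        for j, c2 in enumerate(free[: i + 1]):
            a[i, j] = a[j, i] = float(np.sum(gi * mats_s[c2]))
    try:
        theta_c = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError:
        theta_c = np.full(k, 0.05)
    canon = np.zeros(7)
    for val, c in zip(theta_c, free):
        canon[c] = val
    var_y = float(np.var(r))
    s2e = float(np.clip(canon[6], 0.05 * var_y, 2.0 * var_y))
    sig = np.array(
        [
            [canon[0], canon[3], canon[4]],
            [canon[3], canon[1], canon[5]],
            [canon[4], canon[5], canon[2]],
        ]
    )
    w, q = np.linalg.eigh(sig)
    floor = max(1e-3 * var_y, 1e-6)
    sig = q @ np.diag(np.clip(w, floor, None)) @ q.T
    l_full = np.linalg.cholesky(sig)
    theta = np.array([l_full[i, j] for (i, j) in spec.free_l] + [np.log(s2e)])
    return theta


def _newton(obj: _Objective, theta0: np.ndarray, opts: FitOptions):
    theta = theta0.copy()
    f, g, h, beta = obj(theta)
    if not np.isfinite(f):
        return theta, np.inf, None, False
    lam = 1e-4
    converged = False

    def _damped(hm, lm):
        d = np.diag(hm).copy()
        floor = 1e-2 * max(1.0, np.abs(d).max())
        return hm + lm * np.diag(np.maximum(d, floor))

    for _ in range(opts.max_iter):
        scale = max(1.0, abs(f))
        if np.max(np.abs(g)) < opts.grad_tol * scale:
            converged = True
            break
        try:
            step = np.linalg.solve(_damped(h, lam), -g)
        except np.linalg.LinAlgError:
            lam *= 10
            continue
        accepted = False
        for _ in range(30):
            trial = theta + step
            trial[-1] = np.clip(trial[-1], -20.0, 6.0)
            ft, gt, ht, bt = obj(trial)
            if np.isfinite(ft) and ft <= f + 1e-12:
                improved = f - ft
                theta, f, g, h, beta = trial, ft, gt, ht, bt
                lam = max(lam * 0.3, 1e-8)
                accepted = True
                if improved < opts.rel_tol * scale and np.max(np.abs(g)) < opts.grad_tol * scale:
                    converged = True
                break
            lam *= 10
            try:
                step = np.linalg.solve(_damped(h, lam), -g)
            except np.linalg.LinAlgError:
                continue
        if converged or not accepted:
            break
    return theta, f, beta, converged


def fit_model(
    spec: ModelSpec,
    grms: GRMSet,
    y: np.ndarray,
    x: np.ndarray,
    options: FitOptions | None = None,
    *,
    x_names: list[str] | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one model specification.

    The best of ``options.restarts`` seeded starts (a Haseman-Elston
    moment start plus jittered copies) is returned; ``converged`` reflects
    the winning start.  Raises :class:`NonConvergenceError` (carrying the
    best incumbent) when no start converges.
    """
    opts = options or FitOptions()
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    names = _check_design(x, x_names)
    mats = _component_matrices(grms, spec.focal_role, needed=set(spec.free_canon))
    obj = _Objective(spec, mats, y, x)

    if spec.name == "NULL":
        # closed form: GLS under V = s2e I is OLS; ML residual variance
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        s2e = float(r @ r / y.size)
        ll = -0.5 * y.size * (np.log(2 * np.pi * s2e) + 1.0)
        return _make_result(spec, VCParams(sigma2_e=s2e), ll, True, y.size, beta, names, opts)

    rng = np.random.default_rng(np.random.SeedSequence([opts.seed, 11]))
    theta0 = _he_start(spec, mats, y, x)
    best = None
    for k in range(max(opts.restarts, 1)):
        start = theta0.copy()
        if k > 0:
            start[:-1] = start[:-1] * np.exp(0.3 * rng.standard_normal(start.size - 1)) + \
                0.02 * rng.standard_normal(start.size - 1)
            start[-1] += 0.2 * rng.standard_normal()
        theta, f, beta, conv = _newton(obj, start, opts)
        if best is None or (conv and not best[3]) or (conv == best[3] and f < best[1]):
            best = (theta, f, beta, conv)
    theta, f, beta, conv = best
    l, s2e = _unpack(theta, spec)
    canon = _canon_from(l, s2e)
    est = VCParams(**dict(zip(COMPONENT_NAMES, canon)))
    result = _make_result(spec, est, -f, conv, y.size, beta, names, opts)
    if not conv:
        raise NonConvergenceError(
            f"no restart converged for model {spec.name}", result
        )
    return result


def _make_result(spec, est, ll, converged, n_obs, beta, names, opts) -> FitResult:
    k = spec.n_free
    aic = 2 * k - 2 * ll
    bic = k * np.log(n_obs) - 2 * ll
    shares, r_om, r_op = _shares(est)
    return FitResult(
        spec=spec,
        estimates=est,
        loglik=float(ll),
        n_free=k,
        aic=float(aic),
        bic=float(bic),
        converged=bool(converged),
        n_obs=int(n_obs),
        beta=np.asarray(beta),
        beta_names=list(names),
        variance_shares=shares,
        r_om=r_om,
        r_op=r_op,
        metadata={
            "criterion": "ML",
            "aic_counts": "free covariance parameters only",
            "restarts": opts.restarts,
        },
    )


def _shares(est: VCParams):
    total = (
        est.sigma2_o + est.sigma2_m + est.sigma2_p + est.sigma_om + est.sigma_op + est.sigma2_e
    )
    if total <= 0:
        raise ValueError("total phenotypic variance is not positive")
    shares = {
        "sigma2_o": est.sigma2_o / total,
        "sigma2_m": est.sigma2_m / total,
        "sigma2_p": est.sigma2_p / total,
        "sigma_om": est.sigma_om / total,
        "sigma_op": est.sigma_op / total,
        "sigma2_e": est.sigma2_e / total,
    }
    r_om = (
        est.sigma_om / np.sqrt(est.sigma2_o * est.sigma2_m)
        if est.sigma2_o > 0 and est.sigma2_m > 0
        else float("nan")
    )
    r_op = (
        est.sigma_op / np.sqrt(est.sigma2_o * est.sigma2_p)
        if est.sigma2_o > 0 and est.sigma2_p > 0
        else float("nan")
    )
    return shares, float(r_om), float(r_op)


def summarize_components(fit: FitResult) -> dict:
    """Variance shares and derived correlations for a converged fit.

    Each component's contribution to Var(Y) is divided by the total
    (sigma_mp is reported but excluded from the total, since it does not
    contribute to phenotypic variance under random mating).  Signed shares
    sum to one by construction.
    """
    if not fit.converged:
        raise ValueError("summaries require a converged fit")
    shares, r_om, r_op = _shares(fit.estimates)
    return {
        "shares": shares,
        "r_om": r_om,
        "r_op": r_op,
        "sigma_mp": fit.estimates.sigma_mp,
    }


# ---------------------------------------------------------------------------
# model comparison


def compare_models(fits: dict[str, FitResult] | list[FitResult]) -> ModelComparison:
    """AIC/BIC ranking and likelihood-ratio tests of nested models vs FULL.

    The LRT p-value uses a plain chi-square on the difference in free
    parameters; with variance components on the boundary this is
    conservative, which is flagged in the comparison metadata.
    """
    if isinstance(fits, list):
        fits = {f.spec.name: f for f in fits}
    n_obs = {f.n_obs for f in fits.values()}
    if len(n_obs) != 1:
        raise ValueError(f"fits disagree on n_obs: {sorted(n_obs)}")
    lrt = {}
    if "FULL" in fits:
        full = fits["FULL"]
        for name, fit in fits.items():
            if name == "FULL":
                continue
            stat = max(2.0 * (full.loglik - fit.loglik), 0.0)
            df = full.n_free - fit.n_free
            p = float(sps.chi2.sf(stat, df)) if df > 0 else float("nan")
            lrt[name] = (float(stat), int(df), p)
    order = sorted(fits.values(), key=lambda f: (f.aic, f.n_free))
    best_aic = order[0].aic
    candidates = [f for f in order if f.aic <= best_aic + 1e-9]
    selected = min(candidates, key=lambda f: f.n_free).spec.name
    return ModelComparison(fits=fits, lrt_vs_full=lrt, selected=selected)


def run_model_comparison(
    grms: GRMSet,
    pheno: pd.DataFrame,
    focal_role: str,
    wave: int,
    covariates: list[str] | None = None,
    options: FitOptions | None = None,
    models: tuple[str, ...] = MODEL_NAMES,
) -> ModelComparison:
    """Fit the five nested models on one wave's complete cases.

    The scored phenotype table is matched to GRM families; rows with a
    missing transformed score are dropped (cross-sectional complete cases
    per wave).
    """
    covariates = covariates if covariates is not None else ["sex"]
    sub = pheno[(pheno["role"] == focal_role) & (pheno["wave"] == wave)]
    sub = sub.dropna(subset=["transformed_score"] + covariates)
    fam_index = {fid: i for i, fid in enumerate(grms.family_ids)}
    sub = sub[sub["family_id"].isin(fam_index)]
    if len(sub) < 10:
        raise ValueError(
            f"only {len(sub)} complete cases for focal {focal_role!r} wave {wave} "
            "after matching GRM families; cannot fit"
        )
    idx = np.array([fam_index[fid] for fid in sub["family_id"]])
    grms_sub = grms.subset(idx)
    y = sub["transformed_score"].to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in covariates])
    names = ["intercept"] + covariates
    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in models:
            spec = ModelSpec(name=name, focal_role=focal_role)
            fits[name] = fit_model(spec, grms_sub, y, x, options, x_names=names)
    return compare_models(fits)
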