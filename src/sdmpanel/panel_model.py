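"""Maximum-likelihood estimation of spatial panel models (SDM, SLM, SEM).

The spatial Durbin model (SDM) for a balanced panel of n units over T periods
is, period by period,

    y_t = rho * W y_t + X_t beta + (W X_t) theta + mu + eps_t,

where W is a row-standardized spatial weight matrix, ``rho`` the spatial
autoregressive parameter, ``theta`` the coefficients on the spatially lagged
covariates, and ``mu`` unit effects. Setting ``theta = 0`` gives the spatial
lag model (SLM); the spatial error model (SEM) instead puts the autoregression
in the disturbance, ``u = lambda W u + eps``.

Estimation is by concentrated maximum likelihood. For fixed effects the data
are within-demeaned (unit means removed); for random effects they are
quasi-demeaned with weight ``1 - theta_qd``, where
``theta_qd = sqrt(sigma_e^2 / (sigma_e^2 + T*sigma_mu^2))`` so that the
transformed disturbances are spherical. The log-Jacobian of the spatial
filter, ``T * ln|I_n - rho W|``, is evaluated through the eigenvalues of W as
``T * sum_i ln(1 - rho*lambda_i)``, so each likelihood evaluation is cheap and
``rho`` can be maximized by bounded scalar search inside the admissible
interval ``(1/lambda_min, 1)``. Covariances come from a central-difference
numerical Hessian of the full log-likelihood at the optimum.

Specification tests: likelihood-ratio and Wald tests of the reductions
SDM -> SLM (``theta = 0``) and SDM -> SEM (common factor
``theta + rho*beta = 0``), and the Hausman test of fixed vs random effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import PanelDataset
from .weights import SpatialWeightMatrix, rho_interval, row_standardize

logger = logging.getLogger(__name__)

__all__ = [
    "SDMSpec",
    "SDMFit",
    "SpecTestResult",
    "fit_spatial_panel",
    "fit_sdm_fe",
    "fit_sdm_re",
    "fit_slm",
    "fit_sem",
    "lr_test",
    "wald_reduction_tests",
    "hausman_test",
]

_RHO_SHRINK = 0.999       # search interval shrink factor
_RHO_XTOL = 1e-8          # scalar-search convergence tolerance
_BOUNDARY_FRAC = 1e-5     # relative distance to a bound that counts as stuck
_HESS_STEP = 1e-5         # relative central-difference step


class CollinearityError(ValueError):
    """Design matrix is rank deficient after the panel transformation."""


class NonConvergenceError(RuntimeError):
    """The spatial parameter search terminated at the interval boundary."""


@dataclass(frozen=True)
class SDMSpec:
    """Specification of a spatial panel regression.

    Parameters
    ----------
    outcome : str
        Name of the dependent variable in the panel.
    covariates : sequence of str
        Ordered explanatory variable names (no duplicates, outcome excluded).
    W : SpatialWeightMatrix
        Spatial weights; row-standardized internally if not already.
    effects : {"fixed", "random"}
    model : {"SDM", "SLM", "SEM"}
    """

    outcome: str
    covariates: tuple
    W: SpatialWeightMatrix
    effects: str = "fixed"
    model: str = "SDM"

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if not self.covariates:
            raise ValueError("covariates must be nonempty")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariates")
        if self.outcome in self.covariates:
            raise ValueError("outcome cannot appear among covariates")
        if self.effects not in ("fixed", "random"):
            raise ValueError(f"unknown effects {self.effects!r}")
        if self.model not in ("SDM", "SLM", "SEM"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass(frozen=True)
class SDMFit:
    """Fitted spatial panel model.

    ``rho`` holds the spatial autoregressive parameter for SDM/SLM and the
    disturbance parameter lambda for SEM. ``param_names`` orders the joint
    covariance ``vcov`` as (rho, beta..., theta...).
    """

    spec: SDMSpec
    rho: float
    beta: np.ndarray
    theta: np.ndarray | None
    sigma2: float
    loglik: float
    vcov: pd.DataFrame          # (rho, beta, theta) block
    unit_effects: pd.Series | None
    re_variance: float | None   # sigma_mu^2 (random effects only)
    intercept: float | None     # random effects only
    R2: float
    n: int
    T: int
    rho_bounds: tuple
    null_loglik: float = field(default=np.nan)

    @property
    def model(self) -> str:
        return self.spec.model

    @property
    def effects(self) -> str:
        return self.spec.effects

    @property
    def k(self) -> int:
        return len(self.beta)

    @property
    def param_names(self) -> tuple:
        return tuple(self.vcov.index)

    @property
    def params(self) -> pd.Series:
        vals = [self.rho, *self.beta]
        if self.theta is not None:
            vals += list(self.theta)
        return pd.Series(vals, index=list(self.param_names))

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())),
                         index=list(self.param_names))

    def n_free(self) -> int:
        return 1 + len(self.beta) + (len(self.theta) if self.theta is not None else 0)

    def summary(self) -> pd.DataFrame:
        se = self.bse
        est = self.params
        z = est / se
        p = 2 * stats.norm.sf(np.abs(z))
        from .esda import significance_stars
        return pd.DataFrame(
            {"estimate": est, "se": se, "z": z, "p": p,
             "stars": [significance_stars(pi) for pi in p]}
        )


@dataclass(frozen=True)
class SpecTestResult:
    """A chi-square specification test."""

    statistic: float
    df: int
    p: float
    hypothesis: str

    @property
    def stars(self) -> str:
        from .esda import significance_stars
        return significance_stars(self.p)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _prepare(panel: PanelDataset, spec: SDMSpec) -> dict:
    W = row_standardize(spec.W)
    if tuple(W.unit_ids) != tuple(panel.unit_ids):
        if set(W.unit_ids) != set(panel.unit_ids):
            raise ValueError("weight matrix units do not match panel units")
        W = W.subset(panel.unit_ids)
    Y = panel.matrix(spec.outcome)                    # (n, T)
    X = np.stack([panel.matrix(v) for v in spec.covariates], axis=2)  # (n, T, k)
    WY = W.W @ Y
    WX = np.einsum("ij,jtk->itk", W.W, X)
    lo, hi = rho_interval(W)
    lo = max(lo, -1e4)  # edgeless or near-edgeless matrices: cap the search
    return {"W": W, "Y": Y, "X": X, "WY": WY, "WX": WX, "eigs": W.eigs,
            "bounds": (lo, hi), "n": panel.n, "T": panel.T,
            "k": len(spec.covariates)}


def _within(M: np.ndarray) -> np.ndarray:
    """Remove unit (time-)means: M is (n, T) or (n, T, k)."""
    return M - M.mean(axis=1, keepdims=True)


def _quasi(M: np.ndarray, tq: float) -> np.ndarray:
    """Quasi-demean with weight (1 - theta_qd)."""
    return M - (1.0 - tq) * M.mean(axis=1, keepdims=True)


def _stack(M: np.ndarray) -> np.ndarray:
    """(n, T[, k]) -> (nT[, k]) observation-stacked arrays."""
    if M.ndim == 2:
        return M.reshape(-1)
    return M.reshape(-1, M.shape[2])


def _logdet_term(rho: float, eigs: np.ndarray) -> float:
    vals = 1.0 - rho * eigs
    if np.any(vals <= 0):
        return -np.inf
    return float(np.sum(np.log(vals)))


def _check_rank(Z: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise CollinearityError(
            f"design matrix rank deficient over columns {list(names)}"
        )


def _maximize_scalar(neg_ll: Callable[[float], float],
                     bounds: tuple) -> float:
    """Deterministic global-ish scalar search: coarse grid, then Brent."""
    lo, hi = bounds
    lo, hi = lo * _RHO_SHRINK if lo < 0 else lo / _RHO_SHRINK, hi * _RHO_SHRINK
    grid = np.linspace(lo, hi, 41)
    vals = np.array([neg_ll(r) for r in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_ll, bounds=(a, b), method="bounded",
                                   options={"xatol": _RHO_XTOL})
    rho = float(res.x)
    span = hi - lo
    if min(rho - lo, hi - rho) < _BOUNDARY_FRAC * span:
        raise NonConvergenceError(
            f"spatial parameter stuck at interval boundary (rho={rho:.6f}, "
            f"bounds=({lo:.4f}, {hi:.4f}))"
        )
    return rho


def _numerical_hessian(f: Callable[[np.ndarray], float],
                       x0: np.ndarray, rel_step: float = _HESS_STEP) -> np.ndarray:
    """Central-difference Hessian with relative steps."""
    p = len(x0)
    h = rel_step * np.maximum(np.abs(x0), 1.0)
    H = np.empty((p, p))
    f0 = f(x0)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej)
                - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _vcov_from_hessian(f_ll: Callable[[np.ndarray], float], x0: np.ndarray,
                       names: Sequence[str], keep: slice) -> pd.DataFrame:
    H = _numerical_hessian(f_ll, x0)
    try:
        V = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        warnings.warn("Hessian singular; using pseudo-inverse for vcov")
        V = np.linalg.pinv(-H)
    V = 0.5 * (V + V.T)
    Vb = V[keep, keep]
    nm = list(names[keep])
    return pd.DataFrame(Vb, index=nm, columns=nm)


def _param_names(spec: SDMSpec) -> list:
    label = "lambda" if spec.model == "SEM" else "rho"
    names = [label] + list(spec.covariates)
    if spec.model == "SDM":
        names += [f"W.{v}" for v in spec.covariates]
    return names


# ---------------------------------------------------------------------------
# fixed-effects SDM / SLM
# ---------------------------------------------------------------------------

def _fit_lag_fe(panel: PanelDataset, spec: SDMSpec,
                fix_rho: float | None = None) -> SDMFit:
    d = _prepare(panel, spec)
    n, T, k = d["n"], d["T"], d["k"]
    # within-demeaning leaves n(T-1) effective observations: the demeaned data
    # are an orthonormal (forward-deviation) transform of T-1 periods, so the
    # exact conditional likelihood carries N = n(T-1) and T-1 log-det terms
    Te = T - 1
    N = n * Te
    Yd, WYd = _within(d["Y"]), _within(d["WY"])
    Xd, WXd = _within(d["X"]), _within(d["WX"])
    y, wy = _stack(Yd), _stack(WYd)
    Z = _stack(Xd) if spec.model == "SLM" else np.hstack([_stack(Xd), _stack(WXd)])
    names = _param_names(spec)
    _check_rank(Z, names[1:])
    ZtZ = Z.T @ Z
    coef0 = np.linalg.solve(ZtZ, Z.T @ y)
    coef1 = np.linalg.solve(ZtZ, Z.T @ wy)
    e0 = y - Z @ coef0
    e1 = wy - Z @ coef1
    a, b, c = e0 @ e0, e0 @ e1, e1 @ e1
    eigs = d["eigs"]
    const = -(N / 2) * (np.log(2 * np.pi) + 1)

    def conc_ll(rho: float) -> float:
        rss = a - 2 * rho * b + rho**2 * c
        return const - (N / 2) * np.log(rss / N) + Te * _logdet_term(rho, eigs)

    if fix_rho is None:
        rho = _maximize_scalar(lambda r: -conc_ll(r), d["bounds"])
    else:
        rho = float(fix_rho)
    delta = coef0 - rho * coef1
    resid = e0 - rho * e1
    sigma2 = float(resid @ resid / N)
    loglik = float(conc_ll(rho))

    # full FE log-likelihood for the covariance
    def full_ll(p: np.ndarray) -> float:
        r, dl, s2 = p[0], p[1:-1], p[-1]
        if s2 <= 0:
            return -np.inf
        e = y - r * wy - Z @ dl
        return (-(N / 2) * np.log(2 * np.pi * s2)
                + Te * _logdet_term(r, eigs) - (e @ e) / (2 * s2))

    x0 = np.concatenate([[rho], delta, [sigma2]])
    vcov = _vcov_from_hessian(full_ll, x0, names + ["sigma2"],
                              keep=slice(0, len(names)))

    beta = delta[:k]
    theta = delta[k:] if spec.model == "SDM" else None
    mu = (d["Y"] - rho * d["WY"]
          - np.einsum("itk,k->it", d["X"], beta)
          - (np.einsum("itk,k->it", d["WX"], theta) if theta is not None else 0)
          ).mean(axis=1)
    fitted = rho * d["WY"] + np.einsum("itk,k->it", d["X"], beta) + mu[:, None]
    if theta is not None:
        fitted = fitted + np.einsum("itk,k->it", d["WX"], theta)
    R2 = float(np.corrcoef(d["Y"].ravel(), fitted.ravel())[0, 1] ** 2)
    return SDMFit(
        spec=spec, rho=float(rho), beta=beta, theta=theta, sigma2=sigma2,
        loglik=loglik, vcov=vcov,
        unit_effects=pd.Series(mu, index=list(panel.unit_ids), name="unit_effect"),
        re_variance=None, intercept=None, R2=R2, n=n, T=T, rho_bounds=d["bounds"],
    )


# ---------------------------------------------------------------------------
# random-effects SDM / SLM
# ---------------------------------------------------------------------------

def _fit_lag_re(panel: PanelDataset, spec: SDMSpec) -> SDMFit:
    d = _prepare(panel, spec)
    n, T, k = d["n"], d["T"], d["k"]
    nT = n * T
    eigs = d["eigs"]
    ones = np.ones((n, T))
    names = _param_names(spec)
    const = -(nT / 2) * (np.log(2 * np.pi) + 1)

    def transform(tq: float):
        y = _stack(_quasi(d["Y"], tq))
        wy = _stack(_quasi(d["WY"], tq))
        cols = [_stack(_quasi(ones, tq))[:, None], _stack(_quasi(d["X"], tq))]
        if spec.model == "SDM":
            cols.append(_stack(_quasi(d["WX"], tq)))
        Z = np.hstack(cols)
        return y, wy, Z

    def conc_ll(rho: float, tq: float) -> float:
        y, wy, Z = transform(tq)
        coef, *_ = np.linalg.lstsq(Z, np.column_stack([y, wy]), rcond=None)
        e0 = y - Z @ coef[:, 0]
        e1 = wy - Z @ coef[:, 1]
        r = e0 - rho * e1
        rss = r @ r
        return (const - (nT / 2) * np.log(rss / nT)
                + n * np.log(tq) + T * _logdet_term(rho, eigs))

    lo, hi = d["bounds"]
    lo = lo * _RHO_SHRINK if lo < 0 else lo / _RHO_SHRINK
    hi = hi * _RHO_SHRINK
    starts = [(0.0, 0.5), (0.4, 0.9), (-0.4, 0.3)]
    best = None
    for s in starts:
        res = optimize.minimize(
            lambda p: -conc_ll(p[0], p[1]), x0=np.array(s),
            method="L-BFGS-B", bounds=[(lo, hi), (1e-4, 1.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    rho, tq = float(best.x[0]), float(best.x[1])
    if min(rho - lo, hi - rho) < _BOUNDARY_FRAC * (hi - lo):
        raise NonConvergenceError("RE spatial parameter stuck at boundary")

    y, wy, Z = transform(tq)
    _check_rank(Z, ["const"] + names[1:])
    coef, *_ = np.linalg.lstsq(Z, np.column_stack([y, wy]), rcond=None)
    delta = coef[:, 0] - rho * coef[:, 1]
    resid = (y - rho * wy) - Z @ delta
    sigma2 = float(resid @ resid / nT)
    sigma_mu2 = sigma2 * (1.0 / tq**2 - 1.0) / T
    if tq > 1.0 - 1e-4:
        warnings.warn("random-effect variance at zero boundary; "
                      "RE estimates collapse toward pooled OLS")
    loglik = float(conc_ll(rho, tq))

    def full_ll(p: np.ndarray) -> float:
        r, dl, s2, t = p[0], p[1:-2], p[-2], p[-1]
        # t marginally above 1 is allowed so central differences stay finite
        # when the variance component sits at its zero boundary (t_hat = 1)
        if s2 <= 0 or not (0 < t <= 1.5):
            return -np.inf
        yt, wyt, Zt = transform(t)
        e = yt - r * wyt - Zt @ dl
        return (-(nT / 2) * np.log(2 * np.pi * s2) + n * np.log(t)
                + T * _logdet_term(r, eigs) - (e @ e) / (2 * s2))

    full_names = [names[0], "const"] + names[1:] + ["sigma2", "theta_qd"]
    x0 = np.concatenate([[rho], delta, [sigma2, tq]])
    H = _numerical_hessian(full_ll, x0)
    try:
        V = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        warnings.warn("Hessian singular; using pseudo-inverse for vcov")
        V = np.linalg.pinv(-H)
    V = 0.5 * (V + V.T)
    keep = [0] + list(range(2, 2 + len(names) - 1))  # rho + slopes, skip const
    Vb = V[np.ix_(keep, keep)]
    vcov = pd.DataFrame(Vb, index=names, columns=names)

    intercept = float(delta[0])
    beta = delta[1:1 + k]
    theta = delta[1 + k:] if spec.model == "SDM" else None
    fitted = (rho * d["WY"] + intercept
              + np.einsum("itk,k->it", d["X"], beta))
    if theta is not None:
        fitted = fitted + np.einsum("itk,k->it", d["WX"], theta)
    R2 = float(np.corrcoef(d["Y"].ravel(), fitted.ravel())[0, 1] ** 2)
    return SDMFit(
        spec=spec, rho=rho, beta=beta, theta=theta, sigma2=sigma2,
        loglik=loglik, vcov=vcov, unit_effects=None,
        re_variance=float(sigma_mu2), intercept=intercept, R2=R2,
        n=n, T=T, rho_bounds=d["bounds"],
    )


# ---------------------------------------------------------------------------
# spatial error model (fixed effects)
# ---------------------------------------------------------------------------

def _fit_sem_fe(panel: PanelDataset, spec: SDMSpec) -> SDMFit:
    d = _prepare(panel, spec)
    n, T, k = d["n"], d["T"], d["k"]
    Te = T - 1        # effective periods after within-demeaning
    N = n * Te
    eigs = d["eigs"]
    Yd = _within(d["Y"])
    Xd = _within(d["X"])
    names = _param_names(spec)
    _check_rank(_stack(Xd), names[1:])
    const = -(N / 2) * (np.log(2 * np.pi) + 1)
    Wm = d["W"].W

    def filtered(lam: float):
        Yt = Yd - lam * (Wm @ Yd)
        Xt = Xd - lam * np.einsum("ij,jtk->itk", Wm, Xd)
        return _stack(Yt), _stack(Xt)

    def conc_ll(lam: float) -> float:
        y, Z = filtered(lam)
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        r = y - Z @ coef
        return const - (N / 2) * np.log(r @ r / N) + Te * _logdet_term(lam, eigs)

    lam = _maximize_scalar(lambda v: -conc_ll(v), d["bounds"])
    y, Z = filtered(lam)
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    sigma2 = float(resid @ resid / N)
    loglik = float(conc_ll(lam))

    def full_ll(p: np.ndarray) -> float:
        lv, bv, s2 = p[0], p[1:-1], p[-1]
        if s2 <= 0:
            return -np.inf
        yt, Zt = filtered(lv)
        e = yt - Zt @ bv
        return (-(N / 2) * np.log(2 * np.pi * s2)
                + Te * _logdet_term(lv, eigs) - (e @ e) / (2 * s2))

    x0 = np.concatenate([[lam], beta, [sigma2]])
    vcov = _vcov_from_hessian(full_ll, x0, names + ["sigma2"],
                              keep=slice(0, len(names)))
    mu = (d["Y"] - np.einsum("itk,k->it", d["X"], beta)).mean(axis=1)
    fitted = np.einsum("itk,k->it", d["X"], beta) + mu[:, None]
    R2 = float(np.corrcoef(d["Y"].ravel(), fitted.ravel())[0, 1] ** 2)
    return SDMFit(
        spec=spec, rho=float(lam), beta=beta, theta=None, sigma2=sigma2,
        loglik=loglik, vcov=vcov,
        unit_effects=pd.Series(mu, index=list(panel.unit_ids), name="unit_effect"),
        re_variance=None, intercept=None, R2=R2, n=n, T=T, rho_bounds=d["bounds"],
    )


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def fit_spatial_panel(panel: PanelDataset, spec: SDMSpec,
                      fix_rho: float | None = None) -> SDMFit:
    """Fit the spatial panel model described by ``spec`` by concentrated ML.

    ``fix_rho`` pins the spatial parameter instead of profiling it (restricted
    fits; ``fix_rho=0`` gives the non-spatial within regression for SLM).
    """
    if spec.model in ("SDM", "SLM"):
        if spec.effects == "fixed":
            return _fit_lag_fe(panel, spec, fix_rho=fix_rho)
        if fix_rho is not None:
            raise NotImplementedError("fix_rho is supported for fixed effects only")
        return _fit_lag_re(panel, spec)
    if spec.effects != "fixed":
        raise NotImplementedError("SEM is implemented with fixed effects only")
    if fix_rho is not None:
        raise NotImplementedError("fix_rho applies to SDM/SLM fits")
    return _fit_sem_fe(panel, spec)


def fit_sdm_fe(panel: PanelDataset, spec: SDMSpec) -> SDMFit:
    """Fixed-effects spatial Durbin model."""
    return fit_spatial_panel(panel, SDMSpec(spec.outcome, spec.covariates,
                                            spec.W, "fixed", "SDM"))


def fit_sdm_re(panel: PanelDataset, spec: SDMSpec) -> SDMFit:
    """Random-effects spatial Durbin model."""
    return fit_spatial_panel(panel, SDMSpec(spec.outcome, spec.covariates,
                                            spec.W, "random", "SDM"))


def fit_slm(panel: PanelDataset, spec: SDMSpec) -> SDMFit:
    """Spatial lag model (SDM with theta = 0)."""
    return fit_spatial_panel(panel, SDMSpec(spec.outcome, spec.covariates,
                                            spec.W, spec.effects, "SLM"))


def fit_sem(panel: PanelDataset, spec: SDMSpec) -> SDMFit:
    """Spatial error model (autoregressive disturbance)."""
    return fit_spatial_panel(panel, SDMSpec(spec.outcome, spec.covariates,
                                            spec.W, "fixed", "SEM"))


# ---------------------------------------------------------------------------
# specification tests
# ---------------------------------------------------------------------------

_NESTED = {("SDM", "SLM"), ("SDM", "SEM")}


def lr_test(full: SDMFit, restricted: SDMFit) -> SpecTestResult:
    """Likelihood-ratio test of a nested spatial specification."""
    if full.spec.outcome != restricted.spec.outcome or \
            full.spec.covariates != restricted.spec.covariates or \
            full.effects != restricted.effects:
        raise ValueError("models are not fitted on the same specification")
    if (full.n, full.T) != (restricted.n, restricted.T):
        raise ValueError("models are not fitted on the same data")
    same = full.model == restricted.model
    if not same and (full.model, restricted.model) not in _NESTED:
        raise ValueError(
            f"{restricted.model} is not nested in {full.model}"
        )
    df = full.n_free() - restricted.n_free()
    if same:
        df = 0
    stat = max(0.0, 2.0 * (full.loglik - restricted.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    if df == 0:
        stat = 0.0
    return SpecTestResult(statistic=stat, df=df, p=p,
                          hypothesis=f"{full.model} vs {restricted.model}")


def _quad_form(g: np.ndarray, Vg: np.ndarray, label: str) -> tuple[float, int]:
    try:
        stat = float(g @ np.linalg.solve(Vg, g))
        df = len(g)
    except np.linalg.LinAlgError:
        warnings.warn(f"singular restricted covariance in {label}; "
                      "using pseudo-inverse")
        Vp = np.linalg.pinv(Vg)
        stat = float(g @ Vp @ g)
        df = int(np.linalg.matrix_rank(Vg))
    return max(stat, 0.0), df


def wald_reduction_tests(fit: SDMFit) -> tuple[SpecTestResult, SpecTestResult]:
    """Wald tests of the SDM reductions to SLM and SEM.

    H01 (``theta = 0``): the spatially lagged covariates drop out and the SDM
    collapses to the spatial lag model. H02 (``theta + rho*beta = 0``): the
    common-factor restriction under which the SDM collapses to the spatial
    error model; its Jacobian ``G = [beta, rho*I, I]`` feeds the delta method.
    """
    if fit.model != "SDM":
        raise ValueError("reduction tests require an SDM fit")
    k = fit.k
    V = fit.vcov.to_numpy()
    theta = fit.theta
    beta = fit.beta
    rho = fit.rho
    # H01: theta = 0
    Vtt = V[1 + k:, 1 + k:]
    stat1, df1 = _quad_form(theta, Vtt, "Wald theta=0")
    p1 = float(stats.chi2.sf(stat1, df1))
    # H02: theta + rho*beta = 0 (delta method)
    g = theta + rho * beta
    G = np.zeros((k, 1 + 2 * k))
    G[:, 0] = beta
    G[:, 1:1 + k] = rho * np.eye(k)
    G[:, 1 + k:] = np.eye(k)
    stat2, df2 = _quad_form(g, G @ V @ G.T, "Wald theta+rho*beta=0")
    p2 = float(stats.chi2.sf(stat2, df2))
    return (
        SpecTestResult(stat1, df1, p1, hypothesis="theta = 0"),
        SpecTestResult(stat2, df2, p2, hypothesis="theta + rho*beta = 0"),
    )


def hausman_test(fe: SDMFit, re: SDMFit) -> SpecTestResult:
    """Hausman test of fixed vs random effects over the common slopes.

    Under the null (random effects consistent and efficient) the quadratic
    form ``(b_FE - b_RE)' (V_FE - V_RE)^- (b_FE - b_RE)`` is chi-square with
    df equal to the rank of the variance difference; a Moore-Penrose inverse
    is used when the difference is not positive definite.
    """
    if fe.effects != "fixed" or re.effects != "random":
        raise ValueError("hausman_test expects (fixed fit, random fit)")
    if fe.model != re.model or fe.spec.covariates != re.spec.covariates:
        raise ValueError("FE and RE fits must share the model specification")
    slopes = [nm for nm in fe.param_names if nm not in ("rho", "lambda")]
    b_fe = fe.params[slopes].to_numpy()
    b_re = re.params[slopes].to_numpy()
    V_fe = fe.vcov.loc[slopes, slopes].to_numpy()
    V_re = re.vcov.loc[slopes, slopes].to_numpy()
    q = b_fe - b_re
    Vd = 0.5 * ((V_fe - V_re) + (V_fe - V_re).T)
    w, U = np.linalg.eigh(Vd)
    tol = 1e-12 * max(abs(w).max(), 1e-30)
    if w.min() < -tol:
        logger.info("Hausman variance difference not positive definite "
                    "(min eigenvalue %.3e); pseudo-inverting its positive part",
                    w.min())
    keep = w > tol
    # Moore-Penrose inverse restricted to the positive eigenspace keeps the
    # quadratic form nonnegative when V_FE - V_RE is indefinite in finite samples
    Vp = (U[:, keep] / w[keep]) @ U[:, keep].T
    stat = max(0.0, float(q @ Vp @ q))
    df = int(keep.sum())
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return SpecTestResult(stat, df, p, hypothesis="FE vs RE")
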