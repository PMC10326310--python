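"""Total, direct, and indirect effect decomposition for spatial panel fits.

In a spatial autoregressive model a change in covariate r at one unit
propagates through the spatial multiplier. The matrix of partial derivatives
of the outcome with respect to covariate r across all unit pairs is

    S_r(W) = (I_n - rho*W)^{-1} (I_n * beta_r + W * theta_r),

whose diagonal carries own-unit responses and whose off-diagonal entries
carry cross-unit spillovers. Summaries:

    direct_r   = n^{-1} tr(S_r)        (average own-unit effect)
    total_r    = n^{-1} 1' S_r 1       (average effect over all pairs)
    indirect_r = total_r - direct_r    (average spillover)

so total = direct + indirect holds as an identity. Standard errors come from
parameter simulation: draw (rho, beta, theta) from a multivariate normal at
the ML estimate and covariance, recompute the three summaries per draw, and
report the draw standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel_model import SDMFit

__all__ = ["ImpactDecomposition", "impact_matrix", "decompose", "impact_inference"]

_COND_LIMIT = 1e12


class ConditioningError(ArithmeticError):
    """(I - rho*W) is too ill-conditioned for a reliable solve."""


@dataclass(frozen=True)
class ImpactDecomposition:
    """Per-covariate total/direct/indirect effects, optionally with SEs.

    ``effects`` is a covariate x (total, direct, indirect) frame of point
    estimates; ``se`` and ``p`` (same shape) are present after simulation
    inference, else None.
    """

    effects: pd.DataFrame
    se: pd.DataFrame | None
    p: pd.DataFrame | None
    D: int | None
    seed: int | None

    def stars(self) -> pd.DataFrame | None:
        if self.p is None:
            return None
        from .esda import significance_stars
        return self.p.map(significance_stars)

    def to_report(self) -> pd.DataFrame:
        """Effect table with parenthesized SEs and significance stars."""
        if self.se is None:
            return self.effects.round(4).astype(str)
        st = self.stars()
        out = {}
        for col in self.effects.columns:
            out[col] = [
                f"{e:.4f}{s} ({sd:.4f})"
                for e, sd, s in zip(self.effects[col], self.se[col], st[col])
            ]
        return pd.DataFrame(out, index=self.effects.index)


def _solve_multiplier(rho: float, W: np.ndarray) -> np.ndarray:
    """V(W) = (I - rho*W)^{-1} with a conditioning check."""
    n = W.shape[0]
    A = np.eye(n) - rho * W
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise ConditioningError(
            f"I - rho*W has condition number {cond:.2e} (rho={rho:.4f})"
        )
    return np.linalg.solve(A, np.eye(n))


def impact_matrix(fit: SDMFit, r: int) -> np.ndarray:
    """The n x n partial-derivative matrix S_r(W) for covariate index ``r``."""
    lo, hi = fit.rho_bounds
    if not (lo < fit.rho < hi):
        raise ValueError(f"rho={fit.rho} outside admissible interval ({lo}, {hi})")
    W = fit.spec.W.W
    V = _solve_multiplier(fit.rho, W)
    beta_r = fit.beta[r]
    theta_r = fit.theta[r] if fit.theta is not None else 0.0
    return V @ (beta_r * np.eye(len(W)) + theta_r * W)


def _summaries(rho: float, W: np.ndarray) -> tuple[float, float, float, float]:
    """Multiplier summaries reused across covariates and draws.

    Returns (mean diag V, mean entry V, mean diag VW, mean entry VW), so that
    for any covariate r: direct = beta_r*a_d + theta_r*b_d and
    total = beta_r*a_t + theta_r*b_t. Exploits that V depends only on rho.
    """
    n = W.shape[0]
    V = _solve_multiplier(rho, W)
    VW = V @ W
    a_d = float(np.trace(V) / n)
    a_t = float(V.sum() / n)
    b_d = float(np.trace(VW) / n)
    b_t = float(VW.sum() / n)
    return a_d, a_t, b_d, b_t


def decompose(fit: SDMFit) -> ImpactDecomposition:
    """Point estimates of total/direct/indirect effects for every covariate."""
    if fit.model not in ("SDM", "SLM"):
        raise ValueError("effect decomposition applies to SDM/SLM fits")
    W = fit.spec.W.W
    a_d, a_t, b_d, b_t = _summaries(fit.rho, W)
    theta = fit.theta if fit.theta is not None else np.zeros_like(fit.beta)
    direct = fit.beta * a_d + theta * b_d
    total = fit.beta * a_t + theta * b_t
    eff = pd.DataFrame(
        {"total": total, "direct": direct, "indirect": total - direct},
        index=list(fit.spec.covariates),
    )
    return ImpactDecomposition(effects=eff, se=None, p=None, D=None, seed=None)


def impact_inference(fit: SDMFit, D: int = 1000, seed: int | None = 0
                     ) -> ImpactDecomposition:
    """Simulation-based standard errors for the effect decomposition.

    Draws ``D`` parameter vectors (rho, beta, theta) from the multivariate
    normal at the ML estimate with the fit covariance; any draw with rho
    outside the admissible interval is redrawn. Per-covariate p-values use
    the normal approximation on the draw t-ratio (draw mean / draw SD).
    """
    if D < 100:
        raise ValueError("need at least 100 parameter draws")
    point = decompose(fit)
    W = fit.spec.W.W
    k = fit.k
    mean = fit.params.to_numpy()
    cov = fit.vcov.to_numpy()
    rng = np.random.default_rng(seed)
    if not np.any(cov):
        se = point.effects * 0.0
        p = point.effects * 0.0
        return ImpactDecomposition(point.effects, se, p, D, seed)
    draws = rng.multivariate_normal(mean, cov, size=D, method="svd")
    lo, hi = fit.rho_bounds
    bad = (draws[:, 0] <= lo) | (draws[:, 0] >= hi)
    n_bad = int(bad.sum())
    tries = 0
    while bad.any() and tries < 50:
        redraw = rng.multivariate_normal(mean, cov, size=int(bad.sum()),
                                         method="svd")
        draws[bad] = redraw
        bad = (draws[:, 0] <= lo) | (draws[:, 0] >= hi)
        tries += 1
    if n_bad > 0.1 * D:
        warnings.warn(
            f"{n_bad}/{D} parameter draws fell outside the admissible rho "
            "interval; simulation inference may be unstable"
        )
    tot = np.empty((D, k))
    dire = np.empty((D, k))
    for j in range(D):
        r = draws[j, 0]
        b = draws[j, 1:1 + k]
        t = draws[j, 1 + k:1 + 2 * k] if fit.theta is not None else np.zeros(k)
        a_d, a_t, b_d, b_t = _summaries(r, W)
        dire[j] = b * a_d + t * b_d
        tot[j] = b * a_t + t * b_t
    ind = tot - dire
    idx = list(fit.spec.covariates)
    se = pd.DataFrame(
        {"total": tot.std(axis=0, ddof=1),
         "direct": dire.std(axis=0, ddof=1),
         "indirect": ind.std(axis=0, ddof=1)},
        index=idx,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = pd.DataFrame(
            {"total": tot.mean(0) / se["total"].to_numpy(),
             "direct": dire.mean(0) / se["direct"].to_numpy(),
             "indirect": ind.mean(0) / se["indirect"].to_numpy()},
            index=idx,
        )
    p = 2 * z.abs().apply(lambda c: pd.Series(stats.norm.sf(c), index=idx))
    return ImpactDecomposition(point.effects, se, p, D, seed)
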