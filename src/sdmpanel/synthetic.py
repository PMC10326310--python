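"""Synthetic spatial panels with a known spatial Durbin data-generating process.

Real province-level expenditure panels are rarely redistributable, so every
stage of the pipeline is exercised on synthetic data whose statistical
structure matches what the analysis assumes: a planar "map" of units with a
contiguity graph and capital coordinates, a four-region partition, covariates
with realistic first and second moments and mild serial persistence, and an
outcome generated from the SDM reduced form

    y_t = (I - rho*W)^{-1} (X_t beta + (W X_t) theta + alpha + mu + eps_t)

with unit effects mu ~ N(0, fe_sd^2) fixed over time and i.i.d. disturbances
eps_t ~ N(0, sigma^2). Because the true (rho, beta, theta) are known,
parameter-recovery and test-calibration experiments have an exact oracle.

Default parameter values reproduce the study conditions of the motivating
application (Chinese provincial panel, n = 30 units, T = 12 years): covariate
means/SDs follow its descriptive table, the coefficient vectors follow its
fixed-effects SDM estimates under the contiguity matrix, and the outcome FME
(medical-expenditure-to-income ratio) is centered at 0.067.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .panel import PanelDataset
from .weights import (
    SpatialWeightMatrix,
    contiguity_from_adjacency,
    inverse_distance_from_coords,
    rho_interval,
    row_standardize,
)

__all__ = ["DGPConfig", "generate_map", "generate_covariates",
           "generate_outcome", "generate_panel"]

#: covariate name -> (mean, SD) targets for the default application
DEFAULT_MOMENTS = {
    "lnRTI": (0.536, 1.305),
    "lnPS": (5.438, 0.690),
    "RH": (0.961, 0.333),
    "REF": (0.043, 0.028),
    "RMI": (0.652, 0.184),
    "lnRLG": (2.180, 1.400),
    "lnRPC": (8.474, 0.507),
}

#: fixed-effects SDM coefficients under the contiguity matrix (default truth)
DEFAULT_BETA = (-0.055, -0.021, 0.142, -0.230, 0.107, 0.034, 0.056)
DEFAULT_THETA = (0.023, -0.029, 0.218, -0.192, 0.091, -0.045, -0.036)

REGIONS = ("eastern", "central", "western", "northeast")


@dataclass(frozen=True)
class DGPConfig:
    """Parameters of the synthetic spatial Durbin data-generating process.

    Attributes
    ----------
    n, T : int
        Units and periods (defaults 30 x 12, the application's panel shape).
    rho : float
        True spatial autoregressive parameter (must lie inside the admissible
        interval of the generated weight matrix).
    beta, theta : tuple of float
        True covariate and spatial-lag coefficients, one per covariate.
    sigma : float
        Disturbance SD (default sqrt(0.004), the application's sigma^2).
    fe_sd : float
        SD of the time-constant unit effects, on the outcome scale.
    outcome_mean : float
        Target unconditional mean of the outcome (intercept is solved for).
    covariate_moments : mapping
        Per-covariate (mean, SD) targets.
    persistence : float
        AR(1) coefficient of the covariate innovations over time.
    unit_share : float
        Share of covariate variance attributable to time-constant unit
        heterogeneity (between-unit variation).
    fe_x_corr : float
        Correlation between the unit effects mu and the unit means of the
        first covariate; nonzero values violate the random-effects assumption
        and give the Hausman test something to detect.
    region_betas : mapping or None
        Optional region -> beta-tuple overrides for heterogeneous-effect
        experiments.
    seed : int
    """

    n: int = 30
    T: int = 12
    rho: float = -0.5
    beta: tuple = DEFAULT_BETA
    theta: tuple = DEFAULT_THETA
    sigma: float = float(np.sqrt(0.004))
    fe_sd: float = 0.02
    outcome_mean: float = 0.067
    covariate_moments: dict = field(
        default_factory=lambda: dict(DEFAULT_MOMENTS))
    persistence: float = 0.5
    unit_share: float = 0.3
    fe_x_corr: float = 0.0
    region_betas: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.fe_sd < 0:
            raise ValueError("fe_sd must be nonnegative")
        if not (0 <= self.persistence < 1):
            raise ValueError("persistence must be in [0, 1)")
        if not (0 <= self.unit_share < 1):
            raise ValueError("unit_share must be in [0, 1)")
        k = len(self.covariate_moments)
        if len(self.beta) != k or len(self.theta) != k:
            raise ValueError("beta/theta length must match covariate_moments")
        for v, (m, s) in self.covariate_moments.items():
            if not np.isfinite(m) or not np.isfinite(s) or s <= 0:
                raise ValueError(f"invalid moment target for {v!r}: ({m}, {s})")

    @property
    def covariates(self) -> tuple:
        return tuple(self.covariate_moments)


def _unit_ids(n: int) -> tuple:
    return tuple(f"U{i+1:02d}" for i in range(n))


def generate_map(n: int, seed: int = 0, partition: bool = True):
    """A synthetic planar map: coordinates, contiguity, and a 4-region split.

    Units are uniform points on the unit square; contiguity is the edge set of
    their Delaunay triangulation (planar and connected); regions come from a
    spatially contiguous split (median split on x, then median split on y
    within each half), so each region is a nonempty block of the plane.

    Returns
    -------
    coords : DataFrame (unit -> x, y)
    adjacency : list of unit-id pairs
    partition : dict unit -> region, or None when ``partition=False``
    """
    if partition and n < 8:
        raise ValueError("a 4-region partition needs at least 8 units")
    if n < 3:
        raise ValueError("need at least 3 units for a triangulated map")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(size=(n, 2))
    ids = _unit_ids(n)
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
            edges.add((i, j))
    adjacency = [(ids[i], ids[j]) for i, j in sorted(edges)]
    coords = pd.DataFrame(pts, index=pd.Index(ids, name="unit"),
                          columns=["x", "y"])
    part = None
    if partition:
        order_x = np.argsort(pts[:, 0], kind="stable")
        west_half, east_half = order_x[: n // 2], order_x[n // 2:]
        part = {}
        for half, (lo_name, hi_name) in (
            (west_half, ("western", "northeast")),
            (east_half, ("central", "eastern")),
        ):
            ys = pts[half, 1]
            order_y = half[np.argsort(ys, kind="stable")]
            m = len(order_y) // 2
            for i in order_y[:m]:
                part[ids[i]] = lo_name
            for i in order_y[m:]:
                part[ids[i]] = hi_name
        part = {u: part[u] for u in ids}
    return coords, adjacency, part


def generate_covariates(config: DGPConfig, seed: int | None = None
                        ) -> pd.DataFrame:
    """Covariate panel with target moments, unit heterogeneity, and AR(1) time
    persistence.

    Each covariate is built from a standardized latent process
    ``s_it = sqrt(unit_share)*a_i + sqrt(1-unit_share)*v_it`` with ``a_i``
    i.i.d. standard normal and ``v_it`` a stationary AR(1) with unit variance,
    then scaled as ``mean + SD * s_it``. Covariates are mutually independent.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, T = config.n, config.T
    ids = _unit_ids(n)
    years = list(range(2006, 2006 + T))
    idx = pd.MultiIndex.from_product([ids, years], names=["unit", "year"])
    out = {}
    phi = config.persistence
    innov_sd = np.sqrt(1.0 - phi**2)
    for var, (mean, sd) in config.covariate_moments.items():
        a = rng.standard_normal(n)
        v = np.empty((n, T))
        v[:, 0] = rng.standard_normal(n)
        for t in range(1, T):
            v[:, t] = phi * v[:, t - 1] + innov_sd * rng.standard_normal(n)
        s = (np.sqrt(config.unit_share) * a[:, None]
             + np.sqrt(1.0 - config.unit_share) * v)
        out[var] = (mean + sd * s).reshape(-1)
    return pd.DataFrame(out, index=idx)


def generate_outcome(
    covariates: pd.DataFrame,
    W: SpatialWeightMatrix,
    config: DGPConfig,
    seed: int | None = None,
    return_components: bool = False,
    partition: dict | None = None,
):
    """Outcome panel from the SDM reduced form with known parameters.

    Per period t: ``y_t = (I - rho*W)^{-1}(X_t beta + (W X_t) theta + alpha
    + mu + eps_t)``. The intercept ``alpha`` is solved so the unconditional
    outcome mean equals ``config.outcome_mean`` given the covariate means.
    With ``region_betas`` set (and ``partition`` supplied), each unit's own
    covariate response uses its region's beta vector.

    Returns a :class:`PanelDataset` holding the outcome ``FME`` plus the
    covariates; with ``return_components=True`` also returns a dict with the
    drawn ``mu`` and ``eps`` for reduced-form verification.
    """
    W = row_standardize(W)
    lo, hi = rho_interval(W)
    if not (lo < config.rho < hi):
        raise ValueError(f"rho={config.rho} outside admissible ({lo:.3f}, {hi:.3f})")
    n, T = config.n, config.T
    names = list(config.covariates)
    Xw = covariates[names]
    units = Xw.index.get_level_values(0).unique()
    if len(units) != n:
        raise ValueError("covariate panel does not match config.n")
    X = np.stack(
        [Xw[v].unstack().loc[list(units)].to_numpy() for v in names], axis=2
    )  # (n, T, k)
    beta = np.asarray(config.beta, dtype=float)
    theta = np.asarray(config.theta, dtype=float)
    B = np.tile(beta, (n, 1))
    if config.region_betas:
        if partition is None:
            raise ValueError("region_betas requires a partition")
        for i, u in enumerate(units):
            override = config.region_betas.get(partition[u])
            if override is not None:
                B[i] = np.asarray(override, dtype=float)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mu = rng.standard_normal(n) * config.fe_sd
    if config.fe_x_corr:
        # tilt mu toward the unit means of the first covariate to violate RE
        x1 = X[:, :, 0].mean(axis=1)
        x1s = (x1 - x1.mean()) / (x1.std() or 1.0)
        c = config.fe_x_corr
        mu = config.fe_sd * (c * x1s + np.sqrt(1 - c**2) * mu / (config.fe_sd or 1.0))
    eps = rng.standard_normal((n, T)) * config.sigma
    means = np.array([config.covariate_moments[v][0] for v in names])
    alpha = config.outcome_mean * (1.0 - config.rho) - means @ (beta + theta)
    WX = np.einsum("ij,jtk->itk", W.W, X)
    rhs = ((B[:, None, :] * X).sum(axis=2)
           + np.einsum("itk,k->it", WX, theta)
           + alpha + mu[:, None] + eps)
    A = np.eye(n) - config.rho * W.W
    Y = np.linalg.solve(A, rhs)
    df = Xw.copy()
    df.insert(0, "FME", Y.reshape(-1))
    panel = PanelDataset(df, transforms={"FME": "ratio"})
    if return_components:
        return panel, {"mu": mu, "eps": eps, "alpha": alpha, "rhs": rhs}
    return panel


def generate_panel(config: DGPConfig | None = None, seed: int | None = None):
    """One-call synthetic bundle: panel, both weight matrices, map, partition.

    Returns a dict with keys ``panel`` (PanelDataset with FME + covariates),
    ``W_contiguity``, ``W_distance`` (row-standardized), ``coords``,
    ``adjacency``, ``partition``, and ``config``.
    """
    config = config or DGPConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    coords, adjacency, partition = generate_map(config.n, seed=config.seed)
    ids = tuple(coords.index)
    W_cont = row_standardize(contiguity_from_adjacency(adjacency, ids))
    W_dist = row_standardize(
        inverse_distance_from_coords(coords.to_numpy(), ids))
    # covariates and outcome get child seeds so stages are independently seeded
    seq = np.random.SeedSequence(config.seed)
    s_cov, s_out = (int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(2))
    cov = generate_covariates(config, seed=s_cov)
    panel = generate_outcome(cov, W_cont, config, seed=s_out,
                             partition=partition)
    return {
        "panel": panel,
        "W_contiguity": W_cont,
        "W_distance": W_dist,
        "coords": coords,
        "adjacency": adjacency,
        "partition": partition,
        "config": config,
    }
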