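"""Exploratory spatial data analysis: global Moran's I and the Moran scatter.

Moran's I measures global spatial autocorrelation of a cross-sectional
variable x under a spatial weight matrix W:

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with S0 the sum of all weights. Its null expectation is E(I) = -1/(n-1);
values above that indicate clustering of similar values (hot/cold spots),
values below indicate checkerboard-like dispersion. Significance is assessed
with the normal approximation Z = (I - E(I)) / sqrt(VAR(I)), where VAR(I) has
closed forms under either the normality null (x i.i.d. Gaussian) or the
randomization null (x fixed, locations permuted; kurtosis-adjusted). The
randomization null is the default, being agnostic about the marginal
distribution of x.

The Moran scatter plots each unit's standardized value against the weighted
average of its neighbors' values; the four quadrants classify units as
high-surrounded-by-high (HH), low-by-low (LL), or spatial outliers (HL / LH).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PanelDataset
from .weights import SpatialWeightMatrix, row_standardize

__all__ = [
    "MoranResult",
    "MoranScatter",
    "morans_i",
    "moran_moments",
    "moran_scatter",
    "yearly_moran_table",
    "significance_stars",
]


@dataclass(frozen=True)
class MoranResult:
    """Global Moran's I with its null moments and normal test."""

    I: float
    E_I: float
    VAR_I: float
    Z: float
    p: float
    n: int
    null: str

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


@dataclass(frozen=True)
class MoranScatter:
    """Per-unit standardized values, spatial lags, and quadrant labels."""

    unit_ids: tuple
    z_value: np.ndarray
    spatial_lag: np.ndarray
    quadrant: tuple  # "HH" | "LH" | "LL" | "HL" per unit

    def counts(self) -> dict:
        out = {"HH": 0, "LH": 0, "LL": 0, "HL": 0}
        for q in self.quadrant:
            out[q] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z_value": self.z_value, "spatial_lag": self.spatial_lag,
             "quadrant": self.quadrant},
            index=pd.Index(self.unit_ids, name="unit"),
        )


def significance_stars(p: float) -> str:
    """10/5/1% two-sided star convention: * / ** / ***."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def _check_x(x: np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (n,):
        raise ValueError(f"x has shape {x.shape}, expected ({n},)")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    if np.ptp(x) == 0:
        raise ZeroDivisionError("x is constant: Moran's I is undefined")
    if n < 4:
        raise ValueError("Moran's I needs at least 4 units")
    return x


def morans_i(
    x, swm: SpatialWeightMatrix, null: str = "randomization"
) -> MoranResult:
    """Global Moran's I of one cross-sectional variable with a normal Z-test."""
    W = swm.W
    x = _check_x(x, swm.n)
    z = x - x.mean()
    S0 = W.sum()
    if S0 == 0:
        raise ZeroDivisionError("weight matrix has no links; Moran's I undefined")
    num = z @ W @ z
    den = z @ z
    I = (swm.n / S0) * (num / den)
    E_I, VAR_I = moran_moments(x, swm, null=null)
    Z = (I - E_I) / np.sqrt(VAR_I)
    p = 2 * stats.norm.sf(abs(Z))
    return MoranResult(I=float(I), E_I=E_I, VAR_I=VAR_I, Z=float(Z), p=float(p),
                       n=swm.n, null=null)


def moran_moments(
    x, swm: SpatialWeightMatrix, null: str = "randomization"
) -> tuple[float, float]:
    """Null expectation and variance of Moran's I.

    ``E(I) = -1/(n-1)`` under either null. The variance uses the textbook
    closed forms built from the weight sums

        S0 = sum_ij w_ij,
        S1 = (1/2) sum_ij (w_ij + w_ji)^2,
        S2 = sum_i (row_i sum + col_i sum)^2,

    and, under the randomization null, the sample kurtosis
    ``b2 = m4 / m2^2`` of x.
    """
    W = swm.W
    n = swm.n
    x = _check_x(x, n)
    S0 = W.sum()
    S1 = 0.5 * ((W + W.T) ** 2).sum()
    S2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    E_I = -1.0 / (n - 1)
    if null == "normality":
        var = (n**2 * S1 - n * S2 + 3 * S0**2) / (S0**2 * (n**2 - 1)) - E_I**2
    elif null == "randomization":
        z = x - x.mean()
        m2 = (z**2).mean()
        m4 = (z**4).mean()
        b2 = m4 / m2**2
        num = (n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2)
               - b2 * ((n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2))
        var = num / ((n - 1) * (n - 2) * (n - 3) * S0**2) - E_I**2
    else:
        raise ValueError(f"unknown null {null!r}; use 'normality' or 'randomization'")
    if var <= 0:
        raise ArithmeticError("nonpositive Moran variance (degenerate W or x)")
    return E_I, float(var)


def moran_scatter(x, swm: SpatialWeightMatrix) -> MoranScatter:
    """Moran scatter: standardized values vs spatial lags, with quadrants.

    Units exactly on a quadrant boundary (z-value or lag exactly zero) are
    assigned to the positive side, so every unit gets a label.
    """
    swm = row_standardize(swm)
    x = _check_x(x, swm.n)
    z = (x - x.mean()) / x.std()
    lag = swm.W @ z
    quad = []
    for zi, li in zip(z, lag):
        if zi >= 0:
            quad.append("HH" if li >= 0 else "HL")
        else:
            quad.append("LH" if li >= 0 else "LL")
    return MoranScatter(unit_ids=swm.unit_ids, z_value=z, spatial_lag=lag,
                        quadrant=tuple(quad))


def plot_moran_scatter(scatter: MoranScatter, path, title: str = "") -> None:
    """Render a Moran scatter (z-values vs spatial lags) to an image file.

    The quadrant table is the tested artifact; this rendering is a
    convenience for visual inspection.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(scatter.z_value, scatter.spatial_lag, s=18)
    lim = 1.1 * max(np.abs(scatter.z_value).max(),
                    np.abs(scatter.spatial_lag).max(), 1.0)
    ax.axhline(0, color="gray", lw=0.8)
    ax.axvline(0, color="gray", lw=0.8)
    ax.set(xlim=(-lim, lim), ylim=(-lim, lim),
           xlabel="standardized value", ylabel="spatial lag", title=title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def yearly_moran_table(
    panel: PanelDataset,
    variable: str,
    swm: SpatialWeightMatrix,
    null: str = "randomization",
) -> pd.DataFrame:
    """One Moran test per period for one panel variable.

    Returns a frame with columns ``I, Z, p, stars`` indexed by year. A year in
    which the variable is constant (Moran undefined) is flagged with NaNs
    rather than aborting the whole table.
    """
    if variable not in panel.variables:
        raise KeyError(f"variable {variable!r} not in panel")
    rows = {}
    for year in panel.periods:
        xv = panel.cross_section(variable, year)
        try:
            r = morans_i(xv, swm, null=null)
            rows[year] = {"I": r.I, "Z": r.Z, "p": r.p, "stars": r.stars}
        except ZeroDivisionError:
            rows[year] = {"I": np.nan, "Z": np.nan, "p": np.nan,
                          "stars": "undefined"}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "year"
    return out
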