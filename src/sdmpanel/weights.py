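"""Spatial weight matrices: contiguity, inverse distance, grouped, standardization.

A spatial weight matrix ``W`` is an n x n nonnegative matrix with zero diagonal
encoding proximity between observation units. Two constructions are supported:

* **contiguity** — binary adjacency, ``w_ij = 1`` iff units i and j share a border;
* **inverse distance** — ``w_ij = 1 / d_ij`` with ``d_ij`` the Euclidean distance
  between unit coordinates (so nearer units get larger weights).

Row standardization divides each nonzero row by its sum, making the spatial lag
``Wx`` a weighted average of neighboring values and bounding the largest
eigenvalue at 1 (the Perron root of a row-stochastic matrix). Grouped
(inter-regional) matrices keep only links *between* two designated unit groups,
which isolates cross-region spillovers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialWeightMatrix",
    "contiguity_from_adjacency",
    "inverse_distance_from_coords",
    "row_standardize",
    "inter_group_weights",
    "rho_interval",
]

#: tolerance on the imaginary part of eigenvalues of standardized matrices
_EIG_IMAG_TOL = 1e-8


class DegenerateGeometryError(ValueError):
    """Two units share coordinates, so an inverse-distance weight is undefined."""


@dataclass(frozen=True)
class SpatialWeightMatrix:
    """An n x n spatial weight matrix with provenance metadata.

    Attributes
    ----------
    W : ndarray
        Nonnegative weights, zero diagonal.
    unit_ids : tuple of str
        Ordered unit identifiers; row/column i belongs to ``unit_ids[i]``.
    style : {"binary", "raw", "row_standardized"}
        Standardization state. Inverse-distance matrices start as ``"raw"``.
    kind : {"contiguity", "inverse_distance", "grouped"}
    d : ndarray or None
        Pairwise Euclidean distances (inverse-distance matrices only).
    """

    W: np.ndarray
    unit_ids: tuple
    style: str
    kind: str
    d: np.ndarray | None = None
    _eigs_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"W must be square, got shape {W.shape}")
        if len(self.unit_ids) != W.shape[0]:
            raise ValueError("unit_ids length does not match W")
        if np.any(np.diag(W) != 0):
            raise ValueError("W must have a zero diagonal")
        if np.any(W < 0):
            raise ValueError("W must be nonnegative")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "unit_ids", tuple(self.unit_ids))

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def eigs(self) -> np.ndarray:
        """Real eigenvalue spectrum of ``W`` (cached).

        Raises a numeric error if the spectrum has an imaginary component
        beyond tolerance — our matrices are similar to symmetric ones, so
        complex eigenvalues indicate a construction bug.
        """
        if "eigs" not in self._eigs_cache:
            ev = np.linalg.eigvals(self.W)
            if np.max(np.abs(ev.imag)) > _EIG_IMAG_TOL * max(1.0, np.max(np.abs(ev))):
                raise ArithmeticError(
                    "weight matrix has complex eigenvalues beyond tolerance"
                )
            self._eigs_cache["eigs"] = np.sort(ev.real)
        return self._eigs_cache["eigs"]

    def index_of(self, units: Iterable) -> np.ndarray:
        """Positions of ``units`` in ``unit_ids`` (raises KeyError on unknowns)."""
        pos = {u: i for i, u in enumerate(self.unit_ids)}
        try:
            return np.array([pos[u] for u in units], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown unit id {exc.args[0]!r}") from None

    def subset(self, units: Sequence) -> "SpatialWeightMatrix":
        """Restrict to ``units`` (row/column selection), keeping style/kind."""
        idx = self.index_of(units)
        d = self.d[np.ix_(idx, idx)] if self.d is not None else None
        return SpatialWeightMatrix(
            self.W[np.ix_(idx, idx)], tuple(units), self.style, self.kind, d
        )

    def neighbors(self, unit) -> tuple:
        i = self.index_of([unit])[0]
        return tuple(self.unit_ids[j] for j in np.flatnonzero(self.W[i]))


def _warn_isolates(W: np.ndarray, unit_ids: Sequence) -> None:
    iso = np.flatnonzero(W.sum(axis=1) == 0)
    if len(iso) == len(unit_ids):
        logger.warning("all %d units are isolates (zero weight matrix)", len(unit_ids))
        warnings.warn("all units are isolates: weight matrix is zero", stacklevel=3)
    elif len(iso):
        names = [unit_ids[i] for i in iso]
        logger.warning("isolated units with no neighbors: %s", names)
        warnings.warn(f"isolated units retained with zero spatial lag: {names}",
                      stacklevel=3)


def contiguity_from_adjacency(
    adjacency: Iterable[tuple], unit_ids: Sequence
) -> SpatialWeightMatrix:
    """Binary contiguity matrix from an unordered adjacency pair list.

    ``w_ij = 1`` iff the unordered pair ``{i, j}`` appears in ``adjacency``
    (either orientation); the result is symmetric with zero diagonal.

    Raises
    ------
    KeyError
        If a pair references an unknown unit id.
    ValueError
        If a pair links a unit to itself.
    """
    unit_ids = tuple(unit_ids)
    pos = {u: i for i, u in enumerate(unit_ids)}
    n = len(unit_ids)
    W = np.zeros((n, n))
    for a, b in adjacency:
        if a not in pos:
            raise KeyError(f"unknown unit id {a!r} in adjacency list")
        if b not in pos:
            raise KeyError(f"unknown unit id {b!r} in adjacency list")
        if a == b:
            raise ValueError(f"self-pair ({a!r}, {b!r}) is not a valid contiguity")
        W[pos[a], pos[b]] = W[pos[b], pos[a]] = 1.0
    _warn_isolates(W, unit_ids)
    return SpatialWeightMatrix(W, unit_ids, style="binary", kind="contiguity")


def inverse_distance_from_coords(
    coords, unit_ids: Sequence | None = None
) -> SpatialWeightMatrix:
    """Inverse-distance weights ``w_ij = 1/d_ij`` from planar coordinates.

    Parameters
    ----------
    coords : (n, 2) array or mapping unit_id -> (x, y)
        Planar coordinates, one point per unit (e.g. provincial capitals on a
        projected plane); distances are straight-line Euclidean.
    unit_ids : sequence, optional
        Required when ``coords`` is an array; inferred from mapping keys otherwise.
    """
    if hasattr(coords, "items"):
        unit_ids = tuple(coords.keys())
        pts = np.asarray([coords[u] for u in unit_ids], dtype=float)
    else:
        pts = np.asarray(coords, dtype=float)
        if unit_ids is None:
            unit_ids = tuple(range(len(pts)))
        unit_ids = tuple(unit_ids)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("coords must be n x 2 planar points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    off = ~np.eye(len(pts), dtype=bool)
    if np.any(d[off] == 0):
        i, j = np.argwhere((d == 0) & off)[0]
        raise DegenerateGeometryError(
            f"units {unit_ids[i]!r} and {unit_ids[j]!r} share coordinates"
        )
    W = np.zeros_like(d)
    W[off] = 1.0 / d[off]
    return SpatialWeightMatrix(W, unit_ids, style="raw", kind="inverse_distance", d=d)


def row_standardize(swm: SpatialWeightMatrix) -> SpatialWeightMatrix:
    """Divide every nonzero row by its sum; all-zero rows pass through.

    Row standardization makes each row of ``W`` a probability vector, so the
    spatial lag is a weighted average of neighbors and the largest eigenvalue
    is exactly 1 for any matrix with at least one link per unit.
    """
    if swm.style == "row_standardized":
        return swm
    rs = swm.W.sum(axis=1)
    _warn_isolates(swm.W, swm.unit_ids)
    scale = np.where(rs > 0, rs, 1.0)
    W = swm.W / scale[:, None]
    return replace(swm, W=W, style="row_standardized", _eigs_cache={})


def inter_group_weights(
    swm: SpatialWeightMatrix, group_a: Sequence, group_b: Sequence
) -> SpatialWeightMatrix:
    """Grouped weight matrix keeping only links *between* two unit groups.

    Restricts ``swm`` to the units of ``group_a | group_b``, zeroes every
    within-group entry, and re-row-standardizes, so that the spatial lag of a
    unit in one group averages only over units of the other group. This is the
    construction used to measure cross-region spillovers.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError(f"groups overlap: {sorted(set_a & set_b)}")
    if not set_a or not set_b:
        raise ValueError("both groups must be nonempty")
    units = tuple(list(group_a) + list(group_b))
    sub = swm.subset(units)
    in_a = np.array([u in set_a for u in units])
    cross = in_a[:, None] ^ in_a[None, :]
    W = np.where(cross, sub.W, 0.0)
    # zeroing invalidates any prior standardization: rebuild from raw weights
    grouped = SpatialWeightMatrix(W, units, style="raw", kind="grouped", d=sub.d)
    return row_standardize(grouped)


def rho_interval(swm: SpatialWeightMatrix) -> tuple[float, float]:
    """Open interval of spatial parameters for which ``I - rho*W`` is invertible
    with positive-definite structure: ``(1/lambda_min, 1/lambda_max)``.

    Requires a row-standardized matrix, whose largest eigenvalue is 1 (so the
    upper bound is 1). The lower bound is ``1/lambda_min`` for the most
    negative eigenvalue; an edgeless matrix has no finite bounds.
    """
    if swm.style != "row_standardized":
        raise ValueError("rho_interval requires a row-standardized matrix")
    ev = swm.eigs
    lam_min, lam_max = ev[0], ev[-1]
    hi = 1.0 / lam_max if lam_max > 0 else np.inf
    lo = 1.0 / lam_min if lam_min < 0 else -np.inf
    return (lo, hi)
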