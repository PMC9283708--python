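"""Screened chemotactic field and the pairwise cell-cell attraction it induces.

Every cell is modelled as a point source of a diffusible attractant that is
degraded at a constant rate.  The chemical diffuses orders of magnitude
faster than a cell crawls, so its concentration field is taken as
stationary, obeying a screened Poisson equation

    -grad^2 phi(r) = alpha0 * sum_j delta(r - r_j) - lambda * phi(r).

In two dimensions the Green's function of this equation is the modified
Bessel function of the second kind of order zero, so the field produced by
a set of cells at positions ``r_j`` is ``phi(r) = alpha0 * sum_j
K0(|r - r_j| / sigma)`` with ``sigma`` the dimensionless screening
(attraction) range.  The drift it exerts on cell *i* is the corresponding
gradient: a sum of central pair terms of magnitude ``(Delta / sigma) *
K1(r_ij / sigma)`` pointing from cell *i* toward cell *j*.  ``Delta`` is
the dimensionless attraction strength, the single free parameter of the
model; all lengths are measured in cell diameters and times in
proliferation cycles.

The functions here are the exact reference implementations; the simulation
loop in :mod:`tumornet.dynamics` uses a tabulated version of the same force
for speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.special import k0, k1

__all__ = [
    "ForceFieldParams",
    "DimensionalMapping",
    "pair_force",
    "net_forces",
    "chemical_field",
]


@dataclass(frozen=True)
class ForceFieldParams:
    """Parameters of the screened pairwise attraction.

    Parameters
    ----------
    delta
        Dimensionless attraction strength ``Delta >= 0``.
    sigma
        Dimensionless attraction (screening) range, ``sigma > 0``.
    cutoff_radius
        Pair separations beyond this distance are dropped from force sums.
        Defaults to ``8 * sigma``; the magnitude of any dropped pair term is
        bounded by ``(delta / sigma) * K1(cutoff_radius / sigma)``, which at
        the default is a relative truncation of order ``K1(8)/K1(1) ~ 2e-4``.
    """

    delta: float
    sigma: float = 1.5
    cutoff_radius: float | None = None

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.cutoff_radius is None:
            object.__setattr__(self, "cutoff_radius", 8.0 * self.sigma)
        if self.cutoff_radius < self.sigma:
            raise ValueError("cutoff_radius must be >= sigma")


@dataclass(frozen=True)
class DimensionalMapping:
    """Dimensional parameters absorbed into the dimensionless model.

    The simulation runs entirely in units of the cell diameter ``ell`` and
    the proliferation cycle ``tau``; this record is metadata that documents
    how the dimensionless attraction strength ``Delta = mu * alpha0 * tau /
    ell**2`` and the unit diffusion coefficient arise from measurable
    quantities.

    Attributes
    ----------
    tau : float
        Cell proliferation cycle in seconds (default 1e4 s).
    ell : float
        Cell diameter in micrometres (default 10 um).
    D_cell : float
        Cell diffusion coefficient in um^2/s (default 1e-2, typical for
        cancer cells; note ``D_cell * tau / ell**2 = 1`` at the defaults).
    D_chem : float
        Chemical diffusion coefficient in um^2/s (order 1e2 for proteins).
    alpha0 : float
        Chemical emission rate divided by the chemical diffusion coefficient.
    lam : float
        Chemical degradation rate divided by the chemical diffusion
        coefficient (um^-2); the screening length is ``1/sqrt(lam)``.
    kappa : float
        Force strength coupling the cell to the chemical gradient.
    nu : float
        Friction coefficient of a cell in the extracellular matrix.
    """

    tau: float = 1.0e4
    ell: float = 10.0
    D_cell: float = 1.0e-2
    D_chem: float = 1.0e2
    alpha0: float = 1.0e-2
    lam: float = 1.0 / 225.0
    kappa: float = 1.0
    nu: float = 1.0

    @property
    def mu(self) -> float:
        """Cell motility ``kappa / nu``."""
        return self.kappa / self.nu

    @property
    def delta(self) -> float:
        """Dimensionless attraction strength ``mu * alpha0 * tau / ell**2``."""
        return self.mu * self.alpha0 * self.tau / self.ell**2

    @property
    def sigma(self) -> float:
        """Dimensionless attraction range ``1 / (ell * sqrt(lam))``."""
        return 1.0 / (self.ell * math.sqrt(self.lam))

    @property
    def dimensionless_diffusion(self) -> float:
        """Cell diffusion coefficient in simulation units, ``D_cell * tau / ell**2``."""
        return self.D_cell * self.tau / self.ell**2


def _positions(config) -> np.ndarray:
    """Accept either a CellConfiguration-like object or a raw (N, 2) array."""
    pos = getattr(config, "positions", config)
    pos = np.asarray(pos, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError(f"expected an (N, 2) array of positions, got shape {pos.shape}")
    return pos


def pair_force(delta: float, sigma: float, r_vec) -> np.ndarray:
    """Attractive force on cell *i* from cell *j*.

    Parameters
    ----------
    delta, sigma
        Attraction strength and range.
    r_vec
        2-vector from cell *j* to cell *i* (``r_i - r_j``).

    Returns
    -------
    numpy.ndarray
        Force on cell *i*: magnitude ``(delta / sigma) * K1(|r_vec| / sigma)``
        directed toward cell *j*.  Antisymmetric under exchange of *i* and *j*.

    Raises
    ------
    ValueError
        If the separation is zero (coincident centers are excluded by the
        overlap rule, and K1 diverges there).
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = math.hypot(r_vec[0], r_vec[1])
    if r == 0.0:
        raise ValueError("pair_force is undefined at zero separation")
    mag = (delta / sigma) * k1(r / sigma)
    return -mag * r_vec / r


def net_forces(config, ff: ForceFieldParams, method: str = "auto") -> np.ndarray:
    """Total attraction force on every cell.

    Each cell's force is the sum of :func:`pair_force` over all other cells
    within ``ff.cutoff_radius``.

    Parameters
    ----------
    config
        A cell configuration (anything with an ``(N, 2)`` ``positions``
        attribute, or the array itself).
    ff
        Force-field parameters.
    method
        ``"brute"`` sums all pairs directly, ``"tree"`` restricts the sum to
        pairs found by a k-d tree within the cutoff, ``"auto"`` picks by size.
        Both apply the same cutoff and agree to floating tolerance.

    Returns
    -------
    numpy.ndarray
        ``(N, 2)`` array of force vectors.
    """
    pos = _positions(config)
    n = len(pos)
    if n <= 1 or ff.delta == 0.0:
        return np.zeros((n, 2))
    if method == "auto":
        method = "tree" if n > 512 else "brute"

    if method == "brute":
        diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = r_j - r_i
        dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dist, np.inf)
        within = dist <= ff.cutoff_radius
        scale = np.zeros_like(dist)
        scale[within] = (ff.delta / ff.sigma) * k1(dist[within] / ff.sigma) / dist[within]
        return np.einsum("ij,ijk->ik", scale, diff)

    if method == "tree":
        tree = cKDTree(pos)
        pairs = tree.query_pairs(ff.cutoff_radius, output_type="ndarray")
        forces = np.zeros((n, 2))
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            diff = pos[j] - pos[i]
            dist = np.hypot(diff[:, 0], diff[:, 1])
            if np.any(dist == 0.0):
                raise ValueError("coincident cell centers in configuration")
            s = (ff.delta / ff.sigma) * k1(dist / ff.sigma) / dist
            contrib = s[:, None] * diff
            np.add.at(forces, i, contrib)
            np.add.at(forces, j, -contrib)
        return forces

    raise ValueError(f"unknown method {method!r}")


def chemical_field(sources, query_points, sigma: float = 1.5) -> np.ndarray:
    """Stationary chemoattractant concentration at the query points.

    Returns ``sum_j K0(|r - r_j| / sigma)`` for each query point ``r``, in
    units where the emission prefactor ``alpha0`` is one.

    Raises
    ------
    ValueError
        If a query point coincides with a source center (K0 diverges at 0).
    """
    query = np.atleast_2d(np.asarray(query_points, dtype=float))
    src = _positions(sources) if np.size(getattr(sources, "positions", sources)) else np.empty((0, 2))
    if len(src) == 0:
        return np.zeros(len(query))
    d = cdist(query, src)
    if np.any(d == 0.0):
        raise ValueError("chemical_field query coincides with a source center")
    return k0(d / sigma).sum(axis=1)
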