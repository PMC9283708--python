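"""Spatial observables: pair distribution, radius of gyration, power-law fits.

The pair distribution function used here is the tumor-literature convention

    g(r) = (1/N) * sum over ordered pairs (i != j) of 1[|r_i - r_j| in bin]
           / bin width,

*not* the density-normalized radial distribution function of liquid-state
theory: its total mass integrates to exactly N - 1.  The radius of gyration
``R_g = sqrt((1/N) sum_i |r_i - r_cm|^2)`` is the root-mean-square distance
of cells from the tumor's center of mass and serves as its characteristic
size.

Power-law exponents (for component-size histograms and critical g(r)
shapes) are estimated by ordinary least squares on log-log points, with a
logarithmic-binning helper that converts raw counts into width-normalized
densities so that a density ~ s**a yields slope a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "RadialHistogram",
    "PowerLawFit",
    "pair_distribution",
    "radius_of_gyration",
    "gyration_series",
    "log_binned_histogram",
    "fit_power_law_slope",
    "degree_snapshot",
    "plot_degree_snapshot",
]


@dataclass
class RadialHistogram:
    """Binned pair-distance weights.

    ``values[b]`` is the ordered-pair count in bin ``b`` divided by N and by
    the bin width (i.e. g(r) evaluated on the bin); ``normalization``
    records the convention so exported figures are comparable.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    normalization: str = "ordered-pairs / N per unit distance (mass = N - 1)"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.values * np.diff(self.bin_edges)))


@dataclass
class PowerLawFit:
    """Least-squares log-log slope over a fit range."""

    exponent: float
    intercept: float
    fit_range: tuple
    r_squared: float
    n_points: int


def pair_distribution(config, bin_edges) -> RadialHistogram:
    """Histogram of inter-cell distances, normalized by cell count.

    Single-configuration version of the ensemble-averaged g(r); averaging
    over replicates is the caller's job (the per-bin values of replicate
    histograms can simply be averaged).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    pos = np.asarray(getattr(config, "positions", config), dtype=float).reshape(-1, 2)
    n = len(pos)
    if n < 1:
        raise ValueError("pair_distribution needs at least one cell")
    widths = np.diff(edges)
    if n == 1:
        return RadialHistogram(edges, np.zeros(len(widths)))
    d = pdist(pos)
    counts, _ = np.histogram(d, bins=edges)
    values = 2.0 * counts / n / widths  # ordered pairs: each unordered pair twice
    return RadialHistogram(edges, values)


def radius_of_gyration(config) -> float:
    """Root-mean-square distance of cells from their center of mass."""
    pos = np.asarray(getattr(config, "positions", config), dtype=float).reshape(-1, 2)
    if len(pos) == 0:
        raise ValueError("radius_of_gyration needs at least one cell")
    rel = pos - pos.mean(axis=0)
    return float(np.sqrt(np.mean(rel[:, 0] ** 2 + rel[:, 1] ** 2)))


def gyration_series(record):
    """R_g evaluated on each stored snapshot of a run, in snapshot order.

    Returns (times, values) arrays; raises if the run kept no snapshots.
    """
    if not record.snapshots:
        raise ValueError("run record has no snapshots (set snapshot_every > 0)")
    times = np.array([s.time for s in record.snapshots])
    values = np.array([radius_of_gyration(s) for s in record.snapshots])
    return times, values


def log_binned_histogram(values, factor: float = 2.0, x_min: float | None = None):
    """Geometric binning of positive values into width-normalized densities.

    Bin edges grow by ``factor`` from ``x_min`` (default: smallest value);
    returns (centers, density, counts) with geometric-mean bin centers and
    ``density = count / bin width``, the convention under which data drawn
    from a density ~ x**a fit a log-log slope of a.  Empty trailing bins are
    kept so the caller can see gaps; zero-count bins are excluded by the
    fitting helper.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("log binning requires positive values")
    if factor <= 1:
        raise ValueError("factor must be > 1")
    lo = float(v.min()) if x_min is None else float(x_min)
    hi = float(v.max())
    n_bins = max(1, int(np.ceil(np.log(hi / lo) / np.log(factor) + 1e-12)))
    edges = lo * factor ** np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi * (1 + 1e-12))  # make top edge inclusive
    counts, _ = np.histogram(v, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    density = counts / np.diff(edges)
    return centers, density, counts


def fit_power_law_slope(x, y=None, fit_range: tuple | None = None) -> PowerLawFit:
    """Ordinary least squares on log-log points.

    Parameters
    ----------
    x, y
        Abscissae and (density) ordinates, or a :class:`RadialHistogram`
        as the single first argument (bin centers / values are used).
    fit_range
        ``(lo, hi)`` restriction on x; default: the full support.

    Zero or negative ordinates are excluded; at least three usable points
    are required.
    """
    if y is None:
        hist = x
        x = hist.bin_centers
        y = hist.values
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = (y > 0) & (x > 0)
    if fit_range is not None:
        lo, hi = fit_range
        mask &= (x >= lo) & (x <= hi)
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 usable points in fit range, got {int(mask.sum())}")
    lx = np.log(x[mask])
    ly = np.log(y[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    used_x = x[mask]
    return PowerLawFit(
        exponent=float(slope),
        intercept=float(intercept),
        fit_range=(float(used_x.min()), float(used_x.max())),
        r_squared=float(r2),
        n_points=int(mask.sum()),
    )


def degree_snapshot(config, net):
    """Table of (cell_id, x, y, degree) for color-by-degree plotting.

    Isolated cells carry degree 0; rows are ordered by cell id so that the
    row count equals the total cell count (network nodes plus isolated).
    """
    import pandas as pd

    pos = np.asarray(getattr(config, "positions", config), dtype=float).reshape(-1, 2)
    ids = np.asarray(getattr(config, "ids", np.arange(len(pos))), dtype=np.int64)
    deg = {int(i): len(net.neighbors[int(i)]) for i in net.node_ids}
    order = np.argsort(ids)
    return pd.DataFrame(
        {
            "cell_id": ids[order],
            "x": pos[order, 0],
            "y": pos[order, 1],
            "degree": [deg.get(int(i), 0) for i in ids[order]],
        }
    )


def plot_degree_snapshot(table, ax=None, cmap: str = "viridis", size: float = 25.0):
    """Minimal degree heat plot: cells as points colored by contact degree."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(table["x"], table["y"], c=table["degree"], s=size,
                    cmap=cmap, vmin=0, vmax=6)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cell diameters)")
    ax.set_ylabel("y (cell diameters)")
    plt.colorbar(sc, ax=ax, label="degree")
    return ax
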