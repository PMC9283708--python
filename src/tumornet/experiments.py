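"""Attraction-strength sweeps, transition detection, and test fixtures.

The phase analysis treats the inverse attraction strength ``1/Delta`` as a
temperature-like control parameter.  For each ``Delta`` a batch of
surviving replicate runs is collected, every replicate's *final*
configuration is summarized by its contact-network measures, and the
replicate mean and standard deviation of each measure are recorded against
``1/Delta``.  The transitions show up as peaks of the numerical derivative
of these curves:

* liquid-gas from the derivative of ``P_2`` (fraction of degree-2 nodes),
* solid-liquid from the derivative of ``P_6`` (fraction of stiff nodes;
  the curve is decreasing so its derivative's most negative point is the
  transition),
* an internal rearrangement (poly- to single-crystal-like ordering) from
  the transitivity derivative.

Also here: deterministic geometric fixtures (hexagonal packings, hard-core
gases, well-separated clusters) used throughout the test-suite and as
reference configurations for the three phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .contact_network import build_contact_network, summarize
from .dynamics import CellConfiguration, SimulationParams, run_surviving_replicates

__all__ = [
    "MEASURES",
    "SweepCurve",
    "PeakResult",
    "TransitionReport",
    "summarize_record",
    "aggregate_summaries",
    "run_sweep",
    "finite_difference",
    "locate_peak",
    "transition_report",
    "classify_phase",
    "pooled_component_sizes",
    "fixture_hexagonal",
    "fixture_hardcore_gas",
    "fixture_clusters",
]

#: Attraction strengths used for the reference degree-colored snapshots of
#: the three phases.  Two presets are provided: one spanning the liquid to
#: deep-solid regimes and one centered on the critical region.
SNAPSHOT_PRESETS = {
    "solid_series": (1.5, 1.9, 2.5),
    "critical_series": (1.2, 1.5, 2.0),
}

#: Measures tracked per sweep point (keys of NetworkSummary.measures()).
MEASURES = (
    "n_nodes", "total_cells", "n_links", "n_components", "rho_c",
    "P_2", "P_6", "mean_degree", "knn", "transitivity", "mean_clustering",
    "s_max",
)


def summarize_record(record, threshold: float = 1.0) -> dict:
    """Scalar network measures of a run's final configuration.

    An all-isolated (or empty) final configuration yields ``n_nodes = 0``
    and NaN for the measures that are undefined without nodes; NaNs are
    ignored by the sweep aggregation.
    """
    net = build_contact_network(record.final, threshold)
    if net.n_nodes == 0:
        out = {m: math.nan for m in MEASURES}
        out["n_nodes"] = 0.0
        out["n_links"] = 0.0
        out["total_cells"] = float(record.final.n_cells)
        return out
    return summarize(net).measures()


def aggregate_summaries(rows: list) -> dict:
    """Replicate mean and sample SD (ddof=1; 0 for a single replicate)."""
    out = {}
    for m in MEASURES:
        vals = np.array([r[m] for r in rows], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            out[m] = (math.nan, math.nan, 0)
        elif len(vals) == 1:
            out[m] = (float(vals[0]), 0.0, 1)
        else:
            out[m] = (float(vals.mean()), float(vals.std(ddof=1)), len(vals))
    return out


@dataclass
class SweepCurve:
    """Replicate-averaged network measures on an increasing 1/Delta grid."""

    delta: np.ndarray
    delta_inv: np.ndarray
    means: dict          # measure -> array over grid
    sds: dict            # measure -> array over grid
    n_replicates: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.delta_inv) <= 0):
            raise ValueError("delta_inv grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (grid point, measure)."""
        rows = []
        for g in range(len(self.delta)):
            for m in MEASURES:
                rows.append(
                    {
                        "delta": self.delta[g],
                        "delta_inv": self.delta_inv[g],
                        "measure": m,
                        "mean": self.means[m][g],
                        "sd": self.sds[m][g],
                        "n_reps": int(self.n_replicates[g]),
                    }
                )
        return pd.DataFrame(rows)


def run_sweep(deltas, base_params: SimulationParams, n_replicates: int = 20,
              progress: bool = False) -> SweepCurve:
    """Run surviving replicates for each attraction strength and aggregate.

    Replicate seeds derive from ``base_params.seed`` plus a per-Delta
    offset, so distinct grid points use disjoint seed blocks.
    """
    deltas = np.asarray(sorted(deltas, reverse=True), dtype=float)  # increasing 1/Delta
    if np.any(deltas <= 0):
        raise ValueError("all deltas must be > 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    means = {m: [] for m in MEASURES}
    sds = {m: [] for m in MEASURES}
    n_reps = []
    for gi, d in enumerate(deltas):
        params = replace(base_params, delta=float(d),
                         seed=base_params.seed + 100_000 * gi)
        if progress:
            print(f"Delta = {d:g} (1/Delta = {1/d:.3f})")
        records = run_surviving_replicates(params, n_replicates, progress=progress)
        agg = aggregate_summaries([summarize_record(r, base_params.contact_threshold)
                                   for r in records])
        for m in MEASURES:
            means[m].append(agg[m][0])
            sds[m].append(agg[m][1])
        n_reps.append(agg["n_nodes"][2])
    return SweepCurve(
        delta=deltas,
        delta_inv=1.0 / deltas,
        means={m: np.array(v) for m, v in means.items()},
        sds={m: np.array(v) for m, v in sds.items()},
        n_replicates=np.array(n_reps),
    )


def finite_difference(x, y, smooth_window: int = 0):
    """dy/dx by central differences (one-sided at the ends).

    ``smooth_window`` > 1 applies a centered moving average to y first
    (window 1 or 0 is the identity); useful for noisy replicate means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if smooth_window and smooth_window > 1:
        w = int(smooth_window)
        kernel = np.ones(w) / w
        pad = w // 2
        padded = np.concatenate([np.full(pad, y[0]), y, np.full(w - 1 - pad, y[-1])])
        y = np.convolve(padded, kernel, mode="valid")
    d = np.empty_like(y)
    d[0] = (y[1] - y[0]) / (x[1] - x[0])
    d[-1] = (y[-1] - y[-2]) / (x[-1] - x[-2])
    d[1:-1] = (y[2:] - y[:-2]) / (x[2:] - x[:-2])
    return d


@dataclass(frozen=True)
class PeakResult:
    """Location of a derivative peak, with +/- one grid spacing uncertainty."""

    location: float
    uncertainty: float
    index: int


def locate_peak(x, dy, search_range: tuple | None = None) -> PeakResult | None:
    """Abscissa of the maximum of ``dy`` (pass ``-dy`` for decreasing measures).

    Returns ``None`` when ``dy`` is monotone over the searched range with
    its maximum on the boundary — no interior extremum means no detected
    transition.  Ties break toward the lower abscissa.  The uncertainty is
    the local grid spacing.
    """
    x = np.asarray(x, dtype=float)
    dy = np.asarray(dy, dtype=float)
    idx = np.arange(len(x))
    if search_range is not None:
        lo, hi = search_range
        sel = (x >= lo) & (x <= hi)
        if sel.sum() < 3:
            raise ValueError("need >= 3 points inside search_range")
        x, dy, idx = x[sel], dy[sel], idx[sel]
    k = int(np.argmax(dy))  # argmax takes the first (lowest-x) maximum
    if k == 0 or k == len(x) - 1:
        diffs = np.diff(dy)
        if np.all(diffs >= 0) or np.all(diffs <= 0):
            return None
    spacing = x[min(k + 1, len(x) - 1)] - x[max(k - 1, 0)]
    return PeakResult(location=float(x[k]),
                      uncertainty=float(spacing / 2.0),
                      index=int(idx[k]))


@dataclass
class TransitionReport:
    """Detected transition points on the 1/Delta axis.

    When all three peaks are found they obey
    ``rearrangement < solid_liquid < liquid_gas``.
    """

    solid_liquid_peak: PeakResult | None
    liquid_gas_peak: PeakResult | None
    rearrangement_peak: PeakResult | None
    smooth_window: int = 0

    @property
    def ordering_ok(self) -> bool:
        peaks = [self.rearrangement_peak, self.solid_liquid_peak, self.liquid_gas_peak]
        if any(p is None for p in peaks):
            return True  # nothing to violate
        locs = [p.location for p in peaks]
        return locs[0] < locs[1] < locs[2]

    @property
    def phase_bounds(self) -> tuple:
        """(solid/liquid boundary, liquid/gas boundary) on the 1/Delta axis."""
        if self.solid_liquid_peak is None or self.liquid_gas_peak is None:
            raise ValueError("both main peaks are required for phase bounds")
        return (self.solid_liquid_peak.location, self.liquid_gas_peak.location)

    def to_dict(self) -> dict:
        def _p(p):
            return None if p is None else {
                "delta_inv": p.location, "uncertainty": p.uncertainty,
            }
        return {
            "solid_liquid_peak": _p(self.solid_liquid_peak),
            "liquid_gas_peak": _p(self.liquid_gas_peak),
            "rearrangement_peak": _p(self.rearrangement_peak),
            "smooth_window": self.smooth_window,
            "ordering_ok": self.ordering_ok,
        }


# Sign conventions: +1 for measures increasing with 1/Delta (their
# derivative peak is a maximum), -1 for decreasing ones (the transition is
# the most negative derivative, i.e. the maximum of -dy).
_MEASURE_SIGN = {"P_2": +1.0, "P_6": -1.0, "transitivity": -1.0}


def transition_report(curve: SweepCurve, smooth_window: int = 0) -> TransitionReport:
    """Locate the three transition peaks on a sweep curve."""
    peaks = {}
    for measure in ("P_2", "P_6", "transitivity"):
        dy = finite_difference(curve.delta_inv, curve.means[measure], smooth_window)
        peaks[measure] = locate_peak(curve.delta_inv, _MEASURE_SIGN[measure] * dy)
    return TransitionReport(
        solid_liquid_peak=peaks["P_6"],
        liquid_gas_peak=peaks["P_2"],
        rearrangement_peak=peaks["transitivity"],
        smooth_window=smooth_window,
    )


def classify_phase(delta_inv: float, report: TransitionReport) -> str:
    """Assign 'solid' / 'liquid' / 'gas' from the detected phase bounds."""
    sl, lg = report.phase_bounds
    if delta_inv < sl:
        return "solid"
    if delta_inv > lg:
        return "gas"
    return "liquid"


def pooled_component_sizes(records, threshold: float = 1.0) -> np.ndarray:
    """Component sizes of every record's final contact network, pooled."""
    sizes: list[int] = []
    for rec in records:
        net = build_contact_network(rec.final, threshold)
        if net.n_nodes == 0:
            continue
        from .contact_network import connected_components

        _, s = connected_components(net)
        sizes.extend(s)
    return np.array(sizes, dtype=np.int64)


# ---------------------------------------------------------------------------
# Geometric fixtures
# ---------------------------------------------------------------------------

def fixture_hexagonal(n_shells: int) -> CellConfiguration:
    """Triangular-lattice packing at spacing exactly 1, centered at origin.

    Shell counts are 1, 7, 19, 37, ... (1 + 3 n (n + 1)); every node with
    a full shell of neighbors has the kissing degree six.
    """
    if n_shells < 0:
        raise ValueError("n_shells must be >= 0")
    pts = []
    for q in range(-n_shells, n_shells + 1):
        for r in range(-n_shells, n_shells + 1):
            if abs(q + r) > n_shells:
                continue
            pts.append((q + 0.5 * r, r * math.sqrt(3.0) / 2.0))
    pts.sort(key=lambda p: (p[0] ** 2 + p[1] ** 2, p[0], p[1]))
    pos = np.array(pts)
    return CellConfiguration(time=0.0, positions=pos, ids=np.arange(len(pos)))


def fixture_hardcore_gas(n: int, box_side: float, min_dist: float = 1.0,
                         seed: int = 0, max_attempts_per_point: int = 1000) -> CellConfiguration:
    """Rejection-sampled points in a box with all pairwise distances >= min_dist.

    Raises if the requested density is infeasible within the attempt budget.
    """
    rng = np.random.default_rng(seed)
    pts: list = []
    for _ in range(n):
        for attempt in range(max_attempts_per_point):
            cand = rng.random(2) * box_side
            if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_dist**2
                   for p in pts):
                pts.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place point {len(pts) + 1}/{n} at min_dist={min_dist} "
                f"in a {box_side} x {box_side} box (density too high)"
            )
    pos = np.array(pts).reshape(-1, 2)
    return CellConfiguration(time=0.0, positions=pos, ids=np.arange(n))


def fixture_clusters(k_clusters: int, cluster_size: int, intra_spacing: float = 0.9,
                     inter_gap: float = 5.0, seed: int = 0) -> CellConfiguration:
    """k compact hexagonal-patch clusters far enough apart to stay disconnected.

    Each cluster is a patch of the triangular lattice scaled to
    ``intra_spacing``; cluster centers sit on a coarse grid ``inter_gap``
    plus cluster diameter apart, so the contact network has exactly k
    components (for ``inter_gap`` above the contact threshold).
    """
    if inter_gap <= 1.0:
        raise ValueError("inter_gap must exceed the contact threshold (1.0)")
    rng = np.random.default_rng(seed)
    shell = 0
    while 1 + 3 * shell * (shell + 1) < cluster_size:
        shell += 1
    patch = fixture_hexagonal(shell).positions[:cluster_size] * intra_spacing
    diameter = 2 * shell * intra_spacing + 1.0
    pitch = diameter + inter_gap
    side = int(np.ceil(np.sqrt(k_clusters)))
    pos_blocks = []
    for c in range(k_clusters):
        phi = rng.random() * 2 * math.pi  # random per-cluster orientation
        rot = np.array([[math.cos(phi), -math.sin(phi)],
                        [math.sin(phi), math.cos(phi)]])
        cx = (c % side) * pitch
        cy = (c // side) * pitch
        pos_blocks.append(patch @ rot.T + np.array([cx, cy]))
    pos = np.vstack(pos_blocks)
    return CellConfiguration(time=0.0, positions=pos, ids=np.arange(len(pos)))
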