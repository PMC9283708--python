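"""Stochastic growth dynamics: death, birth, and Brownian motion sweeps.

A tumor starts as a single founder cell at the origin.  Each time step
applies three sub-sweeps in the fixed order

1. **death** — every cell dies independently with probability ``gamma * dt``;
2. **birth** — every surviving pre-existing cell proliferates with
   probability ``Gamma * dt``, placing its daughter at distance exactly one
   cell diameter at a uniform random angle (the placement is redrawn up to
   ``max_retries`` times if it overlaps an existing cell too deeply, then
   the birth is rejected);
3. **motion** — every cell takes an Euler-Maruyama step
   ``drift * dt + sqrt(2 * D * dt) * eta`` with the drift given by the
   screened pairwise attraction (:mod:`tumornet.chemistry`) and ``eta`` a
   standard Gaussian 2-vector, cells updated one by one in id order.  A step
   that would bring two centers closer than the overlap floor redraws its
   noise up to ``max_retries`` times and otherwise leaves the cell in place.

Cells are unit-diameter compressible discs: center distances down to the
overlap floor (default 0.8, i.e. overlap depth < 0.2 diameters) are
admissible, anything closer is rejected.  The plane is unbounded.

Everything is dimensionless — lengths in cell diameters, time in
proliferation cycles — and fully reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.special import k1

from ._kernels import move_sweep_kernel

__all__ = [
    "SimulationParams",
    "CellConfiguration",
    "RunRecord",
    "death_sweep",
    "birth_sweep",
    "move_sweep",
    "is_admissible",
    "run_simulation",
    "run_surviving_replicates",
    "ExtinctionCapError",
]


class ExtinctionCapError(RuntimeError):
    """Raised when too many replicate runs go extinct to collect survivors."""


@dataclass(frozen=True)
class SimulationParams:
    """All dimensionless control parameters of one simulation run.

    Attributes
    ----------
    delta : float
        Attraction strength ``Delta``; the single free parameter.
    sigma : float
        Attraction range (default 1.5).
    birth_rate : float
        Proliferation rate ``Gamma`` per proliferation cycle (default 1).
    death_rate : float
        Death rate ``gamma`` (default 0.1).  A growing tumor needs
        ``Gamma > gamma``; this is documented, not enforced, so that
        degenerate test settings (no birth, certain death) remain legal.
    diffusion : float
        Dimensionless cell diffusion coefficient ``D`` (default 1).
    dt : float
        Time step (default 1e-3).  ``Gamma * dt`` and ``gamma * dt`` must be
        valid per-step probabilities.
    n_steps : int
        Number of time steps (default 40_000, i.e. 40 proliferation cycles).
    seed : int
        RNG seed; one seeded generator drives the whole run.
    max_retries : int
        Attempts for overlapping birth placements / motion proposals.
    overlap_floor : float
        Minimum admissible center distance (default 0.8, inclusive).
    contact_threshold : float
        Center distance defining a network contact (default 1.0).
    cutoff_radius : float or None
        Pairwise force cutoff; ``None`` means ``8 * sigma``.
    snapshot_every : int
        Record a configuration snapshot every this many steps (0 = none;
        the final configuration is always available in the record).
    """

    delta: float
    sigma: float = 1.5
    birth_rate: float = 1.0
    death_rate: float = 0.1
    diffusion: float = 1.0
    dt: float = 1.0e-3
    n_steps: int = 40_000
    seed: int = 0
    max_retries: int = 100
    overlap_floor: float = 0.8
    contact_threshold: float = 1.0
    cutoff_radius: float | None = None
    snapshot_every: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.birth_rate * self.dt > 1 or self.death_rate * self.dt > 1:
            raise ValueError("rate * dt must be a valid per-step probability (<= 1)")
        if self.diffusion < 0:
            raise ValueError("diffusion must be >= 0")
        if self.n_steps < 0 or self.max_retries < 1:
            raise ValueError("n_steps must be >= 0 and max_retries >= 1")
        if not (0 < self.overlap_floor <= self.contact_threshold):
            raise ValueError("need 0 < overlap_floor <= contact_threshold")
        if self.cutoff_radius is not None and self.cutoff_radius < self.sigma:
            raise ValueError("cutoff_radius must be >= sigma")

    @property
    def cutoff(self) -> float:
        return 8.0 * self.sigma if self.cutoff_radius is None else self.cutoff_radius


@dataclass
class CellConfiguration:
    """Positions of the live cells at one time point.

    Positions are in units of the cell diameter; ids are stable integers
    assigned in birth order (the founder is id 0).
    """

    time: float
    positions: np.ndarray  # (N, 2) float64
    ids: np.ndarray        # (N,) int64

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64).reshape(-1, 2)
        self.ids = np.asarray(self.ids, dtype=np.int64).reshape(-1)
        if len(self.positions) != len(self.ids):
            raise ValueError("positions and ids must have the same length")

    @classmethod
    def founder(cls) -> "CellConfiguration":
        return cls(time=0.0, positions=np.zeros((1, 2)), ids=np.array([0]))

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    def copy(self) -> "CellConfiguration":
        return CellConfiguration(self.time, self.positions.copy(), self.ids.copy())

    def validate(self, overlap_floor: float = 0.8) -> None:
        """Check invariants: finite positions, unique ids, pairwise distances >= floor."""
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite cell positions")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("duplicate cell ids")
        if self.n_cells > 1:
            from scipy.spatial.distance import pdist

            dmin = pdist(self.positions).min()
            if dmin < overlap_floor - 1e-12:
                raise ValueError(
                    f"overlap violation: min center distance {dmin:.6f} < {overlap_floor}"
                )


@dataclass
class RunRecord:
    """Everything recorded from one simulation run."""

    params: SimulationParams
    final: CellConfiguration
    extinct: bool
    population_times: np.ndarray
    population_counts: np.ndarray
    snapshots: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.extinct != (self.final.n_cells == 0):
            raise ValueError("extinct flag inconsistent with final population")


def is_admissible(positions, candidate, ignore_index: int | None = None,
                  overlap_floor: float = 0.8) -> bool:
    """True iff ``candidate`` keeps center distance >= ``overlap_floor``
    (inclusive) from every other cell center."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    if len(pos) == 0:
        return True
    d2 = (pos[:, 0] - candidate[0]) ** 2 + (pos[:, 1] - candidate[1]) ** 2
    if ignore_index is not None:
        d2 = np.delete(d2, ignore_index)
    if len(d2) == 0:
        return True
    return bool(d2.min() >= overlap_floor**2 - 1e-12)


def death_sweep(config: CellConfiguration, params: SimulationParams,
                rng: np.random.Generator) -> CellConfiguration:
    """Remove each cell independently with probability ``gamma * dt``."""
    n = config.n_cells
    if n == 0:
        return config.copy()
    keep = rng.random(n) >= params.death_rate * params.dt
    return CellConfiguration(config.time, config.positions[keep], config.ids[keep])


def birth_sweep(config: CellConfiguration, params: SimulationParams,
                rng: np.random.Generator) -> CellConfiguration:
    """Let each pre-existing cell proliferate with probability ``Gamma * dt``.

    The daughter is placed at distance exactly one cell diameter from its
    mother at a uniform random angle.  If the site is inadmissible the angle
    is redrawn, up to ``max_retries`` times, after which the birth is
    rejected.  Daughters born in this sweep do not divide within it, but
    they do count as obstacles for later placements.
    """
    n = config.n_cells
    if n == 0:
        return config.copy()
    p = params.birth_rate * params.dt
    mothers = np.flatnonzero(rng.random(n) < p)
    if len(mothers) == 0:
        return config.copy()

    floor2 = params.overlap_floor**2 - 1e-12
    new_ids = list(config.ids)
    next_id = int(config.ids.max()) + 1
    px = config.positions[:, 0]
    py = config.positions[:, 1]
    extra_x: list[float] = []
    extra_y: list[float] = []
    for i in mothers:
        mx = config.positions[i, 0]
        my = config.positions[i, 1]
        for _ in range(params.max_retries):
            theta = rng.random() * 2.0 * math.pi
            cx = mx + math.cos(theta)
            cy = my + math.sin(theta)
            d2 = (px - cx) ** 2 + (py - cy) ** 2
            if d2.min() < floor2:
                continue
            ok = True
            for ex, ey in zip(extra_x, extra_y):
                if (ex - cx) ** 2 + (ey - cy) ** 2 < floor2:
                    ok = False
                    break
            if ok:
                extra_x.append(cx)
                extra_y.append(cy)
                new_ids.append(next_id)
                next_id += 1
                break
    if not extra_x:
        return config.copy()
    positions = np.column_stack(
        [np.concatenate([config.positions[:, 0], extra_x]),
         np.concatenate([config.positions[:, 1], extra_y])]
    )
    return CellConfiguration(config.time, positions, np.array(new_ids))


@lru_cache(maxsize=32)
def _force_table(delta: float, sigma: float, cutoff: float):
    """Tabulate ``(delta/sigma) * K1(r/sigma) / r`` on [0.2, cutoff + 2*dr].

    Pair separations never drop below the overlap floor (0.8 by default),
    so 0.2 is a comfortable lower bound; the kernel clamps below it.
    """
    r0, dr = 0.2, 0.002
    r = np.arange(r0, cutoff + 2 * dr, dr)
    tab = (delta / sigma) * k1(r / sigma) / r
    return r0, dr, tab


_GRID_BIN = 3.0


def _build_grid(pos: np.ndarray):
    ox = float(pos[:, 0].min())
    oy = float(pos[:, 1].min())
    ix = np.floor((pos[:, 0] - ox) / _GRID_BIN).astype(np.int64)
    iy = np.floor((pos[:, 1] - oy) / _GRID_BIN).astype(np.int64)
    nbx = int(ix.max()) + 1
    nby = int(iy.max()) + 1
    flat = ix * nby + iy
    order = np.argsort(flat, kind="stable").astype(np.int64)
    counts = np.bincount(flat, minlength=nbx * nby)
    bin_start = np.zeros(nbx * nby + 1, dtype=np.int64)
    np.cumsum(counts, out=bin_start[1:])
    return ox, oy, nbx, nby, bin_start, order


def move_sweep(config: CellConfiguration, params: SimulationParams,
               rng: np.random.Generator) -> CellConfiguration:
    """Advance every cell by one Euler-Maruyama step; returns time + dt.

    Cells are updated sequentially in id order, each later cell seeing the
    new positions of earlier ones.  Inadmissible proposals redraw only their
    Gaussian noise (the drift is configuration-determined), up to
    ``max_retries`` times, then the cell keeps its position.
    """
    n = config.n_cells
    if n == 0:
        return CellConfiguration(config.time + params.dt, config.positions.copy(),
                                 config.ids.copy())
    pos = config.positions.copy()
    use_force = params.delta > 0 and n > 1
    cutoff = params.cutoff
    r0, dr, tab = _force_table(params.delta, params.sigma, cutoff)
    ox, oy, nbx, nby, bin_start, order = _build_grid(pos)
    scan = max(2, math.ceil((cutoff + 1.5) / _GRID_BIN)) if use_force else 2
    seed = int(rng.integers(0, 2**31))
    move_sweep_kernel(
        pos, use_force, tab, r0, dr, cutoff**2,
        params.dt, math.sqrt(2.0 * params.diffusion * params.dt),
        params.overlap_floor**2 - 1e-12, params.max_retries, seed,
        ox, oy, 1.0 / _GRID_BIN, nbx, nby, bin_start, order, scan,
    )
    return CellConfiguration(config.time + params.dt, pos, config.ids.copy())


def run_simulation(params: SimulationParams) -> RunRecord:
    """Run a full growth simulation from a single founder cell at the origin.

    Per step the death, birth, and motion sweeps are applied in that order;
    the run terminates early (with ``extinct=True``) if the population
    reaches zero.  The per-step population series is always recorded;
    configuration snapshots are kept every ``snapshot_every`` steps (plus
    the final one) when requested.  Bit-reproducible from the seed.
    """
    rng = np.random.default_rng(params.seed)
    config = CellConfiguration.founder()
    times = [0.0]
    counts = [1]
    snapshots: list[CellConfiguration] = []
    extinct = False
    for step in range(params.n_steps):
        config = death_sweep(config, params, rng)
        if config.n_cells == 0:
            config = CellConfiguration((step + 1) * params.dt, config.positions, config.ids)
            extinct = True
            times.append(config.time)
            counts.append(0)
            break
        config = birth_sweep(config, params, rng)
        config = move_sweep(config, params, rng)
        times.append(config.time)
        counts.append(config.n_cells)
        if params.snapshot_every and (step + 1) % params.snapshot_every == 0:
            snapshots.append(config.copy())
    if params.snapshot_every and not extinct:
        if not snapshots or snapshots[-1].time != config.time:
            snapshots.append(config.copy())
    return RunRecord(
        params=params,
        final=config,
        extinct=extinct,
        population_times=np.array(times),
        population_counts=np.array(counts, dtype=np.int64),
        snapshots=snapshots,
    )


def run_surviving_replicates(params: SimulationParams, n_survivors: int,
                             max_attempt_factor: int = 10,
                             progress: bool = False) -> list[RunRecord]:
    """Collect ``n_survivors`` non-extinct runs with sequentially derived seeds.

    Replicate seeds are ``params.seed + attempt_index``.  Extinct runs are
    discarded (their count is visible from the seeds actually used).  If
    ``max_attempt_factor * n_survivors`` attempts do not yield enough
    survivors, an :class:`ExtinctionCapError` signals implausible parameters.
    """
    if n_survivors < 1:
        raise ValueError("n_survivors must be >= 1")
    survivors: list[RunRecord] = []
    attempts = 0
    cap = max_attempt_factor * n_survivors
    while len(survivors) < n_survivors:
        if attempts >= cap:
            raise ExtinctionCapError(
                f"{attempts} runs produced only {len(survivors)} survivors "
                f"(needed {n_survivors}); parameters look implausible"
            )
        rec = run_simulation(replace(params, seed=params.seed + attempts))
        attempts += 1
        if not rec.extinct:
            survivors.append(rec)
        if progress:
            print(f"  replicate attempt {attempts}: "
                  f"{'extinct' if rec.extinct else f'N={rec.final.n_cells}'}")
    return survivors
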