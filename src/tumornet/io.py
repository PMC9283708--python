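"""File formats: snapshot CSV, edge-list TSV, JSON summaries, run configs.

All distances in files are in cell-diameter units.  Snapshot CSVs have the
header ``cell_id,x,y``; lines starting with ``#`` carry a JSON metadata
sidecar (package version, parameters, seed) and are ignored on read.
Round trips are lossless at full float precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np

from . import __version__
from .dynamics import CellConfiguration, RunRecord, SimulationParams

__all__ = [
    "SnapshotParseError",
    "RunConfig",
    "read_snapshot",
    "write_snapshot",
    "write_edge_list",
    "write_network_summary",
    "write_degree_snapshot",
    "write_run_record",
    "write_population_series",
]


class SnapshotParseError(ValueError):
    """Malformed snapshot CSV; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


def _metadata_line(metadata: dict | None) -> str:
    payload = {"package": f"tumornet {__version__}"}
    if metadata:
        payload.update(metadata)
    return "# " + json.dumps(payload, default=str)


def write_snapshot(config: CellConfiguration, path, metadata: dict | None = None) -> None:
    """Write a configuration as ``cell_id,x,y`` CSV with a metadata comment."""
    path = Path(path)
    meta = dict(metadata or {})
    meta.setdefault("time", config.time)
    lines = [_metadata_line(meta), "cell_id,x,y"]
    for cid, (x, y) in zip(config.ids, config.positions):
        lines.append(f"{int(cid)},{float(x)!r},{float(y)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_snapshot(path) -> CellConfiguration:
    """Read a snapshot CSV; accepts LF/CRLF and ``#`` comment lines.

    Raises :class:`SnapshotParseError` (with line number) on a wrong
    header, non-numeric or non-finite coordinates, or duplicate ids.
    """
    path = Path(path)
    time = 0.0
    ids: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    header_seen = False
    with path.open("r", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                try:
                    meta = json.loads(line[1:].strip())
                    time = float(meta.get("time", time))
                except (json.JSONDecodeError, TypeError, ValueError):
                    pass
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols != ["cell_id", "x", "y"]:
                    raise SnapshotParseError(
                        f"expected header 'cell_id,x,y', got {line!r}", lineno)
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise SnapshotParseError(f"expected 3 fields, got {len(parts)}", lineno)
            try:
                cid = int(parts[0])
                x = float(parts[1])
                y = float(parts[2])
            except ValueError as exc:
                raise SnapshotParseError(f"non-numeric value ({exc})", lineno) from exc
            if not (math.isfinite(x) and math.isfinite(y)):
                raise SnapshotParseError("non-finite coordinate", lineno)
            if cid in set(ids):
                raise SnapshotParseError(f"duplicate cell_id {cid}", lineno)
            ids.append(cid)
            xs.append(x)
            ys.append(y)
    if not header_seen:
        raise SnapshotParseError("no 'cell_id,x,y' header found in file")
    return CellConfiguration(
        time=time,
        positions=np.column_stack([xs, ys]) if ids else np.empty((0, 2)),
        ids=np.array(ids, dtype=np.int64),
    )


def write_edge_list(net, path, metadata: dict | None = None) -> None:
    """Edge-list TSV: one undirected edge per line as ``i<TAB>j`` with i < j."""
    path = Path(path)
    lines = [_metadata_line(metadata)]
    lines.extend(f"{i}\t{j}" for i, j in net.edges())
    path.write_text("\n".join(lines) + "\n")


def write_network_summary(summary, path, metadata: dict | None = None) -> None:
    """NetworkSummary as a flat JSON record."""
    record = {
        "package": f"tumornet {__version__}",
        "n_nodes": summary.n_nodes,
        "n_links": summary.n_links,
        "n_isolated": summary.n_isolated,
        "degree_dist": {str(k): v for k, v in summary.degree_dist.items()},
        "mean_degree": summary.mean_degree,
        "knn": summary.knn,
        "transitivity": summary.transitivity,
        "mean_clustering": summary.mean_clustering,
        "n_components": summary.n_components,
        "component_sizes": summary.component_sizes,
        "largest_component": summary.largest_component,
        "components_per_node": summary.components_per_node,
    }
    if metadata:
        record["metadata"] = metadata
    Path(path).write_text(json.dumps(record, indent=2) + "\n")


def write_degree_snapshot(table, path, metadata: dict | None = None) -> None:
    """Degree table as ``cell_id,x,y,degree`` CSV with a metadata comment."""
    path = Path(path)
    lines = [_metadata_line(metadata), "cell_id,x,y,degree"]
    for row in table.itertuples(index=False):
        lines.append(f"{int(row.cell_id)},{float(row.x)!r},{float(row.y)!r},{int(row.degree)}")
    path.write_text("\n".join(lines) + "\n")


def write_run_record(record: RunRecord, path) -> None:
    """Run metadata (params, seed, extinct flag, final N) as JSON."""
    payload = {
        "package": f"tumornet {__version__}",
        "params": asdict(record.params),
        "seed": record.params.seed,
        "extinct": record.extinct,
        "final_n_cells": record.final.n_cells,
        "final_time": record.final.time,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_population_series(record: RunRecord, path) -> None:
    """Per-step population counts as ``time,n_cells`` CSV."""
    path = Path(path)
    lines = [_metadata_line({"seed": record.params.seed}), "time,n_cells"]
    for t, n in zip(record.population_times, record.population_counts):
        lines.append(f"{float(t)!r},{int(n)}")
    path.write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """Flat, serializable union of simulation and sweep settings.

    Round-trips losslessly through JSON; unknown keys are rejected so a
    typo in a config file fails loudly instead of silently using defaults.
    """

    delta: float = 1.5
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
    replicates: int = 20
    delta_grid: list | None = None
    out_dir: str = "."

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    def simulation_params(self, **overrides) -> SimulationParams:
        kwargs = {
            f.name: getattr(self, f.name)
            for f in fields(SimulationParams)
            if hasattr(self, f.name)
        }
        kwargs.update(overrides)
        return SimulationParams(**kwargs)
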