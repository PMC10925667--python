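"""File formats and run manifests.

Weighted matrices are read from dense header-less CSV (N rows of N
comma-separated floats) or MatrixMarket coordinate files; validation (symmetry,
non-negativity, zero diagonal) happens at load.  Trajectories are written as
long-format CSV (``time,node_index,node_label,concentration``) so 379-node runs
stay friendly to downstream tools; observables as ``time,M,N_above``.  Every
run writes one JSON manifest (config echo, input checksums, index base, RNG
seed, stopping rule) so deterministic runs can be replayed bit-identically.

Node indices are 0-based internally; files declare their index base in a
header line / manifest field, and label tables carry 1-based indices
alongside for cross-referencing with parcellation conventions.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_array

from . import __version__
from .dynamics import Trajectory
from .errors import FormatError
from .graph import WeightedConnectome
from .observables import ObservableSeries

#: every float written by this module uses 12 significant digits
FLOAT_FMT = "%.12e"


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "mtx"):
            raise FormatError(f"unknown weighted-matrix format {fmt!r}")
        return fmt
    return "mtx" if path.suffix.lower() in (".mtx", ".mm") else "csv"


def read_weighted_matrix(
    path: str | Path, fmt: str | None = None, fix_diagonal: bool = False
) -> WeightedConnectome:
    """Load and validate a weighted connectome matrix.

    ``fix_diagonal=True`` zeroes a nonzero diagonal with a warning instead
    of rejecting the file.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "csv":
        rows: list[list[float]] = []
        for ln_no, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                rows.append([float(x) for x in line.split(",")])
            except ValueError as err:
                raise FormatError(f"{path}:{ln_no}: non-numeric entry ({err})") from err
        if not rows:
            raise FormatError(f"{path}: empty matrix file")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(
                f"{path}: ragged CSV rows (row lengths {sorted(widths)})"
            )
        W = np.array(rows, dtype=float)
    else:
        try:
            W = mmread(str(path))
        except Exception as err:
            raise FormatError(f"{path}: not a readable MatrixMarket file ({err})") from err
        W = np.asarray(W.todense() if hasattr(W, "todense") else W, dtype=float)
    if fix_diagonal and W.ndim == 2 and W.shape[0] == W.shape[1]:
        if np.any(np.diag(W) != 0):
            warnings.warn(
                f"{path}: zeroing {int(np.count_nonzero(np.diag(W)))} nonzero "
                "diagonal entries (self-loops are not modelled)",
                stacklevel=2,
            )
            np.fill_diagonal(W, 0.0)
    return WeightedConnectome(weights=W)


def write_weighted_matrix(
    W: WeightedConnectome, path: str | Path, fmt: str | None = None
) -> None:
    """Write ``W`` as dense CSV or symmetric MatrixMarket coordinate file."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "csv":
        np.savetxt(path, W.weights, delimiter=",", fmt=FLOAT_FMT)
    else:
        # MatrixMarket symmetric coordinate format stores the lower triangle
        mmwrite(str(path), coo_array(np.tril(W.weights)), symmetry="symmetric")


def read_labels(path: str | Path) -> tuple[tuple[str, ...], int]:
    """Read a two-column ``index<TAB>label`` table.

    The first line may declare ``# index_base=0`` or ``# index_base=1``
    (default 0).  Returns the labels ordered by 0-based index plus the
    declared base.
    """
    path = Path(path)
    base = 0
    entries: dict[int, str] = {}
    for ln_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "index_base=" in line:
                base = int(line.split("index_base=")[1].strip())
                if base not in (0, 1):
                    raise FormatError(f"{path}: index_base must be 0 or 1, got {base}")
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{ln_no}: expected 'index<TAB>label'")
        entries[int(parts[0]) - base] = parts[1]
    if sorted(entries) != list(range(len(entries))):
        raise FormatError(f"{path}: label indices are not contiguous from {base}")
    return tuple(entries[i] for i in range(len(entries))), base


def write_labels(labels, path: str | Path, index_base: int = 1) -> None:
    path = Path(path)
    lines = [f"# index_base={index_base}"]
    lines += [f"{i + index_base}\t{lab}" for i, lab in enumerate(labels)]
    path.write_text("\n".join(lines) + "\n")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_manifest(
    config: Any = None,
    inputs: dict[str, str | Path] | None = None,
    extra: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Assemble the run manifest: config echo, checksums, version, timestamp."""
    manifest: dict[str, Any] = {
        "software": "netspread",
        "version": __version__,
        "index_base": 0,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    if config is not None:
        manifest["config"] = _jsonable(config)
    if inputs:
        manifest["inputs"] = {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in inputs.items()
        }
    if extra:
        manifest.update(_jsonable(extra))
    return manifest


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_trajectory(
    traj: Trajectory,
    series: ObservableSeries,
    prefix: str | Path,
    labels=None,
    wide: bool = False,
    manifest_extra: dict[str, Any] | None = None,
) -> dict[str, Path]:
    """Write ``<prefix>_trajectory.csv``, ``<prefix>_observables.csv`` and
    ``<prefix>_manifest.json``.

    The trajectory CSV is long format (one row per time x node) unless
    ``wide=True`` (one column per node).
    """
    if len(traj.times) != len(series.times) or not np.array_equal(
        traj.times, series.times
    ):
        raise FormatError("trajectory and observable series have different time grids")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = traj.n_nodes
    labels = list(labels) if labels is not None else [f"node_{i:03d}" for i in range(n)]

    traj_path = prefix.parent / (prefix.name + "_trajectory.csv")
    if wide:
        header = "time," + ",".join(labels)
        body = np.column_stack([traj.times, traj.states])
        np.savetxt(traj_path, body, delimiter=",", fmt=FLOAT_FMT,
                   header=header, comments="")
    else:
        with open(traj_path, "w") as fh:
            fh.write("time,node_index,node_label,concentration\n")
            for t, state in zip(traj.times, traj.states):
                t_s = FLOAT_FMT % t
                for i in range(n):
                    fh.write(f"{t_s},{i},{labels[i]},{FLOAT_FMT % state[i]}\n")

    obs_path = prefix.parent / (prefix.name + "_observables.csv")
    with open(obs_path, "w") as fh:
        fh.write("time,M,N_above\n")
        for t, m, na in zip(series.times, series.M, series.N_above):
            fh.write(f"{FLOAT_FMT % t},{FLOAT_FMT % m},{int(na)}\n")

    man_path = prefix.parent / (prefix.name + "_manifest.json")
    extra = {
        "graph": traj.graph_provenance,
        "t_converged": traj.t_converged,
        "theta_c_used": series.theta_c_used,
    }
    if manifest_extra:
        extra.update(manifest_extra)
    man_path.write_text(
        json.dumps(build_manifest(config=traj.config, extra=extra), indent=2) + "\n"
    )
    return {"trajectory": traj_path, "observables": obs_path, "manifest": man_path}


def read_observables(path: str | Path) -> pd.DataFrame:
    """Read an observables CSV back into a DataFrame (time, M, N_above)."""
    df = pd.read_csv(path)
    expected = ["time", "M", "N_above"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


def read_trajectory_long(path: str | Path) -> pd.DataFrame:
    """Read a long-format trajectory CSV back into a DataFrame."""
    df = pd.read_csv(path)
    expected = ["time", "node_index", "node_label", "concentration"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


def write_final_state(
    traj: Trajectory, path: str | Path, labels=None
) -> None:
    """Per-node endpoint CSV (``node_index,label,concentration``) for
    external brain-surface viewers."""
    n = traj.n_nodes
    labels = list(labels) if labels is not None else [f"node_{i:03d}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("node_index,label,concentration\n")
        for i in range(n):
            fh.write(f"{i},{labels[i]},{FLOAT_FMT % traj.final_state[i]}\n")
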