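"""Output writing: tidy CSV tables, JSON run manifest, plain-text log.

A run directory contains ``summary.csv`` (task-appropriate aggregate
table), optionally ``trials.csv`` (raw per-trial log), ``config.json``
(resolved configuration, seed, and a file inventory with SHA-256 hashes)
and ``run.log``.  Re-running with an identical configuration and seed
reproduces the CSV files byte for byte.  On failure, files created by
the partial run are removed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from importlib import metadata as importlib_metadata
from pathlib import Path

import pandas as pd

from .engine import (
    SimulationResult,
    deck_frequencies,
    stay_probabilities,
    summarize_q,
)
from .readouts import transient_table

__all__ = ["summary_table", "write_outputs"]


def _package_version() -> str:
    try:
        return importlib_metadata.version("competing-critics")
    except importlib_metadata.PackageNotFoundError:
        return "unknown"


def summary_table(result: SimulationResult) -> pd.DataFrame:
    """The task-appropriate aggregate table for a run, in tidy form."""
    task = result.config.task
    if task == "stationary":
        return summarize_q(result).table
    if task == "igt":
        return deck_frequencies(result).rename_axis("deck").reset_index()
    if task == "two_stage":
        return stay_probabilities(result).reset_index()
    if task == "market":
        return transient_table(result).reset_index()
    raise ValueError(f"no summary defined for task {task!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    result: SimulationResult,
    out_dir: str | Path,
    *,
    write_trials: bool = False,
    extra_tables: dict[str, pd.DataFrame] | None = None,
) -> dict[str, str]:
    """Write a run directory and return the {filename: sha256} inventory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    log_lines = [f"task={result.config.task} seed={result.config.seed}"]
    t0 = time.perf_counter()
    try:
        path = out / "summary.csv"
        summary_table(result).to_csv(path, index=False)
        created.append(path)
        log_lines.append(f"summary.csv written ({time.perf_counter() - t0:.2f}s)")
        if write_trials:
            path = out / "trials.csv"
            result.to_trials_frame().to_csv(path, index=False)
            created.append(path)
            log_lines.append(f"trials.csv written ({time.perf_counter() - t0:.2f}s)")
        for name, table in (extra_tables or {}).items():
            path = out / name
            table.to_csv(path, index=False)
            created.append(path)
            log_lines.append(f"{name} written ({time.perf_counter() - t0:.2f}s)")

        inventory = {p.name: _sha256(p) for p in created}
        manifest = {
            "package_version": _package_version(),
            "config": _jsonable(dataclasses.asdict(result.config)),
            "seed": result.config.seed,
            "replicates": result.config.replicates,
            "trials": result.config.trials,
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "files": inventory,
        }
        manifest_path = out / "config.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        created.append(manifest_path)
        log_path = out / "run.log"
        log_path.write_text("\n".join(log_lines) + "\n")
        created.append(log_path)
        inventory["config.json"] = _sha256(manifest_path)
        inventory["run.log"] = _sha256(log_path)
        return inventory
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj
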