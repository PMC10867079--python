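"""Readers and writers for trial tables, summaries and result files.

Trial data travel as comma-separated text with a header row
(subject, task, congruency, rt_ms, accuracy); parameter sets, fit
configurations and results use a flat JSON dialect.  Every CLI run also
emits a manifest recording the command, configuration, seed and the
package version, so any output can be regenerated bit-identically.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model_core import Congruency
from .simulator import TrialTable

__all__ = [
    "read_trials",
    "write_trials",
    "write_results",
    "write_manifest",
    "write_delta_plot",
    "write_caf",
]

REQUIRED_COLUMNS = ("subject", "task", "congruency", "rt_ms", "accuracy")
VALID_CONGRUENCY = {c.value for c in Congruency}


def read_trials(path: "str | Path") -> TrialTable:
    """Read and validate a trial table from delimited text.

    Raises ValueError naming the offending rows for unknown congruency
    labels, non-positive or non-finite RTs, and accuracy outside {0, 1}.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no trial rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    problems = []
    bad_cong = ~df["congruency"].astype(str).str.lower().isin(VALID_CONGRUENCY)
    for i in df.index[bad_cong]:
        problems.append(f"row {i + 2}: unknown congruency "
                        f"{df.at[i, 'congruency']!r}")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad_rt = ~np.isfinite(rt) | (rt <= 0)
    for i in df.index[bad_rt]:
        problems.append(f"row {i + 2}: rt_ms must be positive finite, "
                        f"got {df.at[i, 'rt_ms']!r}")
    acc = pd.to_numeric(df["accuracy"], errors="coerce")
    bad_acc = ~acc.isin([0, 1])
    for i in df.index[bad_acc]:
        problems.append(f"row {i + 2}: accuracy must be 0 or 1, "
                        f"got {df.at[i, 'accuracy']!r}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems[:10]))

    df = df.copy()
    df["congruency"] = df["congruency"].astype(str).str.lower()
    df["rt_ms"] = rt
    df["accuracy"] = acc.astype(int)
    if "censored" not in df.columns:
        df["censored"] = False
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TrialTable(df, meta)


def write_trials(trials: TrialTable, path: "str | Path") -> Path:
    """Write a trial table as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in ("subject", "task", "congruency", "rt_ms",
                        "accuracy", "decision_ms", "censored")
            if c in trials.data.columns]
    trials.data[cols].to_csv(path, index=False)
    if trials.meta:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(_dumps(trials.meta))
    return path


def _round6(obj):
    """Round floats to 6 significant digits, recursively."""
    if isinstance(obj, dict):
        return {k: _round6(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round6(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        return x if not np.isfinite(x) or x == 0.0 else float(f"{x:.6g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round6(obj.tolist())
    return obj


def _dumps(obj) -> str:
    return json.dumps(_round6(obj), indent=2, allow_nan=True,
                      default=str) + "\n"


def write_results(obj, path: "str | Path") -> Path:
    """Serialize a result object (anything with to_dict, or a dict)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = obj.to_dict() if hasattr(obj, "to_dict") else obj
    path.write_text(_dumps(d))
    return path


def write_delta_plot(dp, path: "str | Path") -> Path:
    """Delta plot as CSV: one row per quantile level."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"prob": dp.probs, "x_ms": dp.x,
                  "delta_ms": dp.delta}).to_csv(path, index=False)
    return path


def write_caf(caf, path: "str | Path") -> Path:
    """CAF as CSV: one row per (condition, bin)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [{"condition": cond, "bin": b, "accuracy": acc, "n": n}
            for cond, accs in caf.accuracy.items()
            for b, (acc, n) in enumerate(zip(accs, caf.bin_counts[cond]))]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_manifest(command: str, config: dict, seed, inputs, outputs,
                   path: "str | Path") -> Path:
    """Write the run manifest that makes a CLI invocation reproducible."""
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(_dumps(manifest))
    return path
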