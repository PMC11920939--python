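"""Reading user-supplied numeric tables and writing run outputs.

All outputs are plain UTF-8 CSV with a header row, '.' decimal separator and
floats printed with 17 significant digits so that every table re-parses to
the same values.  A JSON run manifest records the fully resolved
configuration, the root seed, the richness grid and the package version,
which together reproduce every table bit-identically on the same platform.
"""

from __future__ import annotations

import json
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import ScenarioConfig
from .errors import DimensionMismatchError
from .experiments import ReplicateRecord

FLOAT_FORMAT = "%.17g"


def _read_table(path: str | Path) -> np.ndarray:
    """Parse a comma-, tab- or whitespace-delimited numeric table.

    A non-numeric first row is treated as a header and skipped.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8").strip()
    if not text:
        raise ValueError(f"{path}: file is empty")
    lines = text.splitlines()
    delim = None
    if "," in lines[0]:
        delim = ","
    elif "\t" in lines[0]:
        delim = "\t"

    def _parse(line: str) -> list[str]:
        return [tok for tok in (line.split(delim) if delim else line.split())
                if tok != ""]

    rows = [_parse(line) for line in lines if line.strip()]
    start = 0
    try:
        [float(tok) for tok in rows[0]]
    except ValueError:
        start = 1  # header row
        if len(rows) == 1:
            raise ValueError(f"{path}: no numeric rows found")
    try:
        data = [[float(tok) for tok in row] for row in rows[start:]]
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric value ({exc})") from None
    widths = {len(row) for row in data}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    return np.asarray(data, dtype=float)


def read_interaction_matrix(path: str | Path) -> np.ndarray:
    """Read an S x S interaction matrix from a delimited text file."""
    M = _read_table(path)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DimensionMismatchError(
            f"{path}: interaction matrix must be square, got shape {M.shape}")
    return M


def read_equilibrium_vector(path: str | Path) -> np.ndarray:
    """Read a strictly positive length-S abundance vector (one row per species)."""
    M = _read_table(path)
    vec = M.ravel()
    if M.ndim == 2 and 1 not in M.shape:
        raise DimensionMismatchError(
            f"{path}: expected a vector, got shape {M.shape}")
    bad = np.flatnonzero(vec <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: equilibrium abundances must be strictly positive "
            f"(row {bad[0] + 1} is {vec[bad[0]]})")
    return vec


def write_records_csv(records: Iterable[ReplicateRecord],
                      path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records])
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_summary_csv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_trajectory_csv(t: np.ndarray, y: np.ndarray,
                         path: str | Path) -> None:
    """Write a trajectory as columns (t, N_1 ... N_S), one row per checkpoint."""
    S = y.shape[1]
    df = pd.DataFrame(y, columns=[f"N_{i + 1}" for i in range(S)])
    df.insert(0, "t", t)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_manifest(path: str | Path, config: ScenarioConfig,
                   S_grid: Sequence[int], n_reps: int,
                   outputs: dict[str, str]) -> None:
    manifest = {
        "package": "glvsim",
        "version": __version__,
        "python": sys.version.split()[0],
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "config": config.to_dict(),
        "root_seed": config.seed,
        "S_grid": [int(s) for s in S_grid],
        "n_reps": int(n_reps),
        "outputs": outputs,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
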