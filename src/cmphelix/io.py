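"""Readers and writers for the package's CSV/JSON schemas.

All tabular artifacts are plain CSV and all models/configs are JSON, so
every stage of the pipeline can be driven from files on disk.  The
campaign-table reader is deliberately tolerant: it auto-detects which
column holds the hexamer codes, which holds the selection round and which
columns carry replicate melting temperatures (either several numeric
replicate columns or a single delimiter-separated list), because
supplementary tables in the wild rarely share an exact header.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .errors import SchemaError, ValidationError
from .melt import TmEstimate, TrajectoryObservables
from .fes import UmbrellaWindow
from .palette import validate_sequence

TRAJ_COLUMNS = ["time_ns", "rg1_nm", "rg2_nm", "rg3_nm", "d12_nm", "d13_nm", "d23_nm"]


@dataclass
class CandidateRecord:
    sequence: str
    round: int | None
    replicate_Tms: tuple
    mean_Tm: float
    se_Tm: float

    @property
    def estimate(self) -> TmEstimate:
        return TmEstimate(
            mean_Tm=self.mean_Tm, se_Tm=self.se_Tm,
            n_replicates=max(len(self.replicate_Tms), 1),
            replicate_Tms=self.replicate_Tms,
        )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: TrajectoryObservables, path) -> None:
    df = pd.DataFrame(
        {
            "time_ns": traj.frame_times,
            "rg1_nm": traj.rg_per_strand[0],
            "rg2_nm": traj.rg_per_strand[1],
            "rg3_nm": traj.rg_per_strand[2],
            "d12_nm": traj.pair_distances[0],
            "d13_nm": traj.pair_distances[1],
            "d23_nm": traj.pair_distances[2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_trajectory_csv(path, T0: float = 320.0, ramp_rate: float = 1.0,
                        replicate_id: int = 0) -> TrajectoryObservables:
    df = pd.read_csv(path)
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trajectory CSV missing columns {missing}")
    return TrajectoryObservables(
        frame_times=df["time_ns"].to_numpy(),
        rg_per_strand=df[["rg1_nm", "rg2_nm", "rg3_nm"]].to_numpy().T,
        pair_distances=df[["d12_nm", "d13_nm", "d23_nm"]].to_numpy().T,
        T0=T0, ramp_rate=ramp_rate, replicate_id=replicate_id,
    )


# ---------------------------------------------------------------------------
# umbrella windows
# ---------------------------------------------------------------------------

def write_windows_csv(windows: list[UmbrellaWindow], path) -> None:
    rows = []
    for i, w in enumerate(windows):
        for v in w.samples:
            rows.append((i, w.center, w.force_constant, v))
    pd.DataFrame(
        rows, columns=["window_id", "center", "force_constant", "value"]
    ).to_csv(path, index=False, float_format="%.8f")


def read_windows_csv(path) -> list[UmbrellaWindow]:
    df = pd.read_csv(path)
    needed = {"window_id", "center", "force_constant", "value"}
    if not needed.issubset(df.columns):
        raise SchemaError(
            f"window CSV must have columns {sorted(needed)}, got {list(df.columns)}"
        )
    if df.empty:
        raise SchemaError("window CSV contains no samples")
    windows = []
    for _, grp in df.groupby("window_id", sort=True):
        windows.append(
            UmbrellaWindow(
                center=float(grp["center"].iloc[0]),
                force_constant=float(grp["force_constant"].iloc[0]),
                samples=grp["value"].to_numpy(),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# campaign tables
# ---------------------------------------------------------------------------

_SEQ_RE = re.compile(r"^[A-Z0-9]{6}$")


def write_campaign_table(audit: pd.DataFrame, path) -> None:
    audit.to_csv(path, index=False)


def _detect_sequence_column(df: pd.DataFrame) -> str:
    best, best_frac = None, 0.0
    for col in df.columns:
        vals = df[col].astype(str).str.strip()
        frac = vals.apply(lambda s: bool(_SEQ_RE.match(s))).mean()
        if frac > best_frac:
            best, best_frac = col, frac
    if best is None or best_frac < 0.9:
        raise SchemaError("could not identify a hexamer-code column")
    return best


def _detect_round_column(df: pd.DataFrame, seq_col: str) -> str | None:
    for col in df.columns:
        if col == seq_col:
            continue
        if "round" in str(col).lower():
            return col
    return None


def _replicate_values(df: pd.DataFrame, seq_col, round_col) -> list[tuple]:
    """Per-row replicate Tm tuples from whichever layout the table uses."""
    # layout 1: a single column of delimiter-separated replicate values
    for col in df.columns:
        if col in (seq_col, round_col):
            continue
        vals = df[col].astype(str)
        if vals.str.contains(";").mean() > 0.9:
            return [
                tuple(float(x) for x in s.split(";") if x.strip() != "")
                for s in vals
            ]
    # layout 2: several numeric replicate columns (tm1..tm6, rep_*, ...)
    numeric = [
        c for c in df.columns
        if c not in (seq_col, round_col)
        and pd.api.types.is_numeric_dtype(df[c])
        and re.search(r"(?i)(tm|melt|rep)", str(c))
        and not re.search(r"(?i)(mean|se|err|std)", str(c))
    ]
    if len(numeric) >= 2:
        return [tuple(float(v) for v in row if np.isfinite(v))
                for row in df[numeric].to_numpy()]
    # layout 3: a single mean column (optionally with an SE column)
    mean_col = next(
        (c for c in df.columns
         if re.search(r"(?i)(mean|tm)", str(c))
         and pd.api.types.is_numeric_dtype(df[c])
         and not re.search(r"(?i)(se|err|std)", str(c))),
        None,
    )
    if mean_col is None:
        raise SchemaError("could not identify replicate or mean Tm columns")
    return [(float(v),) for v in df[mean_col]]


def read_campaign_table(path, validate: bool = True) -> list[CandidateRecord]:
    """Parse a campaign table into candidate records.

    Accepts the audit log written by :func:`cmphelix.acquire.run_campaign`
    as well as foreign tables with replicate columns; sequence codes are
    validated against the palette unless ``validate=False``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path} contains no rows")
    seq_col = _detect_sequence_column(df)
    round_col = _detect_round_column(df, seq_col)
    reps = _replicate_values(df, seq_col, round_col)

    se_col = next(
        (c for c in df.columns if re.search(r"(?i)se", str(c))
         and pd.api.types.is_numeric_dtype(df[c])),
        None,
    )
    records = []
    seen = {}
    for i, (_, row) in enumerate(df.iterrows()):
        code = str(row[seq_col]).strip()
        if validate:
            try:
                validate_sequence(code)
            except Exception as err:
                raise ValidationError(
                    f"row {i + 1}: invalid sequence {code!r}: {err}"
                ) from err
        r = reps[i]
        if len(r) > 1:
            arr = np.asarray(r, float)
            mean = float(arr.mean())
            se = float(arr.std(ddof=1) / np.sqrt(arr.size))
        else:
            mean = float(r[0])
            se = float(row[se_col]) if se_col is not None else 0.0
        rnd = int(row[round_col]) if round_col is not None else None
        if code in seen:  # replicate rows of the same candidate are merged
            prev = seen[code]
            merged = prev.replicate_Tms + r
            arr = np.asarray(merged, float)
            seen[code] = CandidateRecord(
                code, prev.round, tuple(merged), float(arr.mean()),
                float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0,
            )
        else:
            seen[code] = CandidateRecord(code, rnd, tuple(r), mean, se)
    records = list(seen.values())
    return records


# ---------------------------------------------------------------------------
# models and provenance
# ---------------------------------------------------------------------------

def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def provenance_record(command: str, inputs: dict, config: dict, seed) -> dict:
    """Machine-readable run record (deliberately timestamp-free so that two
    identical runs produce byte-identical artifacts)."""
    return {
        "tool": "cmphelix",
        "version": _pkg_version,
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": config,
        "seed": seed,
    }
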