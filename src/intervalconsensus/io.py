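"""CSV/JSON ingest and egress for response tables and results."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_responses", "write_results", "config_hash"]

REQUIRED_COLUMNS = ("respondent_id", "item_id", "lower", "upper")


def read_responses(path, scale_max: float = 1.0) -> pd.DataFrame:
    """Read and validate a long-format interval response CSV.

    Required columns: ``respondent_id, item_id, lower, upper``.  Bounds are
    divided by ``scale_max`` (use 100 for percentage sliders) and must then
    satisfy ``0 <= lower <= upper <= 1``; violations are reported with their
    1-based data row numbers.  Duplicate (respondent, item) pairs are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"response file not found: {path}")
    if scale_max <= 0:
        raise ValueError("scale_max must be positive")
    table = pd.read_csv(path, dtype={"respondent_id": str, "item_id": str})
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("lower", "upper"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() & table[col].notna()
        if bad.any():
            rows = (np.flatnonzero(bad) + 1).tolist()
            raise ValueError(f"{path}: unparsable numbers in column {col!r}, rows {rows}")
        table[col] = vals / scale_max
    invalid = (
        (table["lower"] < 0) | (table["upper"] > 1) | (table["lower"] > table["upper"])
        | table["lower"].isna() | table["upper"].isna()
    )
    if invalid.any():
        rows = (np.flatnonzero(invalid) + 1).tolist()
        raise ValueError(
            f"{path}: invalid intervals (need 0 <= lower <= upper <= scale_max) "
            f"in rows {rows}"
        )
    dup = table.duplicated(subset=["respondent_id", "item_id"])
    if dup.any():
        rows = (np.flatnonzero(dup) + 1).tolist()
        raise ValueError(f"{path}: duplicate (respondent, item) pairs in rows {rows}")
    return table


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir,
    manifest: dict | None = None,
) -> list[Path]:
    """Write tabular outputs as CSV plus an optional JSON manifest.

    ``tables`` maps file stems to frames.  The manifest is augmented with a
    hash of itself minus volatile fields, so re-runs are comparable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for stem, frame in tables.items():
        p = out_dir / f"{stem}.csv"
        frame.to_csv(p, index=False)
        written.append(p)
    if manifest is not None:
        manifest = dict(manifest)
        manifest["config_hash"] = config_hash(
            {k: v for k, v in manifest.items() if k != "config_hash"}
        )
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        written.append(p)
    return written
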