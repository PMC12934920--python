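"""Reading and writing the pipeline's tabular artifacts.

Call tables are plain CSV in the dialect emitted by USV-detection tools
(one row per detected call).  One file may hold many pups and ages;
``(pup_id, age_day)`` keys a recording session.  Times are seconds,
durations milliseconds, frequencies Hz, intensities dB.  Unknown extra
columns are preserved.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .config import PipelineConfig

REQUIRED_CALL_COLUMNS = [
    "pup_id", "genotype", "age_day", "onset_s", "duration_ms",
    "bandwidth_hz", "freq_max_hz", "freq_mean_hz", "freq_min_hz",
    "intensity_max_db", "intensity_mean_db", "intensity_min_db",
    "harmonic_flag",
]

#: Optional columns recognised by downstream stages.
OPTIONAL_CALL_COLUMNS = ["contour", "call_type"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """An input table violates a row-level invariant."""


def read_call_table(path: str | Path,
                    config: PipelineConfig | None = None) -> pd.DataFrame:
    """Read and validate a per-call CSV table.

    Returns the table sorted by ``(pup_id, age_day, onset_s)``.  Raises
    :class:`SchemaError` naming the first missing required column and
    :class:`ValidationError` (with the offending row index) for
    non-monotone onsets within a session, non-positive durations or
    disordered frequency summaries.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in REQUIRED_CALL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"call table {path} is missing column {col!r}")
    df = df.sort_values(["pup_id", "age_day", "onset_s"],
                        kind="stable").reset_index(drop=True)
    validate_call_table(df)
    return df


def validate_call_table(df: pd.DataFrame) -> None:
    bad = df.index[df["duration_ms"] <= 0]
    if len(bad):
        raise ValidationError(f"non-positive duration_ms at row {bad[0]}")
    bad = df.index[(df["freq_min_hz"] > df["freq_mean_hz"])
                   | (df["freq_mean_hz"] > df["freq_max_hz"])]
    if len(bad):
        raise ValidationError(
            f"frequency summaries out of order (min <= mean <= max) at row {bad[0]}")
    for (_, _), grp in df.groupby(["pup_id", "age_day"], sort=False):
        onsets = grp["onset_s"].to_numpy()
        if len(onsets) > 1 and (onsets[1:] < onsets[:-1]).any():
            row = grp.index[1:][onsets[1:] < onsets[:-1]][0]
            raise ValidationError(f"onset_s decreases within a session at row {row}")


def write_call_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_results(bundle: dict[str, pd.DataFrame], out_dir: str | Path,
                  config: PipelineConfig | None = None,
                  seed: int | None = None) -> dict:
    """Write one CSV per result family plus a JSON manifest.

    ``bundle`` maps a result-family name (e.g. ``"entropies"``) to a
    DataFrame.  The manifest records the files written, the configuration
    hash and the seed, so a run can be audited and re-run.  Floats are
    written with 12 significant digits, which round-trips the analysis
    values.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in bundle.items():
        fname = f"{name}.csv"
        df.to_csv(out_dir / fname, index=False, float_format="%.12g")
        files[name] = fname
    manifest = {
        "files": files,
        "config_hash": config_hash(config) if config is not None else None,
        "seed": seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_results(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return {name: pd.read_csv(out_dir / fname)
            for name, fname in manifest["files"].items()}
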