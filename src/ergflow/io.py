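"""CSV and JSON round-trip helpers.

Cohort tables are plain comma-separated UTF-8 with a header row; lines
starting with ``#`` carry a JSON config echo so every file records how it
was produced.  Reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "ANIMAL_COLUMNS",
    "SUMMARY_COLUMNS",
    "SchemaError",
    "write_cohort_csv",
    "read_cohort_csv",
    "read_config_echo",
    "write_json_report",
]

ANIMAL_COLUMNS = (
    "group", "animal_id", "step", "iop_mmHg", "map_mmHg",
    "flow_pct", "erg_pct", "po2_pct",
)
SUMMARY_COLUMNS = (
    "group", "step", "iop_mmHg", "map_mmHg",
    "flow_pct", "erg_pct", "erg_sem_pct",
)


class SchemaError(ValueError):
    """A table is missing a required column."""


def write_cohort_csv(df: pd.DataFrame, path, config: Optional[dict] = None) -> None:
    """Write a cohort table; ``config`` is echoed in '#' header comments."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if config is not None:
            fh.write("# ergflow cohort file\n")
            fh.write(f"# config: {json.dumps(config, sort_keys=True)}\n")
        df.to_csv(fh, index=False)


def read_cohort_csv(path, required: Sequence[str] = ("iop_mmHg", "flow_pct", "erg_pct")) -> pd.DataFrame:
    """Read a cohort table, skipping comment lines; checks required columns."""
    df = pd.read_csv(path, comment="#")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def read_config_echo(path) -> Optional[dict]:
    """Recover the JSON config echo from a cohort file, if present."""
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# config:"):
                return json.loads(line.split(":", 1)[1])
            if not line.startswith("#"):
                break
    return None


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
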