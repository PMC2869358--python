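"""Result serialization.

CSV outputs carry a one-line ``#`` comment header with the seed and the
hash of the effective config that produced them, so every artifact is
traceable to its inputs.  Read them back with ``pandas.read_csv(path,
comment="#")``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.6g"


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_hash: str = "",
) -> Path:
    """Write a tidy results table as CSV with a provenance comment line."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# rescuesim seed={seed} config_hash={config_hash}\n")
        table.to_csv(fh, index=False, float_format=FLOAT_FORMAT)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
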