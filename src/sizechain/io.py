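"""Reading and writing the CSV dialects used by the pipeline.

Cell tables carry one row per cell: ``cell_id``, ``mother_id`` (empty
for founder cells), ``birth_length_um``, and ``division_length_um``
(empty when the cell was not observed to divide).  Profile tables are
long format: ``cell_id``, ``position_um``, ``intensity``.  All lengths
are micrometres.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError

CELL_COLUMNS = ["cell_id", "mother_id", "birth_length_um", "division_length_um"]
PROFILE_COLUMNS = ["cell_id", "position_um", "intensity"]


def _detect_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a single-cell length table (CSV or TSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"cell table missing columns {missing}")
    if (df["birth_length_um"] <= 0).any():
        raise DomainError("birth lengths must be positive")
    both = df["division_length_um"].notna()
    if (df.loc[both, "division_length_um"] < df.loc[both, "birth_length_um"]).any():
        raise DomainError("division length below birth length")
    _check_acyclic(df)
    return df


def _check_acyclic(df: pd.DataFrame) -> None:
    parent = dict(zip(df["cell_id"], df["mother_id"]))
    state: dict = {}
    for start in parent:
        node, chain = start, []
        while node in parent and not (isinstance(node, float) and np.isnan(node)):
            if state.get(node) == "done":
                break
            if state.get(node) == "visiting":
                raise DomainError(f"mother links contain a cycle through cell {node}")
            state[node] = "visiting"
            chain.append(node)
            node = parent[node]
        for c in chain:
            state[c] = "done"


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_detect_sep(path), index=False)


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read a long-format fluorescence profile table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"profile table missing columns {missing}")
    return df


def write_profiles(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_distribution(states: np.ndarray, probs: np.ndarray, path: str | Path) -> None:
    """Two-column CSV (state, probability)."""
    pd.DataFrame({"state": states, "probability": probs}).to_csv(path, index=False)


def write_matrix(P: np.ndarray, path: str | Path) -> None:
    """Dense transition-matrix CSV with 1-based state headers."""
    n = P.shape[0]
    cols = [f"from_{m}" for m in range(1, n + 1)]
    df = pd.DataFrame(P, columns=cols)
    df.insert(0, "to", np.arange(1, n + 1))
    df.to_csv(path, index=False)
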