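"""Delimited-text readers/writers and component bookkeeping.

The unit of input is the extracted network time course: one whitespace- or
comma-delimited text file per subject, T rows x N columns, no header. The
cohort design is a TSV with columns subject_id, group, age, sex. All
indices in files are 1-based; internal indexing is 0-based.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from dynconn.prep import NetworkTimecourses

__all__ = [
    "read_timecourses",
    "write_timecourses",
    "read_design",
    "write_design",
    "write_truth",
    "select_components",
]


def read_timecourses(
    path: str | os.PathLike, tr_seconds: float, subject_id: str | None = None
) -> NetworkTimecourses:
    """Read a T x N delimited numeric matrix (whitespace or comma separated).

    Non-numeric cells and ragged rows are rejected with 1-based row/column
    coordinates in the error message.
    """
    path = os.fspath(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            tokens = line.replace(",", " ").split()
            row = []
            for j, tok in enumerate(tokens):
                try:
                    row.append(float(tok))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {tok!r} at row {i + 1}, column {j + 1}"
                    ) from None
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        bad = next(i for i, r in enumerate(rows) if len(r) != len(rows[0]))
        raise ValueError(
            f"{path}: ragged rows (row {bad + 1} has {len(rows[bad])} columns, "
            f"row 1 has {len(rows[0])})"
        )
    sid = subject_id or os.path.splitext(os.path.basename(path))[0]
    return NetworkTimecourses(sid, np.asarray(rows, dtype=float), tr_seconds)


def write_timecourses(tc: NetworkTimecourses, path: str | os.PathLike) -> None:
    """Write a subject matrix as tab-delimited text, no header."""
    np.savetxt(path, tc.data, delimiter="\t", fmt="%.10g")


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design file lacks columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject IDs in design")
    return df


def write_design(design: pd.DataFrame, path: str | os.PathLike) -> None:
    design.to_csv(path, sep="\t", index=False)


def write_truth(truths, path: str | os.PathLike) -> None:
    """Planted state sequences as TSV: subject_id, volume_index (1-based), state."""
    rows = []
    for t in truths:
        for v, s in enumerate(t.state_sequence):
            rows.append({"subject_id": t.subject_id, "volume_index": v + 1, "state": int(s)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def select_components(
    n_total: int,
    noise: list[int] | tuple[int, ...] = (),
    out_of_mask: list[int] | tuple[int, ...] = (),
) -> list[int]:
    """Retained component indices after excluding noise/out-of-mask ones.

    Mirrors ICA-component bookkeeping: from ``n_total`` estimated
    components, those classified as non-neuronal noise and (in the
    high-dimensional case) those falling mainly outside the group mask are
    dropped. Indices are 1-based; e.g. 25 components minus 4 noise leaves
    21, and 100 minus 45 noise minus 4 out-of-mask leaves 51.
    """
    if n_total < 1:
        raise ValueError("n_total must be positive")
    excluded = set(noise) | set(out_of_mask)
    for idx in excluded:
        if not 1 <= idx <= n_total:
            raise ValueError(f"component index {idx} outside [1, {n_total}]")
    if set(noise) & set(out_of_mask):
        raise ValueError("a component cannot be both noise and out-of-mask")
    return [i for i in range(1, n_total + 1) if i not in excluded]
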