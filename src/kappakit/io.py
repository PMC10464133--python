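"""Reading rating data from disk: wide contingency matrices and long ratings.

Wide dialect: CSV/TSV, first row = rater B's category labels, first
column = rater A's, cells = non-negative integer counts; the body must
be square.  Long dialect: one row per subject with columns subject_id,
rater_a, rater_b.  The dialect is auto-detected by shape and content,
overridable.  Simulation specs load from YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scale import RatingScale
from .simulate import JointRatingModel
from .table import ContingencyTable, PairedRatings, TableError, build_table


class FormatError(ValueError):
    """File does not parse as any supported dialect."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _looks_long(df: pd.DataFrame) -> bool:
    cols = [str(c).strip().lower() for c in df.columns]
    return cols[:3] == ["subject_id", "rater_a", "rater_b"] or (
        df.shape[1] == 3 and not _body_is_counts(df)
    )


def _body_is_counts(df: pd.DataFrame) -> bool:
    body = df.iloc[:, 1:]
    try:
        vals = body.astype(float)
    except (ValueError, TypeError):
        return False
    return bool(np.isfinite(vals.to_numpy()).all())


def read_table(
    path: str | Path,
    dialect: str = "auto",
    is_ordinal: bool = True,
    rater_names: tuple[str, str] = ("rater_a", "rater_b"),
) -> ContingencyTable:
    """Load a contingency table from a wide matrix or long ratings file.

    ``dialect`` is "auto", "wide" or "long".  Long input is tallied via
    :func:`kappakit.table.build_table` over the union of observed labels
    (in first-appearance order of the sorted union); pass a wide file to
    control the scale explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    if dialect == "auto":
        dialect = "long" if _looks_long(df) else "wide"
    if dialect == "long":
        return _table_from_long(df, path, is_ordinal, rater_names)
    if dialect == "wide":
        return _table_from_wide(df, path, is_ordinal, rater_names)
    raise FormatError(f"unknown dialect {dialect!r}; use auto, wide or long")


def _table_from_wide(df, path, is_ordinal, rater_names) -> ContingencyTable:
    col_labels = [str(c).strip() for c in df.columns[1:]]
    row_labels = [str(x).strip() for x in df.iloc[:, 0]]
    body = df.iloc[:, 1:]
    if len(row_labels) != len(col_labels):
        raise FormatError(
            f"{path}: wide matrix must be square, got {len(row_labels)} rows x "
            f"{len(col_labels)} columns"
        )
    if row_labels != col_labels:
        raise FormatError(
            f"{path}: row labels {row_labels} do not match column labels {col_labels}"
        )
    counts = np.empty((len(row_labels), len(col_labels)), dtype=np.int64)
    for i in range(len(row_labels)):
        for j in range(len(col_labels)):
            cell = str(body.iat[i, j]).strip()
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: line {i + 2}, column {j + 2}: {cell!r} is not a number"
                ) from None
            if v < 0 or v != int(v):
                raise FormatError(
                    f"{path}: line {i + 2}, column {j + 2}: count {cell!r} must be a "
                    "non-negative integer"
                )
            counts[i, j] = int(v)
    scale = RatingScale(tuple(row_labels), is_ordinal)
    try:
        return ContingencyTable(counts, scale, rater_names, table_id=path.stem)
    except TableError as e:
        raise FormatError(f"{path}: {e}") from None


def _table_from_long(df, path, is_ordinal, rater_names) -> ContingencyTable:
    ratings = read_ratings_frame(df, path)
    labels = tuple(sorted(set(ratings.rater_a) | set(ratings.rater_b)))
    scale = RatingScale(labels, is_ordinal)
    return build_table(ratings, scale, rater_names, table_id=path.stem)


def read_ratings(path: str | Path) -> PairedRatings:
    """Load long-format paired ratings (subject_id, rater_a, rater_b)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    return read_ratings_frame(df, path)


def read_ratings_frame(df: pd.DataFrame, origin=None) -> PairedRatings:
    cols = [str(c).strip().lower() for c in df.columns]
    if cols[:3] != ["subject_id", "rater_a", "rater_b"]:
        if df.shape[1] != 3:
            raise FormatError(
                f"{origin or 'long input'}: expected 3 columns "
                f"(subject_id, rater_a, rater_b), got {list(df.columns)}"
            )
    df = df.iloc[:, :3].set_axis(["subject_id", "rater_a", "rater_b"], axis=1)
    return PairedRatings.from_dataframe(df)


def write_ratings(ratings: PairedRatings, path: str | Path) -> None:
    ratings.to_dataframe().to_csv(path, index=False)


def read_simulation_spec(path: str | Path) -> tuple[JointRatingModel, int, int]:
    """Load a YAML simulation spec: labels, joint matrix, n, seed."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    for key in ("joint", "n", "seed"):
        if key not in spec:
            raise FormatError(f"{path}: simulation spec missing key {key!r}")
    joint = np.asarray(spec["joint"], dtype=float)
    labels = spec.get("labels") or [f"c{i}" for i in range(joint.shape[0])]
    scale = RatingScale(tuple(str(x) for x in labels), bool(spec.get("is_ordinal", True)))
    model = JointRatingModel(joint, scale)
    return model, int(spec["n"]), int(spec["seed"])


def read_config(path: str | Path) -> dict:
    """YAML config mirroring the CLI flags."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg
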