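"""Paired ratings and the square contingency tables tallied from them.

The fully-crossed two-rater design: every subject is rated once by each
rater on a shared scale.  The contingency table holds the raw counts
(rows = rater A's category, columns = rater B's); all kappa statistics
are functions of its joint proportion matrix and marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .scale import RatingScale, ScaleError


class TableError(ValueError):
    """Invalid contingency table or ratings input."""


@dataclass(frozen=True)
class PairedRatings:
    """Subject-level ratings by two raters.

    All three sequences have equal length; labels are validated against a
    scale only when a table is built, so ratings can be carried around
    before the scale is chosen.
    """

    subject_ids: tuple
    rater_a: tuple[str, ...]
    rater_b: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "rater_a", tuple(str(x) for x in self.rater_a))
        object.__setattr__(self, "rater_b", tuple(str(x) for x in self.rater_b))
        n = len(self.subject_ids)
        if len(self.rater_a) != n or len(self.rater_b) != n:
            raise TableError(
                f"ragged ratings: {n} subjects, {len(self.rater_a)} ratings by "
                f"rater A, {len(self.rater_b)} by rater B"
            )

    def __len__(self) -> int:
        return len(self.subject_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PairedRatings":
        """Build from a long-format frame with columns subject_id, rater_a, rater_b."""
        cols = ["subject_id", "rater_a", "rater_b"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            if df.shape[1] == 3:
                df = df.set_axis(cols, axis=1)
            else:
                raise TableError(f"long-format input missing columns {missing}")
        return cls(tuple(df["subject_id"]), tuple(df["rater_a"]), tuple(df["rater_b"]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_ids, "rater_a": self.rater_a, "rater_b": self.rater_b}
        )

    def observed_labels(self) -> tuple[str, ...]:
        """Distinct labels used by either rater, in order of first appearance."""
        seen: dict[str, None] = {}
        for a, b in zip(self.rater_a, self.rater_b):
            seen.setdefault(a)
            seen.setdefault(b)
        return tuple(seen)


@dataclass(frozen=True)
class ContingencyTable:
    """Square table of paired-rating counts over a shared scale.

    Categories declared on the scale but never used keep their zero
    row/column: weight distances depend on the declared scale, not the
    observed one.
    """

    counts: np.ndarray
    scale: RatingScale
    rater_names: tuple[str, str] = ("rater_a", "rater_b")
    table_id: str | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise TableError(f"contingency table must be square, got shape {c.shape}")
        if c.shape[0] != self.scale.n_categories:
            raise TableError(
                f"table side {c.shape[0]} does not match the scale's "
                f"{self.scale.n_categories} categories"
            )
        if not np.issubdtype(c.dtype, np.integer):
            rounded = np.rint(np.asarray(c, dtype=float))
            if not np.array_equal(rounded, np.asarray(c, dtype=float)):
                raise TableError("counts must be integers")
            c = rounded.astype(np.int64)
        else:
            c = c.astype(np.int64)
        if (c < 0).any():
            raise TableError("counts must be non-negative")
        if c.sum() == 0:
            raise TableError("contingency table has no observations")
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "rater_names", tuple(self.rater_names))

    # -- derived quantities ------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return int(self.counts.sum())

    @property
    def joint(self) -> np.ndarray:
        """Joint proportion matrix p_ij = counts_ij / n."""
        return self.counts / self.n_subjects

    @property
    def row_marginals(self) -> np.ndarray:
        """Rater A's category-usage proportions p_i."""
        return self.joint.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        """Rater B's category-usage proportions q_j."""
        return self.joint.sum(axis=0)

    @property
    def diagonal_proportions(self) -> np.ndarray:
        """Per-category exact-agreement proportions (the u_jj of Cohen's formula)."""
        return np.diag(self.joint)

    # -- transformations ---------------------------------------------------

    def transpose(self) -> "ContingencyTable":
        """Swap the raters."""
        return ContingencyTable(
            self.counts.T.copy(),
            self.scale,
            (self.rater_names[1], self.rater_names[0]),
            self.table_id,
        )

    def permute_categories(self, order: Sequence[int]) -> "ContingencyTable":
        """Reindex both axes by ``order`` (a permutation of category indices)."""
        order = list(order)
        if sorted(order) != list(range(self.scale.n_categories)):
            raise TableError(f"{order} is not a permutation of the categories")
        labels = tuple(self.scale.labels[i] for i in order)
        return ContingencyTable(
            self.counts[np.ix_(order, order)].copy(),
            RatingScale(labels, self.scale.is_ordinal),
            self.rater_names,
            self.table_id,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.scale.labels), columns=list(self.scale.labels))


def build_table(
    ratings: PairedRatings,
    scale: RatingScale,
    rater_names: tuple[str, str] = ("rater_a", "rater_b"),
    table_id: str | None = None,
) -> ContingencyTable:
    """Tally paired ratings into a contingency table over ``scale``.

    Every rating must be a label on the scale; an unknown label is
    reported together with the offending subject id.
    """
    if len(ratings) == 0:
        raise TableError("no subjects: cannot build a contingency table")
    n = scale.n_categories
    counts = np.zeros((n, n), dtype=np.int64)
    for sid, a, b in zip(ratings.subject_ids, ratings.rater_a, ratings.rater_b):
        for rater, label in ((rater_names[0], a), (rater_names[1], b)):
            if label not in scale:
                raise ScaleError(
                    f"subject {sid!r}: rating {label!r} by {rater} is not on the "
                    f"scale {scale.labels}"
                )
        counts[scale.index(a), scale.index(b)] += 1
    return ContingencyTable(counts, scale, rater_names, table_id)
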