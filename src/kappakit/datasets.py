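"""Bundled RECIST response-assessment confusion matrices.

Six 3x3 matrices of treatment-response calls (PR/SD/PD, ordered by
worsening response) against a reference standard: two radiologists (R1,
8 years' experience; R2, 4 years') and an automated deep-learning
segmentation pipeline, each on a testing dataset and a validation
cohort of 31 patients with liver metastases.  Rows are the rater's
category, columns the reference standard's.

``kappa_star`` carries the agreement values originally reported by the
study that produced the data; how those were computed is not known, so
they are reference metadata only and are never recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scale import RECIST_SCALE
from .table import ContingencyTable


@dataclass(frozen=True)
class RecistComparison:
    """One rater-vs-reference confusion matrix plus its provenance."""

    table: ContingencyTable
    dataset: str  # "testing" | "validation"
    rater: str  # "R1" | "R2" | "auto"
    kappa_star: float  # originally reported value; metadata, not reproducible


_RAW: tuple[tuple[str, str, tuple[tuple[int, ...], ...], float], ...] = (
    ("testing", "R1", ((1, 0, 2), (4, 3, 3), (1, 1, 16)), 0.48),
    ("testing", "R2", ((1, 0, 3), (3, 3, 5), (2, 1, 13)), 0.30),
    ("testing", "auto", ((2, 0, 2), (3, 3, 1), (1, 1, 18)), 0.51),
    ("validation", "R1", ((3, 2, 0), (3, 2, 1), (1, 0, 19)), 0.63),
    ("validation", "R2", ((2, 2, 2), (4, 2, 2), (1, 0, 16)), 0.45),
    ("validation", "auto", ((4, 2, 0), (1, 2, 3), (2, 0, 17)), 0.60),
)


def recist_comparisons() -> tuple[RecistComparison, ...]:
    """The six bundled rater-vs-reference comparisons, in report order."""
    out = []
    for dataset, rater, counts, kstar in _RAW:
        table = ContingencyTable(
            np.array(counts, dtype=np.int64),
            RECIST_SCALE,
            rater_names=(rater, "reference"),
            table_id=f"{dataset}/{rater}",
        )
        out.append(RecistComparison(table, dataset, rater, kstar))
    return tuple(out)


def recist_table(dataset: str, rater: str) -> ContingencyTable:
    """Look up one bundled matrix by dataset ('testing'/'validation') and rater."""
    for comp in recist_comparisons():
        if comp.dataset == dataset and comp.rater == rater:
            return comp.table
    raise KeyError(f"no bundled table for dataset={dataset!r}, rater={rater!r}")
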