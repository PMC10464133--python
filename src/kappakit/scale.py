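"""Rating scales: the ordered (or nominal) category sets raters assign from.

A scale fixes the category labels, their order, and whether that order is
meaningful.  Distance-based agreement weights are only defined for ordinal
scales, so the flag gates the weighted-kappa machinery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ScaleError(ValueError):
    """Invalid rating scale or a label outside the scale."""


@dataclass(frozen=True)
class RatingScale:
    """An ordered set of rating categories shared by both raters.

    Parameters
    ----------
    labels : tuple of str
        Category names in scale order.  Must be unique, at least two.
    is_ordinal : bool
        Whether the order of ``labels`` carries meaning (e.g. RECIST
        PR < SD < PD, or Likert items).  Nominal scales (eye colour)
        set this False and are rejected by distance-based weights.
    """

    labels: tuple[str, ...]
    is_ordinal: bool = True
    _index: dict[str, int] = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ScaleError(f"a rating scale needs at least 2 categories, got {len(labels)}")
        if len(set(labels)) != len(labels):
            raise ScaleError(f"duplicate category labels in {labels}")
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(labels)})

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """0-based position of ``label`` in scale order."""
        try:
            return self._index[label]
        except KeyError:
            raise ScaleError(
                f"label {label!r} is not on the scale {self.labels}"
            ) from None

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def reversed(self) -> "RatingScale":
        """The same scale read in the opposite direction."""
        return RatingScale(tuple(reversed(self.labels)), self.is_ordinal)


#: RECIST 1.1 response categories in order of worsening response.
RECIST_SCALE = RatingScale(("PR", "SD", "PD"), is_ordinal=True)
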