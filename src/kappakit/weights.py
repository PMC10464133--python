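"""Agreement weight matrices for the weighted-kappa family.

The power scheme gives partial credit for near-miss disagreements:

    w_ij = 1 - (|i - j| / (n - 1))**m

with 0-based category indices i, j in scale order.  m = 1 is the linear
weighted kappa (LWK), m = 2 the quadratic (QWK); any real m >= 1 is
accepted.  The identity matrix recovers Cohen's kappa as the
all-or-nothing special case, and for n = 2 the power scheme collapses to
the identity for every m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scale import RatingScale, ScaleError


class WeightError(ValueError):
    """Invalid agreement weight matrix."""


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric agreement weights in [0, 1] with a unit diagonal.

    ``scheme`` tags provenance: ``"power"`` (built by :func:`power_weights`,
    with ``exponent_m`` set), ``"identity"``, or ``"custom"`` for
    user-supplied matrices — a choice that rests on expert judgment, but
    one that must still be symmetric with ones on the diagonal.
    """

    weights: np.ndarray
    scheme: str = "custom"
    exponent_m: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise WeightError(f"weight matrix must be square, got shape {w.shape}")
        if w.shape[0] < 2:
            raise WeightError("weight matrix needs side >= 2")
        if not np.allclose(w, w.T, atol=1e-12):
            raise WeightError("weight matrix must be symmetric")
        if not np.allclose(np.diag(w), 1.0, atol=1e-12):
            raise WeightError("weight matrix diagonal must be all ones")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise WeightError("weights must lie in [0, 1]")
        w = np.clip(w, 0.0, 1.0)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        if self.scheme not in ("power", "identity", "custom"):
            raise WeightError(f"unknown weight scheme {self.scheme!r}")

    @property
    def n_categories(self) -> int:
        return self.weights.shape[0]

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.weights, np.eye(self.n_categories)))


def identity_weights(n_categories: int) -> WeightMatrix:
    """All-or-nothing weights: exact agreement only (Cohen's kappa)."""
    if n_categories < 2:
        raise WeightError("need at least 2 categories")
    return WeightMatrix(np.eye(n_categories), scheme="identity")


def power_weights(
    scale: RatingScale | int,
    exponent_m: float,
    *,
    force: bool = False,
) -> WeightMatrix:
    """Power-distance weights w_ij = 1 - (|i-j|/(n-1))**m.

    Parameters
    ----------
    scale : RatingScale or int
        The rating scale (or just its category count).  A nominal scale
        is rejected unless ``force=True``, since distance between
        unordered categories is meaningless.
    exponent_m : float
        Distance exponent, >= 1.  1 gives linear, 2 quadratic weights.
    force : bool
        Build weights for a nominal scale anyway (caller takes
        responsibility for the implied ordering).
    """
    if isinstance(scale, RatingScale):
        if not scale.is_ordinal and not force:
            raise ScaleError(
                "power weights presume ordered categories; the scale is nominal "
                "(pass force=True to override)"
            )
        n = scale.n_categories
    else:
        n = int(scale)
        if n < 2:
            raise WeightError("need at least 2 categories")
    m = float(exponent_m)
    if m < 1:
        raise WeightError(f"exponent m must be >= 1, got {m}")
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :]) / (n - 1)
    w = 1.0 - dist**m
    return WeightMatrix(w, scheme="power", exponent_m=m)


def linear_weights(scale: RatingScale | int, *, force: bool = False) -> WeightMatrix:
    """Power weights with m = 1 (linear weighted kappa)."""
    return power_weights(scale, 1.0, force=force)


def quadratic_weights(scale: RatingScale | int, *, force: bool = False) -> WeightMatrix:
    """Power weights with m = 2 (quadratic weighted kappa)."""
    return power_weights(scale, 2.0, force=force)
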