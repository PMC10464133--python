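"""Population agreement models, rating simulation, and the prevalence paradox.

A :class:`JointRatingModel` is the population analogue of a contingency
table: a joint probability over (rater A category, rater B category)
pairs.  Population kappas come in closed form; samples drawn from the
model feed estimator-recovery and CI-coverage checks.

The prevalence (kappa) paradox: at a fixed raw observed agreement,
Cohen's kappa falls as the category marginals grow more imbalanced,
because chance agreement rises with prevalence.
:func:`prevalence_paradox_demo` makes that concrete on 2x2 models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import UndefinedKappaError
from .scale import RatingScale
from .table import PairedRatings
from .weights import WeightMatrix, identity_weights


class ModelError(ValueError):
    """Invalid joint rating model."""


@dataclass(frozen=True)
class JointRatingModel:
    """Joint probability model over paired category assignments.

    ``joint[i, j]`` is the probability a subject is rated category i by
    rater A and j by rater B.  Entries are non-negative and sum to one.
    """

    joint: np.ndarray
    scale: RatingScale

    def __post_init__(self) -> None:
        j = np.asarray(self.joint, dtype=float)
        n = self.scale.n_categories
        if j.shape != (n, n):
            raise ModelError(f"joint must be {n}x{n} for this scale, got {j.shape}")
        if (j < -1e-15).any():
            raise ModelError("joint probabilities must be non-negative")
        if abs(j.sum() - 1.0) > 1e-12:
            raise ModelError(f"joint probabilities must sum to 1, got {j.sum()!r}")
        j = np.clip(j, 0.0, None)
        j.setflags(write=False)
        object.__setattr__(self, "joint", j)

    @property
    def row_marginals(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.joint.sum(axis=0)

    @classmethod
    def from_counts(cls, counts, scale: RatingScale) -> "JointRatingModel":
        """Empirical proportions of a count matrix as a population model."""
        c = np.asarray(counts, dtype=float)
        return cls(c / c.sum(), scale)


def population_kappa(model: JointRatingModel, weights: WeightMatrix | None = None) -> float:
    """Closed-form population kappa of a joint model (no sampling).

    Identity (or None) weights give population Cohen's kappa; any power
    weight matrix gives the corresponding population weighted kappa.
    """
    n = model.scale.n_categories
    w = identity_weights(n).weights if weights is None else weights.weights
    if w.shape[0] != n:
        raise ModelError("weight matrix side does not match the model")
    po = float((w * model.joint).sum())
    pe = float((w * np.outer(model.row_marginals, model.col_marginals)).sum())
    if pe >= 1.0 - 1e-15:
        raise UndefinedKappaError("population kappa undefined at expected agreement 1")
    return (po - pe) / (1.0 - pe)


def sample_ratings(model: JointRatingModel, n: int, seed: int) -> PairedRatings:
    """Draw n independent subjects from the joint model.

    One generator stream seeded once; subjects are drawn in index order
    (subject 0 first), so runs are reproducible at the sequence level.
    """
    if n < 1:
        raise ModelError(f"need n >= 1 subjects, got {n}")
    rng = np.random.default_rng(seed)
    k = model.scale.n_categories
    cells = rng.choice(k * k, size=n, p=model.joint.ravel())
    ii, jj = np.divmod(cells, k)
    labels = model.scale.labels
    return PairedRatings(
        tuple(range(n)),
        tuple(labels[i] for i in ii),
        tuple(labels[j] for j in jj),
    )


def balanced_agreement_model(
    observed_agreement: float, skew: float, scale: RatingScale | None = None
) -> JointRatingModel:
    """2x2 model with fixed raw agreement and a symmetric marginal skew.

    Both off-diagonal cells carry (1 - P_o)/2 each; the diagonal splits
    so that both raters' first-category marginal equals ``skew``.
    Feasible only for skew within (1 - P_o)/2 .. (1 + P_o)/2.
    """
    if not (0 < observed_agreement < 1):
        raise ModelError("observed agreement must be in (0, 1)")
    if scale is None:
        scale = RatingScale(("pos", "neg"))
    if scale.n_categories != 2:
        raise ModelError("the prevalence construction is defined for 2 categories")
    off = (1.0 - observed_agreement) / 2.0
    d1 = skew - off
    d2 = observed_agreement - d1
    if d1 < -1e-12 or d2 < -1e-12:
        raise ModelError(
            f"no 2x2 model has observed agreement {observed_agreement} with "
            f"marginal skew {skew}: feasible skews are "
            f"[{off:.3g}, {1 - off:.3g}]"
        )
    joint = np.array([[max(d1, 0.0), off], [off, max(d2, 0.0)]])
    return JointRatingModel(joint / joint.sum(), scale)


def prevalence_paradox_demo(
    base_agreement: float = 0.8,
    imbalance_grid=None,
) -> pd.DataFrame:
    """Cohen's kappa across a marginal-imbalance grid at constant raw agreement.

    Returns a frame with columns ``skew``, ``observed_agreement``,
    ``cohen_kappa`` and ``feasible``.  Infeasible (agreement, skew)
    combinations are flagged rows with NaN kappa, not silently dropped.
    Demonstrates kappa declining as imbalance grows even though the raw
    agreement never moves.
    """
    if imbalance_grid is None:
        imbalance_grid = np.round(np.arange(0.50, 0.951, 0.05), 10)
    rows = []
    for skew in imbalance_grid:
        try:
            model = balanced_agreement_model(base_agreement, float(skew))
            k = population_kappa(model)
            rows.append((float(skew), base_agreement, k, True))
        except (ModelError, UndefinedKappaError):
            rows.append((float(skew), base_agreement, float("nan"), False))
    return pd.DataFrame(rows, columns=["skew", "observed_agreement", "cohen_kappa", "feasible"])
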