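"""Point estimation of Cohen's kappa and the weighted-kappa family.

Both statistics are chance-corrected agreement rates

    kappa = (P_o - P_e) / (1 - P_e)

where the observed agreement P_o = sum_ij w_ij p_ij weights the joint
proportion matrix and the expected agreement P_e = sum_ij w_ij p_i q_j
weights the product of the two raters' marginals.  Identity weights
recover Cohen's kappa; power weights with exponent m give the linear
(m=1) and quadratic (m=2) weighted kappas.

Kappa is undefined when P_e = 1, i.e. both raters put every subject in
one and the same category; that degenerate case raises
:class:`UndefinedKappaError` rather than returning a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .table import ContingencyTable, TableError
from .weights import WeightMatrix, identity_weights


class UndefinedKappaError(ZeroDivisionError):
    """Expected agreement is 1: chance correction has nothing to correct."""


@dataclass(frozen=True)
class KappaEstimate:
    """A kappa point estimate with its agreement components.

    ``statistic`` is ``"cohen"`` or ``"weighted"``; for weighted kappa
    ``exponent_m`` records the power-weight exponent (None for custom
    weights).
    """

    statistic: str
    point: float
    observed_agreement: float
    expected_agreement: float
    n_subjects: int
    exponent_m: float | None = None
    table_id: str | None = None

    @property
    def label(self) -> str:
        """Short name: 'cohen', 'linear', 'quadratic' or 'weighted(m=..)'."""
        if self.statistic == "cohen":
            return "cohen"
        if self.exponent_m == 1:
            return "linear"
        if self.exponent_m == 2:
            return "quadratic"
        if self.exponent_m is not None:
            return f"weighted(m={self.exponent_m:g})"
        return "weighted(custom)"


def _agreement_components(table: ContingencyTable, w: np.ndarray) -> tuple[float, float]:
    p = table.joint
    po = float((w * p).sum())
    pe = float((w * np.outer(table.row_marginals, table.col_marginals)).sum())
    return po, pe


def _kappa(po: float, pe: float) -> float:
    if pe >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            f"kappa undefined: expected agreement {pe} leaves no room for "
            "chance correction (both raters use a single identical category)"
        )
    return (po - pe) / (1.0 - pe)


def cohen_kappa(table: ContingencyTable) -> KappaEstimate:
    """Cohen's kappa: exact-match agreement corrected for chance.

    P_o sums the diagonal joint proportions; P_e sums, per category, the
    product of the two raters' marginal proportions for that category.
    """
    n = table.scale.n_categories
    po, pe = _agreement_components(table, np.eye(n))
    return KappaEstimate(
        statistic="cohen",
        point=_kappa(po, pe),
        observed_agreement=po,
        expected_agreement=pe,
        n_subjects=table.n_subjects,
        table_id=table.table_id,
    )


def weighted_kappa(table: ContingencyTable, weights: WeightMatrix) -> KappaEstimate:
    """Weighted kappa with an arbitrary symmetric unit-diagonal weight matrix.

    Equivalently written 1 - (1 - P_o)/(1 - P_e): one minus the ratio of
    weighted disagreement observed to weighted disagreement expected by
    chance.
    """
    if weights.n_categories != table.scale.n_categories:
        raise TableError(
            f"weight matrix side {weights.n_categories} does not match table "
            f"side {table.scale.n_categories}"
        )
    po, pe = _agreement_components(table, weights.weights)
    return KappaEstimate(
        statistic="weighted",
        point=_kappa(po, pe),
        observed_agreement=po,
        expected_agreement=pe,
        n_subjects=table.n_subjects,
        exponent_m=weights.exponent_m,
        table_id=table.table_id,
    )


def kappa_estimate(table: ContingencyTable, weights: WeightMatrix | None = None) -> KappaEstimate:
    """Dispatch: identity/None weights -> Cohen's kappa, else weighted kappa."""
    if weights is None or weights.is_identity:
        return cohen_kappa(table)
    return weighted_kappa(table, weights)


def brute_force_kappa(ratings_a, ratings_b, scale, weights: WeightMatrix | None = None) -> float:
    """Kappa by direct per-subject-pair tallying, bypassing the matrix algebra.

    Observed agreement averages w[a_s, b_s] over subjects s; expected
    agreement averages w[a_s, b_t] over all ordered subject pairs (s, t),
    which is exactly the product-of-marginals chance model.  Exists as an
    independent check of the matrix computation.
    """
    if weights is None:
        w = identity_weights(scale.n_categories).weights
    else:
        w = weights.weights
    ia = [scale.index(x) for x in ratings_a]
    ib = [scale.index(x) for x in ratings_b]
    n = len(ia)
    if n == 0:
        raise TableError("no subjects")
    po = sum(w[a, b] for a, b in zip(ia, ib)) / n
    pe = sum(w[a, b] for a in ia for b in ib) / (n * n)
    return _kappa(po, pe)
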