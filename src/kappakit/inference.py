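"""Standard errors, confidence intervals and tests for kappa.

Asymptotic route: the Fleiss–Cohen–Everitt large-sample variance of
weighted kappa under the non-null distribution (Cohen's kappa is the
identity-weight case), paired with a two-sided Wald test of kappa = 0 so
that "p < alpha" and "the (1-alpha) CI excludes 0" always agree.

Bootstrap route: nonparametric resampling — subjects with replacement
from paired ratings, or equivalently a multinomial redraw of the table's
cells — with percentile intervals.  Replicates on which kappa is
undefined are dropped and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import KappaEstimate, UndefinedKappaError, kappa_estimate
from .scale import RatingScale
from .table import ContingencyTable, PairedRatings, TableError, build_table
from .weights import WeightMatrix, identity_weights


class InferenceError(ValueError):
    """Inference cannot be carried out on this input."""


@dataclass(frozen=True)
class KappaInference:
    """A kappa estimate with uncertainty attached.

    ``method`` is "asymptotic" or "bootstrap".  ``degenerate`` flags a
    zero-width interval from se = 0 (or an all-identical bootstrap).
    """

    estimate: KappaEstimate
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    alpha: float = 0.05
    method: str = "asymptotic"
    degenerate: bool = False
    n_boot: int | None = None
    seed: int | None = None
    n_boot_dropped: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise InferenceError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.se < 0:
            raise InferenceError("standard error cannot be negative")
        if self.ci_low > self.ci_high + 1e-12:
            raise InferenceError("ci_low exceeds ci_high")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        est = self.estimate
        out = {
            "statistic": est.statistic,
            "m": est.exponent_m,
            "point": est.point,
            "observed_agreement": est.observed_agreement,
            "expected_agreement": est.expected_agreement,
            "se": self.se,
            "ci": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "alpha": self.alpha,
            "method": self.method,
            "n": est.n_subjects,
        }
        if self.method == "bootstrap":
            out["n_boot"] = self.n_boot
            out["seed"] = self.seed
            out["n_boot_dropped"] = self.n_boot_dropped
        if self.degenerate:
            out["degenerate"] = True
        return out


# ---------------------------------------------------------------------------
# asymptotic route


def asymptotic_se(table: ContingencyTable, weights: WeightMatrix | None = None) -> float:
    """Large-sample standard error of (weighted) kappa, non-null form.

    Fleiss, Cohen & Everitt's variance for weighted kappa:

        n * var = [ sum_ij p_ij (w_ij (1-P_e) - (wbar_i. + wbar_.j)(1-P_o))^2
                    - (P_o P_e - 2 P_e + P_o)^2 ] / (1 - P_e)^4

    with wbar_i. = sum_j q_j w_ij and wbar_.j = sum_i p_i w_ij the
    marginal-averaged weights.  Identity weights give the classical
    non-null variance of Cohen's kappa.  Scales as 1/sqrt(n).
    """
    if table.n_subjects < 2:
        raise InferenceError("need at least 2 subjects for a standard error")
    if weights is None:
        weights = identity_weights(table.scale.n_categories)
    if weights.n_categories != table.scale.n_categories:
        raise TableError("weight matrix side does not match the table")
    w = weights.weights
    p = table.joint
    pi = table.row_marginals
    qj = table.col_marginals
    po = float((w * p).sum())
    pe = float((w * np.outer(pi, qj)).sum())
    if pe >= 1.0 - 1e-15:
        raise UndefinedKappaError("kappa (and its SE) undefined at expected agreement 1")
    wbar_row = (w * qj[None, :]).sum(axis=1)  # average weight of row i vs rater B
    wbar_col = (w * pi[:, None]).sum(axis=0)
    term = w * (1 - pe) - (wbar_row[:, None] + wbar_col[None, :]) * (1 - po)
    var_n = ((p * term**2).sum() - (po * pe - 2 * pe + po) ** 2) / (1 - pe) ** 4
    var = max(float(var_n), 0.0) / table.n_subjects
    return math.sqrt(var)


def wald_interval(
    estimate: KappaEstimate, se: float, alpha: float = 0.05, method: str = "asymptotic"
) -> KappaInference:
    """Wald CI point ± z_{1-alpha/2}·se, clipped to [-1, 1], and the matching
    two-sided test of kappa = 0.

    With se = 0 the interval collapses to the point and the p-value is 0
    (1 when the point itself is 0); the result is flagged degenerate.
    """
    if se < 0:
        raise InferenceError("se must be non-negative")
    if not (0 < alpha < 1):
        raise InferenceError(f"alpha must be in (0, 1), got {alpha}")
    k = estimate.point
    if se == 0:
        return KappaInference(
            estimate=estimate,
            se=0.0,
            ci_low=max(k, -1.0),
            ci_high=min(k, 1.0),
            p_value=1.0 if k == 0 else 0.0,
            alpha=alpha,
            method=method,
            degenerate=True,
        )
    z = stats.norm.ppf(1 - alpha / 2)
    lo = max(k - z * se, -1.0)
    hi = min(k + z * se, 1.0)
    p = 2 * stats.norm.sf(abs(k / se))
    return KappaInference(
        estimate=estimate, se=se, ci_low=lo, ci_high=hi, p_value=float(p),
        alpha=alpha, method=method,
    )


def asymptotic_inference(
    table: ContingencyTable, weights: WeightMatrix | None = None, alpha: float = 0.05
) -> KappaInference:
    """Point estimate + FCE standard error + Wald CI/test in one call."""
    est = kappa_estimate(table, weights)
    return wald_interval(est, asymptotic_se(table, weights), alpha)


# ---------------------------------------------------------------------------
# bootstrap route


def bootstrap_ci(
    ratings: PairedRatings,
    scale: RatingScale,
    weights: WeightMatrix | None = None,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
    rater_names: tuple[str, str] = ("rater_a", "rater_b"),
) -> KappaInference:
    """Percentile bootstrap CI, resampling subjects with replacement.

    Replicates with undefined kappa (a resample where both raters use a
    single identical category) are dropped and counted; more than 50%
    dropped aborts with a diagnostic.  Fully reproducible given ``seed``.
    """
    if n_boot < 100:
        raise InferenceError(f"n_boot must be >= 100, got {n_boot}")
    if seed is None:
        raise InferenceError("bootstrap requires an explicit seed")
    table = build_table(ratings, scale, rater_names)
    est = kappa_estimate(table, weights)

    n = len(ratings)
    ia = np.array([scale.index(x) for x in ratings.rater_a])
    ib = np.array([scale.index(x) for x in ratings.rater_b])
    k = scale.n_categories
    w = identity_weights(k).weights if weights is None else weights.weights

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    dropped = 0
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        counts = np.zeros((k, k))
        np.add.at(counts, (ia[idx], ib[idx]), 1.0)
        p = counts / n
        po = float((w * p).sum())
        pe = float((w * np.outer(p.sum(1), p.sum(0))).sum())
        if pe >= 1.0 - 1e-15:
            dropped += 1
            continue
        reps[kept] = (po - pe) / (1 - pe)
        kept += 1
    if dropped > n_boot / 2:
        raise InferenceError(
            f"bootstrap failed: kappa undefined on {dropped}/{n_boot} resamples "
            "(ratings are nearly degenerate)"
        )
    reps = reps[:kept]
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    lo = float(max(lo, -1.0))
    hi = float(min(hi, 1.0))
    se = float(reps.std(ddof=1)) if kept > 1 else 0.0
    # p-value from the percentile principle: smallest alpha at which the
    # interval excludes 0 = twice the tail proportion of resamples across 0.
    tail = min((reps <= 0).mean(), (reps >= 0).mean())
    p_value = float(min(1.0, 2 * tail))
    return KappaInference(
        estimate=est, se=se, ci_low=lo, ci_high=hi, p_value=p_value, alpha=alpha,
        method="bootstrap", degenerate=(lo == hi), n_boot=n_boot, seed=seed,
        n_boot_dropped=dropped,
    )


def bootstrap_ci_from_table(
    table: ContingencyTable,
    weights: WeightMatrix | None = None,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> KappaInference:
    """Percentile bootstrap redrawing the table's cells multinomially.

    Equivalent to subject resampling when only the table is available.
    """
    ratings = _table_to_ratings(table)
    return bootstrap_ci(
        ratings, table.scale, weights, n_boot=n_boot, alpha=alpha, seed=seed,
        rater_names=table.rater_names,
    )


def _table_to_ratings(table: ContingencyTable) -> PairedRatings:
    """Expand a contingency table into one rating pair per subject."""
    sids, ra, rb = [], [], []
    labels = table.scale.labels
    s = 0
    for i in range(table.scale.n_categories):
        for j in range(table.scale.n_categories):
            for _ in range(int(table.counts[i, j])):
                sids.append(s)
                ra.append(labels[i])
                rb.append(labels[j])
                s += 1
    return PairedRatings(tuple(sids), tuple(ra), tuple(rb))
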