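"""Model/Results interface over the agreement machinery.

:class:`InterRaterModel` wraps a two-rater dataset (a contingency table,
or paired ratings plus a scale); :meth:`InterRaterModel.fit` estimates a
chosen kappa statistic and returns :class:`KappaResults` carrying the
point estimate, its standard error, confidence interval, test of
kappa = 0, and a qualitative verdict, with a ``summary()`` table.

    >>> model = InterRaterModel.from_counts([[1, 0, 2], [4, 3, 3], [1, 1, 16]],
    ...                                     labels=("PR", "SD", "PD"))
    >>> res = model.fit(statistic="weighted", m=1)
    >>> round(res.point, 2)
    0.38
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import KappaEstimate, kappa_estimate
from .inference import (
    KappaInference,
    asymptotic_se,
    bootstrap_ci,
    wald_interval,
)
from .interpret import (
    LANDIS_KOCH_BANDS,
    AgreementVerdict,
    StatisticAdvice,
    interpret,
    select_statistic,
)
from .scale import RatingScale
from .table import ContingencyTable, PairedRatings, build_table
from .weights import WeightMatrix, identity_weights, power_weights


class InterRaterModel:
    """Two-rater agreement model over a shared rating scale.

    Construct from a contingency table (:meth:`from_table`,
    :meth:`from_counts`) or subject-level paired ratings
    (:meth:`from_ratings`, :meth:`from_dataframe`); bootstrap inference
    requires the subject-level route only in the sense that a table is
    expanded implicitly (subject resampling and multinomial cell redraw
    coincide).
    """

    def __init__(
        self,
        table: ContingencyTable,
        ratings: PairedRatings | None = None,
    ) -> None:
        self.table = table
        self.ratings = ratings
        self.scale = table.scale

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_table(cls, table: ContingencyTable) -> "InterRaterModel":
        return cls(table)

    @classmethod
    def from_counts(
        cls,
        counts,
        labels=None,
        is_ordinal: bool = True,
        rater_names: tuple[str, str] = ("rater_a", "rater_b"),
        table_id: str | None = None,
    ) -> "InterRaterModel":
        counts = np.asarray(counts)
        if labels is None:
            labels = tuple(f"c{i}" for i in range(counts.shape[0]))
        scale = RatingScale(tuple(labels), is_ordinal)
        return cls(ContingencyTable(counts, scale, rater_names, table_id))

    @classmethod
    def from_ratings(
        cls,
        ratings: PairedRatings,
        scale: RatingScale | None = None,
        rater_names: tuple[str, str] = ("rater_a", "rater_b"),
    ) -> "InterRaterModel":
        if scale is None:
            scale = RatingScale(tuple(sorted(ratings.observed_labels())))
        return cls(build_table(ratings, scale, rater_names), ratings)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, scale: RatingScale | None = None
    ) -> "InterRaterModel":
        """Long-format frame with columns subject_id, rater_a, rater_b."""
        return cls.from_ratings(PairedRatings.from_dataframe(df), scale)

    # -- advice ------------------------------------------------------------

    def advise(self) -> StatisticAdvice:
        """Which kappa statistic suits this model's scale."""
        return select_statistic(self.scale)

    # -- fitting -----------------------------------------------------------

    def _weights(self, statistic: str, m: float, weights: WeightMatrix | None) -> WeightMatrix | None:
        if weights is not None:
            return weights
        if statistic == "auto":
            statistic = self.advise().recommended
        if statistic == "cohen":
            return None
        if statistic == "weighted":
            return power_weights(self.scale, m)
        raise ValueError(f"unknown statistic {statistic!r}; use 'cohen', 'weighted' or 'auto'")

    def fit(
        self,
        statistic: str = "auto",
        m: float = 1.0,
        weights: WeightMatrix | None = None,
        ci: str = "asymptotic",
        alpha: float = 0.05,
        n_boot: int = 2000,
        seed: int | None = None,
        gate_interpretation: bool = True,
        band_edges=LANDIS_KOCH_BANDS,
    ) -> "KappaResults":
        """Estimate one kappa statistic with inference attached.

        Parameters
        ----------
        statistic : {"auto", "cohen", "weighted"}
            "auto" follows :meth:`advise` (weighted for ordinal scales of
            3+ categories, Cohen otherwise).
        m : float
            Power-weight exponent when ``statistic="weighted"``
            (1 linear, 2 quadratic; any m >= 1).
        weights : WeightMatrix, optional
            Explicit weight matrix; overrides ``statistic``/``m``.
        ci : {"asymptotic", "bootstrap"}
            Asymptotic (Fleiss–Cohen–Everitt SE + Wald) or percentile
            bootstrap over subjects (requires ``seed``).
        """
        w = self._weights(statistic, m, weights)
        est = kappa_estimate(self.table, w)
        if ci == "asymptotic":
            inf = wald_interval(est, asymptotic_se(self.table, w), alpha)
        elif ci == "bootstrap":
            ratings = self.ratings
            if ratings is None:
                from .inference import _table_to_ratings

                ratings = _table_to_ratings(self.table)
            inf = bootstrap_ci(
                ratings, self.scale, w, n_boot=n_boot, alpha=alpha, seed=seed,
                rater_names=self.table.rater_names,
            )
        else:
            raise ValueError(f"unknown ci method {ci!r}")
        verdict = interpret(inf, gate=gate_interpretation, band_edges=band_edges)
        return KappaResults(self, est, inf, verdict)

    def fit_family(
        self,
        statistics: tuple[str, ...] = ("cohen", "linear", "quadratic"),
        **kwargs,
    ) -> dict[str, "KappaResults"]:
        """Fit several statistics at once; keys are the statistic labels.

        ``statistics`` entries are "cohen", "linear", "quadratic", or
        "m=<value>" for other exponents.
        """
        out: dict[str, KappaResults] = {}
        for name in statistics:
            if name == "cohen":
                out[name] = self.fit(statistic="cohen", **kwargs)
            elif name == "linear":
                out[name] = self.fit(statistic="weighted", m=1, **kwargs)
            elif name == "quadratic":
                out[name] = self.fit(statistic="weighted", m=2, **kwargs)
            elif name.startswith("m="):
                out[name] = self.fit(statistic="weighted", m=float(name[2:]), **kwargs)
            else:
                raise ValueError(
                    f"unknown statistic {name!r}; use cohen, linear, quadratic or m=<x>"
                )
        return out


@dataclass(frozen=True)
class KappaResults:
    """Fitted agreement results: estimate, uncertainty, verdict."""

    model: InterRaterModel
    estimate: KappaEstimate
    inference: KappaInference
    verdict: AgreementVerdict

    # convenience accessors
    @property
    def point(self) -> float:
        return self.estimate.point

    @property
    def se(self) -> float:
        return self.inference.se

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.inference.ci_low, self.inference.ci_high)

    @property
    def p_value(self) -> float:
        return self.inference.p_value

    def to_dict(self) -> dict:
        d = self.inference.to_dict()
        d["interpretation"] = self.verdict.label
        return d

    def summary(self) -> str:
        """Plain-text summary table."""
        est, inf = self.estimate, self.inference
        lines = [
            "Inter-rater agreement",
            "=" * 54,
            f"statistic:        {est.label} kappa",
            f"raters:           {self.model.table.rater_names[0]} vs "
            f"{self.model.table.rater_names[1]}",
            f"subjects:         {est.n_subjects}",
            f"categories:       {', '.join(self.model.scale.labels)}",
            "-" * 54,
            f"kappa:            {est.point:8.4f}",
            f"observed agr.:    {est.observed_agreement:8.4f}",
            f"expected agr.:    {est.expected_agreement:8.4f}",
            f"std. error:       {inf.se:8.4f}  ({inf.method})",
            f"{(1 - inf.alpha) * 100:.0f}% CI:           "
            f"[{inf.ci_low:7.4f}, {inf.ci_high:7.4f}]",
            f"p-value (k=0):    {inf.p_value:8.4f}",
            f"interpretation:   {self.verdict.label}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<KappaResults {self.estimate.label} kappa={self.point:.4f} "
            f"ci=({self.inference.ci_low:.4f}, {self.inference.ci_high:.4f})>"
        )
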