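"""Qualitative interpretation of kappa, and advice on which statistic fits.

Magnitude bands follow Landis & Koch, the de-facto convention for
agreement strength; edges are configurable.  A significance gate
(default on) reports "no agreement" whenever the test of kappa = 0 is
not significant, regardless of the point estimate — the reporting rule
used when reanalysing response-assessment agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .inference import KappaInference
from .scale import RatingScale

#: Landis–Koch band edges: right-closed intervals over (-1, 1].
#: (upper_edge, label); a kappa <= 0 is "no agreement".
LANDIS_KOCH_BANDS: tuple[tuple[float, str], ...] = (
    (0.0, "no agreement"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)


@dataclass(frozen=True)
class AgreementVerdict:
    """Qualitative label for an agreement estimate."""

    label: str
    gated_by_significance: bool
    band_edges: tuple[tuple[float, str], ...] = LANDIS_KOCH_BANDS


@dataclass(frozen=True)
class StatisticAdvice:
    """Which kappa statistic suits a rating scale, and why."""

    recommended: str  # "cohen" | "weighted"
    reason: str
    suggest_both_weightings: bool = False


def band_label(point: float, band_edges=LANDIS_KOCH_BANDS) -> str:
    """Map a kappa value to its band; intervals are closed on the right."""
    for upper, label in band_edges:
        if point <= upper:
            return label
    return band_edges[-1][1]


def interpret(
    inference: KappaInference,
    gate: bool = True,
    band_edges=LANDIS_KOCH_BANDS,
) -> AgreementVerdict:
    """Label an inference result.

    With the gate on, an estimate whose p-value is not below alpha is
    reported as "no agreement" whatever its magnitude; otherwise the
    label is a pure band lookup on the point estimate.
    """
    if gate and inference.p_value >= inference.alpha:
        return AgreementVerdict("no agreement", True, tuple(band_edges))
    return AgreementVerdict(band_label(inference.estimate.point, band_edges), gate, tuple(band_edges))


def select_statistic(scale: RatingScale) -> StatisticAdvice:
    """Advise Cohen's vs weighted kappa for a scale.

    Two categories: Cohen's kappa (weights cannot distinguish
    disagreements).  Three or more nominal categories: Cohen's kappa
    (no distance between unordered categories).  Three or more ordered
    categories: weighted kappa, reporting both the linear and quadratic
    weightings for a fuller picture of how disagreements distribute.
    """
    if scale.n_categories == 2:
        return StatisticAdvice(
            "cohen",
            "two categories: every disagreement is one step, so weighting adds "
            "nothing and Cohen's kappa applies",
        )
    if not scale.is_ordinal:
        return StatisticAdvice(
            "cohen",
            f"{scale.n_categories} unordered categories: distance between nominal "
            "categories is undefined, so Cohen's kappa applies",
        )
    return StatisticAdvice(
        "weighted",
        f"{scale.n_categories} ordered categories: near-miss disagreements should "
        "earn partial credit; report both linear and quadratic weighted kappa",
        suggest_both_weightings=True,
    )
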