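"""Shared fixtures: the published RECIST reanalysis values and random-table helpers.

``TABLE1_EXPECTED`` freezes the printed reanalysis of the six bundled
confusion matrices: point estimates at 2 decimals, 95% CI bounds at
2 decimals, and whether each statistic was significant at alpha = 0.05.
"""

import numpy as np
import pytest

from kappakit import RatingScale

# (dataset, rater) -> statistic -> (point_2dp, ci_low_2dp, ci_high_2dp, significant)
TABLE1_EXPECTED = {
    ("testing", "R1"): {
        "cohen": (0.35, 0.11, 0.60, True),
        "linear": (0.38, 0.11, 0.66, True),
        "quadratic": (0.40, 0.08, 0.73, True),
    },
    ("testing", "R2"): {
        "cohen": (0.22, -0.03, 0.47, False),
        "linear": (0.20, -0.08, 0.48, False),
        "quadratic": (0.18, -0.17, 0.53, False),
    },
    ("testing", "auto"): {
        "cohen": (0.49, 0.23, 0.76, True),
        "linear": (0.51, 0.23, 0.79, True),
        "quadratic": (0.52, 0.19, 0.85, True),
    },
    ("validation", "R1"): {
        "cohen": (0.57, 0.34, 0.80, True),
        "linear": (0.67, 0.46, 0.87, True),
        "quadratic": (0.75, 0.54, 0.95, True),
    },
    ("validation", "R2"): {
        "cohen": (0.38, 0.14, 0.61, True),
        "linear": (0.45, 0.20, 0.69, True),
        "quadratic": (0.51, 0.23, 0.79, True),
    },
    ("validation", "auto"): {
        "cohen": (0.52, 0.26, 0.78, True),
        "linear": (0.60, 0.35, 0.85, True),
        "quadratic": (0.66, 0.39, 0.93, True),
    },
}

# Kappa values originally reported for the same six matrices (metadata only).
KAPPA_STAR = {
    ("testing", "R1"): 0.48,
    ("testing", "R2"): 0.30,
    ("testing", "auto"): 0.51,
    ("validation", "R1"): 0.63,
    ("validation", "R2"): 0.45,
    ("validation", "auto"): 0.60,
}


@pytest.fixture
def recist_scale():
    return RatingScale(("PR", "SD", "PD"), is_ordinal=True)


@pytest.fixture
def testing_r1_counts():
    return np.array([[1, 0, 2], [4, 3, 3], [1, 1, 16]])


def random_ratings(rng, n_subjects, n_categories):
    """Random paired ratings over generic labels, skewed enough to vary."""
    labels = [f"c{i}" for i in range(n_categories)]
    probs = rng.dirichlet(np.ones(n_categories * n_categories))
    cells = rng.choice(n_categories * n_categories, size=n_subjects, p=probs)
    a = [labels[c // n_categories] for c in cells]
    b = [labels[c % n_categories] for c in cells]
    return list(range(n_subjects)), a, b, labels
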