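"""Published reference values for Atlantic Bulwer's petrel assignment.

These are the reported quantities this pipeline is designed to reproduce and
be checked against: the linear classification functions for assigning a bird
to its non-breeding area from S8 / R6 feather isotope values, the per-class
correct-classification table, and the per-group isotope means (the means also
parameterize the synthetic generator; see :mod:`isoflight.synthetic`).

Classification functions map (d15N, d13C) in per mil to a score; the larger
of the Central/South scores assigns the bird. Coefficients are stored as
(coef_d15N, coef_d13C, constant).
"""

from __future__ import annotations

import numpy as np

from .synthetic import CENTRAL_ATLANTIC, SOUTH_ATLANTIC

__all__ = [
    "AREA_CLASSIFICATION_FUNCTIONS",
    "CLASSIFICATION_RATE_TABLE",
    "evaluate_classification_function",
    "assign_area",
]

#: Published per-feather, per-area linear classification functions.
AREA_CLASSIFICATION_FUNCTIONS: dict[str, dict[str, tuple[float, float, float]]] = {
    "S8": {
        CENTRAL_ATLANTIC: (5.8, -116.2, -983.7),
        SOUTH_ATLANTIC: (7.0, -118.8, -1043.9),
    },
    "R6": {
        CENTRAL_ATLANTIC: (1.3, -79.0, -660.9),
        SOUTH_ATLANTIC: (2.3, -82.2, -727.1),
    },
}

#: Published correct-classification rates (%): per class, (n_train, n_test,
#: pct_train, pct_test). "colony" block is P1; "area" blocks are per feather.
CLASSIFICATION_RATE_TABLE: dict[str, dict[str, tuple[int, int, float, float]]] = {
    "P1_colony": {
        "Vila": (5, 2, 40.0, 50.0),
        "M. Clara": (31, 14, 51.6, 57.1),
        "Raso": (10, 5, 60.0, 0.0),
        "Cima": (12, 5, 76.9, 33.3),
    },
    "P1_area": {
        CENTRAL_ATLANTIC: (38, 16, 51.3, 47.1),
        SOUTH_ATLANTIC: (21, 9, 61.9, 77.8),
    },
    "S8_area": {
        CENTRAL_ATLANTIC: (38, 16, 87.2, 94.1),
        SOUTH_ATLANTIC: (21, 9, 76.2, 88.9),
    },
    "R6_area": {
        CENTRAL_ATLANTIC: (38, 16, 89.7, 82.4),
        SOUTH_ATLANTIC: (21, 9, 66.7, 77.8),
    },
}


def evaluate_classification_function(
    feather: str, area: str, d15n: float, d13c: float
) -> float:
    """Score of one published classification function at (d15N, d13C)."""
    a, b, c = AREA_CLASSIFICATION_FUNCTIONS[feather][area]
    return a * d15n + b * d13c + c


def assign_area(feather: str, d15n, d13c) -> np.ndarray:
    """Assign birds to Central/South Atlantic with the published functions."""
    d15n = np.atleast_1d(np.asarray(d15n, dtype=float))
    d13c = np.atleast_1d(np.asarray(d13c, dtype=float))
    sc = np.stack(
        [
            evaluate_classification_function(feather, area, d15n, d13c)
            for area in (CENTRAL_ATLANTIC, SOUTH_ATLANTIC)
        ]
    )
    return np.where(sc[0] >= sc[1], CENTRAL_ATLANTIC, SOUTH_ATLANTIC)
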