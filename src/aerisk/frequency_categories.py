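"""SmPC frequency categories for adverse-event risks.

The European SmPC guideline classifies an AE risk as very rare, rare,
uncommon, common or very common when it is <0.01%, <0.1%, <1%, <10% and
>=10% respectively. The upper cut-points are exclusive except the last:
a risk of exactly 10% is "very common". Categories are computed from
unrounded probability estimates.
"""

from __future__ import annotations

from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["FrequencyCategory", "categorize", "category_crosstab"]


class FrequencyCategory(IntEnum):
    VERY_RARE = 0
    RARE = 1
    UNCOMMON = 2
    COMMON = 3
    VERY_COMMON = 4

    @property
    def label(self) -> str:
        return self.name.replace("_", " ").lower()


_UPPER_BOUNDS = (1e-4, 1e-3, 1e-2, 1e-1)


def categorize(p: float) -> FrequencyCategory:
    """Map a probability in [0, 1] to its SmPC frequency category."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must lie in [0, 1], got {p!r}")
    for cat, bound in zip(FrequencyCategory, _UPPER_BOUNDS):
        if p < bound:
            return cat
    return FrequencyCategory.VERY_COMMON


def category_crosstab(
    gold: Sequence[float] | Iterable[float],
    other: Sequence[float] | Iterable[float],
    name: str = "comparator",
) -> pd.DataFrame:
    """5x5 cross-tabulation of frequency categories, gold rows vs comparator columns.

    Inputs are paired probability estimates for the same (trial, AE type)
    units; off-diagonal counts are category switches induced by the choice
    of estimator.
    """
    gold = list(gold)
    other = list(other)
    if len(gold) != len(other):
        raise ValueError(
            f"paired inputs required: {len(gold)} gold vs {len(other)} {name}"
        )
    labels = [c.label for c in FrequencyCategory]
    mat = np.zeros((5, 5), dtype=int)
    for g, o in zip(gold, other):
        mat[int(categorize(g)), int(categorize(o))] += 1
    df = pd.DataFrame(mat, index=labels, columns=labels)
    df.index.name = "gold"
    df.columns.name = name
    return df
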