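"""New-item series and accumulation curves.

Walking respondents in stored order, the *new-item series* counts, for each
respondent position x = 1..N, how many items that respondent is the first to
mention.  Its cumulative sum is the accumulation curve (unique items
observed through the first n respondents).  The series is the response
variable of every saturation model downstream.

Respondents are never reordered: reordering to best fit a declining curve
can make saturation appear earlier than it really is.  A permutation-
averaged curve is available as an explicitly labelled diagnostic, off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import FreeListDataset

__all__ = ["NewItemSeries", "new_item_series", "accumulation_curve",
           "permutation_averaged_curve"]


@dataclass(frozen=True)
class NewItemSeries:
    """Counts of first-occurrence items per respondent position.

    ``x[i]`` is the 1-based respondent position, ``y[i]`` the number of
    items first observed there.  ``y[0]`` equals the first respondent's
    list length, and ``sum(y)`` the total number of unique items.
    """

    x: np.ndarray
    y: np.ndarray
    domain_label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=int)
        y = np.asarray(self.y, dtype=int)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if (y < 0).any():
            raise ValueError("new-item counts must be non-negative")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.x)

    @property
    def total_unique(self) -> int:
        return int(self.y.sum())

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": self.x, "new_items": self.y, "cumulative_unique": self.cumulative}
        )


def new_item_series(data: FreeListDataset) -> NewItemSeries:
    """Per-respondent counts of never-before-seen items, in stored order."""
    seen: set[str] = set()
    counts = []
    for r in data.respondents:
        fresh = [i for i in r.items if i not in seen]
        counts.append(len(fresh))
        seen.update(fresh)
    return NewItemSeries(
        np.arange(1, len(counts) + 1), np.array(counts), data.domain_label
    )


def accumulation_curve(series: NewItemSeries) -> np.ndarray:
    """Cumulative unique-item counts by sample size n (non-decreasing)."""
    return series.cumulative


def permutation_averaged_curve(
    data: FreeListDataset, n_permutations: int = 100, seed: int | None = None
) -> np.ndarray:
    """DIAGNOSTIC ONLY: accumulation curve averaged over random respondent
    orders (a rarefaction-style smoothing).  Not used by the saturation
    pipeline, which respects interview order."""
    rng = np.random.default_rng(seed)
    n = data.n_respondents
    total = np.zeros(n)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        seen: set[str] = set()
        for pos, idx in enumerate(perm):
            seen.update(data.respondents[idx].items)
            total[pos] += len(seen)
    return total / n_permutations
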