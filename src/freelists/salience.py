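"""Item salience: prevalence, Smith and Sutrop indices, salient-item capture.

Salience — the cultural importance of an item in a domain — shows up in free
lists in two ways: salient items are mentioned by more respondents
(prevalence) and are mentioned earlier within lists (rank).  Two standard
indices combine the two signals:

* Smith's index averages the rank-discounted weight ``(L - R + 1) / L``
  over *all* N respondents (a respondent who does not mention the item
  contributes 0), where L is that respondent's list length and R the item's
  1-based rank on the list.
* Sutrop's index is ``F / (N * mR)`` where F is the number of lists
  containing the item and mR its mean rank over those lists.

Both lie in (0, 1], are bounded above by prevalence p = F/N, and equal p
exactly when the item is always mentioned first.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import FreeListDataset

__all__ = [
    "salience_table",
    "prevalence_table",
    "smith_index",
    "sutrop_index",
    "index_correlations",
    "salient_set",
    "capture_proportion",
    "write_salience_table",
]

#: column order of a salience table
COLUMNS = ["item", "frequency", "prevalence", "mean_rank", "smith", "sutrop"]


def salience_table(data: FreeListDataset) -> pd.DataFrame:
    """Per-item salience table with columns item, frequency, prevalence,
    mean_rank, smith, sutrop; sorted by descending prevalence, then item.

    The denominator N is the number of respondents in the dataset,
    including any with empty lists: prevalence is a proportion of *people*,
    not of non-empty lists.
    """
    n = data.n_respondents
    freq: dict[str, int] = {}
    rank_sum: dict[str, int] = {}
    smith_sum: dict[str, float] = {}
    for r in data.respondents:
        length = len(r)
        for rank, item in enumerate(r.items, start=1):
            freq[item] = freq.get(item, 0) + 1
            rank_sum[item] = rank_sum.get(item, 0) + rank
            smith_sum[item] = smith_sum.get(item, 0.0) + (length - rank + 1) / length
    if not freq:
        raise ValueError("dataset contains no responses")
    tab = pd.DataFrame(
        {
            "item": list(freq),
            "frequency": list(freq.values()),
            "mean_rank": [rank_sum[i] / freq[i] for i in freq],
            "smith": [smith_sum[i] / n for i in freq],
        }
    )
    tab["prevalence"] = tab["frequency"] / n
    tab["sutrop"] = tab["frequency"] / (n * tab["mean_rank"])
    tab = tab[COLUMNS]
    return tab.sort_values(
        ["prevalence", "item"], ascending=[False, True], ignore_index=True
    )


def prevalence_table(data: FreeListDataset) -> pd.DataFrame:
    """Frequency, prevalence and mean rank per item (no rank-weighted scores)."""
    return salience_table(data)[["item", "frequency", "prevalence", "mean_rank"]]


def smith_index(data: FreeListDataset) -> pd.Series:
    """Smith's salience score per item, indexed by item label."""
    tab = salience_table(data)
    return pd.Series(tab["smith"].to_numpy(), index=tab["item"], name="smith")


def sutrop_index(data: FreeListDataset) -> pd.Series:
    """Sutrop's salience score per item, indexed by item label."""
    tab = salience_table(data)
    return pd.Series(tab["sutrop"].to_numpy(), index=tab["item"], name="sutrop")


def index_correlations(tab: pd.DataFrame, min_frequency: int = 2) -> pd.DataFrame:
    """Pairwise Spearman and Pearson correlations among prevalence, Smith
    and Sutrop scores, over items mentioned by at least ``min_frequency``
    respondents.

    The frequency filter drops the long tail of items mentioned once, whose
    scores are dominated by a single rank observation.  Returns a frame with
    columns pair, spearman, pearson.
    """
    sub = tab[tab["frequency"] >= min_frequency]
    if len(sub) < 3:
        raise ValueError(
            f"only {len(sub)} items with frequency >= {min_frequency}; need >= 3"
        )
    measures = {"prevalence": sub["prevalence"], "smith": sub["smith"],
                "sutrop": sub["sutrop"]}
    rows = []
    names = list(measures)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x, y = measures[a].to_numpy(), measures[b].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                sp = pe = 1.0 if np.allclose(x, x[0]) and np.allclose(y, y[0]) else np.nan
            else:
                sp = stats.spearmanr(x, y).statistic
                pe = stats.pearsonr(x, y).statistic
            rows.append((f"{a}~{b}", sp, pe))
    return pd.DataFrame(rows, columns=["pair", "spearman", "pearson"])


def salient_set(
    data: FreeListDataset,
    threshold: float = 0.20,
    reference_n: int = 20,
) -> frozenset[str]:
    """Items mentioned by at least ``threshold`` of the first
    ``reference_n`` respondents with full listing.

    This is the reference set for "saturation in salience": instead of
    asking whether new items have stopped appearing, ask whether the items
    a fixed-size full-listing sample flags as salient have been captured.
    """
    if data.n_respondents < reference_n:
        raise ValueError(
            f"need at least {reference_n} respondents, have {data.n_respondents}"
        )
    ref = data.prefix(reference_n)
    tab = salience_table(ref)
    return frozenset(tab.loc[tab["prevalence"] >= threshold, "item"])


def capture_proportion(
    salient: Iterable[str],
    data: FreeListDataset,
    n: int,
    k: int | None = None,
) -> float:
    """Proportion of the salient set present on the first *n* lists,
    optionally truncated to *k* responses per person."""
    salient = frozenset(salient)
    if not salient:
        raise ValueError("empty salient set")
    if n > data.n_respondents:
        raise ValueError(f"n={n} exceeds N={data.n_respondents}")
    sub = data if k is None else data.truncate(k)
    observed = sub.prefix(n).item_universe
    return len(salient & observed) / len(salient)


def write_salience_table(tab: pd.DataFrame, path, sep: str = ",") -> None:
    tab.to_csv(path, sep=sep, index=False)
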