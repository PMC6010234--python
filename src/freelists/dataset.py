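"""Free-list interview datasets: reading, normalization, truncation.

A *free list* is an ordered list of verbatim responses one respondent gives
to an open-ended elicitation prompt ("Name all the fruits you can think
of").  A dataset holds one such list per respondent for a single topical
domain.  Respondent order is part of the data: every downstream analysis
(accumulation curves, saturation models, prefix subsamples) walks the
respondents in stored order, which is taken to be the order in which the
interviews occurred.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RespondentList",
    "FreeListDataset",
    "normalize_label",
    "build_synonym_map",
    "read_long",
    "read_wide",
    "read_workbook",
    "write_long",
    "truncate_lists",
]

_WS = re.compile(r"\s+")


def normalize_label(raw: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Normalize one response label.

    Case-folds, strips leading/trailing whitespace, collapses internal runs
    of whitespace to a single space, then applies the optional synonym map
    (keyed on normalized variants).  Merging of misspelled duplicates beyond
    an explicit synonym map is deliberately out of scope: automatic fuzzy
    matching would silently change item counts.

    Raises ``ValueError`` if the label is empty after trimming.
    """
    label = _WS.sub(" ", str(raw).strip()).casefold()
    if not label:
        raise ValueError("empty response label after normalization")
    if synonyms is not None:
        label = synonyms.get(label, label)
    return label


def build_synonym_map(pairs: Mapping[str, str]) -> dict[str, str]:
    """Normalize a raw variant->canonical mapping and make it idempotent.

    Both sides are label-normalized; chains (a->b, b->c) are resolved so the
    returned map is idempotent.  A cycle raises ``ValueError``.
    """
    norm = {normalize_label(k): normalize_label(v) for k, v in pairs.items()}
    resolved: dict[str, str] = {}
    for key in norm:
        seen = [key]
        cur = key
        while cur in norm and norm[cur] != cur:
            cur = norm[cur]
            if cur in seen:
                raise ValueError(f"synonym cycle involving {cur!r}")
            seen.append(cur)
        resolved[key] = cur
    return {k: v for k, v in resolved.items() if k != v}


@dataclass(frozen=True)
class RespondentList:
    """One respondent's ordered, normalized responses.

    Ranks are 1-based: the k-th item on the list has rank k.  Duplicates
    within a list (after normalization) keep the earliest rank.
    """

    respondent_id: str
    items: tuple[str, ...]

    @classmethod
    def from_raw(
        cls,
        respondent_id: str,
        raw_items: Iterable[str],
        synonyms: Mapping[str, str] | None = None,
    ) -> "RespondentList":
        seen: dict[str, None] = {}
        for raw in raw_items:
            label = normalize_label(raw, synonyms)
            seen.setdefault(label, None)
        return cls(str(respondent_id), tuple(seen))

    def __len__(self) -> int:
        return len(self.items)

    def rank_of(self, item: str) -> int | None:
        """1-based rank of *item*, or None if absent."""
        try:
            return self.items.index(item) + 1
        except ValueError:
            return None


@dataclass(frozen=True)
class FreeListDataset:
    """Ordered free lists for one domain.

    ``respondents`` is an ordered sequence; stored order is analysis order.
    """

    domain_label: str
    respondents: tuple[RespondentList, ...]
    _universe: frozenset[str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.respondents) < 1:
            raise ValueError("a dataset needs at least one respondent")
        ids = [r.respondent_id for r in self.respondents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate respondent ids")
        universe = frozenset(i for r in self.respondents for i in r.items)
        object.__setattr__(self, "_universe", universe)

    # -- basic accessors -------------------------------------------------

    @property
    def n_respondents(self) -> int:
        return len(self.respondents)

    @property
    def item_universe(self) -> frozenset[str]:
        """All distinct normalized items observed on at least one list."""
        return self._universe

    @property
    def list_lengths(self) -> list[int]:
        return [len(r) for r in self.respondents]

    @property
    def mean_list_length(self) -> float:
        return sum(self.list_lengths) / self.n_respondents

    @property
    def total_mentions(self) -> int:
        return sum(self.list_lengths)

    def __len__(self) -> int:
        return self.n_respondents

    def __iter__(self):
        return iter(self.respondents)

    # -- derived datasets ------------------------------------------------

    def prefix(self, n: int) -> "FreeListDataset":
        """Dataset of the first *n* respondents in stored order."""
        if not 1 <= n <= self.n_respondents:
            raise ValueError(f"prefix size {n} outside 1..{self.n_respondents}")
        return FreeListDataset(self.domain_label, self.respondents[:n])

    def truncate(self, k: int) -> "FreeListDataset":
        return truncate_lists(self, k)

    # -- frames ----------------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        """Long form: one row per (respondent, order, response)."""
        rows = [
            (r.respondent_id, rank, item)
            for r in self.respondents
            for rank, item in enumerate(r.items, start=1)
        ]
        return pd.DataFrame(rows, columns=["respondent", "order", "response"])


def truncate_lists(data: FreeListDataset, k: int) -> FreeListDataset:
    """Keep only the first ``min(L, k)`` responses of every list.

    Emulates limited probing: an interviewer who stops after *k* responses
    collects the prefix of what exhaustive listing would have produced.
    Respondent order is unchanged; the item universe is recomputed.
    """
    if k < 1:
        raise ValueError("truncation depth k must be >= 1")
    return FreeListDataset(
        data.domain_label,
        tuple(
            RespondentList(r.respondent_id, r.items[:k]) for r in data.respondents
        ),
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _from_long_frame(
    frame: pd.DataFrame,
    domain_label: str,
    synonyms: Mapping[str, str] | None,
) -> FreeListDataset:
    required = {"respondent", "order", "response"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if frame.empty:
        raise ValueError("no response rows")
    frame = frame.dropna(subset=["response"])
    if frame.duplicated(subset=["respondent", "order"]).any():
        raise ValueError("duplicate (respondent, order) pairs")
    order_vals = pd.to_numeric(frame["order"], errors="raise")
    if (order_vals < 1).any() or (order_vals != order_vals.astype(int)).any():
        raise ValueError("order values must be positive integers")
    frame = frame.assign(order=order_vals.astype(int))
    respondents = []
    # respondent order = first appearance in the file
    for rid in frame["respondent"].drop_duplicates():
        sub = frame[frame["respondent"] == rid].sort_values("order")
        respondents.append(
            RespondentList.from_raw(str(rid), sub["response"].astype(str), synonyms)
        )
    return FreeListDataset(domain_label, tuple(respondents))


def read_long(
    path: str | Path,
    synonyms: Mapping[str, str] | None = None,
    domain_label: str | None = None,
    sep: str = ",",
) -> FreeListDataset:
    """Read a long-format delimited file with header respondent,order,response."""
    path = Path(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    frame.columns = [c.strip().lower() for c in frame.columns]
    return _from_long_frame(frame, domain_label or path.stem, synonyms)


def read_wide(
    path: str | Path,
    synonyms: Mapping[str, str] | None = None,
    domain_label: str | None = None,
    sep: str = ",",
    header: bool = False,
) -> FreeListDataset:
    """Read a wide-format file: respondent id, then responses in rank order.

    Trailing blank cells are allowed and ignored.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, sep=sep, header=0 if header else None, dtype=str, skipinitialspace=True
    )
    if frame.empty:
        raise ValueError("no respondent rows")
    respondents = []
    for _, row in frame.iterrows():
        rid = str(row.iloc[0])
        raw = [v for v in row.iloc[1:] if isinstance(v, str) and v.strip()]
        respondents.append(RespondentList.from_raw(rid, raw, synonyms))
    return FreeListDataset(domain_label or path.stem, tuple(respondents))


def read_workbook(
    path: str | Path,
    sheet: str,
    synonyms: Mapping[str, str] | None = None,
    orientation: str = "columns",
    skip_rows: int = 0,
    id_in_header: bool = True,
    domain_label: str | None = None,
) -> FreeListDataset:
    """Read one example from a one-sheet-per-example XLSX workbook.

    The deposited-data layout stores each example on its own sheet with one
    respondent per column (responses running down the column, rank order top
    to bottom) or one respondent per row.  The exact layout varies by
    example, so it is configuration: ``orientation`` is ``"columns"`` or
    ``"rows"``; ``skip_rows`` drops leading title rows; with
    ``id_in_header`` the first cell of each respondent line is the id,
    otherwise ids are assigned positionally.
    """
    from openpyxl import load_workbook

    wb = load_workbook(Path(path), read_only=True, data_only=True)
    if sheet not in wb.sheetnames:
        raise ValueError(f"sheet {sheet!r} not in workbook")
    rows = [
        [c for c in row]
        for row in wb[sheet].iter_rows(min_row=skip_rows + 1, values_only=True)
    ]
    wb.close()
    if orientation == "columns":
        width = max((len(r) for r in rows), default=0)
        grid = [[r[i] if i < len(r) else None for r in rows] for i in range(width)]
    elif orientation == "rows":
        grid = rows
    else:
        raise ValueError("orientation must be 'columns' or 'rows'")
    respondents = []
    for pos, line in enumerate(grid, start=1):
        cells = [c for c in line if c is not None and str(c).strip()]
        if not cells:
            continue
        if id_in_header:
            rid, raw = str(cells[0]), cells[1:]
        else:
            rid, raw = str(pos), cells
        respondents.append(RespondentList.from_raw(rid, map(str, raw), synonyms))
    if not respondents:
        raise ValueError(f"sheet {sheet!r} contains no lists")
    return FreeListDataset(domain_label or sheet, tuple(respondents))


def write_long(data: FreeListDataset, path: str | Path, sep: str = ",") -> None:
    data.to_long_frame().to_csv(Path(path), sep=sep, index=False)
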