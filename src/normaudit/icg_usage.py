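"""Gene-usage statistics for internal control genes (ICG).

Two rates summarize how often a gene appears in a publication subset:

* the *normalized impact* ``Count_X / Count_TOT`` — instances of gene X
  divided by the number of unique ICG in the subset (a diversity-weighted
  rate, unbounded above);
* the *per-publication factor* ``Count_X / N_pub`` — the fraction of
  publications in the subset that used gene X (always in [0, 1]).

``Count_X`` counts publications whose (deduplicated) gene list contains X,
one instance per record. Selection ratios summarize validation outcomes
(how often a tested candidate was actually kept), and the contingency
builders feed the Fisher exact test for YAL/NAL usage contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._round import percent_1dp
from .dataset_model import AuditDataset
from .stats_engine import ContingencyTable2x2

__all__ = [
    "UsageTable",
    "Impact",
    "SelectionRatio",
    "usage_table",
    "normalized_impact",
    "per_publication_factor",
    "selection_ratio",
    "usage_contingency",
    "reporting_contingency",
]

_LIST_FIELDS = ("icg_used", "icg_tested")
_FLAG_FIELDS = ("reported_integrity", "reported_260_280")


@dataclass(frozen=True)
class UsageTable:
    """Per-symbol instance counts over one subset.

    ``counts`` maps canonical symbol -> number of records containing it,
    ordered by descending count then lexicographically. ``count_tot`` is
    the number of unique genes (the normalized-impact denominator);
    ``n_pub`` the number of publications (the per-publication denominator).
    """

    counts: dict[str, int]
    n_pub: int
    field: str

    @property
    def count_tot(self) -> int:
        return len(self.counts)

    @property
    def total_instances(self) -> int:
        return sum(self.counts.values())

    def count(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)


@dataclass(frozen=True)
class Impact:
    """Normalized impact of one gene; ``present`` is False for unseen symbols."""

    value: float
    present: bool


@dataclass(frozen=True)
class SelectionRatio:
    """Validation outcome of a candidate gene: kept / tested."""

    tested: int
    selected: int

    @property
    def ratio_percent(self) -> float:
        return percent_1dp(self.selected, self.tested)


def usage_table(ds: AuditDataset, field: str = "icg_used") -> UsageTable:
    """Count, per gene, the records whose ``field`` list contains it."""
    if field not in _LIST_FIELDS:
        raise ValueError(f"field must be one of {_LIST_FIELDS}, got {field!r}")
    raw: dict[str, int] = {}
    for rec in ds:
        for sym in getattr(rec, field):
            raw[sym] = raw.get(sym, 0) + 1
    ordered = dict(sorted(raw.items(), key=lambda kv: (-kv[1], kv[0])))
    return UsageTable(counts=ordered, n_pub=len(ds), field=field)


def normalized_impact(ut: UsageTable, symbol: str) -> Impact:
    """``Count_X / Count_TOT``: instance count over unique-gene count.

    The denominator is the number of *unique* genes in the subset, not the
    total instance count, so popular genes can exceed 1.
    """
    if ut.count_tot == 0:
        raise ValueError("usage table is empty (no genes in subset)")
    c = ut.count(symbol)
    return Impact(value=c / ut.count_tot, present=c > 0)


def per_publication_factor(ut: UsageTable, symbol: str) -> float:
    """``Count_X / N_pub``: fraction of publications in the subset using X."""
    if ut.n_pub == 0:
        raise ValueError("subset contains no publications")
    return ut.count(symbol) / ut.n_pub


def selection_ratio(tested: int, selected: int) -> SelectionRatio:
    """Share of publications where a tested candidate gene was kept."""
    if tested < 1:
        raise ValueError("tested must be >= 1")
    if not 0 <= selected <= tested:
        raise ValueError("selected must satisfy 0 <= selected <= tested")
    return SelectionRatio(tested=tested, selected=selected)


def _split_yal_nal(ds: AuditDataset) -> tuple[AuditDataset, AuditDataset]:
    yal = ds.subset(validated=True)
    nal = ds.subset(validated=False)
    if len(yal) == 0 or len(nal) == 0:
        raise ValueError("dataset must contain both validated and non-validated records")
    return yal, nal


def usage_contingency(
    ds: AuditDataset, symbol: str, field: str = "icg_used"
) -> ContingencyTable2x2:
    """YAL/NAL x uses/does-not-use table for one gene, for the exact test."""
    yal, nal = _split_yal_nal(ds)
    a = sum(1 for r in yal if symbol in getattr(r, field))
    c = sum(1 for r in nal if symbol in getattr(r, field))
    return ContingencyTable2x2(
        a=a,
        b=len(yal) - a,
        c=c,
        d=len(nal) - c,
        row_labels=("YAL", "NAL"),
        col_labels=(f"uses {symbol}", f"no {symbol}"),
    )


def reporting_contingency(ds: AuditDataset, flag: str) -> ContingencyTable2x2:
    """YAL/NAL x reported/not-reported table for a MIQE reporting flag."""
    if flag not in _FLAG_FIELDS:
        raise ValueError(f"flag must be one of {_FLAG_FIELDS}, got {flag!r}")
    yal, nal = _split_yal_nal(ds)
    a = sum(1 for r in yal if getattr(r, flag))
    c = sum(1 for r in nal if getattr(r, flag))
    return ContingencyTable2x2(
        a=a,
        b=len(yal) - a,
        c=c,
        d=len(nal) - c,
        row_labels=("YAL", "NAL"),
        col_labels=(flag, f"no {flag}"),
    )
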