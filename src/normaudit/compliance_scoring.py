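"""The 0-100 normalization-compliance SCORE.

SCORE = GENE + VALID + REPORT, a weighted semi-quantitative scale over three
MIQE-motivated criteria:

* GENE  — number of internal control genes in the normalization factor:
  0 points for at most one gene, 23 for two, 35 for three or more
  (three ICG being the widely cited "gold standard").
* VALID — 50 points when the genes were chosen by a validated stability
  algorithm (geNorm/NormFinder/BestKeeper class), 0 otherwise.
* REPORT — 15 points when quantifiable output of that algorithm (stability
  values, pairwise variation) is reported; requires VALID by construction.

The scale runs from 0 (single unvalidated housekeeping gene, nothing
reported) to 100 (three or more algorithm-validated genes with stability
output reported). Because REPORT presupposes VALID, the reachable scores
are exactly {0, 23, 35, 50, 65, 73, 85, 88, 100}.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._round import percent_1dp
from .dataset_model import AuditDataset, PublicationRecord

__all__ = [
    "GENE_WEIGHTS",
    "VALID_WEIGHT",
    "REPORT_WEIGHT",
    "REACHABLE_SCORES",
    "ScoreBreakdown",
    "ScoreSummary",
    "Proportion",
    "gene_component",
    "score_record",
    "score_dataset",
    "score_distribution",
    "proportion_scoring",
]

GENE_WEIGHTS = {0: 0, 1: 0, 2: 23}  # 3+ genes -> 35
_GENE_MAX = 35
VALID_WEIGHT = 50
REPORT_WEIGHT = 15

#: All scores reachable under the REPORT-requires-VALID constraint.
REACHABLE_SCORES = (0, 23, 35, 50, 65, 73, 85, 88, 100)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Component points and their sum for one record."""

    gene_component: int
    valid_component: int
    report_component: int

    @property
    def score(self) -> int:
        return self.gene_component + self.valid_component + self.report_component


@dataclass(frozen=True)
class Proportion:
    """An exact fraction with its one-decimal percentage rendering."""

    numerator: int
    denominator: int

    @property
    def percent(self) -> float:
        return percent_1dp(self.numerator, self.denominator)

    @property
    def value(self) -> float:
        return self.numerator / self.denominator


@dataclass(frozen=True)
class ScoreSummary:
    """Per-group score distribution (counts, mean, per-score proportions)."""

    group_by: str
    table: pd.DataFrame  # index: group key; columns: n, mean, p_<score>...


def gene_component(n_icg_used: int) -> int:
    """GENE points for a normalization factor of ``n_icg_used`` distinct genes."""
    if n_icg_used < 0:
        raise ValueError("n_icg_used must be non-negative")
    return GENE_WEIGHTS.get(n_icg_used, _GENE_MAX)


def score_record(rec: PublicationRecord) -> ScoreBreakdown:
    """Score one record from its (deduplicated) used-gene count and flags."""
    return ScoreBreakdown(
        gene_component=gene_component(rec.n_icg_used),
        valid_component=VALID_WEIGHT if rec.validated else 0,
        report_component=REPORT_WEIGHT if rec.reported_stability else 0,
    )


def score_dataset(ds: AuditDataset) -> pd.DataFrame:
    """Per-record score table (id, year, journal, components, score)."""
    rows = []
    for r in ds:
        b = score_record(r)
        rows.append(
            {
                "id": r.id,
                "year": r.year,
                "journal": r.journal,
                "validated": r.validated,
                "gene_component": b.gene_component,
                "valid_component": b.valid_component,
                "report_component": b.report_component,
                "score": b.score,
            }
        )
    return pd.DataFrame(rows)


def score_distribution(ds: AuditDataset, group_by: str = "year") -> ScoreSummary:
    """Score distribution grouped by a record attribute (``year``/``journal``).

    Returns per-group count, mean score and the proportion of each distinct
    score value, groups ordered by key.
    """
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    df = score_dataset(ds)
    if group_by not in df.columns:
        raise ValueError(f"unknown grouping key {group_by!r}")
    scores = sorted(df["score"].unique())
    out = {}
    for key, grp in df.groupby(group_by, sort=True):
        row = {"n": len(grp), "mean": grp["score"].mean()}
        for s in scores:
            row[f"p_{s}"] = (grp["score"] == s).sum() / len(grp)
        out[key] = row
    table = pd.DataFrame.from_dict(out, orient="index").rename_axis(group_by)
    return ScoreSummary(group_by=group_by, table=table)


def proportion_scoring(ds: AuditDataset, threshold: int, mode: str = "ge") -> Proportion:
    """Fraction of records scoring exactly (``eq``) or at least (``ge``) a threshold."""
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    if mode not in ("eq", "ge"):
        raise ValueError(f"mode must be 'eq' or 'ge', got {mode!r}")
    scores = [score_record(r).score for r in ds]
    if mode == "eq":
        k = sum(s == threshold for s in scores)
    else:
        k = sum(s >= threshold for s in scores)
    return Proportion(numerator=k, denominator=len(scores))
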