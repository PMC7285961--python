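"""Synthetic publication datasets and the canonical 225-record fixture.

Two sources of data stand in for a hand-annotated survey of RT-qPCR
publications:

* :func:`generate_dataset` draws stochastic datasets with the structure the
  analysis assumes — a validated/non-validated split, per-record gene
  counts from an (under)dispersed Conway-Maxwell-Poisson model with a
  group rate ratio, gene identities drawn from subgroup frequency profiles
  dominated by the classical housekeeping genes, and conditional reporting
  flags. Fully reproducible per seed.

* :func:`fixture_dataset` reconstructs, with no randomness at all, a
  225-record dataset that simultaneously satisfies every printed marginal
  the audit reproduces: the 67/158 validated split, 24 records at SCORE 100
  and 49 at or above 85, the per-publication usage counts of GAPDH / ACTB /
  RNA18S in each subgroup, 64 vs. 50 unique genes, the integrity- and
  purity-reporting counts, and the 118-of-156 single-gene share among
  non-technical unvalidated records (two records are flagged as technical
  reference-gene articles, which is what makes the 156 denominator exist).

Fixture construction order: records are laid out per subgroup with fixed
gene-count slots, reporting flags are assigned to leading record indices,
and gene identities are dealt deterministically — genes sorted by
descending target count, each dealt to the records with the most remaining
free slots (ties by record index). Unconstrained cells (years, journals,
algorithm names) cycle through their levels by record index. The builder
verifies every anchor through the scoring and usage modules and refuses to
return a dataset that violates any of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import compliance_scoring as cs
from . import icg_usage as iu
from .dataset_model import AuditDataset, PublicationRecord
from .stats_engine import cmp_pmf_table

__all__ = [
    "GeneratorConfig",
    "GenerationError",
    "FixtureError",
    "FixtureMarginals",
    "FIXTURE_MARGINALS",
    "default_yal_profile",
    "default_nal_profile",
    "cmp_sample",
    "generate_dataset",
    "fixture_dataset",
    "RECOVERY_CONFIG",
]

_ALGORITHMS = ("geNorm", "NormFinder", "BestKeeper")

#: Named reference genes used before synthetic placeholders when filling
#: the unique-gene anchors (deterministic, field-plausible symbols first).
_NAMED_FILLERS = ("EIF3K", "PPIA", "RPL19", "RPS9", "TBP", "UXT")


def _filler_genes(n: int) -> list[str]:
    """First the named reference genes, then GENE001, GENE002, ..."""
    fillers = list(_NAMED_FILLERS[:n])
    i = 1
    while len(fillers) < n:
        fillers.append(f"GENE{i:03d}")
        i += 1
    return fillers


class GenerationError(ValueError):
    """The generator configuration is infeasible."""


class FixtureError(RuntimeError):
    """The deterministic fixture violated one of its anchors."""


# --------------------------------------------------------------------------
# stochastic generator
# --------------------------------------------------------------------------


def default_yal_profile() -> dict[str, float]:
    """Per-publication inclusion weights for the validated subgroup.

    Weights are the subgroup per-publication usage rates: the big three at
    their observed shares (GAPDH 0.433, ACTB 0.313, RNA18S 0.015), the rest
    of the expected 2.46 genes/publication spread evenly over 61 minor
    genes so the subgroup stays gene-diverse.
    """
    profile = {"GAPDH": 0.433, "ACTB": 0.313, "RNA18S": 0.015}
    fillers = _filler_genes(61)
    rest = 2.463 - sum(profile.values())
    for g in fillers:
        profile[g] = rest / len(fillers)
    return profile


def default_nal_profile() -> dict[str, float]:
    """Weights for the non-validated subgroup (GAPDH 0.373, ACTB 0.278,
    RNA18S 0.114; remaining mass of ~1.25 genes/publication over 47 genes)."""
    profile = {"GAPDH": 0.373, "ACTB": 0.278, "RNA18S": 0.114}
    fillers = _filler_genes(47)
    rest = 1.253 - sum(profile.values())
    for g in fillers:
        profile[g] = rest / len(fillers)
    return profile


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the stochastic generator.

    Defaults emulate the surveyed corpus: 225 publications over 2013-2017
    in six anonymized journals, a 67/225 chance of algorithm validation,
    underdispersed gene counts (shared nu = 1.8) with the validated group's
    rate lambda raised by the published 1.44 fold, and reporting-flag
    probabilities equal to the subgroup reporting rates.
    """

    seed: int
    n_publications: int = 225
    years: tuple[int, ...] = (2013, 2014, 2015, 2016, 2017)
    year_weights: tuple[float, ...] | None = None
    journals: tuple[str, ...] = ("J1", "J2", "J3", "J4", "J5", "J6")
    journal_weights: tuple[float, ...] | None = None
    p_validated: float = 67 / 225
    p_technical: float = 2 / 225
    log_lambda_nal: float = math.log(2.0)
    log_rate_ratio: float = math.log(1.44)
    nu: float = 1.8
    yal_gene_profile: Mapping[str, float] = field(default_factory=default_yal_profile)
    nal_gene_profile: Mapping[str, float] = field(default_factory=default_nal_profile)
    p_stability_given_validated: float = 36 / 67
    p_integrity_yal: float = 0.701
    p_integrity_nal: float = 0.321
    p_260_280_yal: float = 0.015
    p_260_280_nal: float = 0.025

    def __post_init__(self):
        for name in (
            "p_validated",
            "p_technical",
            "p_stability_given_validated",
            "p_integrity_yal",
            "p_integrity_nal",
            "p_260_280_yal",
            "p_260_280_nal",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name}={v} outside [0, 1]")
        if self.nu <= 0:
            raise GenerationError("nu must be positive")
        if self.n_publications < 1:
            raise GenerationError("n_publications must be >= 1")
        for prof_name in ("yal_gene_profile", "nal_gene_profile"):
            prof = getattr(self, prof_name)
            if not prof or any(w < 0 for w in prof.values()):
                raise GenerationError(f"{prof_name} must have non-negative weights")
        for wname, levels in (("year_weights", self.years), ("journal_weights", self.journals)):
            w = getattr(self, wname)
            if w is not None and (len(w) != len(levels) or abs(sum(w) - 1.0) > 1e-9):
                raise GenerationError(f"{wname} must match its levels and sum to 1")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "GeneratorConfig":
        kwargs = dict(d)
        for key in ("years", "journals", "year_weights", "journal_weights"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])  # type: ignore[arg-type]
        return cls(**kwargs)  # type: ignore[arg-type]


def cmp_sample(
    lam: float,
    nu: float,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """i.i.d. CMP draws by inversion of the truncated CDF."""
    if lam <= 0 or nu <= 0:
        raise ValueError("lam and nu must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    cdf = np.cumsum(cmp_pmf_table(lam, nu))
    u = rng.random(n)
    return np.minimum(np.searchsorted(cdf, u, side="left"), cdf.size - 1)


def generate_dataset(cfg: GeneratorConfig) -> AuditDataset:
    """Draw an annotated-publication dataset under ``cfg``.

    Per record: year/journal from their weights; validation and technical
    status as Bernoulli draws; the used-gene count from the subgroup CMP
    (lambda_NAL vs lambda_NAL * rate-ratio, shared nu) by CDF inversion;
    that many distinct genes without replacement by profile weight; flags
    from their conditional probabilities. Identical seeds give identical
    datasets byte for byte.
    """
    rng = np.random.default_rng(cfg.seed)
    year_w = cfg.year_weights or tuple(1 / len(cfg.years) for _ in cfg.years)
    journal_w = cfg.journal_weights or tuple(1 / len(cfg.journals) for _ in cfg.journals)

    lam_nal = math.exp(cfg.log_lambda_nal)
    lam_yal = math.exp(cfg.log_lambda_nal + cfg.log_rate_ratio)
    cdf = {
        False: np.cumsum(cmp_pmf_table(lam_nal, cfg.nu)),
        True: np.cumsum(cmp_pmf_table(lam_yal, cfg.nu)),
    }
    profiles = {}
    for validated, prof in ((True, cfg.yal_gene_profile), (False, cfg.nal_gene_profile)):
        symbols = np.array(sorted(prof), dtype=object)
        weights = np.array([prof[s] for s in symbols], dtype=float)
        profiles[validated] = (symbols, weights / weights.sum())

    year_range = (min(cfg.years), max(cfg.years))
    records = []
    for i in range(cfg.n_publications):
        year = int(rng.choice(cfg.years, p=year_w))
        journal = str(rng.choice(np.array(cfg.journals, dtype=object), p=journal_w))
        technical = bool(rng.random() < cfg.p_technical)
        validated = bool(rng.random() < cfg.p_validated)
        u = rng.random()
        c = cdf[validated]
        k = int(min(np.searchsorted(c, u, side="left"), c.size - 1))
        symbols, weights = profiles[validated]
        if k > symbols.size:
            raise GenerationError(
                f"sampled gene count {k} exceeds the "
                f"{'YAL' if validated else 'NAL'} profile size {symbols.size}"
            )
        genes = tuple(
            str(g) for g in rng.choice(symbols, size=k, replace=False, p=weights)
        )
        stability = validated and bool(
            rng.random() < cfg.p_stability_given_validated
        )
        integrity = bool(
            rng.random() < (cfg.p_integrity_yal if validated else cfg.p_integrity_nal)
        )
        purity = bool(
            rng.random() < (cfg.p_260_280_yal if validated else cfg.p_260_280_nal)
        )
        records.append(
            PublicationRecord(
                id=f"S{i + 1:04d}",
                year=year,
                journal=journal,
                is_technical=technical,
                validated=validated,
                algorithm=_ALGORITHMS[i % len(_ALGORITHMS)] if validated else None,
                icg_tested=genes if validated else (),
                icg_used=genes,
                reported_stability=stability,
                reported_260_280=purity,
                reported_integrity=integrity,
                species=None,
                year_range=year_range,
            )
        )
    return AuditDataset(
        tuple(records), (f"generated (seed={cfg.seed}, n={cfg.n_publications})",)
    )


#: Simulation conditions for the count-model parameter-recovery check:
#: two groups of 2000 records, shared dispersion nu = 1.8, the group effect
#: set to the published 1.44 rate ratio on a baseline rate of 2.0, seed 42.
RECOVERY_CONFIG = {
    "n_per_group": 2000,
    "nu": 1.8,
    "log_lambda_baseline": math.log(2.0),
    "rate_ratio": 1.44,
    "seed": 42,
}


# --------------------------------------------------------------------------
# deterministic fixture
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureMarginals:
    """Anchor counts the fixture must reproduce exactly.

    Each count is either printed in the audited survey or is the unique
    integer reproducing a printed one-decimal percentage at its documented
    denominator. ``single_icg_nal`` uses denominator convention B: the
    non-validated subgroup minus its technical articles (156 = 158 - 2),
    the only denominator at which 75.6% resolves to an integer count (118).
    """

    total: int = 225
    n_yal: int = 67
    n_nal: int = 158
    n_technical_nal: int = 2
    score_100: int = 24  # 24/225 = 10.7%
    score_ge_85: int = 49  # 49/225 = 21.8%
    yal_users: Mapping[str, int] = field(
        default_factory=lambda: {"GAPDH": 29, "ACTB": 21, "RNA18S": 1}
    )  # 29/67=43.3%, 21/67=31.3%, 1/67=1.5%
    nal_users: Mapping[str, int] = field(
        default_factory=lambda: {"GAPDH": 59, "ACTB": 44, "RNA18S": 18}
    )  # 59/158=37.3%, 44/158=27.8%, 18/158=11.4%
    unique_yal: int = 64
    unique_nal: int = 50
    yal_integrity: int = 47  # 47/67 = 70.1%
    nal_integrity: int = 50  # 50/156 = 32.1% (convention B)
    yal_purity: int = 1  # 1/67 = 1.5%
    nal_purity: int = 4  # 4/158 = 2.5%
    single_icg_nal: int = 118  # 118/156 = 75.6% (convention B)
    yal_tested: Mapping[str, int] = field(
        default_factory=lambda: {"GAPDH": 38, "ACTB": 29, "RNA18S": 8}
    )
    #: tested/selected counts of the validation-outcome table
    table1: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "GAPDH": (38, 28),  # 73.7%
            "ACTB": (29, 22),  # 75.9%
            "RNA18S": (8, 2),  # 25.0%
        }
    )

    def verify(self, ds: AuditDataset) -> list[str]:
        """Recompute every anchor through the pipeline modules."""
        bad: list[str] = []

        def check(name: str, got: object, want: object) -> None:
            if got != want:
                bad.append(f"{name}: got {got}, want {want}")

        yal = ds.subset(validated=True)
        nal = ds.subset(validated=False)
        nal_b = ds.subset(validated=False, exclude_technical=True)
        check("total", len(ds), self.total)
        check("n_yal", len(yal), self.n_yal)
        check("n_nal", len(nal), self.n_nal)
        check("n_technical_nal", len(nal) - len(nal_b), self.n_technical_nal)
        check("score_100", cs.proportion_scoring(ds, 100, "eq").numerator, self.score_100)
        check("score_ge_85", cs.proportion_scoring(ds, 85, "ge").numerator, self.score_ge_85)
        ut_yal = iu.usage_table(yal, "icg_used")
        ut_nal = iu.usage_table(nal, "icg_used")
        for sym, want in self.yal_users.items():
            check(f"yal_users[{sym}]", ut_yal.count(sym), want)
        for sym, want in self.nal_users.items():
            check(f"nal_users[{sym}]", ut_nal.count(sym), want)
        check("unique_yal", ut_yal.count_tot, self.unique_yal)
        check("unique_nal", ut_nal.count_tot, self.unique_nal)
        check(
            "yal_integrity",
            sum(1 for r in yal if r.reported_integrity),
            self.yal_integrity,
        )
        check(
            "nal_integrity",
            sum(1 for r in nal_b if r.reported_integrity),
            self.nal_integrity,
        )
        check("yal_purity", sum(1 for r in yal if r.reported_260_280), self.yal_purity)
        check("nal_purity", sum(1 for r in nal if r.reported_260_280), self.nal_purity)
        check(
            "single_icg_nal",
            sum(1 for r in nal_b if r.n_icg_used == 1),
            self.single_icg_nal,
        )
        ut_tested = iu.usage_table(yal, "icg_tested")
        for sym, want in self.yal_tested.items():
            check(f"yal_tested[{sym}]", ut_tested.count(sym), want)
        return bad


FIXTURE_MARGINALS = FixtureMarginals()


def _deal_genes(
    gene_counts: Sequence[tuple[str, int]], capacities: Sequence[int]
) -> list[list[str]]:
    """Deal gene instances to records without within-record repeats.

    Genes are processed by descending count (then name); each gene's copies
    go to the records with the most remaining free slots, ties broken by
    record index. Capacities and counts must balance exactly.
    """
    total_cap = sum(capacities)
    total_cnt = sum(c for _, c in gene_counts)
    if total_cap != total_cnt:
        raise FixtureError(f"slot/instance mismatch: {total_cap} slots, {total_cnt} instances")
    cap = list(capacities)
    rows: list[list[str]] = [[] for _ in capacities]
    for gene, count in sorted(gene_counts, key=lambda t: (-t[1], t[0])):
        order = sorted(range(len(cap)), key=lambda i: (-cap[i], i))[:count]
        if any(cap[i] <= 0 for i in order):
            raise FixtureError(f"cannot place {count} copies of {gene}")
        for i in order:
            cap[i] -= 1
            rows[i].append(gene)
    if any(c != 0 for c in cap):
        raise FixtureError("unfilled gene slots remain")
    return rows


def _yal_records(m: FixtureMarginals) -> list[PublicationRecord]:
    # slot plan: 37 records x 3 genes, 24 x 2, 6 x 1  (165 gene instances)
    capacities = [3] * 37 + [2] * 24 + [1] * 6
    n_fillers = m.unique_yal - len(m.yal_users)  # 61
    fillers = _filler_genes(n_fillers)
    n_filler_instances = sum(capacities) - sum(m.yal_users.values())  # 114
    base, extra = divmod(n_filler_instances, n_fillers)  # 1 each + 53 seconds
    counts = [(g, c) for g, c in m.yal_users.items()]
    counts += [(g, base + (1 if i < extra else 0)) for i, g in enumerate(fillers)]
    gene_rows = _deal_genes(counts, capacities)

    # tested lists: tested = used, then top up the big-three tested counts
    tested_rows = [list(r) for r in gene_rows]
    for sym, want in m.yal_tested.items():
        have = sum(1 for r in tested_rows if sym in r)
        for i in range(len(tested_rows)):
            if have >= want:
                break
            if sym not in tested_rows[i]:
                tested_rows[i].append(sym)
                have += 1

    records = []
    for i in range(m.n_yal):
        # scores: i<24 -> 100; 24<=i<37 -> 85; 37<=i<49 -> 88; 49<=i<61 -> 73; else 50
        report = i < m.score_100 or 37 <= i < 49
        records.append(
            PublicationRecord(
                id=f"Y{i + 1:03d}",
                year=2013 + i % 5,
                journal=f"J{1 + i % 6}",
                is_technical=False,
                validated=True,
                algorithm=_ALGORITHMS[i % len(_ALGORITHMS)],
                icg_tested=tuple(tested_rows[i]),
                icg_used=tuple(gene_rows[i]),
                reported_stability=report,
                reported_260_280=i < m.yal_purity,
                reported_integrity=i < m.yal_integrity,
                species="Bos taurus",
            )
        )
    return records


def _nal_records(m: FixtureMarginals) -> list[PublicationRecord]:
    # slot plan: 38 non-technical x 2 genes, 2 technical x 2, 118 x 1
    n_doubles = 40
    capacities = [2] * n_doubles + [1] * m.single_icg_nal  # 198 instances
    technical_idx = {38, 39}
    n_fillers = m.unique_nal - len(m.nal_users)  # 47
    fillers = _filler_genes(n_fillers)
    n_filler_instances = sum(capacities) - sum(m.nal_users.values())  # 77
    base, extra = divmod(n_filler_instances, n_fillers)  # 1 each + 30 seconds
    counts = [(g, c) for g, c in m.nal_users.items()]
    counts += [(g, base + (1 if i < extra else 0)) for i, g in enumerate(fillers)]
    gene_rows = _deal_genes(counts, capacities)

    records = []
    n_nontech_seen = 0
    for i in range(m.n_nal):
        technical = i in technical_idx
        if not technical:
            integrity = n_nontech_seen < m.nal_integrity
            purity = n_nontech_seen < m.nal_purity
            n_nontech_seen += 1
        else:
            integrity = purity = False
        records.append(
            PublicationRecord(
                id=f"N{i + 1:03d}",
                year=2013 + i % 5,
                journal=f"J{1 + i % 6}",
                is_technical=technical,
                validated=False,
                algorithm=None,
                icg_tested=(),
                icg_used=tuple(gene_rows[i]),
                reported_stability=False,
                reported_260_280=purity,
                reported_integrity=integrity,
                species="Bos taurus",
            )
        )
    return records


def fixture_dataset(marginals: FixtureMarginals = FIXTURE_MARGINALS) -> AuditDataset:
    """Build the canonical deterministic fixture (no RNG, no floats).

    Raises :class:`FixtureError` listing every violated anchor if the
    construction and the pipeline modules ever disagree.
    """
    records = _yal_records(marginals) + _nal_records(marginals)
    ds = AuditDataset(tuple(records), ("fixture:v1 (deterministic reconstruction)",))
    violations = marginals.verify(ds)
    if violations:
        raise FixtureError("fixture anchors violated: " + "; ".join(violations))
    return ds
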