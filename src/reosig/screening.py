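"""The discovery funnel's screening stages.

Stage order (counts are reported in this order):

1. ``age_related_genes`` — genes differentially expressed between the
   early-onset (< 50 y) and late-onset (> 60 y) strata at ``alpha`` in BOTH
   training cohorts (Wilcoxon rank-sum, two-sided, no multiplicity
   correction).
2. ``encode_pairs`` — every unordered pair of those genes becomes a binary
   per-sample REO indicator: 1 iff the lexicographically first gene's
   expression strictly exceeds the second's.
3. ``screen_cohort`` — univariate Cox screen of each indicator against
   relapse-free survival in the surgery-only population; survivors are
   orientation-canonicalized so the high-risk ordering always has HR > 1.
4. ``consistent_pairs`` — pairs significant with the SAME orientation in
   both cohorts.
5. ``deredundant`` — greedy gene-disjoint filter keeping, among pairs that
   share a gene, the one with the most significant ranking p-value.

Every stage depends on expression only through within-sample orderings, so
all outputs are invariant to strictly increasing per-sample transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .datatypes import (
    AgeGroup,
    Cohort,
    OrientedGenePair,
    PairStats,
    PopulationFilter,
    SURGERY_ONLY_ALL_AGES,
    ValidationError,
)
from .survival import cox_binary_batch, cox_fit

__all__ = [
    "reo_indicator",
    "PairEncoding",
    "encode_pairs",
    "age_related_genes",
    "cox_screen_pair",
    "screen_cohort",
    "consistent_pairs",
    "deredundant",
    "ScreenResult",
    "run_screen",
]


def reo_indicator(expr_i: float, expr_j: float) -> int:
    """1 iff ``expr_i`` strictly exceeds ``expr_j``, else 0 (ties vote 0)."""
    if not (math.isfinite(expr_i) and math.isfinite(expr_j)):
        raise ValidationError("REO indicator requires finite expression values")
    return int(expr_i > expr_j)


@dataclass(frozen=True)
class PairEncoding:
    """Binary pair-by-sample REO matrix for the canonical unordered pairs."""

    pairs: tuple[tuple[str, str], ...]  # (first, second), first < second lexicographically
    sample_ids: tuple[str, ...]
    indicators: np.ndarray  # uint8, shape (n_pairs, n_samples)


def encode_pairs(cohort: Cohort, genes: Sequence[str]) -> PairEncoding:
    """Encode all C(m, 2) unordered gene pairs as binary REO indicators.

    Pairs are indexed (g_a, g_b) with g_a < g_b under lexicographic order;
    the entry is 1 iff expression(g_a) > expression(g_b) within the sample.
    """
    genes = sorted(dict.fromkeys(genes))
    if len(genes) < 2:
        raise ValidationError("need at least 2 genes to form pairs")
    idx = cohort.expression.gene_indices(genes)  # raises naming missing genes
    expr = cohort.expression.values[idx]
    iu, ju = np.triu_indices(len(genes), k=1)
    indicators = (expr[iu] > expr[ju]).astype(np.uint8)
    pairs = tuple((genes[i], genes[j]) for i, j in zip(iu, ju))
    return PairEncoding(pairs=pairs, sample_ids=tuple(cohort.sample_ids), indicators=indicators)


def _age_strata(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    groups = cohort.age_groups
    eo = np.array([g == AgeGroup.EOCRC for g in groups])
    lo = np.array([g == AgeGroup.LOCRC for g in groups])
    if not eo.any() or not lo.any():
        raise ValidationError(f"cohort {cohort.name!r} lacks an age stratum (needs EOCRC and LOCRC)")
    return eo, lo


def _gene_pvalues(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-row two-sided Wilcoxon rank-sum p-values for X rows vs Y rows.

    Exact when both groups <= 25 and a row has no pooled ties, otherwise the
    tie/continuity-corrected normal approximation (same rule as
    :func:`reosig.survival.wilcoxon_rank_sum`).
    """
    n1, n2 = X.shape[1], Y.shape[1]
    if min(n1, n2) == 0:
        raise ValidationError("empty stratum in DEG screen")
    pooled = np.sort(np.concatenate([X, Y], axis=1), axis=1)
    has_ties = (np.diff(pooled, axis=1) == 0).any(axis=1)
    if n1 <= 25 and n2 <= 25:
        p = np.empty(X.shape[0])
        for r in range(X.shape[0]):
            method = "asymptotic" if has_ties[r] else "exact"
            p[r] = sps.mannwhitneyu(X[r], Y[r], alternative="two-sided", method=method).pvalue
        return np.minimum(p, 1.0)
    res = sps.mannwhitneyu(X, Y, alternative="two-sided", method="asymptotic", axis=1)
    return np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)


def age_related_genes(cohort_a: Cohort, cohort_b: Cohort, alpha: float = 0.05) -> list[str]:
    """Genes differentially expressed between age strata in both cohorts.

    Each cohort is tested independently (EOCRC vs LOCRC columns, Wilcoxon
    rank-sum, two-sided); a gene qualifies when p < ``alpha`` in both.  The
    comparison is restricted to the shared gene universe; output preserves
    ``cohort_a``'s gene order.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValidationError(f"alpha must be in [0,1], got {alpha}")
    shared = [g for g in cohort_a.expression.gene_ids if g in cohort_b.expression._gene_index]
    if not shared:
        raise ValidationError("cohorts share no genes")
    passing: list[np.ndarray] = []
    for cohort in (cohort_a, cohort_b):
        eo, lo = _age_strata(cohort)
        expr = cohort.expression.values[cohort.expression.gene_indices(shared)]
        p = _gene_pvalues(expr[:, eo], expr[:, lo])
        passing.append(p < alpha)
    both = passing[0] & passing[1]
    out = [g for g, keep in zip(shared, both) if keep]
    return out


def cox_screen_pair(indicator, times, events, ties: str = "efron"):
    """Univariate Cox fit of one binary REO indicator against survival.

    Raises when the indicator is constant (non-identifiable); a monotone
    likelihood is returned flagged (``converged`` False, ``divergent``
    non-empty) so callers can discard the pair.
    """
    indicator = np.asarray(indicator, dtype=float)
    if np.unique(indicator).size < 2:
        raise ValidationError("indicator is constant: non-identifiable")
    return cox_fit(indicator, times, events, ties=ties, names=("reo_indicator",))


def screen_cohort(
    cohort: Cohort,
    genes: Sequence[str],
    alpha: float = 0.05,
    population: PopulationFilter = SURGERY_ONLY_ALL_AGES,
    ties: str = "efron",
) -> list[OrientedGenePair]:
    """Cox-screen all REO pairs of ``genes`` in one cohort.

    Pairs whose indicator is significantly associated with the endpoint
    (Wald p < ``alpha``) are returned in canonical orientation: if the
    fitted HR for "first gene > second gene" is below 1, the genes are
    swapped so the reported HR is its reciprocal (> 1).  Constant-indicator
    and monotone-likelihood pairs are discarded.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValidationError(f"alpha must be in [0,1], got {alpha}")
    sub = population.apply(cohort)
    times, events = sub.times, sub.events
    if sub.n_samples < 10 or events.sum() < 1:
        raise ValidationError(
            f"cohort {cohort.name!r}: screening population too small "
            f"({sub.n_samples} samples, {int(events.sum())} events)"
        )
    enc = encode_pairs(sub, genes)
    res = cox_binary_batch(enc.indicators, times, events, ties=ties)
    keep = res["ok"] & (res["p"] < alpha)
    out: list[OrientedGenePair] = []
    n = sub.n_samples
    for r in np.flatnonzero(keep):
        g1, g2 = enc.pairs[r]
        beta, p = float(res["coef"][r]), float(res["p"][r])
        if beta > 0:
            high, low, log_hr = g1, g2, beta
        else:
            high, low, log_hr = g2, g1, -beta
        stats = PairStats(log_hr=log_hr, hr=float(np.exp(log_hr)), p=p, n=n)
        out.append(OrientedGenePair(high, low, {cohort.name: stats}))
    return out


def consistent_pairs(
    screen_a: Sequence[OrientedGenePair], screen_b: Sequence[OrientedGenePair]
) -> list[OrientedGenePair]:
    """Pairs significant with the same canonical orientation in both screens.

    A pair oriented (A > B votes risk) in one cohort but (B > A) in the other
    is dropped; survivors carry both cohorts' statistics.
    """
    by_id = {p.pair_id: p for p in screen_b}
    out: list[OrientedGenePair] = []
    for pa in screen_a:
        pb = by_id.get(pa.pair_id)
        if pb is None:
            continue
        merged = dict(pa.stats_per_cohort)
        merged.update(pb.stats_per_cohort)
        out.append(OrientedGenePair(pa.gene_high, pa.gene_low, merged))
    return out


def deredundant(pairs: Sequence[OrientedGenePair]) -> list[OrientedGenePair]:
    """Greedy gene-disjoint filter in ascending ranking-p order.

    The ranking p-value of a pair is the worse (larger) of its per-cohort
    p-values; ties break lexicographically on (gene_high, gene_low).  A pair
    is kept iff neither of its genes appears in an already-kept pair, so the
    output is gene-disjoint.
    """
    ranked = sorted(pairs, key=lambda p: (p.worst_p, p.pair_id))
    used: set[str] = set()
    out: list[OrientedGenePair] = []
    for p in ranked:
        if p.gene_high in used or p.gene_low in used:
            continue
        used.update((p.gene_high, p.gene_low))
        out.append(p)
    return out


@dataclass
class ScreenResult:
    """Everything the screening funnel produced, with per-stage counts."""

    age_related: list[str]
    screened: dict[str, list[OrientedGenePair]]  # cohort name -> significant pairs
    consistent: list[OrientedGenePair]
    candidates: list[OrientedGenePair]  # after de-redundancy
    stage_counts: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.stage_counts:
            self.stage_counts = [
                ("age_related_genes", len(self.age_related)),
                *[(f"cox_screen[{name}]", len(v)) for name, v in self.screened.items()],
                ("consistent_pairs", len(self.consistent)),
                ("deredundant_pairs", len(self.candidates)),
            ]
        if len(self.candidates) > len(self.consistent):
            raise ValidationError("funnel counts must be non-increasing after consistency")


def run_screen(
    cohort_a: Cohort,
    cohort_b: Cohort,
    alpha_deg: float = 0.05,
    alpha_cox: float = 0.05,
    population: PopulationFilter = SURGERY_ONLY_ALL_AGES,
    ties: str = "efron",
) -> ScreenResult:
    """Run DEG screen → pair encoding → dual Cox screens → consistency →
    de-redundancy and collect stage counts."""
    genes = age_related_genes(cohort_a, cohort_b, alpha=alpha_deg)
    if len(genes) < 2:
        return ScreenResult(age_related=genes,
                            screened={cohort_a.name: [], cohort_b.name: []},
                            consistent=[], candidates=[])
    sa = screen_cohort(cohort_a, genes, alpha=alpha_cox, population=population, ties=ties)
    sb = screen_cohort(cohort_b, genes, alpha=alpha_cox, population=population, ties=ties)
    cons = consistent_pairs(sa, sb)
    cand = deredundant(cons)
    return ScreenResult(
        age_related=genes,
        screened={cohort_a.name: sa, cohort_b.name: sb},
        consistent=cons,
        candidates=cand,
    )
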