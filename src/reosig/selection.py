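"""Signature selection and application.

The classifier is a strict-majority vote over oriented gene pairs: each pair
votes high-risk for a sample when expression(gene_high) strictly exceeds
expression(gene_low), and the sample is called HIGH iff more than half of
the k pairs vote high-risk (a split vote on even k is LOW).

Selection is forward-stepwise maximization of Harrell's concordance index of
the vote-derived risk calls on the training population (by default the
surgery-only early-onset stratum): the seed is the single pair with the
largest C-index, and candidates are added one at a time as long as some
addition strictly increases the C-index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import (
    Cohort,
    OrientedGenePair,
    PopulationFilter,
    RiskCall,
    RiskLabel,
    SURGERY_ONLY_EOCRC,
    Signature,
    ValidationError,
)

__all__ = [
    "majority_vote",
    "signature_votes",
    "classify",
    "cindex",
    "StepwiseTrace",
    "forward_stepwise",
]

#: floating-point guard for "strictly increases the C-index"
CINDEX_IMPROVEMENT_TOL = 1e-12


def majority_vote(votes: int, k: int) -> RiskLabel:
    """Strict-majority rule: HIGH iff votes > k/2.

    For k = 6 this means HIGH requires at least 4 of 6 pairs in favor of
    high risk; exactly 3 of 6 is LOW.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if not (0 <= votes <= k):
        raise ValidationError(f"votes {votes} outside [0, {k}]")
    return RiskLabel.HIGH if 2 * votes > k else RiskLabel.LOW


def _pair_indicator_rows(cohort: Cohort, pairs: Sequence[OrientedGenePair]) -> np.ndarray:
    """(n_pairs, n_samples) uint8 matrix of oriented REO votes."""
    genes = [g for p in pairs for g in (p.gene_high, p.gene_low)]
    idx = cohort.expression.gene_indices(genes)  # raises naming missing genes
    vals = cohort.expression.values
    hi = vals[idx[0::2]]
    lo = vals[idx[1::2]]
    return (hi > lo).astype(np.uint8)


def signature_votes(cohort: Cohort, sig: Signature) -> np.ndarray:
    """Per-sample count of signature pairs voting high-risk."""
    return _pair_indicator_rows(cohort, sig.pairs).sum(axis=0).astype(int)


def classify(cohort: Cohort, sig: Signature) -> list[RiskCall]:
    """Apply a frozen signature: per-sample votes and strict-majority label.

    Depends on expression only through within-sample orderings, so the calls
    are invariant to any strictly increasing per-sample transform.
    """
    votes = signature_votes(cohort, sig)
    return [
        RiskCall(sample_id=s, votes=int(v), k=sig.k, label=majority_vote(int(v), sig.k))
        for s, v in zip(cohort.sample_ids, votes)
    ]


def cindex(risk_score, times, events) -> float:
    """Harrell's concordance index.

    Comparable pairs are (i, j) with t_i < t_j and event_i = 1; equal-time
    pairs are skipped.  A comparable pair scores 1 when the earlier-failing
    sample has the higher risk score, 0.5 on a score tie, 0 otherwise.
    """
    s = np.asarray(risk_score, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (s.shape == t.shape == e.shape):
        raise ValidationError("risk_score, times, events must have equal length")
    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValidationError("no comparable pairs (all censored or all times tied)")
    diff = s[:, None] - s[None, :]
    credit = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return float((credit * comparable).sum() / n_comp)


@dataclass(frozen=True)
class StepwiseTrace:
    """Per-round record of the greedy selection."""

    added: tuple[tuple[str, str], ...]  # pair ids in addition order
    cindex_trace: tuple[float, ...]  # training C-index after each addition


def forward_stepwise(
    candidates: Sequence[OrientedGenePair],
    training: Cohort,
    population: PopulationFilter = SURGERY_ONLY_EOCRC,
    score_on: str = "votes",
    tol: float = CINDEX_IMPROVEMENT_TOL,
) -> tuple[Signature, StepwiseTrace]:
    """Greedy forward selection of the pair subset maximizing the C-index.

    Parameters
    ----------
    candidates
        Oriented pairs (normally the de-redundant funnel output, which is
        gene-disjoint).  A candidate sharing a gene with an already-selected
        pair is never added, keeping the signature gene-disjoint.
    training
        Cohort whose ``population`` subset supplies times and events.
    score_on
        ``"votes"`` (default) ranks samples by the raw vote count — the
        signature's natural ordinal risk score; ``"label"`` ranks by the
        binary strict-majority call instead.  Label scoring is two-level, so
        during greedy growth the candidate ranking degenerates (appending a
        second pair turns the decision rule into an AND) and selection can
        stall early; vote scoring avoids that parity artifact.
    tol
        An addition must improve the C-index by more than ``tol`` to count
        as an increase.

    Ties between equally scoring additions break on (larger improvement is
    kept; then smaller ranking p-value, i.e. the pair's worst per-cohort p;
    then lexicographic pair id), making the result independent of candidate
    input order.
    """
    if not candidates:
        raise ValidationError("no candidate pairs to select from")
    if score_on not in ("label", "votes"):
        raise ValidationError(f"score_on must be 'label' or 'votes', got {score_on!r}")
    sub = population.apply(training)
    times, events = sub.times, sub.events
    if events.sum() < 2:
        raise ValidationError(
            f"selection population has {int(events.sum())} events; need >= 2"
        )
    rows = _pair_indicator_rows(sub, candidates)

    def score_of(vote_sum: np.ndarray, k: int) -> np.ndarray:
        if score_on == "label":
            return (2 * vote_sum > k).astype(float)
        return vote_sum.astype(float)

    def sort_key(i: int) -> tuple:
        return (candidates[i].worst_p, candidates[i].pair_id)

    remaining = list(range(len(candidates)))
    # seed: best single pair
    scored = [(cindex(score_of(rows[i], 1), times, events), i) for i in remaining]
    best_c = max(c for c, _ in scored)
    seed = min((i for c, i in scored if c == best_c), key=sort_key)
    selected = [seed]
    vote_sum = rows[seed].astype(int)
    used_genes = set(candidates[seed].genes)
    trace_c = [best_c]
    remaining.remove(seed)

    while remaining:
        k_new = len(selected) + 1
        best_gain, best_i, best_ci = tol, None, None
        for i in sorted(remaining, key=sort_key):
            if candidates[i].genes & used_genes:
                continue
            ci = cindex(score_of(vote_sum + rows[i], k_new), times, events)
            if ci - trace_c[-1] > best_gain:
                best_gain, best_i, best_ci = ci - trace_c[-1], i, ci
        if best_i is None:
            break
        selected.append(best_i)
        vote_sum = vote_sum + rows[best_i]
        used_genes |= set(candidates[best_i].genes)
        trace_c.append(best_ci)
        remaining.remove(best_i)

    pairs = tuple(candidates[i] for i in selected)
    sig = Signature(
        pairs=pairs,
        training_cindex=trace_c[-1],
        training_population=population.describe(),
    )
    trace = StepwiseTrace(
        added=tuple(p.pair_id for p in pairs), cindex_trace=tuple(trace_c)
    )
    return sig, trace
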