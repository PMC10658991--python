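"""Core domain types for REO (relative expression ordering) signature analysis.

The unit of analysis everywhere is a :class:`Cohort`: a validated,
sample-aligned pairing of a gene-by-sample expression matrix with per-sample
clinical records (age, relapse-free-survival endpoint, treatment arm).

A prognostic signature is a set of oriented gene pairs
(:class:`OrientedGenePair`): the pair votes "high risk" for a sample when the
expression of ``gene_high`` strictly exceeds that of ``gene_low`` within that
sample.  Because the vote depends only on the within-sample ordering of two
values, it is invariant to any strictly increasing per-sample transform of
the expression column — the property that makes these signatures robust to
batch effects and normalization choices.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeGroup",
    "Treatment",
    "RiskLabel",
    "age_group_for",
    "ExpressionMatrix",
    "ClinicalRecord",
    "Cohort",
    "PopulationFilter",
    "SURGERY_ONLY_ALL_AGES",
    "SURGERY_ONLY_EOCRC",
    "PairStats",
    "OrientedGenePair",
    "Signature",
    "RiskCall",
    "CoxFit",
    "SurvTestResult",
    "KMCurve",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class AgeGroup(str, enum.Enum):
    EOCRC = "EOCRC"  # early-onset, age < 50 at diagnosis
    LOCRC = "LOCRC"  # late-onset, age > 60 at diagnosis
    EXCLUDED = "EXCLUDED"  # ages in [50, 60] belong to neither stratum


class Treatment(str, enum.Enum):
    SURGERY_ONLY = "SURGERY_ONLY"
    ACT = "ACT"  # adjuvant chemotherapy
    OTHER_UNKNOWN = "OTHER_UNKNOWN"


class RiskLabel(str, enum.Enum):
    HIGH = "HIGH"
    LOW = "LOW"


def age_group_for(age_years: float) -> AgeGroup:
    """Map age at diagnosis to an analysis stratum.

    Strict cut-offs: < 50 years is early-onset (EOCRC), > 60 years is
    late-onset (LOCRC); ages in the closed interval [50, 60] fall in
    neither stratum and are excluded from all age-contrast analyses.
    """
    if not math.isfinite(age_years) or age_years < 0:
        raise ValidationError(f"age_years must be a non-negative finite number, got {age_years!r}")
    if age_years < 50:
        return AgeGroup.EOCRC
    if age_years > 60:
        return AgeGroup.LOCRC
    return AgeGroup.EXCLUDED


class ExpressionMatrix:
    """Gene-by-sample matrix of normalized expression values.

    Values are unitless and platform-agnostic; the pipeline never rescales
    them.  Missing or non-finite entries are rejected outright: the REO
    comparison of an absent value is undefined and no imputation rule is
    applied.
    """

    __slots__ = ("gene_ids", "sample_ids", "values", "_gene_index", "_sample_index")

    def __init__(self, gene_ids: Sequence[str], sample_ids: Sequence[str], values) -> None:
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=float)
        if not gene_ids:
            raise ValidationError("expression matrix has no genes")
        if not sample_ids:
            raise ValidationError("expression matrix has no samples")
        if len(set(gene_ids)) != len(gene_ids):
            dup = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dup[:5]}")
        if len(set(sample_ids)) != len(sample_ids):
            dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dup[:5]}")
        if values.ndim != 2 or values.shape != (len(gene_ids), len(sample_ids)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"({len(gene_ids)} genes, {len(sample_ids)} samples)"
            )
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at gene {gene_ids[bad[0]]!r}, "
                f"sample {sample_ids[bad[1]]!r}"
            )
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.values = values
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise ValidationError(f"gene {gene_id!r} absent from expression matrix") from None

    def gene_indices(self, gene_ids: Sequence[str]) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self._gene_index]
        if missing:
            raise ValidationError(f"genes absent from expression matrix: {missing[:5]}")
        return np.array([self._gene_index[g] for g in gene_ids], dtype=int)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._sample_index[s] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, frame.index)), list(map(str, frame.columns)), frame.to_numpy(dtype=float))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"ExpressionMatrix({len(self.gene_ids)} genes x {len(self.sample_ids)} samples)"


@dataclass(frozen=True)
class ClinicalRecord:
    """One sample's clinical annotation.

    ``age_group`` is always derived from ``age_years`` (strict <50 / >60
    cut-offs), never read from a file.  ``endpoint_time`` is in months by
    convention and must be positive; ``endpoint_event`` is 1 when the
    endpoint (recurrence) was observed, 0 when censored.
    """

    sample_id: str
    age_years: float
    endpoint_time: float
    endpoint_event: int
    treatment: Treatment = Treatment.OTHER_UNKNOWN
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("empty sample_id")
        age_group_for(self.age_years)  # validates the age
        if not (math.isfinite(self.endpoint_time) and self.endpoint_time > 0):
            raise ValidationError(
                f"sample {self.sample_id}: endpoint_time must be > 0, got {self.endpoint_time!r}"
            )
        if self.endpoint_event not in (0, 1):
            raise ValidationError(
                f"sample {self.sample_id}: endpoint_event must be 0 or 1, got {self.endpoint_event!r}"
            )
        if not isinstance(self.treatment, Treatment):
            object.__setattr__(self, "treatment", Treatment(self.treatment))

    @property
    def age_group(self) -> AgeGroup:
        return age_group_for(self.age_years)


class Cohort:
    """A sample-aligned expression matrix plus clinical records.

    The constructor restricts the expression matrix to the clinical samples
    (in expression-column order) so that column ``j`` of ``expression.values``
    always describes ``clinical[j]``.
    """

    def __init__(self, expression: ExpressionMatrix, clinical: Sequence[ClinicalRecord], name: str) -> None:
        ids = [r.sample_id for r in clinical]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"cohort {name!r}: duplicate clinical records")
        missing = [s for s in ids if s not in expression._sample_index]
        if missing:
            raise ValidationError(
                f"cohort {name!r}: clinical samples absent from expression: {missing[:5]}"
            )
        if len(ids) < 2:
            raise ValidationError(f"cohort {name!r}: needs at least 2 samples, got {len(ids)}")
        # keep expression column order as the canonical sample order
        order = sorted(ids, key=lambda s: expression._sample_index[s])
        by_id = {r.sample_id: r for r in clinical}
        self.name = str(name)
        self.clinical: list[ClinicalRecord] = [by_id[s] for s in order]
        self.expression = (
            expression if order == expression.sample_ids else expression.subset_samples(order)
        )

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.clinical)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.endpoint_time for r in self.clinical], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.endpoint_event for r in self.clinical], dtype=int)

    @property
    def ages(self) -> np.ndarray:
        return np.array([r.age_years for r in self.clinical], dtype=float)

    @property
    def age_groups(self) -> list[AgeGroup]:
        return [r.age_group for r in self.clinical]

    @property
    def treatments(self) -> list[Treatment]:
        return [r.treatment for r in self.clinical]

    def subset(self, mask: np.ndarray, name: str | None = None) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        kept = [r for r, m in zip(self.clinical, mask) if m]
        return Cohort(self.expression.subset_samples([r.sample_id for r in kept]),
                      kept, name or self.name)

    def __repr__(self) -> str:
        return f"Cohort({self.name!r}, {self.expression.shape[0]} genes x {self.n_samples} samples)"


@dataclass(frozen=True)
class PopulationFilter:
    """Sample-selection rule applied before a screening or evaluation stage.

    ``None`` for a field means "no restriction on that attribute".
    """

    treatments: frozenset[Treatment] | None = None
    age_groups: frozenset[AgeGroup] | None = None

    def mask(self, cohort: Cohort) -> np.ndarray:
        keep = np.ones(cohort.n_samples, dtype=bool)
        if self.treatments is not None:
            keep &= np.array([r.treatment in self.treatments for r in cohort.clinical])
        if self.age_groups is not None:
            keep &= np.array([r.age_group in self.age_groups for r in cohort.clinical])
        return keep

    def apply(self, cohort: Cohort) -> Cohort:
        return cohort.subset(self.mask(cohort))

    def describe(self) -> str:
        t = "any" if self.treatments is None else "+".join(sorted(x.value for x in self.treatments))
        a = "any" if self.age_groups is None else "+".join(sorted(x.value for x in self.age_groups))
        return f"treatment={t};age_group={a}"


#: Screening population: surgery-only patients of both age strata.
SURGERY_ONLY_ALL_AGES = PopulationFilter(
    treatments=frozenset({Treatment.SURGERY_ONLY}),
    age_groups=frozenset({AgeGroup.EOCRC, AgeGroup.LOCRC}),
)

#: Signature-selection population: surgery-only early-onset patients.
SURGERY_ONLY_EOCRC = PopulationFilter(
    treatments=frozenset({Treatment.SURGERY_ONLY}),
    age_groups=frozenset({AgeGroup.EOCRC}),
)


@dataclass(frozen=True)
class PairStats:
    """Univariate Cox statistics for a pair's REO indicator in one cohort."""

    log_hr: float
    hr: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not (self.hr > 0):
            raise ValidationError(f"hr must be positive, got {self.hr}")
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p must be in [0,1], got {self.p}")


@dataclass(frozen=True)
class OrientedGenePair:
    """A gene pair in canonical risk orientation.

    The indicator ``expression(gene_high) > expression(gene_low)`` votes
    high-risk; orientation is canonicalized so that the fitted hazard ratio
    of that indicator exceeds 1 in every recorded cohort.
    """

    gene_high: str
    gene_low: str
    stats_per_cohort: Mapping[str, PairStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gene_high == self.gene_low:
            raise ValidationError(f"degenerate pair ({self.gene_high}, {self.gene_low})")
        for cohort, st in self.stats_per_cohort.items():
            if st.hr <= 1.0:
                raise ValidationError(
                    f"pair ({self.gene_high}>{self.gene_low}) not in canonical orientation: "
                    f"hr={st.hr} <= 1 in cohort {cohort!r}"
                )

    @property
    def pair_id(self) -> tuple[str, str]:
        return (self.gene_high, self.gene_low)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset((self.gene_high, self.gene_low))

    @property
    def worst_p(self) -> float:
        """Largest (least significant) p across recorded cohorts.

        Used as the ranking key for de-redundancy and selection tie-breaks:
        it is the significance level the pair is guaranteed to meet in every
        training cohort.
        """
        if not self.stats_per_cohort:
            return float("inf")
        return max(st.p for st in self.stats_per_cohort.values())

    def with_stats(self, cohort_name: str, stats: PairStats) -> "OrientedGenePair":
        merged = dict(self.stats_per_cohort)
        merged[cohort_name] = stats
        return OrientedGenePair(self.gene_high, self.gene_low, merged)


@dataclass(frozen=True)
class Signature:
    """A frozen gene-pair voting signature.

    A sample is called high-risk iff strictly more than half of the k pairs
    vote high-risk (``votes > k/2``); with even k a split vote is low-risk.
    """

    pairs: tuple[OrientedGenePair, ...]
    training_cindex: float
    training_population: str = ""
    vote_rule: str = "strict_majority"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        if len(self.pairs) < 1:
            raise ValidationError("signature needs at least one pair")
        seen: set[str] = set()
        for p in self.pairs:
            for g in (p.gene_high, p.gene_low):
                if g in seen:
                    raise ValidationError(f"gene {g!r} appears in two signature pairs")
                seen.add(g)
        if not (0.0 <= self.training_cindex <= 1.0):
            raise ValidationError(f"training_cindex must be in [0,1], got {self.training_cindex}")
        if self.vote_rule != "strict_majority":
            raise ValidationError(f"unsupported vote_rule {self.vote_rule!r}")

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for p in self.pairs:
            out.extend((p.gene_high, p.gene_low))
        return out

    def threshold_rule(self) -> str:
        """Human-readable vote threshold, e.g. 'votes > 3' for k=6."""
        half = self.k / 2
        return f"votes > {int(half) if half == int(half) else half}"


@dataclass(frozen=True)
class RiskCall:
    """Per-sample vote count and risk label under a signature."""

    sample_id: str
    votes: int
    k: int
    label: RiskLabel

    def __post_init__(self) -> None:
        if not (0 <= self.votes <= self.k):
            raise ValidationError(f"votes {self.votes} outside [0, {self.k}]")
        expected = RiskLabel.HIGH if self.votes * 2 > self.k else RiskLabel.LOW
        if self.label != expected:
            raise ValidationError(
                f"label {self.label} inconsistent with votes={self.votes}, k={self.k}"
            )


@dataclass(frozen=True)
class SurvTestResult:
    """Outcome of a two-sample or contingency test."""

    statistic: float
    df: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValidationError(f"p_value must be in [0,1], got {self.p_value}")


@dataclass(frozen=True)
class CoxFit:
    """Fitted Cox proportional-hazards model (partial likelihood).

    One entry per covariate; ``ci95`` is the Wald interval
    exp(coef ± 1.96·se).  ``converged`` is False when the partial likelihood
    is monotone (a coefficient diverges because risk groups' event times are
    perfectly separated); such fits carry the divergence direction in
    ``divergent`` and must not be used for screening.
    """

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: int
    n_events: int
    ties_method: str
    converged: bool
    loglik: float
    divergent: tuple[str, ...] = ()

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.coef - 1.959963984540054 * self.se)
        hi = np.exp(self.coef + 1.959963984540054 * self.se)
        return np.column_stack([lo, hi])

    def single(self) -> tuple[float, float, float]:
        """(log_hr, hr, p) of the sole covariate; errors if multivariate."""
        if len(self.names) != 1:
            raise ValidationError("single() requires a univariate fit")
        return float(self.coef[0]), float(np.exp(self.coef[0])), float(self.p[0])


@dataclass(frozen=True)
class KMCurve:
    """Kaplan–Meier product-limit estimate.

    ``survival[i]`` is S(t) just after ``event_times[i]``; S starts at 1
    before the first event time and is non-increasing.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError("event_times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12) or np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValidationError("survival must be non-increasing within [0,1]")

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])
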