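"""Synthetic two-cohort expression + survival data with known ground truth.

The generator emulates the statistical structure the discovery funnel
assumes, not real tumor biology:

* two independent cohorts, each mixing an early-onset (< 50 y) and a
  late-onset (> 60 y) stratum;
* a subset of genes additively shifted between the age strata (the
  differential-expression signal the first screen looks for);
* a small set of planted, gene-disjoint pairs whose *within-sample ordering*
  — not their raw values — carries a proportional-hazards effect on
  recurrence, so the planted truth is invariant to batch distortions by
  construction (both genes of a planted pair also receive the age shift so
  the pair can enter the funnel's candidate universe);
* exponential event times under the proportional-hazards model, with
  independent uniform censoring whose horizon is solved numerically to hit a
  target censoring fraction;
* optional per-sample strictly increasing batch distortions.

Structural choices (which genes carry which role, baseline means, shift
signs) depend only on ``config.seed``, so cohorts generated under different
labels share the same planted truth; per-cohort noise, ages and survival
draws depend on the cohort label as well.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import rankdata

from .datatypes import (
    ClinicalRecord,
    Cohort,
    ExpressionMatrix,
    OrientedGenePair,
    Treatment,
    ValidationError,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_study",
    "apply_batch_transform",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Defaults describe the reference simulation used throughout the test
    suite: 300 samples per cohort split evenly between age strata, 500
    genes of which 40 are purely age-differential (a 2-SD additive shift on
    unit-SD noise), and 5 planted gene pairs each multiplying the recurrence
    hazard by 3 when the pair sits in its high-risk ordering, under a
    baseline hazard of 0.02 events/month and 20% censoring.
    """

    seed: int = 0
    n_samples_per_cohort: int = 300
    frac_eocrc: float = 0.5
    n_genes: int = 500
    n_age_de_genes: int = 40
    age_effect_size: float = 2.0
    n_planted_pairs: int = 5
    planted_log_hr: float = float(np.log(3.0))
    baseline_hazard: float = 0.02
    censoring_rate_target: float = 0.2
    noise_sd: float = 1.0
    batch_transform: str | Mapping = "none"
    frac_act: float = 0.0  # fraction of samples assigned adjuvant chemotherapy

    def __post_init__(self) -> None:
        if self.n_samples_per_cohort < 2:
            raise ValidationError("n_samples_per_cohort must be >= 2")
        if not (0.0 < self.frac_eocrc < 1.0):
            raise ValidationError("frac_eocrc must be in (0,1)")
        if self.n_planted_pairs * 2 + self.n_age_de_genes > self.n_genes:
            raise ValidationError(
                f"gene budget infeasible: 2*{self.n_planted_pairs} planted + "
                f"{self.n_age_de_genes} age-DE > {self.n_genes} genes"
            )
        if not (0.0 <= self.censoring_rate_target < 1.0):
            raise ValidationError("censoring_rate_target must be in [0,1)")
        if self.noise_sd <= 0 or self.baseline_hazard <= 0:
            raise ValidationError("noise_sd and baseline_hazard must be positive")
        if not (0.0 <= self.frac_act <= 1.0):
            raise ValidationError("frac_act must be in [0,1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["batch_transform"], Mapping):
            d["batch_transform"] = dict(d["batch_transform"])
        return d


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for parameter-recovery tests."""

    age_de_gene_ids: tuple[str, ...]  # purely age-differential genes
    planted_pairs: tuple[OrientedGenePair, ...]  # gene-disjoint, risk orientation
    reo_states: np.ndarray  # (n_planted_pairs, n_samples) true high-risk indicators
    linear_predictor: np.ndarray  # per-sample log relative hazard
    censoring_fraction: float  # realized fraction of censored samples


def _label_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def _censoring_horizon(hazards: np.ndarray, target: float) -> float:
    """Uniform-censoring horizon tau such that the expected censored
    fraction over the cohort's hazards equals ``target``.

    For T ~ Exp(h) and C ~ U(0, tau), P(C < T) = (1 - e^{-h tau}) / (h tau),
    which decreases from 1 to 0 as tau grows; the root is bracketed and
    solved numerically.
    """

    def frac(tau: float) -> float:
        x = hazards * tau
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1.0
    while frac(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            raise ValidationError("cannot reach censoring target; hazards too small")
    return brentq(lambda t: frac(t) - target, lo, hi, xtol=1e-10, rtol=1e-12)


def _structural_roles(config: SyntheticConfig):
    """Seed-only assignment of gene ids, baseline means, roles and signs."""
    rng = _label_rng(config.seed, "structure")
    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    mu = rng.normal(7.0, 1.0, size=config.n_genes)
    perm = rng.permutation(config.n_genes)
    n_pl = config.n_planted_pairs
    planted_idx = perm[: 2 * n_pl].reshape(n_pl, 2) if n_pl else np.empty((0, 2), dtype=int)
    de_idx = perm[2 * n_pl: 2 * n_pl + config.n_age_de_genes]
    de_signs = rng.choice([-1.0, 1.0], size=config.n_age_de_genes)
    pair_signs = rng.choice([-1.0, 1.0], size=n_pl)  # one shared sign per planted pair
    # genes of a planted pair share a baseline mean so both REO states occur
    for a, b in planted_idx:
        mu[b] = mu[a]
    return gene_ids, mu, planted_idx, de_idx, de_signs, pair_signs


def generate_cohort(config: SyntheticConfig, cohort_label: str) -> tuple[Cohort, GroundTruth]:
    """Generate one cohort plus its ground truth.

    Identical (config, cohort_label) always produce bit-identical output.
    """
    gene_ids, mu, planted_idx, de_idx, de_signs, pair_signs = _structural_roles(config)
    rng = _label_rng(config.seed, f"cohort:{cohort_label}")
    n = config.n_samples_per_cohort
    n_eo = int(round(config.frac_eocrc * n))
    n_eo = min(max(n_eo, 1), n - 1)
    is_eocrc = np.zeros(n, dtype=bool)
    is_eocrc[rng.permutation(n)[:n_eo]] = True
    ages = np.where(is_eocrc, rng.uniform(30.0, 49.5, size=n), rng.uniform(61.0, 85.0, size=n))

    expr = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    shift = np.zeros(config.n_genes)
    shift[de_idx] = de_signs * config.age_effect_size
    for (a, b), s in zip(planted_idx, pair_signs):
        shift[a] = s * config.age_effect_size
        shift[b] = s * config.age_effect_size
    expr[:, is_eocrc] += shift[:, None]

    n_pl = config.n_planted_pairs
    if n_pl:
        states = (expr[planted_idx[:, 0]] > expr[planted_idx[:, 1]]).astype(np.uint8)
        lp = config.planted_log_hr * (states.sum(axis=0) - 0.5 * n_pl)
    else:
        states = np.zeros((0, n), dtype=np.uint8)
        lp = np.zeros(n)

    hazards = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazards)
    if config.censoring_rate_target > 0:
        tau = _censoring_horizon(hazards, config.censoring_rate_target)
        t_cens = rng.uniform(0.0, tau, size=n)
        observed = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        observed = t_event
        event = np.ones(n, dtype=int)

    if config.frac_act > 0:
        act = rng.random(n) < config.frac_act
        treatments = [Treatment.ACT if a else Treatment.SURGERY_ONLY for a in act]
    else:
        treatments = [Treatment.SURGERY_ONLY] * n

    sample_ids = [f"{cohort_label}-S{i:04d}" for i in range(1, n + 1)]
    clinical = [
        ClinicalRecord(
            sample_id=sid,
            age_years=float(a),
            endpoint_time=float(t),
            endpoint_event=int(e),
            treatment=tr,
        )
        for sid, a, t, e, tr in zip(sample_ids, ages, observed, event, treatments)
    ]
    cohort = Cohort(ExpressionMatrix(gene_ids, sample_ids, expr), clinical, cohort_label)

    if config.batch_transform not in (None, "none"):
        cohort = apply_batch_transform(cohort, config.batch_transform,
                                       seed=int(zlib.crc32(f"batch:{cohort_label}".encode())))

    truth = GroundTruth(
        age_de_gene_ids=tuple(gene_ids[i] for i in de_idx),
        planted_pairs=tuple(
            OrientedGenePair(gene_ids[a], gene_ids[b]) for a, b in planted_idx
        ),
        reo_states=states,
        linear_predictor=lp,
        censoring_fraction=float(1.0 - event.mean()),
    )
    return cohort, truth


def generate_study(
    config: SyntheticConfig,
    labels: Sequence[str] = ("train_a", "train_b", "validation"),
    batch_transforms: Sequence[str | Mapping] | None = None,
) -> dict[str, tuple[Cohort, GroundTruth]]:
    """Generate several cohorts sharing one planted truth.

    ``batch_transforms`` (one per label) overrides ``config.batch_transform``
    per cohort — the dual-training design applies a different monotone
    distortion to each cohort.
    """
    out: dict[str, tuple[Cohort, GroundTruth]] = {}
    for i, label in enumerate(labels):
        cohort, truth = generate_cohort(config, label)
        if batch_transforms is not None:
            tr = batch_transforms[i]
            if tr not in (None, "none"):
                cohort = apply_batch_transform(
                    cohort, tr, seed=int(zlib.crc32(f"study:{label}".encode()))
                )
        out[label] = (cohort, truth)
    return out


# ---------------------------------------------------------------------------
# Batch distortions
# ---------------------------------------------------------------------------

def _transform_column(col: np.ndarray, kind: str, params: Mapping, rng: np.random.Generator) -> np.ndarray:
    if kind == "affine":
        slope = float(params.get("slope", 2.0))
        if slope <= 0:
            raise ValidationError("affine batch transform needs a positive slope")
        return slope * col + float(params.get("offset", 0.0))
    if kind == "log":
        return np.log1p(col - col.min())
    if kind == "power":
        gamma = float(params.get("gamma", 2.0))
        if gamma <= 0:
            raise ValidationError("power batch transform needs gamma > 0")
        return (col - col.min() + 1.0) ** gamma
    if kind == "rank":
        return rankdata(col, method="average").astype(float)
    if kind == "pwl":
        # random strictly increasing piecewise-linear map over the column range
        n_knots = int(params.get("n_knots", 8))
        lo, hi = col.min(), col.max()
        span = hi - lo if hi > lo else 1.0
        knots = np.linspace(lo - 0.01 * span, hi + 0.01 * span, n_knots)
        values = np.cumsum(rng.uniform(0.1, 2.0, size=n_knots))
        return np.interp(col, knots, values)
    raise ValidationError(f"unknown batch transform {kind!r}")


def apply_batch_transform(cohort: Cohort, transform: str | Mapping, seed: int = 0) -> Cohort:
    """Replace each sample's expression column by a strictly increasing map.

    ``transform`` is either a kind name ("none", "affine", "log", "power",
    "rank", "pwl") or a mapping with a ``kind`` key plus parameters.  Within
    every sample the ordering of values — hence every REO indicator — is
    unchanged; clinical data are untouched.
    """
    if transform in (None, "none"):
        return cohort
    if isinstance(transform, str):
        kind, params = transform, {}
    else:
        params = dict(transform)
        kind = params.pop("kind", None)
        if kind is None:
            raise ValidationError("batch transform mapping needs a 'kind' key")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(kind.encode())])
    vals = cohort.expression.values
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        out[:, j] = _transform_column(vals[:, j], kind, params, rng)
    expr = ExpressionMatrix(cohort.expression.gene_ids, cohort.expression.sample_ids, out)
    return Cohort(expr, cohort.clinical, cohort.name)
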