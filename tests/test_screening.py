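import math

import numpy as np
import pytest

from reosig import (
    OrientedGenePair,
    PairStats,
    SURGERY_ONLY_ALL_AGES,
    SyntheticConfig,
    ValidationError,
    age_related_genes,
    apply_batch_transform,
    consistent_pairs,
    cox_screen_pair,
    deredundant,
    encode_pairs,
    generate_cohort,
    generate_study,
    reo_indicator,
    run_screen,
    screen_cohort,
)
from reosig.datatypes import PopulationFilter

from conftest import make_cohort


def _pair(high, low, p_a=0.01, p_b=0.02):
    stats = {
        "a": PairStats(log_hr=1.0, hr=math.e, p=p_a, n=50),
        "b": PairStats(log_hr=0.7, hr=math.exp(0.7), p=p_b, n=60),
    }
    return OrientedGenePair(high, low, stats)


# --------------------------------------------------------------------------
# REO encoding
# --------------------------------------------------------------------------

@pytest.mark.parametrize("a, b, expected", [(5.0, 3.0, 1), (3.0, 5.0, 0), (4.0, 4.0, 0)])
def test_reo_indicator_strict_inequality(a, b, expected):
    assert reo_indicator(a, b) == expected


def test_reo_indicator_rejects_nonfinite():
    with pytest.raises(ValidationError):
        reo_indicator(float("nan"), 1.0)


def test_encode_pairs_counts_and_order():
    cohort = make_cohort([[3.0, 1.0], [2.0, 2.0], [1.0, 3.0]], [1, 2], [1, 1],
                         gene_ids=["c", "a", "b"])
    enc = encode_pairs(cohort, ["c", "a", "b"])
    assert enc.pairs == (("a", "b"), ("a", "c"), ("b", "c"))  # lexicographic
    # sample 0: a=2, b=1, c=3 -> a>b=1, a>c=0, b>c=0
    assert enc.indicators[:, 0].tolist() == [1, 0, 0]
    # sample 1: a=2, b=3, c=1 -> a>b=0, a>c=1, b>c=1
    assert enc.indicators[:, 1].tolist() == [0, 1, 1]
    # m genes -> C(m,2) rows
    assert enc.indicators.shape[0] == math.comb(3, 2)


def test_encode_pairs_row_count_matches_combinatorics():
    rng = np.random.default_rng(0)
    m = 247
    cohort = make_cohort(rng.normal(size=(m, 4)), [1, 2, 3, 4], [1, 1, 1, 1],
                         gene_ids=[f"g{i:03d}" for i in range(m)])
    enc = encode_pairs(cohort, cohort.expression.gene_ids)
    assert enc.indicators.shape == (30_381, 4)


def test_encode_pairs_invariant_to_rank_transform():
    cfg = SyntheticConfig(seed=4, n_samples_per_cohort=30, n_genes=20, n_age_de_genes=4,
                          n_planted_pairs=2)
    cohort, _ = generate_cohort(cfg, "a")
    ranked = apply_batch_transform(cohort, "rank")
    genes = cohort.expression.gene_ids[:10]
    assert np.array_equal(encode_pairs(cohort, genes).indicators,
                          encode_pairs(ranked, genes).indicators)


def test_encode_pairs_errors():
    cohort = make_cohort([[1.0, 2.0], [2.0, 1.0]], [1, 2], [1, 1], gene_ids=["a", "b"])
    with pytest.raises(ValidationError, match="ghost"):
        encode_pairs(cohort, ["a", "ghost"])
    with pytest.raises(ValidationError, match="at least 2"):
        encode_pairs(cohort, ["a"])


# --------------------------------------------------------------------------
# Age-related DEG screen
# --------------------------------------------------------------------------

def test_age_related_genes_recovers_planted_de_genes():
    hits, total = 0, 0
    for seed in range(5):
        cfg = SyntheticConfig(seed=seed, n_samples_per_cohort=200, n_genes=200,
                              n_age_de_genes=40, n_planted_pairs=0, age_effect_size=2.0)
        study = generate_study(cfg, labels=("a", "b"))
        (ca, truth), (cb, _) = study["a"], study["b"]
        found = set(age_related_genes(ca, cb, alpha=0.05))
        hits += len(found & set(truth.age_de_gene_ids))
        total += len(truth.age_de_gene_ids)
    assert hits / total >= 0.9


def test_age_related_genes_edge_cases(reference_study):
    _, study = reference_study
    (ca, _), (cb, _) = study["train_a"], study["train_b"]
    assert age_related_genes(ca, cb, alpha=0.0) == []
    # a cohort lacking one stratum is rejected
    young_only = ca.subset(np.array([r.age_years < 50 for r in ca.clinical]))
    with pytest.raises(ValidationError, match="stratum"):
        age_related_genes(young_only, cb)


# --------------------------------------------------------------------------
# Cox screening of pairs
# --------------------------------------------------------------------------

def test_cox_screen_pair_worked_example():
    fit = cox_screen_pair([1, 0, 1, 0], [1, 2, 3, 4], [1, 1, 1, 1])
    assert fit.coef[0] == pytest.approx(math.log((1 + math.sqrt(17)) / 2), abs=1e-6)


def test_cox_screen_pair_degenerate_inputs():
    with pytest.raises(ValidationError, match="constant"):
        cox_screen_pair([0, 0, 0, 0], [1, 2, 3, 4], [1, 1, 1, 1])
    fit = cox_screen_pair([1, 1, 0, 0], [1, 2, 3, 4], [1, 1, 1, 1])
    assert fit.divergent and not fit.converged


def test_screen_cohort_orientation_is_canonical(reference_study):
    _, study = reference_study
    (ca, truth), (cb, _) = study["train_a"], study["train_b"]
    genes = age_related_genes(ca, cb)
    pairs = screen_cohort(ca, genes, alpha=0.05)
    assert pairs, "screen should find significant pairs with planted signal"
    for p in pairs:
        st = p.stats_per_cohort[ca.name]
        assert st.hr > 1.0
        # re-fitting the swapped orientation gives the exact reciprocal
        sub = SURGERY_ONLY_ALL_AGES.apply(ca)
        canonical = (sub.expression.gene_row(p.gene_high) > sub.expression.gene_row(p.gene_low))
        fit = cox_screen_pair(1 - canonical.astype(int), sub.times, sub.events)
        assert math.exp(-fit.coef[0]) == pytest.approx(st.hr, rel=1e-6)
        assert fit.p[0] == pytest.approx(st.p, rel=1e-6)


def test_screen_cohort_recovers_planted_pairs(reference_study):
    _, study = reference_study
    (ca, truth), (cb, _) = study["train_a"], study["train_b"]
    genes = age_related_genes(ca, cb)
    found = {p.pair_id for p in screen_cohort(ca, genes)}
    planted = {p.pair_id for p in truth.planted_pairs}
    assert len(found & planted) >= 2  # 3 planted


def test_screen_cohort_alpha_zero_and_small_population(reference_study):
    _, study = reference_study
    ca = study["train_a"][0]
    cb = study["train_b"][0]
    genes = age_related_genes(ca, cb)
    assert screen_cohort(ca, genes, alpha=0.0) == []
    tiny = ca.subset(np.arange(ca.n_samples) < 5)
    with pytest.raises(ValidationError, match="too small"):
        screen_cohort(tiny, genes)


# --------------------------------------------------------------------------
# Consistency and de-redundancy
# --------------------------------------------------------------------------

def test_consistent_pairs_requires_same_orientation():
    a = [_pair("A", "B"), _pair("C", "D"), _pair("E", "F")]
    b = [_pair("A", "B"), _pair("D", "C")]  # C/D flipped orientation in b
    kept = consistent_pairs(a, b)
    assert [p.pair_id for p in kept] == [("A", "B")]
    assert set(kept[0].stats_per_cohort) == {"a", "b"}


def test_deredundant_greedy_worked_examples():
    ex1 = [_pair("A", "B", 0.001, 0.001), _pair("A", "C", 0.01, 0.01),
           _pair("D", "E", 0.02, 0.02)]
    assert [p.pair_id for p in deredundant(ex1)] == [("A", "B"), ("D", "E")]
    chain = [_pair("A", "B", 0.001, 0.001), _pair("B", "C", 0.005, 0.005),
             _pair("C", "D", 0.01, 0.01)]
    assert [p.pair_id for p in deredundant(chain)] == [("A", "B"), ("C", "D")]
    disjoint = [_pair("A", "B"), _pair("C", "D")]
    assert deredundant(disjoint) == sorted(disjoint, key=lambda p: (p.worst_p, p.pair_id))


def test_deredundant_ranks_by_worst_cohort_p():
    # (A,B) is best in cohort a but worst-of-two ranks (A,C) first
    pairs = [_pair("A", "B", 0.0001, 0.04), _pair("A", "C", 0.01, 0.02)]
    assert [p.pair_id for p in deredundant(pairs)] == [("A", "C")]


def test_deredundant_output_gene_disjoint_property():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(12)]
    pairs = []
    for _ in range(40):
        a, b = rng.choice(12, size=2, replace=False)
        p = float(rng.uniform(0.001, 0.05))
        pairs.append(_pair(genes[a], genes[b], p, p * 1.5))
    out = deredundant(pairs)
    used = [g for p in out for g in (p.gene_high, p.gene_low)]
    assert len(used) == len(set(used))


# --------------------------------------------------------------------------
# Full screen: funnel and invariance
# --------------------------------------------------------------------------

def test_run_screen_funnel_counts_monotone(reference_study):
    _, study = reference_study
    (ca, _), (cb, _) = study["train_a"], study["train_b"]
    res = run_screen(ca, cb)
    counts = dict(res.stage_counts)
    assert len(res.consistent) <= min(len(res.screened[ca.name]), len(res.screened[cb.name]))
    assert len(res.candidates) <= len(res.consistent)
    assert counts["deredundant_pairs"] == len(res.candidates)


def test_pair_stages_invariant_to_batch_transform(reference_study):
    """Every pair-level stage (encoding, Cox screen, consistency,
    de-redundancy) is bit-identical under per-sample monotone distortions.

    The gene-level differential-expression stage compares values ACROSS
    samples, so it is only invariant to transforms shared by all samples;
    the pair stages are invariant per sample, which is the property that
    matters once the candidate gene universe is fixed.
    """
    _, study = reference_study
    (ca, _), (cb, _) = study["train_a"], study["train_b"]
    genes = age_related_genes(ca, cb)
    moved_a = apply_batch_transform(ca, "pwl", seed=3)
    moved_b = apply_batch_transform(cb, {"kind": "power", "gamma": 2.5}, seed=4)
    sa, sb = screen_cohort(ca, genes), screen_cohort(cb, genes)
    ma, mb = screen_cohort(moved_a, genes), screen_cohort(moved_b, genes)
    assert sa == ma and sb == mb  # bit-identical stats
    assert consistent_pairs(sa, sb) == consistent_pairs(ma, mb)
    assert deredundant(consistent_pairs(sa, sb)) == deredundant(consistent_pairs(ma, mb))


def test_deg_screen_invariant_to_cohortwide_monotone_transform(reference_study):
    """A transform shared by every sample (a global renormalization) leaves
    the rank-based differential-expression screen unchanged."""
    _, study = reference_study
    (ca, _), (cb, _) = study["train_a"], study["train_b"]
    moved_a = apply_batch_transform(ca, {"kind": "affine", "slope": 3.0, "offset": -2.0})
    assert age_related_genes(ca, cb) == age_related_genes(moved_a, cb)
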