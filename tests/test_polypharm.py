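"""Simple and joint polypharmacology interval estimators.

Independent oracles: statsmodels' Jeffreys interval for the Beta quantiles,
and a naive per-target enumeration for the joint partition.
"""

import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from conftest import random_relation
from ltpoly import (
    ActivityState,
    RateSource,
    active_rate,
    build_relation,
    global_active_rate,
    iter_pairs,
    jeffreys_interval,
    joint_ci,
    joint_estimate,
    joint_partition,
    joint_pmax,
    joint_pmax_estimated,
    joint_pmin,
    joint_prob_estimates,
    joint_report,
    pmax,
    pmax_estimated,
    pmin,
    polypharm_estimate,
    polypharm_report,
)

A, I, N = ActivityState.ACTIVE, ActivityState.INACTIVE, ActivityState.NULL


# ---------------------------------------------------------------------------
# simple polypharmacology on the toy dataset
# ---------------------------------------------------------------------------


def test_toy_simple_bounds(toy_relation):
    p1 = toy_relation.ligand_profile("l1")
    assert pmin(p1) == 2
    assert pmax(p1) == 4


def test_toy_urn_rate_and_estimated_bound(toy_relation):
    p1 = toy_relation.ligand_profile("l1")
    rate, source = active_rate(p1)
    assert rate == pytest.approx(2 / 3)
    assert source is RateSource.LIGAND_SPECIFIC
    p_tilde, delta = pmax_estimated(p1, rate)
    assert p_tilde == pytest.approx(10 / 3)
    assert delta == pytest.approx(4 / 3)


def test_rate_saturation_endpoints(toy_relation):
    p1 = toy_relation.ligand_profile("l1")
    assert pmax_estimated(p1, 1.0)[0] == pmax(p1)
    assert pmax_estimated(p1, 0.0)[0] == pmin(p1)


def test_rate_of_unmeasured_ligand_uses_flagged_fallback():
    rel = build_relation([], ligands=["l1"], targets=["t1", "t2"])
    prof = rel.ligand_profile("l1")
    assert active_rate(prof) == (None, RateSource.UNDEFINED)
    assert active_rate(prof, fallback_rate=0.06) == (0.06, RateSource.GLOBAL_FALLBACK)
    with pytest.raises(ValueError, match="fallback"):
        pmax_estimated(prof, None)


def test_rate_zero_when_only_inactives_measured():
    rel = build_relation([("l1", "t1", I)], targets=["t1", "t2"])
    assert active_rate(rel.ligand_profile("l1")) == (0.0, RateSource.LIGAND_SPECIFIC)


# ---------------------------------------------------------------------------
# Jeffreys intervals
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("k,n", [(2, 3), (1, 10), (5, 10), (17, 40), (0, 7), (7, 7)])
def test_jeffreys_matches_statsmodels_oracle(k, n):
    low, high, no_data = jeffreys_interval(k, n, 0.05)
    assert not no_data
    sm_low, sm_high = proportion_confint(k, n, alpha=0.05, method="jeffreys")
    # statsmodels does not clip the boundary cases to exactly 0 / 1
    if k > 0:
        assert low == pytest.approx(sm_low, abs=1e-12)
    else:
        assert low == 0.0
    if k < n:
        assert high == pytest.approx(sm_high, abs=1e-12)
    else:
        assert high == 1.0
    assert low <= k / n <= high


def test_jeffreys_no_data_and_invalid_inputs():
    assert jeffreys_interval(0, 0, 0.05) == (0.0, 1.0, True)
    with pytest.raises(ValueError):
        jeffreys_interval(5, 3, 0.05)
    with pytest.raises(ValueError):
        jeffreys_interval(1, 2, 1.5)


# ---------------------------------------------------------------------------
# per-ligand report
# ---------------------------------------------------------------------------


def test_toy_polypharm_report(toy_relation):
    estimates = polypharm_report(toy_relation, alpha=0.05)
    assert [e.ligand for e in estimates] == ["l1", "l2"]
    e1 = estimates[0]
    assert (e1.p_min, e1.p_max) == (2, 4)
    assert e1.p_tilde_max == pytest.approx(10 / 3)
    assert e1.delta_e_max == 2
    assert e1.p_min <= e1.ci_low <= e1.p_tilde_max <= e1.ci_high <= e1.p_max


def test_fully_measured_relation_gives_point_intervals():
    rel = build_relation(
        [("l1", "t1", A), ("l1", "t2", I), ("l2", "t1", I), ("l2", "t2", I)]
    )
    for est in polypharm_report(rel):
        assert est.ci_low == est.ci_high == est.p_min == est.p_max == est.p_tilde_max


def test_strict_mode_leaves_unmeasured_ligand_undefined():
    rel = build_relation([("l1", "t1", A)], ligands=["l1", "l2"], targets=["t1", "t2"])
    strict = {e.ligand: e for e in polypharm_report(rel, strict=True)}
    assert strict["l2"].p_hat is None
    assert strict["l2"].p_hat_source is RateSource.UNDEFINED
    assert strict["l2"].p_tilde_max is None
    relaxed = {e.ligand: e for e in polypharm_report(rel)}
    assert relaxed["l2"].p_hat == pytest.approx(global_active_rate(rel))
    assert relaxed["l2"].p_hat_source is RateSource.GLOBAL_FALLBACK


def test_interval_ordering_and_error_identities_on_random_relations():
    rng = np.random.default_rng(17)
    for _ in range(20):
        rel = random_relation(rng, int(rng.integers(1, 12)), int(rng.integers(1, 15)))
        for est in polypharm_report(rel):
            assert est.p_min <= est.p_max
            prof = rel.ligand_profile(est.ligand)
            assert est.delta_e_max == est.p_max - est.p_min == len(prof.null_targets)
            if est.p_tilde_max is not None:
                assert est.p_min - 1e-12 <= est.p_tilde_max <= est.p_max + 1e-12
                assert est.delta_e_tilde == pytest.approx(est.p_tilde_max - est.p_min)
                assert est.ci_low <= est.p_tilde_max <= est.ci_high


# ---------------------------------------------------------------------------
# joint polypharmacology
# ---------------------------------------------------------------------------


def naive_joint_counts(rel, la, lb):
    """Per-target enumeration of the 3x3 joint state table."""
    order = (A, I, N)
    counts = np.zeros((3, 3), dtype=int)
    for t in rel.targets:
        sa = rel.state_of(la, t)
        sb = rel.state_of(lb, t)
        counts[order.index(sa), order.index(sb)] += 1
    return counts


def test_toy_joint_partition(toy_relation):
    part = joint_partition(
        toy_relation.ligand_profile("l1"), toy_relation.ligand_profile("l2")
    )
    expected = np.array([[1, 0, 1], [0, 0, 1], [1, 1, 0]])
    assert np.array_equal(part.counts, expected)
    assert part.n_targets == 5


def test_joint_partition_matches_naive_enumeration():
    rng = np.random.default_rng(23)
    for _ in range(30):
        rel = random_relation(rng, 4, int(rng.integers(1, 10)))
        la, lb = rng.choice(rel.ligands, size=2, replace=False)
        part = joint_partition(rel.ligand_profile(la), rel.ligand_profile(lb))
        assert np.array_equal(part.counts, naive_joint_counts(rel, la, lb))


def test_joint_partition_transposes_under_argument_swap(toy_relation):
    p1 = toy_relation.ligand_profile("l1")
    p2 = toy_relation.ligand_profile("l2")
    assert np.array_equal(
        joint_partition(p1, p2).counts, joint_partition(p2, p1).counts.T
    )


def test_self_pair_partition_is_diagonal(toy_relation):
    p1 = toy_relation.ligand_profile("l1")
    part = joint_partition(p1, p1)
    assert np.array_equal(np.diag(np.diag(part.counts)), part.counts)
    assert joint_pmin(part) == pmin(p1)
    assert joint_pmax(part) == pmax(p1)


def test_toy_joint_bounds(toy_relation):
    part = joint_partition(
        toy_relation.ligand_profile("l1"), toy_relation.ligand_profile("l2")
    )
    assert joint_pmin(part) == 1
    assert joint_pmax(part) == 3


def test_toy_joint_probability_estimates(toy_relation):
    part = joint_partition(
        toy_relation.ligand_profile("l1"), toy_relation.ligand_profile("l2")
    )
    joint_probs = joint_prob_estimates(part, mode="joint")
    assert [p for p, _ in joint_probs] == [1.0, 1.0, 1.0]
    indep_probs = joint_prob_estimates(part, mode="independence")
    assert [p for p, _ in indep_probs] == pytest.approx([2 / 3, 2 / 3, 4 / 9])


def test_toy_joint_estimated_bounds(toy_relation):
    part = joint_partition(
        toy_relation.ligand_profile("l1"), toy_relation.ligand_profile("l2")
    )
    assert joint_pmax_estimated(
        part, joint_prob_estimates(part, mode="joint")
    ) == pytest.approx(3.0)
    assert joint_pmax_estimated(
        part, joint_prob_estimates(part, mode="independence")
    ) == pytest.approx(7 / 3)


def test_joint_bound_dominated_by_individual_minima():
    rng = np.random.default_rng(31)
    for _ in range(20):
        rel = random_relation(rng, 5, 12)
        for la, lb in iter_pairs(rel.ligands):
            part = joint_partition(rel.ligand_profile(la), rel.ligand_profile(lb))
            assert joint_pmin(part) <= min(
                pmin(rel.ligand_profile(la)), pmin(rel.ligand_profile(lb))
            )


def test_zero_numerator_gives_zero_probabilities():
    rel = build_relation(
        [("a", "t1", A), ("a", "t2", I), ("b", "t1", I), ("b", "t2", A)],
        targets=["t1", "t2", "t3"],
    )
    part = joint_partition(rel.ligand_profile("a"), rel.ligand_profile("b"))
    probs = joint_prob_estimates(part, mode="joint")
    assert [p for p, _ in probs] == [0.0, 0.0, 0.0]


def test_joint_probability_fallback_flags():
    rel = build_relation([("a", "t1", A), ("b", "t1", A)], targets=["t1", "t2"])
    part = joint_partition(rel.ligand_profile("a"), rel.ligand_profile("b"))
    # (+,-) and (-,+) cells are empty -> the first two ratios are defined,
    # and so is the third (denominator |S++| = 1)
    probs = joint_prob_estimates(part, mode="joint")
    assert all(src is RateSource.LIGAND_SPECIFIC for _, src in probs)
    # a pair with no doubly measured targets has undefined joint-mode probabilities
    rel2 = build_relation([("a", "t1", A), ("b", "t2", A)], targets=["t1", "t2", "t3"])
    part2 = joint_partition(rel2.ligand_profile("a"), rel2.ligand_profile("b"))
    probs2 = joint_prob_estimates(part2, mode="joint")
    assert all(src is RateSource.UNDEFINED for _, src in probs2)
    probs3 = joint_prob_estimates(part2, mode="joint", fallback_rate=0.2)
    assert all(src is RateSource.GLOBAL_FALLBACK for _, src in probs3)


# ---------------------------------------------------------------------------
# Monte Carlo joint confidence interval
# ---------------------------------------------------------------------------


def test_joint_ci_collapses_without_null_cells():
    rel = build_relation(
        [("a", "t1", A), ("a", "t2", I), ("b", "t1", A), ("b", "t2", A)]
    )
    part = joint_partition(rel.ligand_profile("a"), rel.ligand_profile("b"))
    assert joint_ci(part, seed=1) == (1.0, 1.0)


def test_joint_ci_contains_point_estimate_and_respects_bounds(toy_relation):
    part = joint_partition(
        toy_relation.ligand_profile("l1"), toy_relation.ligand_profile("l2")
    )
    for mode in ("joint", "independence"):
        probs = joint_prob_estimates(part, mode=mode)
        estimate = joint_pmax_estimated(part, probs)
        low, high = joint_ci(part, mode=mode, alpha=0.05, n_draws=20000, seed=3)
        assert joint_pmin(part) <= low <= high <= joint_pmax(part)
        assert low - 0.35 <= estimate <= high + 0.35  # MC quantiles of a wide posterior


def test_joint_ci_is_deterministic_and_converged():
    rng = np.random.default_rng(41)
    rel = random_relation(rng, 3, 30)
    part = joint_partition(rel.ligand_profile("l0"), rel.ligand_profile("l1"))
    first = joint_ci(part, n_draws=20000, seed=11)
    again = joint_ci(part, n_draws=20000, seed=11)
    assert first == again
    more = joint_ci(part, n_draws=40000, seed=11)
    assert first[0] == pytest.approx(more[0], abs=0.2)
    assert first[1] == pytest.approx(more[1], abs=0.2)


def test_joint_ci_rejects_invalid_parameters(toy_relation):
    part = joint_partition(
        toy_relation.ligand_profile("l1"), toy_relation.ligand_profile("l2")
    )
    with pytest.raises(ValueError):
        joint_ci(part, n_draws=10, seed=1)
    with pytest.raises(ValueError):
        joint_ci(part, alpha=0.0, seed=1)


# ---------------------------------------------------------------------------
# pair enumeration and reports
# ---------------------------------------------------------------------------


def test_pair_enumeration_counts():
    assert len(iter_pairs([f"l{i}" for i in range(10)])) == 45
    assert iter_pairs(["a", "b", "c"]) == [("a", "b"), ("a", "c"), ("b", "c")]


def test_joint_report_single_ligand_mode(toy_relation):
    report = joint_report(toy_relation, ligand="l1", n_draws=1000, seed=2)
    assert [e.pair for e in report] == [("l1", "l2")]
    est = report[0]
    assert est.p_min == 1 and est.p_max == 3
    assert est.p_tilde_max_joint == pytest.approx(3.0)
    assert est.p_tilde_max_indep == pytest.approx(7 / 3)
    with pytest.raises(KeyError):
        joint_report(toy_relation, ligand="nope")


def test_joint_estimate_self_pair_reduces_to_simple(toy_relation):
    est = joint_estimate(toy_relation, "l1", "l1", n_draws=1000, seed=5)
    prof = toy_relation.ligand_profile("l1")
    assert est.p_min == pmin(prof)
    assert est.p_max == pmax(prof)
    assert est.p_tilde_max_indep is not None


def test_converting_null_to_inactive_shrinks_pmax_only():
    rel = build_relation([("l1", "t1", A)], targets=["t1", "t2", "t3"])
    before = polypharm_report(rel)[0]
    richer = build_relation(
        [("l1", "t1", A), ("l1", "t2", I)], targets=["t1", "t2", "t3"]
    )
    after = polypharm_report(richer)[0]
    assert after.p_min == before.p_min
    assert after.p_max == before.p_max - 1
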