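"""Interval-valued polypharmacology estimates under incomplete activity data.

A ligand's *simple polypharmacology* P(l) is the number of targets it is
truly active against.  With null (unmeasured) pairs present, P(l) is only
known to lie in the interval [Pmin, Pmax], where Pmin = |S+(l)| counts the
known actives and Pmax = |S+(l)| + |S0(l)| additionally assumes every null
pair active.  An urn-model probability — the active fraction among the
ligand's measured pairs — shrinks the upper bound to the expectation value

    P~max(l) = |S+(l)| + Pr_l * |S0(l)|,   Pr_l = |S+| / (|S+| + |S-|),

and a Jeffreys Bayesian interval on Pr_l, mapped affinely through the same
expression, yields a confidence interval on P~max.

The *joint polypharmacology* P(l, l') counts targets both ligands hit.  The
3x3 cross-tabulation of the two ligands' states over T partitions the target
set; the four cells in which neither ligand is known-inactive bound P(l, l')
from above, the (+,+) cell from below, and cellwise urn probabilities (or a
product-of-marginals independence assumption) give the shrunken estimate.
Confidence intervals for the joint estimate are propagated by seeded Monte
Carlo sampling of the underlying Jeffreys Beta posteriors.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

from .relation import (
    ActivityState,
    LigandProfile,
    STATE_ORDER,
    TernaryRelation,
)

__all__ = [
    "RateSource",
    "PolypharmEstimate",
    "JointPartition",
    "JointPolypharmEstimate",
    "pmin",
    "pmax",
    "active_rate",
    "pmax_estimated",
    "jeffreys_interval",
    "global_active_rate",
    "polypharm_estimate",
    "polypharm_report",
    "joint_partition",
    "joint_pmin",
    "joint_pmax",
    "joint_prob_estimates",
    "joint_pmax_estimated",
    "joint_ci",
    "joint_estimate",
    "joint_report",
    "iter_pairs",
]


class RateSource(enum.Enum):
    """Provenance of an urn-model probability estimate."""

    LIGAND_SPECIFIC = "ligand-specific"
    GLOBAL_FALLBACK = "global-fallback"
    UNDEFINED = "undefined"


# ---------------------------------------------------------------------------
# simple polypharmacology
# ---------------------------------------------------------------------------


def pmin(profile: LigandProfile) -> int:
    """Lower bound on P(l): the count of known active targets |S+(l)|."""
    return len(profile.active_targets)


def pmax(profile: LigandProfile) -> int:
    """Upper bound on P(l): |S+(l)| + |S0(l)| (every null pair assumed active)."""
    return len(profile.active_targets) + len(profile.null_targets)


def active_rate(
    profile: LigandProfile, fallback_rate: float | None = None
) -> tuple[float | None, RateSource]:
    """Urn-model probability that a null pair of this ligand is active.

    The estimate is the active fraction among the ligand's measured pairs,
    |S+| / (|S+| + |S-|).  With no measured pairs the rate is undefined; a
    supplied ``fallback_rate`` (typically the dataset-wide active fraction)
    is then returned with its source flagged.
    """
    k = len(profile.active_targets)
    n = k + len(profile.inactive_targets)
    if n > 0:
        return k / n, RateSource.LIGAND_SPECIFIC
    if fallback_rate is not None:
        return float(fallback_rate), RateSource.GLOBAL_FALLBACK
    return None, RateSource.UNDEFINED


def pmax_estimated(profile: LigandProfile, p_hat: float) -> tuple[float, float]:
    """Expectation-value upper bound P~max and its error term.

    Returns ``(p_tilde_max, delta_e_tilde)`` with
    ``p_tilde_max = |S+| + p_hat * |S0|`` and ``delta_e_tilde = p_hat * |S0|``.
    Expectation values are kept real-valued, never rounded.
    """
    if p_hat is None:
        raise ValueError(
            "p_hat is undefined for this ligand; supply a fallback rate "
            "(e.g. the dataset-wide active fraction)"
        )
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat must lie in [0, 1], got {p_hat}")
    n_null = len(profile.null_targets)
    delta = p_hat * n_null
    return len(profile.active_targets) + delta, delta


def jeffreys_interval(
    k: int, n: int, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Jeffreys Bayesian interval for a binomial proportion.

    Central interval of the Beta(k + 1/2, n - k + 1/2) posterior at levels
    alpha/2 and 1 - alpha/2, with the standard boundary conventions low = 0
    when k = 0 and high = 1 when k = n.  Returns ``(low, high, no_data)``
    where ``no_data`` is True only for n = 0, in which case the interval is
    the trivial (0, 1).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        return 0.0, 1.0, True
    a, b = k + 0.5, n - k + 0.5
    low = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, a, b))
    high = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, a, b))
    return low, high, False


def global_active_rate(rel: TernaryRelation) -> float | None:
    """Dataset-wide active fraction among known pairs (the default fallback)."""
    n_active, n_inactive, _ = rel.class_cardinalities()
    known = n_active + n_inactive
    return n_active / known if known else None


@dataclass(frozen=True)
class PolypharmEstimate:
    """Per-ligand interval estimate [Pmin, P~max, Pmax] with CI and errors."""

    ligand: str
    p_min: int
    p_max: int
    p_hat: float | None
    p_hat_source: RateSource
    p_tilde_max: float | None
    ci_low: float | None
    ci_high: float | None
    delta_e_max: int
    delta_e_tilde: float | None
    alpha: float


def polypharm_estimate(
    profile: LigandProfile,
    alpha: float = 0.05,
    fallback_rate: float | None = None,
    strict: bool = False,
) -> PolypharmEstimate:
    """Interval estimate of one ligand's simple polypharmacology.

    The CI on P~max maps the Jeffreys interval on the urn probability
    affinely: endpoint = |S+| + q * |S0|.  In ``strict`` mode a ligand with
    no measured pairs gets undefined estimates instead of the fallback rate.
    """
    p_lo = pmin(profile)
    p_hi = pmax(profile)
    n_null = len(profile.null_targets)
    p_hat, source = active_rate(profile, None if strict else fallback_rate)
    if p_hat is None:
        return PolypharmEstimate(
            ligand=profile.ligand,
            p_min=p_lo,
            p_max=p_hi,
            p_hat=None,
            p_hat_source=source,
            p_tilde_max=None,
            ci_low=None,
            ci_high=None,
            delta_e_max=n_null,
            delta_e_tilde=None,
            alpha=alpha,
        )
    p_tilde, delta_tilde = pmax_estimated(profile, p_hat)
    k = len(profile.active_targets)
    n = k + len(profile.inactive_targets)
    q_lo, q_hi, _no_data = jeffreys_interval(k, n, alpha)
    return PolypharmEstimate(
        ligand=profile.ligand,
        p_min=p_lo,
        p_max=p_hi,
        p_hat=p_hat,
        p_hat_source=source,
        p_tilde_max=p_tilde,
        ci_low=p_lo + q_lo * n_null,
        ci_high=p_lo + q_hi * n_null,
        delta_e_max=n_null,
        delta_e_tilde=delta_tilde,
        alpha=alpha,
    )


def polypharm_report(
    rel: TernaryRelation,
    alpha: float = 0.05,
    strict: bool = False,
) -> list[PolypharmEstimate]:
    """Simple-polypharmacology estimates for every ligand, in reference order.

    Ligands with no measured pairs fall back to the dataset-wide active
    fraction (flagged), unless ``strict`` is set.
    """
    fallback = None if strict else global_active_rate(rel)
    return [
        polypharm_estimate(rel.ligand_profile(l), alpha=alpha, fallback_rate=fallback, strict=strict)
        for l in rel.ligands
    ]


# ---------------------------------------------------------------------------
# joint polypharmacology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JointPartition:
    """3x3 cross-tabulation of two ligands' states over the target set.

    ``counts[i, j]`` is the number of targets in state i for the first
    ligand and state j for the second, with state order (+, -, 0); the nine
    cells partition T.
    """

    pair: tuple[str, str]
    counts: np.ndarray  # (3, 3) int, rows = first ligand's state

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 3) or (counts < 0).any():
            raise ValueError("joint partition requires a 3x3 table of non-negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def n_targets(self) -> int:
        return int(self.counts.sum())

    def cell(self, state_a: ActivityState, state_b: ActivityState) -> int:
        return int(self.counts[STATE_ORDER.index(state_a), STATE_ORDER.index(state_b)])

    def marginal_known(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """((k, n) of ligand a, (k, n) of ligand b): actives and measured pairs."""
        row = self.counts.sum(axis=1)
        col = self.counts.sum(axis=0)
        return (int(row[0]), int(row[0] + row[1])), (int(col[0]), int(col[0] + col[1]))


def joint_partition(a: LigandProfile, b: LigandProfile) -> JointPartition:
    """Cross-tabulate two ligand profiles over their shared target set."""
    if a.targets != b.targets:
        raise ValueError("profiles are drawn from different target reference sets")
    counts = np.zeros((3, 3), dtype=np.int64)
    sets_a = (a.active_targets, a.inactive_targets, a.null_targets)
    sets_b = (b.active_targets, b.inactive_targets, b.null_targets)
    for i, sa in enumerate(sets_a):
        for j, sb in enumerate(sets_b):
            counts[i, j] = len(sa.intersection(sb))
    return JointPartition(pair=(a.ligand, b.ligand), counts=counts)


def joint_pmin(partition: JointPartition) -> int:
    """Lower bound |S(+,+)|: targets both ligands are known-active against."""
    return int(partition.counts[0, 0])


def joint_pmax(partition: JointPartition) -> int:
    """Upper bound: the four cells where neither ligand is known inactive."""
    c = partition.counts
    return int(c[0, 0] + c[0, 2] + c[2, 0] + c[2, 2])


def joint_prob_estimates(
    partition: JointPartition,
    mode: str = "joint",
    rate_a: float | None = None,
    rate_b: float | None = None,
    fallback_rate: float | None = None,
) -> tuple[tuple[float | None, RateSource], ...]:
    """The three cell probabilities Pr(+,0+), Pr(0+,+), Pr(0+,0+).

    ``joint`` mode conditions on the doubly measured targets:
    Pr(+,0+) = |S++| / (|S++| + |S+-|), Pr(0+,+) symmetric, and
    Pr(0+,0+) = |S++| / (all four doubly measured cells).  ``independence``
    mode factorises over per-ligand marginal rates: Pr(+,0+) = p_hat(b),
    Pr(0+,+) = p_hat(a), Pr(0+,0+) = p_hat(a) * p_hat(b).  Zero denominators
    (or missing marginals) yield the fallback rate, flagged; without a
    fallback they are flagged undefined — never an exception here.
    """
    c = partition.counts

    def ratio(num: int, den: int) -> tuple[float | None, RateSource]:
        if den > 0:
            return num / den, RateSource.LIGAND_SPECIFIC
        if fallback_rate is not None:
            return float(fallback_rate), RateSource.GLOBAL_FALLBACK
        return None, RateSource.UNDEFINED

    if mode == "joint":
        return (
            ratio(int(c[0, 0]), int(c[0, 0] + c[0, 1])),
            ratio(int(c[0, 0]), int(c[0, 0] + c[1, 0])),
            ratio(int(c[0, 0]), int(c[0, 0] + c[0, 1] + c[1, 0] + c[1, 1])),
        )
    if mode == "independence":
        (ka, na), (kb, nb) = partition.marginal_known()
        pa = rate_a if rate_a is not None else (ka / na if na else fallback_rate)
        pb = rate_b if rate_b is not None else (kb / nb if nb else fallback_rate)

        def flag(value: float | None, own: bool) -> tuple[float | None, RateSource]:
            if value is None:
                return None, RateSource.UNDEFINED
            return float(value), (
                RateSource.LIGAND_SPECIFIC if own else RateSource.GLOBAL_FALLBACK
            )

        pa_flagged = flag(pa, rate_a is not None or na > 0)
        pb_flagged = flag(pb, rate_b is not None or nb > 0)
        if pa is None or pb is None:
            prod: tuple[float | None, RateSource] = (None, RateSource.UNDEFINED)
        else:
            prod = (
                float(pa) * float(pb),
                RateSource.LIGAND_SPECIFIC
                if pa_flagged[1] is RateSource.LIGAND_SPECIFIC
                and pb_flagged[1] is RateSource.LIGAND_SPECIFIC
                else RateSource.GLOBAL_FALLBACK,
            )
        return (pb_flagged, pa_flagged, prod)
    raise ValueError(f"unknown mode {mode!r}; expected 'joint' or 'independence'")


def joint_pmax_estimated(
    partition: JointPartition,
    probabilities: tuple[tuple[float | None, RateSource], ...],
) -> float:
    """Expectation-value upper bound on the joint polypharmacology.

    ``|S++| + Pr(+,0+)*|S+0| + Pr(0+,+)*|S0+| + Pr(0+,0+)*|S00|``; lies in
    [joint_pmin, joint_pmax].
    """
    c = partition.counts
    weights = (int(c[0, 2]), int(c[2, 0]), int(c[2, 2]))
    total = float(c[0, 0])
    for (p, _src), w in zip(probabilities, weights):
        if w == 0:
            continue  # an empty cell contributes nothing regardless of its probability
        if p is None:
            raise ValueError(
                "undefined cell probability with a non-empty cell; supply a fallback rate"
            )
        total += p * w
    return total


def joint_ci(
    partition: JointPartition,
    mode: str = "joint",
    alpha: float = 0.05,
    n_draws: int = 4000,
    seed: int = 0,
    fallback_rate: float | None = None,
) -> tuple[float, float]:
    """Monte Carlo confidence interval for the estimated joint upper bound.

    Each underlying probability is sampled from its Jeffreys Beta posterior
    (Beta(k + 1/2, n - k + 1/2) with the k, n of the corresponding urn
    estimator); the expectation-value bound is evaluated per draw and the
    alpha/2, 1 - alpha/2 empirical quantiles are reported.  Deterministic
    given the seed.  With no null cells the interval collapses to |S++|.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n_draws < 1000:
        raise ValueError(f"n_draws must be >= 1000 for stable quantiles, got {n_draws}")
    rng = np.random.default_rng(seed)
    c = partition.counts
    weights = np.array([c[0, 2], c[2, 0], c[2, 2]], dtype=float)
    base = float(c[0, 0])
    if weights.sum() == 0:
        return base, base

    def posterior(k: int, n: int) -> np.ndarray:
        if n == 0:
            if fallback_rate is not None:
                return np.full(n_draws, float(fallback_rate))
            # Jeffreys prior itself: Beta(1/2, 1/2)
            return rng.beta(0.5, 0.5, size=n_draws)
        return rng.beta(k + 0.5, n - k + 0.5, size=n_draws)

    if mode == "joint":
        kn = (
            (int(c[0, 0]), int(c[0, 0] + c[0, 1])),
            (int(c[0, 0]), int(c[0, 0] + c[1, 0])),
            (int(c[0, 0]), int(c[0, 0] + c[0, 1] + c[1, 0] + c[1, 1])),
        )
        draws = np.column_stack([posterior(k, n) for k, n in kn])
    elif mode == "independence":
        (ka, na), (kb, nb) = partition.marginal_known()
        pa = posterior(ka, na)
        pb = posterior(kb, nb)
        draws = np.column_stack([pb, pa, pa * pb])
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'joint' or 'independence'")
    values = base + draws @ weights
    low, high = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(low), float(high)


@dataclass(frozen=True)
class JointPolypharmEstimate:
    """Per-pair joint estimate: partition, bounds, expectations, CI, errors."""

    pair: tuple[str, str]
    partition: JointPartition
    p_min: int
    p_max: int
    p_tilde_max_joint: float | None
    p_tilde_max_indep: float | None
    ci_low: float | None
    ci_high: float | None
    delta_e_max: int
    delta_e_tilde: float | None
    prob_estimates: tuple[tuple[float | None, RateSource], ...]
    alpha: float


def joint_estimate(
    rel: TernaryRelation,
    ligand_a: str,
    ligand_b: str,
    mode: str = "joint",
    alpha: float = 0.05,
    n_draws: int = 4000,
    seed: int = 0,
    strict: bool = False,
) -> JointPolypharmEstimate:
    """Joint-polypharmacology interval estimate for one ligand pair.

    Computes both the joint-mode and independence-mode expectation bounds;
    the CI (Monte Carlo) and the headline ``delta_e_tilde`` follow ``mode``.
    Self-pairs are permitted and reduce to the simple-polypharmacology
    quantities.
    """
    fallback = None if strict else global_active_rate(rel)
    pa = rel.ligand_profile(ligand_a)
    pb = rel.ligand_profile(ligand_b)
    part = joint_partition(pa, pb)
    p_lo = joint_pmin(part)
    p_hi = joint_pmax(part)

    estimates: dict[str, float | None] = {}
    probs_by_mode = {}
    for m in ("joint", "independence"):
        probs = joint_prob_estimates(part, mode=m, fallback_rate=fallback)
        probs_by_mode[m] = probs
        try:
            estimates[m] = joint_pmax_estimated(part, probs)
        except ValueError:
            estimates[m] = None

    headline = estimates[mode]
    if headline is None:
        ci = (None, None)
        delta_tilde = None
    else:
        ci = joint_ci(
            part, mode=mode, alpha=alpha, n_draws=n_draws, seed=seed, fallback_rate=fallback
        )
        delta_tilde = headline - p_lo
    return JointPolypharmEstimate(
        pair=(ligand_a, ligand_b),
        partition=part,
        p_min=p_lo,
        p_max=p_hi,
        p_tilde_max_joint=estimates["joint"],
        p_tilde_max_indep=estimates["independence"],
        ci_low=ci[0],
        ci_high=ci[1],
        delta_e_max=p_hi - p_lo,
        delta_e_tilde=delta_tilde,
        prob_estimates=probs_by_mode[mode],
        alpha=alpha,
    )


def iter_pairs(ligands: list[str] | tuple[str, ...]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered ligand pairs, lexicographic in reference order."""
    return list(itertools.combinations(ligands, 2))


def joint_report(
    rel: TernaryRelation,
    ligand: str | None = None,
    mode: str = "joint",
    alpha: float = 0.05,
    n_draws: int = 4000,
    seed: int = 0,
    strict: bool = False,
) -> list[JointPolypharmEstimate]:
    """Joint estimates for all unordered pairs, or one ligand against all others.

    Per-pair Monte Carlo seeds are drawn deterministically from ``seed`` so
    the report is reproducible and pairs are independent.
    """
    if ligand is not None:
        rel.ligand_index(ligand)  # raises KeyError for unknown ids
        pairs = [(ligand, other) for other in rel.ligands if other != ligand]
    else:
        pairs = iter_pairs(rel.ligands)
    seeds = np.random.SeedSequence(seed).generate_state(max(len(pairs), 1)) % (2**31)
    return [
        joint_estimate(
            rel, a, b, mode=mode, alpha=alpha, n_draws=n_draws, seed=int(s), strict=strict
        )
        for (a, b), s in zip(pairs, seeds)
    ]
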