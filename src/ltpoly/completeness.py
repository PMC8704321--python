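"""Global and local data-completeness measures for ternary activity relations.

Global data completeness (GDC) is the fraction of ligand-target pairs whose
activity status is known (active or inactive).  The local analogue LDC(l)
restricts the fraction to one ligand's row, LDC(t) to one target's column.
Because every row has the same length, the mean of the per-ligand LDC values
equals the GDC exactly, and likewise for the per-target mean — an algebraic
identity this module verifies on every report it builds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .relation import ActivityState, TernaryRelation

__all__ = [
    "gdc",
    "ldc_ligand",
    "ldc_target",
    "completeness_report",
    "CompletenessReport",
    "check_summary_counts",
]

_NULL_CODE = 2  # see relation._CODE


def _known_mask(rel: TernaryRelation) -> np.ndarray:
    return rel.codes != _NULL_CODE


def gdc(rel: TernaryRelation) -> float:
    """Global data completeness: known pairs / all pairs, in [0, 1]."""
    n, m = rel.shape
    if n * m == 0:
        raise ValueError("relation is empty: GDC is undefined")
    return float(_known_mask(rel).sum() / (n * m))


def ldc_ligand(rel: TernaryRelation, ligand: str) -> float:
    """Local data completeness of one ligand's row."""
    if rel.n_targets == 0:
        raise ValueError("relation has no targets: LDC is undefined")
    row = _known_mask(rel)[rel.ligand_index(ligand)]
    return float(row.sum() / rel.n_targets)


def ldc_target(rel: TernaryRelation, target: str) -> float:
    """Local data completeness of one target's column."""
    if rel.n_ligands == 0:
        raise ValueError("relation has no ligands: LDC is undefined")
    col = _known_mask(rel)[:, rel.target_index(target)]
    return float(col.sum() / rel.n_ligands)


def _ecdf(values: np.ndarray) -> list[tuple[float, float]]:
    """Exact empirical step CDF over the observed values (no binning)."""
    if values.size == 0:
        return []
    uniq, counts = np.unique(values, return_counts=True)
    cum = np.cumsum(counts) / values.size
    return [(float(v), float(c)) for v, c in zip(uniq, cum)]


@dataclass(frozen=True)
class CompletenessReport:
    """Completeness summary: GDC, per-ligand/target LDC maps, ECDFs, moments."""

    gdc: float
    ldc_ligand: dict[str, float]
    ldc_target: dict[str, float]
    ligand_cdf: list[tuple[float, float]]
    target_cdf: list[tuple[float, float]]
    mean_ldc_ligand: float
    mean_ldc_target: float
    median_ldc_ligand: float
    median_ldc_target: float


def completeness_report(rel: TernaryRelation) -> CompletenessReport:
    """Full completeness report; checks the mean-LDC = GDC identity.

    Medians use the midpoint convention for even counts.
    """
    n, m = rel.shape
    if n * m == 0:
        raise ValueError("relation is empty: completeness is undefined")
    known = _known_mask(rel)
    ldc_l = known.sum(axis=1) / m
    ldc_t = known.sum(axis=0) / n
    g = float(known.sum() / (n * m))
    mean_l = float(ldc_l.mean())
    mean_t = float(ldc_t.mean())
    # the row/column means of the same indicator matrix must agree with its
    # grand mean; any violation indicates an internal bug
    for mean in (mean_l, mean_t):
        if abs(mean - g) > 1e-12 * max(1.0, abs(g)):
            raise AssertionError("mean LDC does not equal GDC: internal inconsistency")
    return CompletenessReport(
        gdc=g,
        ldc_ligand={l: float(v) for l, v in zip(rel.ligands, ldc_l)},
        ldc_target={t: float(v) for t, v in zip(rel.targets, ldc_t)},
        ligand_cdf=_ecdf(ldc_l),
        target_cdf=_ecdf(ldc_t),
        mean_ldc_ligand=mean_l,
        mean_ldc_target=mean_t,
        median_ldc_ligand=float(np.median(ldc_l)),
        median_ldc_target=float(np.median(ldc_t)),
    )


def check_summary_counts(
    n_ligands: int,
    n_targets: int,
    n_active: int,
    n_inactive: int,
    n_null: int | None = None,
    total: int | None = None,
) -> list[str]:
    """Validate externally supplied dataset summary counts.

    Published dataset summaries sometimes carry internal inconsistencies
    (class counts that do not sum to the printed total, or to the grid size).
    This check reports every such inconsistency as a human-readable message
    instead of silently reconciling the numbers; an empty list means the
    summary is internally consistent.
    """
    problems: list[str] = []
    grid = n_ligands * n_targets
    if total is not None and total != grid:
        problems.append(
            f"declared total {total} does not equal n_ligands*n_targets = {grid}"
        )
    if n_null is not None:
        class_sum = n_active + n_inactive + n_null
        if total is not None and class_sum != total:
            problems.append(
                f"class counts sum to {class_sum}, not the declared total {total}"
            )
        if class_sum != grid:
            problems.append(
                f"class counts sum to {class_sum}, not n_ligands*n_targets = {grid}"
            )
    if n_active + n_inactive > grid:
        problems.append(
            f"known pairs {n_active + n_inactive} exceed the grid size {grid}"
        )
    return problems
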