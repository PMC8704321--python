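"""Ternary ligand-target activity relations and their set-theoretic projections.

The central object is a total assignment of every (ligand, target) pair to
exactly one of three activity states: *active*, *inactive*, or *null*.  The
null state records the absence of an experimental determination and is
deliberately distinct from inactivity — sparse bioactivity panels consist
mostly of pairs that were simply never measured, and conflating the two
states corrupts every downstream statistic.

The relation over ligand set L and target set T partitions the L x T grid
into three classes.  Projections of the relation yield binary incidence
matrices (one per state) and per-ligand / per-target activity profiles: the
triple of target (or ligand) subsets S+, S-, S0 that partition the opposite
reference set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ActivityState",
    "TernaryRelation",
    "BinaryIncidence",
    "ProfileSet",
    "LigandProfile",
    "TargetProfile",
    "build_relation",
    "profile_intersection",
    "profile_union",
    "activity_fractions",
]


class ActivityState(enum.Enum):
    """The three mutually exclusive activity states of a ligand-target pair."""

    ACTIVE = "active"
    INACTIVE = "inactive"
    NULL = "null"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# integer codes used in the dense assignment matrix
_CODE = {ActivityState.ACTIVE: 0, ActivityState.INACTIVE: 1, ActivityState.NULL: 2}
_STATE_OF_CODE = {v: k for k, v in _CODE.items()}
STATE_ORDER = (ActivityState.ACTIVE, ActivityState.INACTIVE, ActivityState.NULL)


def _check_unique(ids: Sequence[str], kind: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {kind} identifier: {dup!r}")
    return ids


@dataclass(frozen=True)
class ProfileSet:
    """A subset of a fixed, ordered reference set (of targets or ligands).

    Set algebra is implemented on characteristic vectors: intersection is the
    elementwise minimum, union the elementwise maximum.  Operations between
    subsets of different reference sets are refused.
    """

    members: frozenset[str]
    reference: tuple[str, ...]

    def __post_init__(self) -> None:
        extra = self.members - set(self.reference)
        if extra:
            raise ValueError(f"members outside reference set: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.members

    def __iter__(self):
        # deterministic: reference order
        return (x for x in self.reference if x in self.members)

    def characteristic(self) -> np.ndarray:
        """0/1 indicator vector over the reference set, in reference order."""
        return np.fromiter(
            (1 if x in self.members else 0 for x in self.reference),
            dtype=np.int8,
            count=len(self.reference),
        )

    def _check_same_reference(self, other: "ProfileSet") -> None:
        if self.reference != other.reference:
            raise ValueError("profile sets are drawn from different reference sets")

    def intersection(self, other: "ProfileSet") -> "ProfileSet":
        self._check_same_reference(other)
        chi = np.minimum(self.characteristic(), other.characteristic())
        members = frozenset(x for x, c in zip(self.reference, chi) if c)
        return ProfileSet(members, self.reference)

    def union(self, other: "ProfileSet") -> "ProfileSet":
        self._check_same_reference(other)
        chi = np.maximum(self.characteristic(), other.characteristic())
        members = frozenset(x for x, c in zip(self.reference, chi) if c)
        return ProfileSet(members, self.reference)

    __and__ = intersection
    __or__ = union


def profile_intersection(a: ProfileSet, b: ProfileSet) -> ProfileSet:
    """Intersection of two profile subsets (elementwise min of indicators)."""
    return a.intersection(b)


def profile_union(a: ProfileSet, b: ProfileSet) -> ProfileSet:
    """Union of two profile subsets (elementwise max of indicators)."""
    return a.union(b)


@dataclass(frozen=True)
class BinaryIncidence:
    """Projection of one activity state onto the L x T grid: a 0/1 matrix."""

    state: ActivityState
    matrix: np.ndarray
    ligands: tuple[str, ...]
    targets: tuple[str, ...]

    @property
    def cardinality(self) -> int:
        return int(self.matrix.sum())


@dataclass(frozen=True)
class LigandProfile:
    """The target-based activity profile of one ligand: S+, S-, S0 partition T."""

    ligand: str
    active_targets: ProfileSet
    inactive_targets: ProfileSet
    null_targets: ProfileSet

    @property
    def targets(self) -> tuple[str, ...]:
        return self.active_targets.reference

    def counts(self) -> tuple[int, int, int]:
        return (len(self.active_targets), len(self.inactive_targets), len(self.null_targets))


@dataclass(frozen=True)
class TargetProfile:
    """The ligand-based activity profile of one target: partition of L."""

    target: str
    active_ligands: ProfileSet
    inactive_ligands: ProfileSet
    null_ligands: ProfileSet

    @property
    def ligands(self) -> tuple[str, ...]:
        return self.active_ligands.reference

    def counts(self) -> tuple[int, int, int]:
        return (len(self.active_ligands), len(self.inactive_ligands), len(self.null_ligands))


class TernaryRelation:
    """Total ternary relation over ligands x targets x {active, inactive, null}.

    Every one of the n*m pairs carries exactly one state; the three state
    classes therefore partition the grid, and their cardinalities sum to n*m.
    The three-dimensional relation is never materialised — the dense state
    matrix *is* the relation, and projections are state-equality masks.

    Parameters
    ----------
    ligands, targets : ordered sequences of unique string identifiers.
    codes : (n, m) int array with entries 0 (active), 1 (inactive), 2 (null).
    """

    def __init__(
        self,
        ligands: Sequence[str],
        targets: Sequence[str],
        codes: np.ndarray,
    ) -> None:
        self.ligands = _check_unique(ligands, "ligand")
        self.targets = _check_unique(targets, "target")
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(self.ligands), len(self.targets)):
            raise ValueError(
                f"assignment matrix shape {codes.shape} does not match "
                f"({len(self.ligands)}, {len(self.targets)})"
            )
        if codes.size and not np.isin(codes, (0, 1, 2)).all():
            raise ValueError("assignment codes must be 0 (active), 1 (inactive) or 2 (null)")
        self._codes = codes
        self._codes.setflags(write=False)
        self._ligand_index = {l: i for i, l in enumerate(self.ligands)}
        self._target_index = {t: j for j, t in enumerate(self.targets)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_triples(
        cls,
        status_triples: Iterable[tuple[str, str, ActivityState]],
        ligands: Sequence[str] | None = None,
        targets: Sequence[str] | None = None,
    ) -> "TernaryRelation":
        """Build a relation from (ligand, target, state) triples.

        Pairs not mentioned in the triples are *null* by definition: absence
        of data is the null state.  A pair mentioned twice is a hard error —
        conflict resolution belongs upstream, in measurement aggregation.
        Reference-set order follows the explicit lists when given, otherwise
        first appearance in the triples.
        """
        triples = [(str(l), str(t), s) for l, t, s in status_triples]
        for _, _, s in triples:
            if not isinstance(s, ActivityState):
                raise TypeError(f"status must be an ActivityState, got {s!r}")

        if ligands is None:
            seen: dict[str, None] = {}
            for l, _, _ in triples:
                seen.setdefault(l)
            ligand_list: Sequence[str] = list(seen)
        else:
            ligand_list = list(ligands)
        if targets is None:
            seen_t: dict[str, None] = {}
            for _, t, _ in triples:
                seen_t.setdefault(t)
            target_list: Sequence[str] = list(seen_t)
        else:
            target_list = list(targets)

        li = {l: i for i, l in enumerate(ligand_list)}
        ti = {t: j for j, t in enumerate(target_list)}
        codes = np.full((len(ligand_list), len(target_list)), _CODE[ActivityState.NULL], dtype=np.int8)
        assigned: set[tuple[str, str]] = set()
        for l, t, s in triples:
            if l not in li:
                raise ValueError(f"ligand {l!r} not in the declared ligand reference set")
            if t not in ti:
                raise ValueError(f"target {t!r} not in the declared target reference set")
            if (l, t) in assigned:
                raise ValueError(f"duplicate status for pair ({l!r}, {t!r})")
            assigned.add((l, t))
            codes[li[l], ti[t]] = _CODE[s]
        return cls(ligand_list, target_list, codes)

    @classmethod
    def from_state_matrix(
        cls,
        ligands: Sequence[str],
        targets: Sequence[str],
        states: np.ndarray,
    ) -> "TernaryRelation":
        """Build from an (n, m) matrix of ActivityState-coded integers."""
        return cls(ligands, targets, states)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_ligands, self.n_targets)

    @property
    def codes(self) -> np.ndarray:
        """Read-only (n, m) state-code matrix (0 active, 1 inactive, 2 null)."""
        return self._codes

    def ligand_index(self, ligand: str) -> int:
        try:
            return self._ligand_index[ligand]
        except KeyError:
            raise KeyError(f"unknown ligand {ligand!r}") from None

    def target_index(self, target: str) -> int:
        try:
            return self._target_index[target]
        except KeyError:
            raise KeyError(f"unknown target {target!r}") from None

    def state_of(self, ligand: str, target: str) -> ActivityState:
        return _STATE_OF_CODE[int(self._codes[self.ligand_index(ligand), self.target_index(target)])]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TernaryRelation):
            return NotImplemented
        return (
            self.ligands == other.ligands
            and self.targets == other.targets
            and np.array_equal(self._codes, other._codes)
        )

    def __repr__(self) -> str:
        a, i, n = self.class_cardinalities()
        return (
            f"TernaryRelation({self.n_ligands} ligands x {self.n_targets} targets: "
            f"{a} active, {i} inactive, {n} null)"
        )

    # -- cardinalities and projections ------------------------------------

    def class_cardinalities(self) -> tuple[int, int, int]:
        """Counts of (active, inactive, null) pairs; they sum to n*m."""
        counts = np.bincount(self._codes.ravel(), minlength=3)
        return (int(counts[0]), int(counts[1]), int(counts[2]))

    def project(self, state: ActivityState) -> BinaryIncidence:
        """Binary incidence of one state over the L x T grid.

        The projection is faithful: its cardinality equals the corresponding
        class cardinality, and the three incidences sum to the all-ones
        matrix.
        """
        matrix = (self._codes == _CODE[state]).astype(np.int8)
        return BinaryIncidence(state=state, matrix=matrix, ligands=self.ligands, targets=self.targets)

    def ligand_profile(self, ligand: str) -> LigandProfile:
        """The triple of target subsets (S+, S-, S0) for one ligand."""
        row = self._codes[self.ligand_index(ligand)]
        sets = []
        for state in STATE_ORDER:
            members = frozenset(t for t, c in zip(self.targets, row) if c == _CODE[state])
            sets.append(ProfileSet(members, self.targets))
        return LigandProfile(ligand, *sets)

    def target_profile(self, target: str) -> TargetProfile:
        """The triple of ligand subsets for one target (column profile)."""
        col = self._codes[:, self.target_index(target)]
        sets = []
        for state in STATE_ORDER:
            members = frozenset(l for l, c in zip(self.ligands, col) if c == _CODE[state])
            sets.append(ProfileSet(members, self.ligands))
        return TargetProfile(target, *sets)

    def to_triples(self, include_null: bool = False) -> list[tuple[str, str, ActivityState]]:
        """Enumerate (ligand, target, state) triples in reference order."""
        out = []
        for i, l in enumerate(self.ligands):
            for j, t in enumerate(self.targets):
                s = _STATE_OF_CODE[int(self._codes[i, j])]
                if include_null or s is not ActivityState.NULL:
                    out.append((l, t, s))
        return out


def build_relation(
    status_triples: Iterable[tuple[str, str, ActivityState]],
    ligands: Sequence[str] | None = None,
    targets: Sequence[str] | None = None,
) -> TernaryRelation:
    """Construct a :class:`TernaryRelation` from status triples.

    See :meth:`TernaryRelation.from_triples`.
    """
    return TernaryRelation.from_triples(status_triples, ligands=ligands, targets=targets)


def activity_fractions(profile: LigandProfile | TargetProfile) -> tuple[float, float, float]:
    """Fractions (f+, f-, f0) of active / inactive / null pairs in a profile.

    The three fractions are the class cardinalities divided by the size of the
    opposite reference set; they are non-negative and sum to one.
    """
    if isinstance(profile, LigandProfile):
        sets = (profile.active_targets, profile.inactive_targets, profile.null_targets)
    else:
        sets = (profile.active_ligands, profile.inactive_ligands, profile.null_ligands)
    total = len(sets[0].reference)
    if total == 0:
        raise ValueError("profile has an empty reference set")
    return tuple(len(s) / total for s in sets)  # type: ignore[return-value]
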