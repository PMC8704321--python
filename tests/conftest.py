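import numpy as np
import pytest

from ltpoly import ActivityState, TernaryRelation, build_relation

A, I, N = ActivityState.ACTIVE, ActivityState.INACTIVE, ActivityState.NULL

TOY_TRIPLES = [
    ("l1", "t1", A),
    ("l1", "t2", A),
    ("l1", "t3", I),
    ("l2", "t2", A),
    ("l2", "t4", A),
    ("l2", "t5", I),
]
TOY_TARGETS = ["t1", "t2", "t3", "t4", "t5"]


@pytest.fixture
def toy_relation() -> TernaryRelation:
    """Two ligands over five targets; six measured pairs, four null."""
    return build_relation(TOY_TRIPLES, ligands=["l1", "l2"], targets=TOY_TARGETS)


def random_relation(rng: np.random.Generator, n: int, m: int, p_null: float = 0.4) -> TernaryRelation:
    """A random ternary relation with roughly p_null null pairs."""
    p_known = (1 - p_null) / 2
    codes = rng.choice([0, 1, 2], size=(n, m), p=[p_known, p_known, p_null]).astype(np.int8)
    ligands = [f"l{i}" for i in range(n)]
    targets = [f"t{j}" for j in range(m)]
    return TernaryRelation(ligands, targets, codes)
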