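import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pooltox import ExpressionStudy, SyntheticConfig, generate_study

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_study(values: dict[str, dict[str, list[float]]], genes: list[str]) -> ExpressionStudy:
    """Build a study from {lot: {condition: per-replicate offsets}} where every
    gene g gets value offset + i for the i-th gene (keeps genes distinct)."""
    cols, ids, lots, conds, reps = [], [], [], [], []
    for lot, arms in values.items():
        for cond, reels in arms.items():
            for r, base in enumerate(reels, start=1):
                cols.append([base + i for i in range(len(genes))])
                ids.append(f"{lot}_{cond}_{r}")
                lots.append(lot)
                conds.append(cond)
                reps.append(r)
    expr = pd.DataFrame(np.array(cols).T, index=pd.Index(genes, name="gene"), columns=ids)
    sheet = pd.DataFrame(
        {"lot": lots, "condition": conds, "replicate": reps},
        index=pd.Index(ids, name="sample_id"),
    )
    return ExpressionStudy(expr, sheet)


@pytest.fixture
def two_lot_study() -> ExpressionStudy:
    return make_study(
        {
            "A": {"control": [5.0, 5.0, 5.2], "high": [6.0, 6.0, 6.1]},
            "B": {"control": [4.0, 4.1, 4.2], "high": [4.0, 4.1, 4.2]},
        },
        genes=["g1", "g2", "g3", "g4"],
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """One modest synthetic study with injected signal, reused across tests."""
    cfg = SyntheticConfig(
        n_genes=1200,
        n_core_de=80,
        n_lot_specific_de=120,
        injected_sets=[("inj_strong", 1.0)],
        n_null_sets=3,
        seed=11,
    )
    return cfg, generate_study(cfg)
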