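import json
from pathlib import Path

import numpy as np
import pytest

from sxc.pipeline import PipelineConfig, run_pipeline
from sxc.synthetic import SyntheticPairSpec, generate_class_pair


def naive_tanimoto(x, y):
    """Independent pairwise Tanimoto oracle (pure-python hand count)."""
    c = sum(1 for a, b in zip(x, y) if a == 1 and b == 1)
    u = sum(1 for a, b in zip(x, y) if a == 1 or b == 1)
    return c / u if u else 0.0


@pytest.fixture(scope="session")
def separable_pair():
    """Strongly separated two-class dataset (disjoint planted bits, no noise)."""
    spec = SyntheticPairSpec(
        n_features=32,
        n_per_class=80,
        planted_a=frozenset(range(6)),
        planted_b=frozenset(range(6, 12)),
        p_planted_on=1.0,
        p_cross_on=0.0,
        p_background=0.05,
        noise_rate=0.0,
        seed=11,
    )
    return generate_class_pair(spec)


#: desk-scale run configuration shared by the acceptance suite; the full
#: default grids are thinned (RF tree count, search budget, explained-subset
#: size) to fit the offline CPU budget.
DESK_CONFIG = PipelineConfig(
    master_seed=20230412,
    n_features=64,
    planted_per_class=8,
    p_planted_on=0.8,
    p_cross_on=0.1,
    p_background=0.1,
    noise_rate=0.05,
    pool_per_class=460,
    class_ids=("A", "B"),
    size_schedule=(5, 8, 12, 16, 24, 32, 48, 64, 96, 128, 192, 256),
    n_trials=3,
    test_per_class=100,
    algorithms=("RF", "SVM"),
    n_search=8,
    rf_grid={
        "n_estimators": [100],
        "criterion": ["gini", "entropy"],
        "min_samples_split": [2, 3, 4, 5],
        "max_features": ["sqrt", "log2"],
        "bootstrap": [True, False],
    },
    explain_per_class=12,
    rf_background=25,
)


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory) -> tuple[PipelineConfig, Path]:
    """One full desk-scale pipeline run shared across acceptance tests."""
    out = tmp_path_factory.mktemp("desk_run")
    run_dir = run_pipeline(DESK_CONFIG, out / "run")
    return DESK_CONFIG, run_dir


@pytest.fixture(scope="session")
def desk_summary(desk_run):
    _, run_dir = desk_run
    return json.loads((run_dir / "summary.json").read_text())


def load_explanation_values(run_dir: Path, job_id: str):
    import pandas as pd

    df = pd.read_csv(run_dir / "explanations" / f"{job_id}.csv")
    value_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    return df, df[value_cols].to_numpy(dtype=np.float64)
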