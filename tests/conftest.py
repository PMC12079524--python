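import numpy as np
import pandas as pd
import pytest

from coexmod import ExpressionMatrix, SyntheticSpec, simulate_dataset


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 4 samples with exact values for round-trip checks."""
    df = pd.DataFrame(
        [[1.25, 2.5, 3.75, 4.0],
         [0.1, 0.2, 0.3, 0.4],
         [5.0, 5.0, 4.0, 3.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def random_expr() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    df = pd.DataFrame(rng.normal(8.0, 1.0, size=(30, 20)),
                      index=[f"g{i:02d}" for i in range(30)],
                      columns=[f"s{j:02d}" for j in range(20)])
    return ExpressionMatrix(df)


def small_spec(seed: int = 0, **kw) -> SyntheticSpec:
    """One 50-gene module (rho 0.64, strong core-periphery gradient) in a
    1000-gene universe: the module-preservation scenario."""
    defaults = dict(n_samples=40, module_sizes=(50,), rho=(0.64,),
                    n_background=950, driver_plan=((1, 0.5),),
                    candidate_plan=(1, 0.64, 0.4, 0.0),
                    de_targets="none", rho_jitter=0.45, seed=seed)
    defaults.update(kw)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic cohort at generator defaults (shared across
    tests; treat as read-only)."""
    return simulate_dataset(SyntheticSpec(), seed=1)
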