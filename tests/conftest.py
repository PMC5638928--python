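import numpy as np
import pandas as pd
import pytest

from trajweight.margins import MarginSpec, acs_margins, child_cohort_margins


def make_cohort(
    categories: dict[str, list[str]],
    ages: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    n: int | None = None,
    **extra_columns,
) -> pd.DataFrame:
    """Small hand-built cohort frame with the required schema columns."""
    if n is None:
        n = len(next(iter(categories.values())))
    if ages is None:
        ages = np.linspace(3, 18, n)
    data = {"participant_id": [f"S{i}" for i in range(n)], "age": ages}
    for var, labels in categories.items():
        data[var] = labels
    for var in ("race", "sex", "parental_education", "income", "scanner"):
        if var not in data:
            data[var] = ["x"] * n
    data.update(extra_columns)
    return pd.DataFrame(data)


def counts_cohort(margins: MarginSpec, n: int) -> pd.DataFrame:
    """Deterministic cohort whose sample proportions equal the margins exactly.

    Requires every ``proportion * n`` to be an integer (e.g. n = 1000 with
    three-decimal proportions).
    """
    columns: dict[str, list[str]] = {}
    for var in margins.variable_names:
        labels: list[str] = []
        for cat in margins.categories(var):
            k = margins.proportion(var, cat) * n
            assert abs(k - round(k)) < 1e-9, (var, cat, k)
            labels.extend([cat] * round(k))
        assert len(labels) == n
        columns[var] = labels
    rng = np.random.default_rng(0)
    # independent shuffles so variables are not artificially aligned
    for var in columns:
        perm = rng.permutation(n)
        columns[var] = [columns[var][i] for i in perm]
    return make_cohort(columns, ages=rng.uniform(3, 18, n), n=n)


@pytest.fixture(scope="session")
def sample_margins() -> MarginSpec:
    return child_cohort_margins()


@pytest.fixture(scope="session")
def target_margins() -> MarginSpec:
    return acs_margins()


@pytest.fixture(scope="session")
def exact_margin_cohort(sample_margins) -> pd.DataFrame:
    """n = 1000 cohort with sample proportions exactly at the cohort margins."""
    return counts_cohort(sample_margins, 1000)
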