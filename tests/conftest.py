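import numpy as np
import pytest

from paincat.calibration import CalibrationConfig, fit_grm
from paincat.item_model import Item, ItemBank
from paincat.synthetic_sim import (
    SLEEP_TEMPLATE,
    BankTemplate,
    generate_bank,
    generate_cohort,
)


@pytest.fixture(scope="session")
def toy_item() -> Item:
    return Item("toy", "X", 4, 1.7, (-1.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def dichotomous_item() -> Item:
    return Item("dich", "X", 2, 2.0, (0.0,))


@pytest.fixture(scope="session")
def toy_bank(toy_item, dichotomous_item) -> ItemBank:
    extra = Item("mid", "Y", 3, 1.0, (-0.5, 0.5))
    return ItemBank("toy", (toy_item, dichotomous_item, extra))


@pytest.fixture(scope="session")
def sleep_bank() -> ItemBank:
    return generate_bank(SLEEP_TEMPLATE, seed=7)


@pytest.fixture(scope="session")
def small_bank() -> ItemBank:
    tpl = BankTemplate(
        n_items=8,
        category_counts=(3,) * 8,
        discrimination_mix={"moderate": 0.5, "high": 0.25, "very_high": 0.25},
    )
    return generate_bank(tpl, seed=2)


@pytest.fixture(scope="session")
def cohort1000(sleep_bank):
    return generate_cohort(sleep_bank, n=1000, seed=8)


@pytest.fixture(scope="session")
def fit1000(cohort1000):
    cohort, _ = cohort1000
    return fit_grm(cohort, CalibrationConfig(tol=1e-3))


@pytest.fixture(scope="session")
def cohort300(sleep_bank):
    return generate_cohort(sleep_bank, n=300, seed=42)


def random_item(rng: np.random.Generator, max_k: int = 5) -> Item:
    """A random well-formed GRM item for property tests."""
    k = int(rng.integers(2, max_k + 1))
    a = float(rng.uniform(0.3, 2.8))
    b = np.sort(rng.uniform(-2.5, 2.5, size=k - 1))
    b += np.arange(k - 1) * 1e-2  # keep strictly increasing
    return Item(f"rnd{rng.integers(1 << 30)}", "R", k, a, tuple(b))
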