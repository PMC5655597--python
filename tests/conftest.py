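import numpy as np
import pytest

from mcatsim.mgrm import ItemBank, ItemParameters
from mcatsim.synthetic import BankRecipe, generate_item_bank


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_item(item_id="i1", domain=1, alpha=1.5, betas=(-1.0, 0.0, 1.0)):
    return ItemParameters(item_id=item_id, domain=domain, alpha=alpha, betas=betas)


def make_bank(items, n_dimensions=None, correlation=None, labels=None):
    D = n_dimensions or max(it.domain for it in items)
    if correlation is None:
        correlation = np.eye(D) + 0.5 * (np.ones((D, D)) - np.eye(D))
    if labels is None:
        labels = tuple(f"dom{d}" for d in range(1, D + 1))
    return ItemBank(items=items, correlation=correlation, domain_labels=labels)


def random_item(rng, item_id="i", domain=1, n_categories=None):
    m = (n_categories or int(rng.integers(2, 6))) - 1
    alpha = float(rng.uniform(0.8, 3.5))
    betas = np.sort(rng.uniform(-3, 3, size=m))
    betas += 0.25 * np.arange(m)  # guarantee strict ordering
    return ItemParameters(item_id=item_id, domain=domain, alpha=alpha,
                          betas=tuple(betas))


@pytest.fixture
def small_bank(rng):
    """20 items over 2 correlated dimensions."""
    items = [random_item(rng, item_id=f"s{k}", domain=1 + k % 2) for k in range(20)]
    corr = np.array([[1.0, 0.6], [0.6, 1.0]])
    return make_bank(items, n_dimensions=2, correlation=corr)


@pytest.fixture(scope="session")
def default_bank():
    """The 194-item synthetic bank from the default recipe."""
    return generate_item_bank(BankRecipe(), np.random.default_rng(2024))


@pytest.fixture
def unidim_bank_factory():
    """Single-dimension banks for grid-search oracle tests."""

    def build(items):
        return ItemBank(items=items, correlation=np.array([[1.0]]),
                        domain_labels=("only",))

    return build
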