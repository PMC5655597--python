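"""Between-item multidimensional graded response model (GRM).

Each item loads on exactly one latent dimension with discrimination
``alpha`` and ordered thresholds ``betas`` on the ``alpha * theta - beta``
metric.  Multidimensionality enters only through the correlation matrix of
the latent traits, stored on the :class:`ItemBank`.

The category probabilities for an item with ``m + 1`` categories are

    P_0 = 1 - F(z - beta_1)
    P_j = F(z - beta_j) - F(z - beta_{j+1})   for 0 < j < m
    P_m = F(z - beta_m)

where ``F`` is the standard logistic function and ``z = alpha * theta_d``
is the linear predictor on the item's own dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "PROB_FLOOR",
    "ItemParameters",
    "ItemBank",
    "category_probabilities",
    "simulate_response",
    "response_log_likelihood",
    "item_information",
]

#: Floor applied to category probabilities before they enter a logarithm
#: or a denominator.  Thresholds span roughly +-7.7, so extreme thetas can
#: push a category's probability below double-precision resolution.
PROB_FLOOR = 1e-10

MAX_CATEGORIES = 5


@dataclass(frozen=True)
class ItemParameters:
    """One item: dimension membership, discrimination, ordered thresholds.

    Parameters
    ----------
    item_id:
        Unique identifier within its bank.
    domain:
        1-based index of the single latent dimension the item loads on.
    alpha:
        Positive discrimination on the item's own dimension; all other
        loadings are zero (between-item multidimensionality).
    betas:
        Strictly increasing thresholds; ``len(betas) = n_categories - 1``.
    """

    item_id: str
    domain: int
    alpha: float
    betas: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))
        if self.domain < 1:
            raise ValueError(f"item {self.item_id!r}: domain must be >= 1, got {self.domain}")
        if not self.alpha > 0:
            raise ValueError(f"item {self.item_id!r}: alpha must be > 0, got {self.alpha}")
        m = len(self.betas)
        if not 1 <= m <= MAX_CATEGORIES - 1:
            raise ValueError(
                f"item {self.item_id!r}: expected 1..{MAX_CATEGORIES - 1} thresholds, got {m}"
            )
        if any(b2 <= b1 for b1, b2 in zip(self.betas, self.betas[1:])):
            raise ValueError(
                f"item {self.item_id!r}: thresholds must be strictly increasing, got {self.betas}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.betas) + 1


@dataclass
class ItemBank:
    """A multidimensional item bank plus the latent-trait correlation matrix."""

    items: list[ItemParameters]
    correlation: np.ndarray
    domain_labels: tuple[str, ...]

    # vectorised views, built once in __post_init__
    alphas: np.ndarray = field(init=False, repr=False)
    domains0: np.ndarray = field(init=False, repr=False)  # 0-based
    n_cats: np.ndarray = field(init=False, repr=False)
    betas_padded: np.ndarray = field(init=False, repr=False)  # (n, MAX-1), +inf padding

    def __post_init__(self) -> None:
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.domain_labels = tuple(self.domain_labels)
        D = self.n_dimensions
        corr = self.correlation
        if corr.shape != (D, D):
            raise ValueError(f"correlation must be {D}x{D}, got {corr.shape}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")

        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in bank")
        for it in self.items:
            if it.domain > D:
                raise ValueError(
                    f"item {it.item_id!r}: domain {it.domain} exceeds bank dimensionality {D}"
                )

        n = len(self.items)
        self.alphas = np.array([it.alpha for it in self.items], dtype=float)
        self.domains0 = np.array([it.domain - 1 for it in self.items], dtype=np.intp)
        self.n_cats = np.array([it.n_categories for it in self.items], dtype=np.intp)
        self.betas_padded = np.full((n, MAX_CATEGORIES - 1), np.inf)
        for k, it in enumerate(self.items):
            self.betas_padded[k, : len(it.betas)] = it.betas
        self._index = {iid: k for k, iid in enumerate(ids)}

    @property
    def n_dimensions(self) -> int:
        return len(self.domain_labels)

    def __len__(self) -> int:
        return len(self.items)

    def index_of(self, item_id: str) -> int:
        try:
            return self._index[item_id]
        except KeyError:
            raise KeyError(f"unknown item id {item_id!r}") from None

    def item(self, item_id: str) -> ItemParameters:
        return self.items[self.index_of(item_id)]

    def domain_indices(self, domain: int) -> np.ndarray:
        """0-based positions of the items loading on 1-based ``domain``."""
        return np.flatnonzero(self.domains0 == domain - 1)


def _check_theta(theta: Sequence[float], n_dimensions: int) -> np.ndarray:
    th = np.asarray(theta, dtype=float)
    if th.shape != (n_dimensions,):
        raise ValueError(f"theta must have shape ({n_dimensions},), got {th.shape}")
    return th


def _extended_cumulative(item: ItemParameters, z: float) -> np.ndarray:
    """[1, F(z - b_1), ..., F(z - b_m), 0] — cumulative category curves."""
    cum = expit(z - np.asarray(item.betas))
    return np.concatenate(([1.0], cum, [0.0]))


def category_probabilities(item: ItemParameters, theta: Sequence[float]) -> np.ndarray:
    """Category response probabilities for one item at a trait vector.

    Returns a length-``n_categories`` vector on the probability simplex.
    ``theta`` must be a full trait vector; only the coordinate of the
    item's own dimension enters the linear predictor.
    """
    th = np.asarray(theta, dtype=float)
    if th.ndim != 1 or th.size < item.domain:
        raise ValueError(
            f"theta must be 1-d with at least {item.domain} coordinates, got shape {th.shape}"
        )
    z = item.alpha * th[item.domain - 1]
    ext = _extended_cumulative(item, z)
    return -np.diff(ext)


def simulate_response(
    item: ItemParameters, theta: Sequence[float], rng: np.random.Generator
) -> int:
    """Draw a category index in ``0..m`` from the model at ``theta``."""
    probs = category_probabilities(item, theta)
    # guard against tiny negative rounding before the cumulative draw
    cdf = np.cumsum(np.clip(probs, 0.0, 1.0))
    u = rng.uniform() * cdf[-1]
    return int(np.searchsorted(cdf, u, side="right").clip(0, len(probs) - 1))


def response_log_likelihood(
    bank: ItemBank,
    administered: Sequence[tuple[str, int]],
    theta: Sequence[float],
) -> float:
    """Sum of log category probabilities of the observed responses.

    Probabilities are floored at :data:`PROB_FLOOR`, so the result is
    always finite.  An empty response pattern has log-likelihood 0.
    """
    th = _check_theta(theta, bank.n_dimensions)
    if not administered:
        return 0.0
    total = 0.0
    for item_id, cat in administered:
        item = bank.item(item_id)
        if not 0 <= cat < item.n_categories:
            raise ValueError(
                f"category {cat} out of range for item {item_id!r} "
                f"with {item.n_categories} categories"
            )
        p = category_probabilities(item, th)[cat]
        total += float(np.log(max(p, PROB_FLOOR)))
    return total


def scalar_information(item: ItemParameters, z: float) -> float:
    """GRM Fisher information of the linear predictor ``z = alpha*theta_d``.

    ``s = sum_j (F'_j - F'_{j+1})^2 / P_j`` with ``F'_j = F_j (1 - F_j)``
    evaluated at ``z - beta_j`` and boundary conventions ``F_0 = 1``,
    ``F_{m+1} = 0``.  Multiplying by ``alpha**2`` gives the information
    about ``theta_d`` itself.
    """
    ext = _extended_cumulative(item, z)
    dpsi = ext * (1.0 - ext)  # zero at both boundaries
    probs = np.maximum(-np.diff(ext), PROB_FLOOR)
    return float(np.sum(np.diff(dpsi) ** 2 / probs))


def item_information(item: ItemParameters, theta: Sequence[float]) -> np.ndarray:
    """Fisher information matrix contribution of one item at ``theta``.

    Rank <= 1 and PSD: ``s(z) * a a^T`` where ``a`` has the single nonzero
    entry ``alpha`` on the item's dimension.
    """
    th = np.asarray(theta, dtype=float)
    if th.ndim != 1 or th.size < item.domain:
        raise ValueError(
            f"theta must be 1-d with at least {item.domain} coordinates, got shape {th.shape}"
        )
    D = th.size
    z = item.alpha * th[item.domain - 1]
    s = scalar_information(item, z)
    info = np.zeros((D, D))
    d = item.domain - 1
    info[d, d] = s * item.alpha**2
    return info


# ---------------------------------------------------------------------------
# vectorised kernels used by the estimation and selection hot loops
# ---------------------------------------------------------------------------


def bank_extended_cumulative(bank: ItemBank, idx: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Extended cumulative curves for the items at positions ``idx``.

    Returns an ``(len(idx), MAX_CATEGORIES + 1)`` array whose row k is
    ``[1, F(z_k - b_1), ..., 0-padding]``; the +inf threshold padding makes
    every column beyond an item's last threshold exactly 0.
    """
    z = bank.alphas[idx] * theta[bank.domains0[idx]]
    ext = np.empty((idx.size, MAX_CATEGORIES + 1))
    ext[:, 0] = 1.0
    ext[:, 1:-1] = expit(z[:, None] - bank.betas_padded[idx])
    ext[:, -1] = 0.0
    return ext


def bank_scalar_information(bank: ItemBank, idx: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Vectorised :func:`scalar_information` for the items at ``idx``."""
    ext = bank_extended_cumulative(bank, idx, theta)
    dpsi = ext * (1.0 - ext)
    probs = np.maximum(-np.diff(ext, axis=1), PROB_FLOOR)
    return np.sum(np.diff(dpsi, axis=1) ** 2 / probs, axis=1)
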