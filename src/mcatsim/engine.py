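"""The adaptive test loop.

A test starts with one uniformly random item per domain (in domain order),
then repeats: check per-dimension SE termination, pick the eligible item
maximising the determinant of the posterior information matrix, simulate
the response at the respondent's true trait vector, re-estimate.  Items
from a terminated dimension are no longer eligible, but the determinant
objective is always evaluated over the full D x D posterior information.

Selection uses the rank-1 determinant identity

    det(J + s * a a') = det(J) * (1 + s * a' J^{-1} a)

so a full scan of the bank needs a single D x D inverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .estimation import PosteriorState, build_state
from .mgrm import ItemBank, bank_scalar_information, simulate_response

__all__ = ["CATConfig", "CATResult", "BankExhaustedError", "select_next_item",
           "administer_and_update", "run_cat"]


class BankExhaustedError(RuntimeError):
    """No eligible item remains (all administered or all domains terminated)."""


@dataclass(frozen=True)
class CATConfig:
    """Tuning knobs of a single adaptive test."""

    se_threshold: float = 0.316
    n_initial_per_domain: int = 1
    max_length: int | None = None  # None -> bank size
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.se_threshold > 0:
            raise ValueError("se_threshold must be positive")
        if self.n_initial_per_domain < 1:
            raise ValueError("n_initial_per_domain must be >= 1")

    def resolved_max_length(self, bank: ItemBank) -> int:
        n = len(bank) if self.max_length is None else self.max_length
        if n < bank.n_dimensions * self.n_initial_per_domain:
            raise ValueError("max_length must cover the initial items")
        return n


@dataclass
class CATResult:
    """Outcome of one simulated adaptive test.

    The first ``n_initial`` entries of ``administered`` are the random
    starting items (one per domain); they count toward ``test_length``
    but are excluded from item-usage statistics downstream.
    """

    respondent_id: str
    true_theta: np.ndarray
    administered: list[tuple[str, int]]
    theta_final: np.ndarray
    se_final: np.ndarray
    converged: bool
    grid_value: float | None = None
    n_initial: int = 0

    @property
    def test_length(self) -> int:
        return len(self.administered)

    @property
    def administered_ids(self) -> list[str]:
        return [iid for iid, _ in self.administered]


def _eligible_mask(state: PosteriorState, bank: ItemBank) -> np.ndarray:
    mask = np.ones(len(bank), dtype=bool)
    for iid in state.administered_ids:
        mask[bank.index_of(iid)] = False
    for d in state.terminated_dims:
        mask &= bank.domains0 != d
    return mask


def select_next_item(
    state: PosteriorState, bank: ItemBank, rng: np.random.Generator
) -> str:
    """Eligible item maximising ``det(J + item information)`` at theta-hat.

    Eligibility excludes already-administered items and all items of
    terminated dimensions.  Exact criterion ties are broken uniformly at
    random from ``rng``.
    """
    mask = _eligible_mask(state, bank)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise BankExhaustedError("no eligible item to select")
    s = bank_scalar_information(bank, idx, state.theta_hat) * bank.alphas[idx] ** 2
    inv_diag = np.diag(np.linalg.inv(state.posterior_info))
    crit = s * inv_diag[bank.domains0[idx]]  # det ratio minus 1, monotone equivalent
    best = np.flatnonzero(crit == crit.max())
    choice = idx[best[0] if best.size == 1 else rng.choice(best)]
    return bank.items[choice].item_id


def administer_and_update(
    state: PosteriorState,
    bank: ItemBank,
    item_id: str,
    category: int,
    prior_correlation: np.ndarray,
    se_threshold: float,
) -> PosteriorState:
    """Append one response and rebuild the posterior state."""
    if item_id in state.administered_ids:
        raise ValueError(f"item {item_id!r} already administered")
    administered = state.administered + [(item_id, category)]
    return build_state(
        bank,
        administered,
        prior_correlation,
        se_threshold,
        theta_start=state.theta_hat,
    )


def run_cat(
    bank: ItemBank,
    true_theta: Sequence[float],
    config: CATConfig,
    rng: np.random.Generator | None = None,
    respondent_id: str = "sim",
) -> CATResult:
    """Simulate one full adaptive test for a respondent at ``true_theta``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    theta_true = np.asarray(true_theta, dtype=float)
    prior = bank.correlation
    max_length = config.resolved_max_length(bank)

    state = build_state(bank, [], prior, config.se_threshold)

    # one random unadministered item per domain, in domain order
    for d in range(1, bank.n_dimensions + 1):
        pool = bank.domain_indices(d)
        for _ in range(config.n_initial_per_domain):
            avail = [i for i in pool if bank.items[i].item_id not in state.administered_ids]
            if not avail:
                break
            i = avail[rng.integers(len(avail))]
            item = bank.items[i]
            cat = simulate_response(item, theta_true, rng)
            state = administer_and_update(
                state, bank, item.item_id, cat, prior, config.se_threshold
            )
    n_initial = len(state.administered)

    all_dims = frozenset(range(bank.n_dimensions))
    while state.terminated_dims != all_dims and len(state.administered) < max_length:
        try:
            item_id = select_next_item(state, bank, rng)
        except BankExhaustedError:
            break
        item = bank.item(item_id)
        cat = simulate_response(item, theta_true, rng)
        state = administer_and_update(state, bank, item_id, cat, prior, config.se_threshold)

    return CATResult(
        respondent_id=respondent_id,
        true_theta=theta_true,
        administered=state.administered,
        theta_final=state.theta_hat,
        se_final=state.se,
        converged=state.terminated_dims == all_dims,
        n_initial=n_initial,
    )
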