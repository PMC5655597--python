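"""MAP trait estimation with a multivariate-normal prior.

The latent trait is estimated as the mode of

    log L(theta | responses) - 0.5 * theta' Phi^{-1} theta

where ``Phi`` is the latent-trait correlation matrix used as the prior
covariance (prior mean zero, unit variances).  The posterior information
matrix ``J = Phi^{-1} + sum_i I_i(theta_hat)`` drives both the reported
standard errors and determinant-based item selection downstream.

Expected (Fisher) item information is used throughout — in the Newton
Hessian, in ``J``, and in selection — so the three stay consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mgrm import (
    PROB_FLOOR,
    ItemBank,
    bank_extended_cumulative,
    bank_scalar_information,
)

__all__ = [
    "MAPConvergenceError",
    "PosteriorState",
    "map_estimate",
    "posterior_information",
    "standard_errors",
    "build_state",
]

_MAX_ITER = 100
_STEP_TOL = 1e-6


class MAPConvergenceError(RuntimeError):
    """Newton iteration failed to converge; carries the last iterate."""

    def __init__(self, theta: np.ndarray, grad_norm: float, n_iter: int):
        self.theta = theta
        self.grad_norm = grad_norm
        self.n_iter = n_iter
        super().__init__(
            f"MAP estimation did not converge after {n_iter} iterations "
            f"(gradient norm {grad_norm:.3e})"
        )


@dataclass
class PosteriorState:
    """Snapshot of a respondent's posterior after some administrations.

    ``terminated_dims`` holds the 0-based dimensions whose standard error
    is below the termination threshold used to build the state.
    """

    administered: list[tuple[str, int]]
    theta_hat: np.ndarray
    posterior_info: np.ndarray
    se: np.ndarray
    terminated_dims: frozenset[int]

    @property
    def administered_ids(self) -> set[str]:
        return {iid for iid, _ in self.administered}


def _administered_arrays(
    bank: ItemBank, administered: Sequence[tuple[str, int]]
) -> tuple[np.ndarray, np.ndarray]:
    idx = np.empty(len(administered), dtype=np.intp)
    cats = np.empty(len(administered), dtype=np.intp)
    for k, (item_id, cat) in enumerate(administered):
        i = bank.index_of(item_id)
        if not 0 <= cat < bank.n_cats[i]:
            raise ValueError(
                f"category {cat} out of range for item {item_id!r} "
                f"with {bank.n_cats[i]} categories"
            )
        idx[k] = i
        cats[k] = cat
    return idx, cats


def _posterior_quantities(
    bank: ItemBank,
    idx: np.ndarray,
    cats: np.ndarray,
    theta: np.ndarray,
    prior_precision: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-posterior, its gradient, and the expected information, in one pass."""
    D = theta.size
    grad = -prior_precision @ theta
    logpost = -0.5 * float(theta @ prior_precision @ theta)
    J = prior_precision.copy()
    if idx.size:
        ext = bank_extended_cumulative(bank, idx, theta)
        rows = np.arange(idx.size)
        p = np.maximum(ext[rows, cats] - ext[rows, cats + 1], PROB_FLOOR)
        dpsi = ext * (1.0 - ext)
        # d log P_c / d theta_d = alpha * (F'_c - F'_{c+1}) / P_c on the item's dim
        g_item = bank.alphas[idx] * (dpsi[rows, cats] - dpsi[rows, cats + 1]) / p
        doms = bank.domains0[idx]
        grad += np.bincount(doms, weights=g_item, minlength=D)
        logpost += float(np.sum(np.log(p)))
        probs = np.maximum(ext[:, :-1] - ext[:, 1:], PROB_FLOOR)
        num = dpsi[:, 1:] - dpsi[:, :-1]
        s = np.sum(num * num / probs, axis=1) * bank.alphas[idx] ** 2
        np.add.at(J, (doms, doms), s)
    return logpost, grad, J


def _expected_information(
    bank: ItemBank, idx: np.ndarray, theta: np.ndarray, prior_precision: np.ndarray
) -> np.ndarray:
    J = prior_precision.copy()
    if idx.size:
        s = bank_scalar_information(bank, idx, theta) * bank.alphas[idx] ** 2
        np.add.at(J, (bank.domains0[idx], bank.domains0[idx]), s)
    return J


def map_estimate(
    bank: ItemBank,
    administered: Sequence[tuple[str, int]],
    prior_correlation: np.ndarray,
    theta_start: np.ndarray | None = None,
) -> np.ndarray:
    """Maximum a posteriori trait estimate given the responses so far.

    Newton–Raphson on the log-posterior with the expected-information
    Hessian and step-halving on non-increase; warm-startable via
    ``theta_start``.  With no responses the prior mode (zero) is returned.
    """
    D = bank.n_dimensions
    prior = np.asarray(prior_correlation, dtype=float)
    prior_precision = np.linalg.inv(prior)
    if not administered:
        return np.zeros(D)
    idx, cats = _administered_arrays(bank, administered)
    theta = np.zeros(D) if theta_start is None else np.asarray(theta_start, dtype=float).copy()

    logpost, grad, J = _posterior_quantities(bank, idx, cats, theta, prior_precision)
    for _ in range(_MAX_ITER):
        step = np.linalg.solve(J, grad)
        # step-halving: the log-posterior must not decrease
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            lp_new, g_new, J_new = _posterior_quantities(
                bank, idx, cats, cand, prior_precision
            )
            if lp_new >= logpost - 1e-12:
                break
            scale *= 0.5
        theta, logpost, grad, J = cand, lp_new, g_new, J_new
        if np.max(np.abs(scale * step)) < _STEP_TOL:
            return theta
    raise MAPConvergenceError(theta, float(np.linalg.norm(grad)), _MAX_ITER)


def posterior_information(
    bank: ItemBank,
    administered: Sequence[tuple[str, int]],
    theta_hat: Sequence[float],
    prior_correlation: np.ndarray,
) -> np.ndarray:
    """``Phi^{-1} + sum of administered items' Fisher information`` at ``theta_hat``."""
    prior = np.asarray(prior_correlation, dtype=float)
    if np.linalg.matrix_rank(prior) < prior.shape[0]:
        raise np.linalg.LinAlgError("prior correlation matrix is singular")
    prior_precision = np.linalg.inv(prior)
    th = np.asarray(theta_hat, dtype=float)
    idx, _ = _administered_arrays(bank, administered)
    return _expected_information(bank, idx, th, prior_precision)


def standard_errors(posterior_info: np.ndarray) -> np.ndarray:
    """Square roots of the diagonal of the inverse posterior information."""
    J = np.asarray(posterior_info, dtype=float)
    try:
        L = np.linalg.cholesky(J)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("posterior information matrix is not positive definite")
    inv = np.linalg.inv(L)
    variances = np.sum(inv**2, axis=0)  # diag of J^{-1} via L^{-T} L^{-1}
    return np.sqrt(variances)


def build_state(
    bank: ItemBank,
    administered: Sequence[tuple[str, int]],
    prior_correlation: np.ndarray,
    se_threshold: float,
    theta_start: np.ndarray | None = None,
) -> PosteriorState:
    """Estimate theta, the posterior information, SEs and terminated dims."""
    theta_hat = map_estimate(bank, administered, prior_correlation, theta_start=theta_start)
    J = posterior_information(bank, administered, theta_hat, prior_correlation)
    se = standard_errors(J)
    terminated = frozenset(int(d) for d in np.flatnonzero(se < se_threshold))
    return PosteriorState(
        administered=list(administered),
        theta_hat=theta_hat,
        posterior_info=J,
        se=se,
        terminated_dims=terminated,
    )
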