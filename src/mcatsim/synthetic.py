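"""Synthetic item banks and respondent populations.

The default recipe emulates a 194-item, 4-domain health-related
quality-of-life bank: domain sizes (50, 63, 35, 46), discriminations in
0.82–5.40, thresholds spanning -7.57 to 7.67, a category profile of 139
five-category, 51 four-category and 4 three-category items, and a fixed
latent-trait correlation matrix with correlations 0.76–0.87.

Distributional forms (log-uniform discrimination, normally spread
thresholds with a minimum gap) reproduce the qualitative regime — highly
discriminating polytomous items with broad trait coverage — without
claiming any real calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mgrm import ItemBank, ItemParameters

__all__ = [
    "DEFAULT_CORRELATION",
    "DEFAULT_DOMAIN_LABELS",
    "BankRecipe",
    "generate_item_bank",
    "generate_population",
    "collapse_sparse_categories",
]

#: Latent-trait correlations among fatigue, physical function, social
#: roles and the disease-specific domain (unit variances).
DEFAULT_CORRELATION = np.array(
    [
        [1.00, 0.77, 0.87, 0.77],
        [0.77, 1.00, 0.84, 0.76],
        [0.87, 0.84, 1.00, 0.77],
        [0.77, 0.76, 0.77, 1.00],
    ]
)

DEFAULT_DOMAIN_LABELS = ("Fatigue", "PhysicalFunction", "SocialRoles", "COPD-SIB")

#: Minimum spacing enforced between adjacent thresholds of one item.
MIN_THRESHOLD_GAP = 0.2


@dataclass(frozen=True)
class BankRecipe:
    """Parameters of the synthetic bank generator."""

    domain_sizes: tuple[int, ...] = (50, 63, 35, 46)
    alpha_range: tuple[float, float] = (0.82, 5.40)
    beta_range: tuple[float, float] = (-7.57, 7.67)
    #: mapping n_categories -> number of items with that many categories
    category_profile: dict[int, int] = field(
        default_factory=lambda: {5: 139, 4: 51, 3: 4}
    )
    correlation: np.ndarray = field(default_factory=lambda: DEFAULT_CORRELATION.copy())
    domain_labels: tuple[str, ...] = DEFAULT_DOMAIN_LABELS
    #: spread of item threshold centres and of thresholds around them;
    #: the defaults make a 194-item bank's generated thresholds span the
    #: emulated bank's printed range of roughly -7.6 to 7.7
    center_sd: float = 2.4
    within_item_sd: float = 1.2

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.domain_sizes):
            raise ValueError("domain sizes must be positive")
        if not self.alpha_range[0] < self.alpha_range[1] or self.alpha_range[0] <= 0:
            raise ValueError("alpha_range must be ordered and positive")
        if not self.beta_range[0] < self.beta_range[1]:
            raise ValueError("beta_range must be ordered")
        if sum(self.category_profile.values()) != sum(self.domain_sizes):
            raise ValueError("category profile counts must sum to the bank size")
        if len(self.domain_labels) != len(self.domain_sizes):
            raise ValueError("one label per domain required")
        max_m = max(self.category_profile) - 1
        if self.beta_range[1] - self.beta_range[0] < MIN_THRESHOLD_GAP * (max_m - 1):
            raise ValueError("beta_range too narrow for the minimum threshold gap")

    @property
    def bank_size(self) -> int:
        return sum(self.domain_sizes)


def _draw_thresholds(
    m: int, lo: float, hi: float, center_sd: float, within_sd: float,
    rng: np.random.Generator,
) -> tuple[float, ...]:
    center = rng.normal(0.0, center_sd)
    draws = np.sort(rng.normal(center, within_sd, size=m))
    gap = MIN_THRESHOLD_GAP
    betas = np.empty(m)
    prev = -np.inf
    for j in range(m):
        # keep room above for the remaining steps, respect the gap below
        upper = hi - gap * (m - 1 - j)
        betas[j] = min(max(draws[j], prev + gap, lo), upper)
        prev = betas[j]
    return tuple(betas)


def generate_item_bank(recipe: BankRecipe, rng: np.random.Generator) -> ItemBank:
    """Draw a full synthetic bank from the recipe.

    Discriminations are log-uniform on ``alpha_range``; thresholds are
    normal draws around a per-item centre, sorted, pushed apart to the
    minimum gap and kept inside ``beta_range``; category counts follow
    the recipe's profile, shuffled over the bank.
    """
    n = recipe.bank_size
    lo_a, hi_a = recipe.alpha_range
    alphas = np.exp(rng.uniform(np.log(lo_a), np.log(hi_a), size=n))
    n_cats = np.repeat(
        list(recipe.category_profile), list(recipe.category_profile.values())
    )
    rng.shuffle(n_cats)

    items = []
    k = 0
    for d, size in enumerate(recipe.domain_sizes, start=1):
        for j in range(size):
            betas = _draw_thresholds(
                int(n_cats[k]) - 1,
                *recipe.beta_range,
                recipe.center_sd,
                recipe.within_item_sd,
                rng,
            )
            items.append(
                ItemParameters(
                    item_id=f"D{d}I{j + 1:03d}", domain=d, alpha=float(alphas[k]),
                    betas=betas,
                )
            )
            k += 1
    return ItemBank(
        items=items,
        correlation=np.asarray(recipe.correlation, dtype=float),
        domain_labels=recipe.domain_labels,
    )


def generate_population(
    correlation: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` trait vectors from MVN(0, correlation); shape ``(n, D)``."""
    corr = np.asarray(correlation, dtype=float)
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ValueError("correlation matrix must be positive definite")
    return rng.multivariate_normal(
        np.zeros(corr.shape[0]), corr, size=n, method="cholesky"
    )


def collapse_sparse_categories(
    response_matrix: np.ndarray, min_count: int = 10
) -> tuple[np.ndarray, list[dict[int, int]]]:
    """Merge low-endorsement response categories with adjacent ones.

    Per item (column), while some category has fewer than ``min_count``
    responses and more than two categories remain, the sparsest
    under-threshold category is merged with a neighbour: extreme
    categories merge inward; interior categories merge into the
    smaller-count neighbour, ties toward the lower index.  Categories are
    renumbered consecutively afterwards.

    Returns the recoded matrix and, per item, the old->new category map.
    Raises if an item has fewer than two categories to begin with.
    """
    X = np.asarray(response_matrix)
    if X.ndim != 2:
        raise ValueError("response matrix must be respondents x items")
    out = X.copy()
    maps: list[dict[int, int]] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        n_cat = int(col.max()) + 1 if col.size else 0
        if n_cat < 2:
            raise ValueError(f"item column {j} has fewer than 2 categories")
        # groups[k] = list of original categories currently merged together
        groups: list[list[int]] = [[c] for c in range(n_cat)]
        counts = [int(np.sum(col == c)) for c in range(n_cat)]
        while len(groups) > 2:
            under = [k for k, c in enumerate(counts) if c < min_count]
            if not under:
                break
            k = min(under, key=lambda i: (counts[i], i))
            if k == 0:
                nb = 1
            elif k == len(groups) - 1:
                nb = k - 1
            else:
                nb = k - 1 if counts[k - 1] <= counts[k + 1] else k + 1
            lo, hi = min(k, nb), max(k, nb)
            groups[lo] = groups[lo] + groups[hi]
            counts[lo] += counts[hi]
            del groups[hi], counts[hi]
        if len(groups) < 2:
            raise ValueError(f"item column {j} collapsed below 2 categories")
        merge_map = {old: new for new, grp in enumerate(groups) for old in grp}
        maps.append(merge_map)
        out[:, j] = np.vectorize(merge_map.__getitem__)(col)
    return out, maps
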