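"""Item-usage and accuracy statistics of a simulated study.

Definitions, all conditional on the grid value ``g`` of the simulees'
true trait vector:

usage rate
    fraction of tests at ``g`` in which the item was *adaptively*
    administered.  The random starting items (one per domain) count
    toward test length but not toward usage: with hundreds of replicates
    the random starts would otherwise mark nearly every item active,
    which is incompatible with a small active bank at central trait
    values.
expected usage rate
    mean (total) test length at ``g`` divided by the *total* bank size,
    for per-domain classification too.
overused
    usage rate strictly greater than the expected usage rate.
active
    usage rate greater than zero.
overlap
    100 * (number overused) / (number active).

Per-domain percentages use the domain size as denominator; the "total"
row uses the bank size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import CATResult
from .mgrm import ItemBank

__all__ = [
    "TOTAL_LABEL",
    "UsageTable",
    "compute_usage_rates",
    "classify_and_summarize",
    "accuracy_metrics",
    "usage_vs_parameters_report",
    "render_percent_table",
]

TOTAL_LABEL = "Total"


@dataclass
class UsageTable:
    """Per-(grid value, item) usage counts/rates plus derived summaries.

    ``counts`` columns: grid_value, item_id, domain, count, usage_rate,
    overused (after classification), with ``n_replicates`` and
    ``mean_test_length`` per grid value in the companion frames.
    ``summary`` (after classification) columns: grid_value, group,
    active_size_pct, overused_pct, overlap_pct, n_active, n_overused.
    """

    counts: pd.DataFrame
    # grid_value, n_replicates, mean_test_length, mean_adaptive_length
    per_grid: pd.DataFrame
    summary: pd.DataFrame | None = None

    @property
    def grid_values(self) -> np.ndarray:
        return self.per_grid["grid_value"].to_numpy()

    def mean_test_length(self, grid_value: float) -> float:
        row = self.per_grid[np.isclose(self.per_grid["grid_value"], grid_value)]
        if row.empty:
            raise KeyError(f"grid value {grid_value} not in table")
        return float(row["mean_test_length"].iloc[0])


def compute_usage_rates(results: Sequence[CATResult], bank: ItemBank) -> UsageTable:
    """Count, per grid value, the tests in which each item appears.

    Each adaptively selected item counts once per test; the random
    starting items are excluded from counts but included in
    ``mean_test_length``.  Items never used at a grid value appear with
    count 0, so the counting identity
    sum_i rate(i|g) = mean_adaptive_length(g) holds exactly.
    """
    item_ids = [it.item_id for it in bank.items]
    domains = {it.item_id: it.domain for it in bank.items}
    grid_of: dict[float, list[CATResult]] = {}
    for r in results:
        g = float(r.grid_value) if r.grid_value is not None else np.nan
        grid_of.setdefault(g, []).append(r)

    count_rows, grid_rows = [], []
    for g in sorted(grid_of):
        batch = grid_of[g]
        n = len(batch)
        counts = dict.fromkeys(item_ids, 0)
        total_len = 0
        adaptive_len = 0
        for r in batch:
            total_len += r.test_length
            adaptive_len += r.test_length - r.n_initial
            for iid in r.administered_ids[r.n_initial:]:
                if iid not in counts:
                    raise KeyError(f"administered item {iid!r} not in bank")
                counts[iid] += 1
        grid_rows.append(
            {
                "grid_value": g,
                "n_replicates": n,
                "mean_test_length": total_len / n,
                "mean_adaptive_length": adaptive_len / n,
            }
        )
        count_rows.extend(
            {
                "grid_value": g,
                "item_id": iid,
                "domain": domains[iid],
                "count": c,
                "usage_rate": c / n,
            }
            for iid, c in counts.items()
        )
    return UsageTable(
        counts=pd.DataFrame(
            count_rows,
            columns=["grid_value", "item_id", "domain", "count", "usage_rate"],
        ),
        per_grid=pd.DataFrame(
            grid_rows,
            columns=["grid_value", "n_replicates", "mean_test_length",
                     "mean_adaptive_length"],
        ),
    )


def classify_and_summarize(table: UsageTable, bank: ItemBank) -> UsageTable:
    """Flag overused items and derive active/overused/overlap summaries.

    The expected usage rate uses the total bank size as denominator even
    when classifying within a domain; overuse is a strict inequality, so
    a bank where every test administers every item has zero overused
    items.  Overlap with no active items is reported as NaN.
    """
    bank_size = len(bank)
    domain_sizes = {
        d: len(bank.domain_indices(d)) for d in range(1, bank.n_dimensions + 1)
    }
    counts = table.counts.copy()
    expected = {
        row.grid_value: row.mean_test_length / bank_size
        for row in table.per_grid.itertuples()
    }
    counts["overused"] = counts.apply(
        lambda r: r.usage_rate > expected[r.grid_value], axis=1
    )
    counts["active"] = counts["usage_rate"] > 0

    rows = []
    groups: list[tuple[str, int | None]] = [(TOTAL_LABEL, None)] + [
        (bank.domain_labels[d - 1], d) for d in range(1, bank.n_dimensions + 1)
    ]
    for g in table.per_grid["grid_value"]:
        at_g = counts[counts["grid_value"] == g]
        for label, d in groups:
            sub = at_g if d is None else at_g[at_g["domain"] == d]
            size = bank_size if d is None else domain_sizes[d]
            n_active = int(sub["active"].sum())
            n_over = int(sub["overused"].sum())
            rows.append(
                {
                    "grid_value": g,
                    "group": label,
                    "n_active": n_active,
                    "n_overused": n_over,
                    "active_size_pct": 100.0 * n_active / size,
                    "overused_pct": 100.0 * n_over / size,
                    "overlap_pct": 100.0 * n_over / n_active if n_active else np.nan,
                }
            )
    return UsageTable(counts=counts, per_grid=table.per_grid.copy(),
                      summary=pd.DataFrame(rows))


def accuracy_metrics(results: Sequence[CATResult]) -> pd.DataFrame:
    """RMSE and bias of the final estimates, per grid value and pooled.

    One row per (grid_value, dimension) plus pooled rows with
    ``grid_value = NaN``; bias is mean(estimate - truth).
    """
    if not results:
        raise ValueError("no results to summarise")
    D = results[0].true_theta.size
    err = np.array([r.theta_final - r.true_theta for r in results])  # (n, D)
    grid = np.array(
        [r.grid_value if r.grid_value is not None else np.nan for r in results]
    )
    rows = []
    for g in sorted(set(grid[~np.isnan(grid)])):
        e = err[grid == g]
        for d in range(D):
            rows.append(
                {
                    "grid_value": g,
                    "dimension": d + 1,
                    "n": e.shape[0],
                    "bias": float(e[:, d].mean()),
                    "rmse": float(np.sqrt((e[:, d] ** 2).mean())),
                }
            )
    for d in range(D):
        rows.append(
            {
                "grid_value": np.nan,
                "dimension": d + 1,
                "n": err.shape[0],
                "bias": float(err[:, d].mean()),
                "rmse": float(np.sqrt((err[:, d] ** 2).mean())),
            }
        )
    return pd.DataFrame(rows)


def usage_vs_parameters_report(table: UsageTable, bank: ItemBank) -> pd.DataFrame:
    """Flat per-item-step records for a discrimination-vs-threshold scatter.

    One row per (item, threshold step) carrying the item's discrimination
    and its maximum usage rate over the grid, ready for a dot-size plot.
    """
    max_rate = table.counts.groupby("item_id")["usage_rate"].max()
    rows = []
    for item in bank.items:
        rate = float(max_rate.get(item.item_id, 0.0))
        rows.extend(
            {
                "item_id": item.item_id,
                "domain": item.domain,
                "domain_label": bank.domain_labels[item.domain - 1],
                "step": j + 1,
                "alpha": item.alpha,
                "beta": b,
                "max_usage_rate": rate,
            }
            for j, b in enumerate(item.betas)
        )
    return pd.DataFrame(rows)


def render_percent_table(table: UsageTable, bank: ItemBank, column: str) -> pd.DataFrame:
    """Pivot a summary percentage to a grid x (Total, domains) layout.

    Percentages are rounded half-up to integers, mirroring how such
    tables are conventionally printed.
    """
    if table.summary is None:
        raise ValueError("summary not computed; call classify_and_summarize first")
    pivot = table.summary.pivot(index="grid_value", columns="group", values=column)
    order = [TOTAL_LABEL, *bank.domain_labels]
    pivot = pivot[order]
    # round half-up (np.round rounds half to even)
    return pivot.apply(lambda c: np.floor(c + 0.5)).astype("Int64")
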