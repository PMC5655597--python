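"""Reading and writing item banks, study outputs and run manifests.

Bank CSV layout: header ``item_id,domain,alpha,b1,b2,b3,b4`` with trailing
threshold fields left empty for items with fewer categories.  ``domain``
is the 1-based dimension index.  A YAML sidecar next to the CSV (same
path with a ``.meta.yaml`` suffix) carries the domain labels and the
latent-trait correlation matrix.

Calibration software that reports "easiness" parameters ``c`` uses the
opposite sign: ``beta = -c``.  Pass ``parametrization="easiness"`` to
convert on read; the strictly-increasing check runs after conversion.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import CATConfig, CATResult
from .mgrm import MAX_CATEGORIES, ItemBank, ItemParameters
from .study import StudyDesign
from .usage import UsageTable, render_percent_table

__all__ = [
    "read_item_bank",
    "write_item_bank",
    "sidecar_path",
    "write_outputs",
    "write_manifest",
]

_BETA_COLS = [f"b{j}" for j in range(1, MAX_CATEGORIES)]


def sidecar_path(bank_path: str | Path) -> Path:
    p = Path(bank_path)
    return p.with_name(p.name + ".meta.yaml")


def write_item_bank(bank: ItemBank, path: str | Path) -> None:
    """Write the bank CSV and its metadata sidecar."""
    rows = []
    for it in bank.items:
        row = {"item_id": it.item_id, "domain": it.domain, "alpha": it.alpha}
        for j, col in enumerate(_BETA_COLS):
            row[col] = it.betas[j] if j < len(it.betas) else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    meta = {
        "domain_labels": list(bank.domain_labels),
        "correlation": [[float(v) for v in row] for row in bank.correlation],
    }
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_item_bank(path: str | Path, parametrization: str = "difficulty") -> ItemBank:
    """Load and validate an item bank from CSV plus YAML sidecar.

    ``parametrization="easiness"`` negates the threshold columns
    (``beta = -c``) before validation.
    """
    if parametrization not in ("difficulty", "easiness"):
        raise ValueError(f"unknown parametrization {parametrization!r}")
    meta_path = sidecar_path(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"missing bank metadata sidecar {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    labels = tuple(meta["domain_labels"])
    correlation = np.asarray(meta["correlation"], dtype=float)

    df = pd.read_csv(path)
    required = {"item_id", "domain", "alpha"}
    if missing := required - set(df.columns):
        raise ValueError(f"bank CSV missing columns {sorted(missing)}")
    beta_cols = [c for c in _BETA_COLS if c in df.columns]

    items = []
    for row_i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        betas = []
        for col in beta_cols:
            v = getattr(row, col)
            if pd.isna(v) or v == "":
                break
            betas.append(-float(v) if parametrization == "easiness" else float(v))
        domain = int(row.domain)
        if not 1 <= domain <= len(labels):
            raise ValueError(f"line {row_i}: unknown domain {row.domain!r}")
        try:
            items.append(
                ItemParameters(
                    item_id=str(row.item_id), domain=domain,
                    alpha=float(row.alpha), betas=tuple(betas),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {row_i}: {exc}") from None
    return ItemBank(items=items, correlation=correlation, domain_labels=labels)


def _results_frame(results: Sequence[CATResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "respondent_id": r.respondent_id,
                "grid_value": r.grid_value,
                "true_theta": ";".join(f"{v:.6g}" for v in r.true_theta),
                "theta_final": ";".join(f"{v:.6g}" for v in r.theta_final),
                "se_final": ";".join(f"{v:.6g}" for v in r.se_final),
                "test_length": r.test_length,
                "n_initial": r.n_initial,
                "converged": r.converged,
                "administered": ";".join(
                    f"{iid}:{cat}" for iid, cat in r.administered
                ),
            }
        )
    return pd.DataFrame(rows)


def write_outputs(
    results: Sequence[CATResult],
    table: UsageTable,
    accuracy: pd.DataFrame,
    bank: ItemBank,
    out_dir: str | Path,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write the CSV bundle for one completed study run.

    Emits the per-respondent log, per-item usage rates, three summary
    tables (active size, overused share, overlap — rows are grid values,
    columns Total plus the domains), the accuracy table, and a manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["respondents"] = out / "respondents.csv"
    _results_frame(results).to_csv(paths["respondents"], index=False)

    paths["usage"] = out / "item_usage.csv"
    table.counts.to_csv(paths["usage"], index=False)

    for name, column in [
        ("active_size", "active_size_pct"),
        ("overused", "overused_pct"),
        ("overlap", "overlap_pct"),
    ]:
        paths[name] = out / f"summary_{name}.csv"
        render_percent_table(table, bank, column).to_csv(paths[name])

    paths["accuracy"] = out / "accuracy.csv"
    accuracy.to_csv(paths["accuracy"], index=False)

    if manifest is not None:
        paths["manifest"] = write_manifest(manifest, out / "manifest.json")
    return paths


def write_manifest(manifest: dict, path: str | Path) -> Path:
    """Persist seed/config/version info needed to reproduce a run."""
    enriched = dict(manifest)
    enriched.setdefault("versions", {})
    enriched["versions"].update(
        {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
    )
    p = Path(path)
    p.write_text(json.dumps(enriched, indent=2, default=str) + "\n")
    return p


def manifest_for(
    design: StudyDesign, config: CATConfig, seed: int, extra: dict | None = None
) -> dict:
    m = {"seed": seed, "design": asdict(design), "cat_config": asdict(config)}
    if extra:
        m.update(extra)
    return m
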