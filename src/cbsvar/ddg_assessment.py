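"""Predicted-stability vs growth-phenotype threshold analysis.

For each candidate ddG cutoff t the classification accuracy ("percent
correct") counts growing alleles predicted below t plus non-growing
alleles predicted at or above t, over all alleles with a prediction.
Sweeping t in 0.5 kcal/mol steps locates the stability threshold above
which variants are functionally impaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AssayCondition, Category, VariantPanel, VariantRecord

__all__ = [
    "ThresholdSweep",
    "growth_indicator",
    "percent_correct",
    "sweep",
    "scatter_table",
]


@dataclass(frozen=True)
class ThresholdSweep:
    thresholds: tuple[float, ...]       # kcal/mol grid, strictly increasing
    percent_correct: tuple[float, ...]  # fraction in [0, 1] per threshold
    n_alleles: int
    best_threshold: float               # argmax; ties resolved to smallest

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds)
        if np.any(np.diff(t) <= 0):
            raise ValueError("threshold grid must be strictly increasing")


def growth_indicator(record: VariantRecord) -> bool:
    """True iff the variant confers growth (any category but nonfunctional)."""
    return record.category is not Category.NONFUNCTIONAL


def percent_correct(panel: VariantPanel, threshold: float) -> float:
    """Classification accuracy of the cutoff ``threshold`` (kcal/mol).

    "Below" is strict (<) and "above" inclusive (>=); only alleles with a
    ddG prediction are scored.
    """
    scored = panel.with_ddg()
    if len(scored) == 0:
        raise ValueError("no alleles carry a ddG prediction")
    correct = 0
    for rec in scored:
        grows = growth_indicator(rec)
        predicted_grows = rec.ddg < threshold
        if grows == predicted_grows:
            correct += 1
    return correct / len(scored)


def sweep(panel: VariantPanel, t_min: float = -3.0, t_max: float = 15.0,
          step: float = 0.5) -> ThresholdSweep:
    """Evaluate percent-correct on a regular cutoff grid."""
    if not t_min < t_max:
        raise ValueError("t_min must be < t_max")
    if not step > 0:
        raise ValueError("step must be positive")
    n_steps = int(round((t_max - t_min) / step))
    grid = [t_min + i * step for i in range(n_steps + 1)]
    fractions = [percent_correct(panel, t) for t in grid]
    best = grid[int(np.argmax(fractions))]   # argmax returns first (smallest t)
    return ThresholdSweep(
        thresholds=tuple(grid),
        percent_correct=tuple(fractions),
        n_alleles=len(panel.with_ddg()),
        best_threshold=best,
    )


def scatter_table(panel: VariantPanel,
                  pyridoxine: float = 400.0) -> pd.DataFrame:
    """Per-allele rows for the ddG vs relative-growth scatter.

    One row per record with a ddG prediction; nonfunctional records carry
    growth 0 (their printed value at the high pyridoxine dose).
    """
    cond = AssayCondition(pyridoxine=pyridoxine)
    rows = []
    for rec in panel.with_ddg():
        res = rec.result_at(cond)
        growth = res.relative_rate
        if growth is None and rec.category is Category.NONFUNCTIONAL:
            growth = 0.0
        rows.append({
            "substitution": str(rec.substitution),
            "ddg": rec.ddg,
            "relative_growth": growth,
            "category": rec.category.value,
        })
    return pd.DataFrame(rows, columns=["substitution", "ddg",
                                       "relative_growth", "category"])
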