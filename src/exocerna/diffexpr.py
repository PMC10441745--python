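"""Two-group differential expression with a conjunctive fold-change / p gate.

Features pass the filter when |log2FC| >= 1 (fold change >= 2 in either
direction) and the two-sample t-test p-value is <= 0.05, both thresholds
configurable and boundary-inclusive.  Testing is done on log2-transformed,
pseudocount-shifted abundances; fold changes come from group means of the
shifted raw values.  No multiple-testing correction enters the gate (a
Benjamini-Hochberg column is emitted for transparency only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import CASE, CONTROL, ExpressionBundle

UP = "up"
DOWN = "down"
NONE = "none"


class DegenerateInputError(ValueError):
    """Raised for t-test inputs with too few values or no variance at all."""


@dataclass(frozen=True)
class DEParams:
    fc_threshold: float = 2.0  # fold change gate; log2 threshold = log2(fc_threshold)
    p_threshold: float = 0.05
    pseudocount: float = 1.0
    pooled: bool = True
    log_transform: bool = True  # t-test on log2(value + pseudocount)

    @property
    def log2fc_threshold(self) -> float:
        return float(np.log2(self.fc_threshold))


def ttest_two_sample(
    x: np.ndarray, y: np.ndarray, pooled: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test.

    Pooled-variance Student's t (df = n1 + n2 - 2) by default; Welch when
    ``pooled`` is False.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2 or not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateInputError("each group needs >= 2 finite values")
    if np.var(x) == 0 and np.var(y) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise DegenerateInputError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=pooled)
    return float(t), float(p)


def ttest_from_summary(
    m1: float, s1: float, n1: int,
    m2: float, s2: float, n2: int,
    pooled: bool = True,
) -> tuple[float, float]:
    """Two-sample t-test from group means, SDs and sizes."""
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise DegenerateInputError("standard deviations must be non-negative")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return 0.0, 1.0
        raise DegenerateInputError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=pooled)
    return float(t), float(p)


def compute_de(
    bundle: ExpressionBundle, params: DEParams | None = None
) -> dict[str, pd.DataFrame]:
    """Per-feature DE tables, one per RNA class.

    Columns: rna_class, mean_case, mean_control, log2fc, t, p_value,
    p_adj_bh, direction, passes_filter.
    """
    params = params or DEParams()
    case_mask = (bundle.groups == CASE).values
    ctrl_mask = (bundle.groups == CONTROL).values
    if case_mask.sum() < 2 or ctrl_mask.sum() < 2:
        raise DegenerateInputError("each group needs >= 2 samples")
    out: dict[str, pd.DataFrame] = {}
    for rna_class, tab in bundle.classes.items():
        vals = tab.values.astype(float) + params.pseudocount
        mean_case = vals[:, case_mask].mean(axis=1)
        mean_ctrl = vals[:, ctrl_mask].mean(axis=1)
        log2fc = np.log2(mean_case / mean_ctrl)
        test_vals = np.log2(vals) if params.log_transform else vals
        t, p = stats.ttest_ind(
            test_vals[:, case_mask], test_vals[:, ctrl_mask],
            axis=1, equal_var=params.pooled,
        )
        passes = (np.abs(log2fc) >= params.log2fc_threshold) & (p <= params.p_threshold)
        direction = np.where(
            passes & (log2fc >= params.log2fc_threshold), UP,
            np.where(passes & (log2fc <= -params.log2fc_threshold), DOWN, NONE),
        )
        out[rna_class] = pd.DataFrame(
            {
                "rna_class": rna_class,
                "mean_case": mean_case - params.pseudocount,
                "mean_control": mean_ctrl - params.pseudocount,
                "log2fc": log2fc,
                "t": t,
                "p_value": p,
                "p_adj_bh": multipletests(p, method="fdr_bh")[1],
                "direction": direction,
                "passes_filter": passes,
            },
            index=tab.index.rename("feature_id"),
        )
    return out


def split_directions(de: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Partition the filtered features of one DE table into (up, down) sets."""
    up = set(de.index[de["direction"] == UP])
    down = set(de.index[de["direction"] == DOWN])
    return up, down


def de_sets(de_tables: dict[str, pd.DataFrame]) -> dict[str, dict[str, set[str]]]:
    """Up/down feature-id sets per RNA class."""
    out = {}
    for rna_class, de in de_tables.items():
        up, down = split_directions(de)
        out[rna_class] = {UP: up, DOWN: down}
    return out
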