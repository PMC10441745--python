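"""Demographic group tests and partial correlation with clinical severity.

Partial correlation is Pearson correlation of the least-squares residuals
of x and y on an intercept plus the covariate matrix; its p-value comes
from t = r * sqrt(df / (1 - r^2)) with df = n - 2 - k on Student's t.
Network-feature correlations control age, sex and education and use case
samples only, since controls carry no PANSS scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cerna import CeRNANetwork
from .synthetic_data import CASE, PANSS_COLUMNS, ExpressionBundle

DEFAULT_COVARIATES = ("age", "sex", "education")


class CollinearityError(ValueError):
    pass


def chisq_proportions(
    table: np.ndarray | list, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 count table.

    With a zero statistic p = 1 regardless of the continuity correction.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any() or not (table == table.round()).all():
        raise ValueError("table must be 2x2 non-negative integer counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson partial correlation of x and y controlling the covariates.

    With no covariates this reduces to the plain Pearson correlation and
    its two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    cov = (
        np.empty((n, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if cov.shape[0] != n:
        cov = cov.T
    if cov.shape[0] != n:
        raise ValueError("covariate matrix length mismatch")
    k = cov.shape[1]
    df = n - 2 - k
    if df < 1:
        raise ValueError(f"insufficient samples: df = n - 2 - k = {df}")
    design = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _find_collinear(design)
        raise CollinearityError(f"rank-deficient covariates (column {bad})")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: constant x or y")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("undefined correlation: residuals constant after control")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def _find_collinear(design: np.ndarray) -> int:
    for j in range(1, design.shape[1]):
        sub = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(design):
            return j - 1  # covariate index (0-based, excluding intercept)
    return design.shape[1] - 2


def correlate_network_features(
    net: CeRNANetwork,
    bundle: ExpressionBundle,
    clinical: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Partial correlation of each network feature with each PANSS score.

    Expression is log2(value + 1); case samples only.  Emits a raw p per
    cell plus a BH-adjusted column for transparency (the ``significant``
    flag uses raw p < alpha).
    """
    features = [
        (n, d["rna_class"]) for n, d in sorted(net.graph.nodes(data=True))
    ]
    if not features:
        return pd.DataFrame(
            columns=["feature_id", "rna_class", "score", "r", "p", "n", "k",
                     "p_adj_bh", "significant"]
        )
    case_ids = [s for s in bundle.sample_ids if bundle.groups[s] == CASE]
    expr = pd.concat([bundle.lncrna, bundle.mirna, bundle.mrna])
    missing = [f for f, _ in features if f not in expr.index]
    if missing:
        raise KeyError(f"network features missing from expression tables: {missing}")
    clin = clinical.loc[case_ids]
    cov = clin.loc[:, list(covariates)].to_numpy(dtype=float)
    rows = []
    for feature_id, rna_class in features:
        x = np.log2(expr.loc[feature_id, case_ids].to_numpy(dtype=float) + 1.0)
        for score in PANSS_COLUMNS:
            y = clin[score].to_numpy(dtype=float)
            r, p = partial_correlation(x, y, cov)
            rows.append(
                (feature_id, rna_class, score.removeprefix("panss_"), r, p,
                 len(case_ids), cov.shape[1])
            )
    out = pd.DataFrame(
        rows, columns=["feature_id", "rna_class", "score", "r", "p", "n", "k"]
    )
    out["p_adj_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p"] < alpha
    return out


def demographics_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Group comparison of age, sex and education (t-test / chi-square)."""
    from .diffexpr import ttest_two_sample

    case = clinical[clinical["group"] == CASE]
    ctrl = clinical[clinical["group"] != CASE]
    rows = []
    for col in ("age", "education"):
        _, p = ttest_two_sample(case[col].to_numpy(), ctrl[col].to_numpy())
        rows.append(
            (col, f"{case[col].mean():.1f} ± {case[col].std(ddof=1):.2f}",
             f"{ctrl[col].mean():.1f} ± {ctrl[col].std(ddof=1):.2f}", "t-test", p)
        )
    counts = np.array(
        [
            [(case["sex"] == 1).sum(), (case["sex"] == 0).sum()],
            [(ctrl["sex"] == 1).sum(), (ctrl["sex"] == 0).sum()],
        ]
    )
    _, p = chisq_proportions(counts)
    rows.append(
        ("sex", f"{counts[0, 0]}/{counts[0].sum()} male",
         f"{counts[1, 0]}/{counts[1].sum()} male", "chi-square", p)
    )
    return pd.DataFrame(rows, columns=["variable", "case", "control", "test", "p"])
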