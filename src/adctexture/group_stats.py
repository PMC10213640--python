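"""Two-group inferential statistics for clinical covariates and texture
features.

Favorable (mRS <= 2) and unfavorable (mRS > 2) groups are compared with the
classic clinical-table battery: Pearson chi-square (no continuity
correction) for categorical variables, pooled-variance two-sample t-test
for normally distributed continuous variables, and the Mann-Whitney U test
(midrank ties; exact enumeration for small samples) otherwise.  Normality
is judged per group by Shapiro-Wilk at alpha = 0.05.  All p-values are
two-tailed.  No multiple-testing correction is applied to the feature
screen — the p < 0.05 "significant features" table is a screening device,
not a confirmatory analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateProblemError
from .texture import FEATURE_NAMES

__all__ = [
    "TwoByKTable",
    "TestResult",
    "pearson_chi2",
    "pooled_t_test",
    "pooled_t_test_from_samples",
    "mann_whitney_u",
    "compare_groups",
    "significant_features",
]


@dataclass
class TwoByKTable:
    """2 x K contingency table of outcome group by category."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("favorable", "unfavorable")
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2 or self.counts.shape[1] < 2:
            raise ConfigurationError(f"need a 2xK table with K >= 2, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ConfigurationError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ConfigurationError("empty table")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    df: float | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def pearson_chi2(table: TwoByKTable) -> TestResult:
    """Pearson chi-square on a 2xK table, no continuity correction, df = K-1."""
    O = table.counts.astype(np.float64)
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ConfigurationError("row and column totals must be positive")
    E = np.outer(row, col) / O.sum()
    warning = "expected cell count < 1" if (E < 1.0).any() else None
    stat = float(((O - E) ** 2 / E).sum())
    df = O.shape[1] - 1
    return TestResult(
        statistic=stat,
        p_value=float(stats.chi2.sf(stat, df)),
        test_name="pearson_chi2",
        df=df,
        warning=warning,
    )


def pooled_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Pooled-variance two-sample t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ConfigurationError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 <= 0:
        # degenerate: all observations identical within each group
        if mean1 == mean2:
            return TestResult(statistic=0.0, p_value=1.0, test_name="pooled_t", df=df)
        return TestResult(statistic=float("inf"), p_value=0.0, test_name="pooled_t", df=df)
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(statistic=float(t), p_value=p, test_name="pooled_t", df=df)


def pooled_t_test_from_samples(x: np.ndarray, y: np.ndarray) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pooled_t_test(x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x against y with midrank ties (U1)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


_EXACT_LIMIT = 12


def mann_whitney_u(x: np.ndarray, y: np.ndarray, exact_limit: int = _EXACT_LIMIT) -> TestResult:
    """Two-tailed Mann-Whitney U with midrank ties.

    For ``n1 + n2 <= exact_limit`` the null distribution of U is obtained by
    full enumeration of all label assignments of the pooled sample (exact
    even under ties); otherwise the tie-corrected normal approximation is
    used.  The two-tailed exact p is ``P(|U - n1 n2 / 2| >= |u_obs - n1 n2
    / 2|)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ConfigurationError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_limit:
        pooled = np.concatenate([x, y])
        dev_obs = abs(u - mu)
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(idx)] = True
            u_perm = _u_statistic(pooled[sel], pooled[~sel])
            total += 1
            if abs(u_perm - mu) >= dev_obs - 1e-12:
                hits += 1
        return TestResult(
            statistic=u, p_value=hits / total, test_name="mann_whitney_u_exact", df=None
        )

    # tie-corrected normal approximation (no continuity correction)
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return TestResult(statistic=u, p_value=1.0, test_name="mann_whitney_u", df=None)
    z = (u - mu) / np.sqrt(sigma2)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return TestResult(statistic=u, p_value=min(1.0, p), test_name="mann_whitney_u", df=None)


_CATEGORICAL = (
    "sex",
    "smoking",
    "drinking",
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "atrial_fibrillation",
    "toast_subtype",
    "discharge_statin",
    "discharge_antiplatelet",
    "discharge_anticoagulant",
)
_CONTINUOUS = ("age", "nihss", "ldl_c", "stroke_volume")


def _summarize_continuous(v: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{v.mean():.2f} +/- {v.std(ddof=1):.2f}"
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}-{q3:.2f})"


def _continuous_row(x: np.ndarray, y: np.ndarray, alpha: float = 0.05):
    """Choose t vs Mann-Whitney by per-group Shapiro-Wilk normality."""
    normal = True
    for v in (x, y):
        if v.size >= 3 and np.ptp(v) > 0:
            if stats.shapiro(v[:5000]).pvalue < alpha:
                normal = False
        else:
            normal = False
    if normal:
        res = pooled_t_test_from_samples(x, y)
    else:
        res = mann_whitney_u(x, y)
    return res, normal


def compare_groups(
    cohort: pd.DataFrame,
    features: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable favorable-vs-unfavorable comparison table.

    Clinical covariates use their natural test (categorical -> chi-square,
    continuous -> t or Mann-Whitney by normality); texture feature columns
    (those present in ``features``) are treated as continuous.  Returns one
    row per variable with group summaries, the test used and the two-tailed
    p-value.
    """
    unfav = cohort["mrs_90d"].to_numpy() > 2
    if unfav.all() or not unfav.any():
        raise DegenerateProblemError("both outcome groups must be present")

    rows = []

    def add_continuous(name: str, values: np.ndarray) -> None:
        x, y = values[~unfav], values[unfav]
        res, normal = _continuous_row(x, y, alpha)
        rows.append(
            {
                "variable": name,
                "favorable": _summarize_continuous(x, normal),
                "unfavorable": _summarize_continuous(y, normal),
                "test": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )

    for var in _CATEGORICAL:
        if var not in cohort.columns:
            continue
        vals = cohort[var]
        if var == "toast_subtype":
            cats = [c for c in ("LAA", "CE", "SAO", "Other", "Undetermined") if (vals == c).any()]
            counts = np.array(
                [[(vals[~unfav] == c).sum() for c in cats], [(vals[unfav] == c).sum() for c in cats]]
            )
            labels = tuple(cats)
        else:
            v = vals.to_numpy().astype(bool)
            counts = np.array(
                [
                    [int(v[~unfav].sum()), int((~v[~unfav]).sum())],
                    [int(v[unfav].sum()), int((~v[unfav]).sum())],
                ]
            )
            labels = ("yes", "no")
        if counts.shape[1] < 2 or (counts.sum(axis=0) == 0).any():
            continue  # covariate constant in the cohort: no test possible
        res = pearson_chi2(TwoByKTable(counts=counts, col_labels=labels))
        n_fav, n_unf = (~unfav).sum(), unfav.sum()
        rows.append(
            {
                "variable": var,
                "favorable": f"{counts[0, 0]} ({100 * counts[0, 0] / n_fav:.1f}%)",
                "unfavorable": f"{counts[1, 0]} ({100 * counts[1, 0] / n_unf:.1f}%)",
                "test": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )

    for var in _CONTINUOUS:
        if var in cohort.columns:
            add_continuous(var, cohort[var].to_numpy().astype(float))

    if features is not None:
        feat_cols = [c for c in features.columns if c in FEATURE_NAMES]
        for var in feat_cols:
            add_continuous(var, features[var].to_numpy().astype(float))

    return pd.DataFrame(rows)


def significant_features(report: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Texture-feature rows of a comparison report with p < alpha."""
    is_feature = report["variable"].isin(FEATURE_NAMES)
    return report[is_feature & (report["p_value"] < alpha)].reset_index(drop=True)
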