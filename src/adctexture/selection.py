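"""L0 sparse-representation feature selection.

The selection model is least squares with an L0 penalty on the coefficient
vector,

    w_hat = argmin_w ||l - F w||_2^2 + eta ||w||_0,

with ``F`` the (standardized) training feature matrix and ``l`` the training
labels.  The exact problem is NP-hard; the solver here is greedy orthogonal
pursuit: at each step the column most correlated with the current residual
joins the support, the coefficients are refit by exact least squares on the
support, and the process stops when a step no longer reduces the squared
residual by more than ``eta`` or the support reaches ``k_max``.  A local
single-swap refinement then exchanges support/non-support columns while the
refit residual improves, which makes the solver agree with exhaustive
support enumeration on small well-conditioned problems.  Coefficient
magnitudes |w_i| are comparable across features because columns are
standardized, so features are selected by simple magnitude thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateProblemError, InputError

__all__ = ["FeatureMatrix", "SparseSolution", "standardize_features", "solve_l0", "select_features"]


@dataclass
class FeatureMatrix:
    """Standardized sample-by-feature matrix with column names.

    Columns are centered to mean 0 and scaled to unit (population) variance;
    constant columns are left at zero and flagged.
    """

    F: np.ndarray
    names: tuple[str, ...]
    constant_columns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=np.float64)
        if self.F.ndim != 2:
            raise InputError("feature matrix must be 2D")
        if not np.all(np.isfinite(self.F)):
            raise InputError("feature matrix contains non-finite values")
        if len(self.names) != self.F.shape[1]:
            raise InputError("one name per column required")


def standardize_features(
    X: np.ndarray, names: "tuple[str, ...] | list[str] | None" = None
) -> FeatureMatrix:
    """Center and scale columns; constant columns become zero and are flagged."""
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise InputError("features contain non-finite values")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    const = np.flatnonzero(sd < 1e-12)
    sd_safe = np.where(sd < 1e-12, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, const] = 0.0
    if names is None:
        names = tuple(f"x{j}" for j in range(X.shape[1]))
    return FeatureMatrix(F=Z, names=tuple(names), constant_columns=tuple(int(c) for c in const))


@dataclass
class SparseSolution:
    """Greedy L0 solution: coefficients, support and the residual trace."""

    w: np.ndarray
    eta: float
    support: tuple[int, ...]
    residual_norm: float
    residual_norms: tuple[float, ...] = field(default_factory=tuple)
    names: tuple[str, ...] = ()

    def selected_names(self) -> tuple[str, ...]:
        if not self.names:
            return ()
        return tuple(self.names[j] for j in self.support)


def _ls_on_support(F: np.ndarray, l: np.ndarray, support: list[int]) -> tuple[np.ndarray, float]:
    """Exact least squares on the support; returns (coef, squared residual)."""
    if not support:
        return np.zeros(0), float(l @ l)
    Fs = F[:, support]
    coef, _, rank, _ = np.linalg.lstsq(Fs, l, rcond=None)
    r = l - Fs @ coef
    return coef, float(r @ r)


def solve_l0(
    F: "FeatureMatrix | np.ndarray",
    l: np.ndarray,
    k_max: int = 10,
    eta: float = 0.0,
    refine: bool = True,
) -> SparseSolution:
    """Greedy orthogonal pursuit for the L0-penalized least-squares model.

    Parameters
    ----------
    F : feature matrix (standardized columns recommended; ``FeatureMatrix``
        or a plain array).
    l : label vector, typically +/-1 class codes or a continuous response.
    k_max : maximum support size.
    eta : sparsity penalty, interpreted as the minimum squared-residual
        reduction that justifies adding one more feature.
    refine : run single-swap local refinement after the greedy pass
        (never increases the residual).
    """
    names: tuple[str, ...] = ()
    if isinstance(F, FeatureMatrix):
        names = F.names
        Fm = F.F
    else:
        Fm = np.asarray(F, dtype=np.float64)
    l = np.asarray(l, dtype=np.float64).ravel()
    m, p = Fm.shape
    if m < 2 or p < 1:
        raise ConfigurationError(f"need m >= 2 samples and p >= 1 features, got {m}x{p}")
    if l.size != m:
        raise InputError(f"label length {l.size} != number of rows {m}")
    if np.ptp(l) == 0:
        raise DegenerateProblemError("constant label vector")
    if k_max < 0 or k_max > min(m, p):
        raise ConfigurationError(f"k_max must be in [0, min(m, p)] = [0, {min(m, p)}]")
    if eta < 0:
        raise ConfigurationError("eta must be >= 0")

    col_norms = np.linalg.norm(Fm, axis=0)
    usable = col_norms > 1e-12

    support: list[int] = []
    coef = np.zeros(0)
    rss = float(l @ l)
    trace = [np.sqrt(rss)]
    resid = l.copy()
    excluded: set[int] = set()
    while len(support) < k_max:
        scores = np.abs(Fm.T @ resid) / np.where(usable, col_norms, np.inf)
        scores[~usable] = -np.inf
        for jdx in support:
            scores[jdx] = -np.inf
        for jdx in excluded:
            scores[jdx] = -np.inf
        j = int(np.argmax(scores))
        if not np.isfinite(scores[j]) or scores[j] <= 1e-12:
            break
        cand = support + [j]
        coef_new, rss_new = _ls_on_support(Fm, l, cand)
        if np.linalg.matrix_rank(Fm[:, cand]) < len(cand):
            # rank-deficient support: drop the offending column, keep going
            excluded.add(j)
            continue
        if rss - rss_new <= eta:
            break
        support, coef, rss = cand, coef_new, rss_new
        resid = l - Fm[:, support] @ coef
        trace.append(np.sqrt(rss))

    if refine and support:
        improved = True
        while improved:
            improved = False
            for pos in range(len(support)):
                for j in range(p):
                    if j in support or j in excluded or not usable[j]:
                        continue
                    cand = support.copy()
                    cand[pos] = j
                    if np.linalg.matrix_rank(Fm[:, cand]) < len(cand):
                        continue
                    coef_new, rss_new = _ls_on_support(Fm, l, cand)
                    if rss_new < rss - 1e-12:
                        support, coef, rss = cand, coef_new, rss_new
                        improved = True
            if improved:
                resid = l - Fm[:, support] @ coef
        trace.append(np.sqrt(rss))

    w = np.zeros(p)
    for k, j in enumerate(support):
        w[j] = coef[k]
    return SparseSolution(
        w=w,
        eta=eta,
        support=tuple(sorted(support)),
        residual_norm=float(np.sqrt(rss)),
        residual_norms=tuple(trace),
        names=names,
    )


def select_features(sol: SparseSolution, threshold: float = 0.0) -> tuple[int, ...]:
    """Indices with |w_i| > threshold, ordered by descending magnitude."""
    mags = np.abs(sol.w)
    idx = [int(j) for j in np.argsort(-mags, kind="stable") if mags[j] > threshold]
    return tuple(idx)
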