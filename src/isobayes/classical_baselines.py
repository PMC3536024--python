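"""Classical count-based tests and GLMs for two-sample differential expression.

These are the standard Poisson-framework procedures the hierarchical model is
compared against: the exact binomial test, the Audic-Claverie negative-binomial
test, the chi-square goodness-of-fit test, Poisson-log and Gaussian GLMs with
depth offsets, plus the closed-form demonstration of how gene length inflates a
t-statistic by sqrt(L).

Two-sidedness convention: double the smaller tail, capped at 1.  All tests
return a no-call (NaN) on (0, 0) input — the degenerate case that destabilizes
classical t-statistics and motivates the presence-indicator rule of the
Bayesian model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoSampleCounts",
    "GlmSpec",
    "binomial_test",
    "audic_claverie_test",
    "chisq_poisson_test",
    "fit_expression_glm",
    "length_bias_t",
    "fisher_2x2",
]


@dataclass
class TwoSampleCounts:
    """Counts for one gene in two samples with their normalizing constants."""

    n1: int
    n2: int
    c1: float = 1.0
    c2: float = 1.0

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("counts must be non-negative")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("normalizing constants must be positive")

    @property
    def p0(self) -> float:
        """Null probability that a read falls in sample 1."""
        return self.c1 / (self.c1 + self.c2)


def _double_tail(lower: float, upper: float) -> float:
    return float(min(1.0, 2.0 * min(lower, upper)))


def binomial_test(x: TwoSampleCounts) -> float:
    """Exact binomial test of equal normalized rates.

    Under the null, n1 | n1+n2 ~ Binomial(n1+n2, C1/(C1+C2)); the two-sided
    p-value doubles the smaller exact tail.  Returns NaN (no call) when both
    counts are zero.
    """
    n = x.n1 + x.n2
    if n == 0:
        return float("nan")
    lower = stats.binom.cdf(x.n1, n, x.p0)
    upper = stats.binom.sf(x.n1 - 1, n, x.p0)  # P(X >= n1)
    return _double_tail(lower, upper)


def audic_claverie_test(x: TwoSampleCounts) -> float:
    """Audic-Claverie tag-count test.

    Under the null, n2 | n1 ~ NegativeBinomial(n1 + 1, C1/(C1+C2)) (the
    posterior predictive of a Poisson rate under a flat prior); the two-sided
    p-value doubles the smaller tail of n2.
    """
    if x.n1 + x.n2 == 0:
        return float("nan")
    size, p = x.n1 + 1, x.p0
    lower = stats.nbinom.cdf(x.n2, size, p)
    upper = stats.nbinom.sf(x.n2 - 1, size, p)
    return _double_tail(lower, upper)


def chisq_poisson_test(x: TwoSampleCounts) -> tuple[float, float]:
    """Chi-square goodness-of-fit test for equal Poisson rates.

    Expected counts under the null are ``m_i = C_i (n1+n2) / (C1+C2)``; the
    statistic ``sum_i (n_i - m_i)^2 / m_i`` is asymptotically chi-square with
    one degree of freedom.
    """
    total = x.n1 + x.n2
    if total == 0:
        return float("nan"), float("nan")
    m1 = x.c1 * total / (x.c1 + x.c2)
    m2 = x.c2 * total / (x.c1 + x.c2)
    if m1 <= 0 or m2 <= 0:
        raise ValueError("expected counts must be positive")
    statistic = (x.n1 - m1) ** 2 / m1 + (x.n2 - m2) ** 2 / m2
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


@dataclass
class GlmSpec:
    """Specification of a per-gene expression GLM.

    ``counts``: response per sample (read counts, or normalized expression for
    the Gaussian family).  ``offsets``: per-sample sequencing depth ``d_i``
    (Poisson family only; enters as ``log d_i``).  ``conditions``: sample ->
    biological condition map ``a(i)`` (defaults to one condition per sample).
    ``design``: optional response-level design matrix for the Gaussian family
    (e.g. the segment x isoform membership matrix); condition-mean
    parameterization, no intercept.
    """

    counts: np.ndarray
    offsets: np.ndarray | None = None
    conditions: list[str] | None = None
    design: np.ndarray | None = None
    family: str = "poisson-log"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.family not in ("poisson-log", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "poisson-log":
            if self.offsets is None:
                self.offsets = np.ones_like(self.counts)
            self.offsets = np.asarray(self.offsets, dtype=float)
            if (self.offsets <= 0).any():
                raise ValueError("offsets must be positive for the poisson-log family")
        if self.conditions is None:
            self.conditions = [f"c{i}" for i in range(len(self.counts))]


def fit_expression_glm(spec: GlmSpec) -> pd.DataFrame:
    """Fit the expression GLM and return a coefficient table with SEs.

    Poisson-log family: ``log E[n_i] = log d_i + lambda_{a(i)}`` with
    condition-mean parameterization (no intercept); with one sample per
    condition the MLEs are the closed-form ``log(n_i / d_i)``.  Gaussian
    family: ordinary least squares of normalized expression on the supplied
    design (the segment x isoform matrix for isoform-level estimates).
    """
    import statsmodels.api as sm

    if spec.family == "gaussian":
        if spec.design is None:
            X = np.ones((len(spec.counts), 1))
            names = ["mean"]
        else:
            X = np.asarray(spec.design, dtype=float)
            names = [f"isoform_{j}" for j in range(X.shape[1])]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            deficient = _confounded_columns(X)
            raise ValueError(f"rank-deficient design; confounded columns: {deficient}")
        # Gaussian GLM == OLS; fit directly (robust to zero residual variance)
        model = sm.OLS(spec.counts, X)
    else:
        conds = pd.Categorical(spec.conditions)
        X = pd.get_dummies(conds, dtype=float).to_numpy()
        names = [str(c) for c in conds.categories]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient condition design")
        model = sm.GLM(
            spec.counts, X, family=sm.families.Poisson(), offset=np.log(spec.offsets)
        )
    res = model.fit()
    return pd.DataFrame(
        {"term": names, "estimate": res.params, "se": res.bse}
    ).reset_index(drop=True)


def _confounded_columns(X: np.ndarray) -> list[int]:
    cols = []
    rank = np.linalg.matrix_rank(X)
    for j in range(X.shape[1]):
        rest = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(rest) == rank:
            cols.append(j)
    return cols


def length_bias_t(lambda1: float, lambda2: float, length_fold: float) -> tuple[float, float]:
    """The closed-form length inflation of a two-sample Poisson t-statistic.

    Scaling both rates by ``L`` gives

        T(L) = (lambda1 - lambda2) / sqrt(lambda1 + lambda2) * sqrt(L),

    so a gene that is ``L`` times longer inflates |T| by exactly ``sqrt(L)``
    with no change in the underlying expression ratio.  Returns ``(T(L),
    sqrt(L))`` — the statistic and its inflation factor relative to L = 1.
    """
    if length_fold <= 0:
        raise ValueError("length fold must be positive")
    if lambda1 + lambda2 <= 0:
        raise ValueError("t undefined for lambda1 = lambda2 = 0")
    t = (lambda1 - lambda2) / np.sqrt(lambda1 + lambda2) * np.sqrt(length_fold)
    return float(t), float(np.sqrt(length_fold))


def fisher_2x2(x: TwoSampleCounts, totals: tuple[int, int]) -> float:
    """Fisher's exact test on the 2x2 table of gene vs rest-of-library counts.

    ``totals`` are the two library totals.  Provided as a thin review helper
    alongside the GLM deviance; it adjusts only for global depth.
    """
    table = [
        [x.n1, x.n2],
        [totals[0] - x.n1, totals[1] - x.n2],
    ]
    return float(stats.fisher_exact(table)[1])
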