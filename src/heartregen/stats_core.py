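"""Group-comparison statistics with a variance-gated test choice.

The study's rule for two-group comparisons of per-heart measurements is:
run Welch's t-test by default, but if an F-test finds the group variances
significantly unequal, fall back to the non-parametric Mann-Whitney U test.
This module implements that gate, a Pearson chi-square comparison of
trichrome stain compositions, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSample",
    "TestResult",
    "gated_two_group_test",
    "chi_square_composition",
    "bh_adjust",
]


@dataclass(frozen=True)
class GroupSample:
    """A named group of real-valued measurements (one value per heart)."""

    values: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) == 0:
            raise ValueError(f"group {self.label!r} is empty")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"group {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``gate_p`` is the p-value of the F variance gate when a gated selection
    was applied, else ``None``. ``degenerate`` flags the zero-variance
    identical-group convention (p = 1 by definition, no information).
    """

    test_name: str
    statistic: float
    p_value: float
    gate_p: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _f_variance_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test p for equality of variances.

    f = var(a)/var(b) (unbiased estimates); p = 2 * min(P(F<=f), P(F>=f)),
    capped at 1.
    """
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        return np.nan, 1.0
    if vb == 0.0:
        return np.inf, 0.0
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = stats.f.cdf(f, dfa, dfb)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(f), float(min(p, 1.0))


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    # exact enumeration for small samples without ties, normal approximation
    # with tie correction otherwise
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(a), len(b)) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def gated_two_group_test(
    a: GroupSample, b: GroupSample, alpha_gate: float = 0.05
) -> TestResult:
    """Welch's t-test, replaced by Mann-Whitney U when variances differ.

    A two-sided F-test on the variance ratio acts as the gate: if its
    p-value is below ``alpha_gate`` the comparison switches to the
    two-sided Mann-Whitney U test, otherwise Welch's two-sided t-test is
    reported. The gate p-value is recorded in ``gate_p`` either way.

    Parameters
    ----------
    a, b
        The two groups; each needs at least two values.
    alpha_gate
        Significance level of the variance gate.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    xa = np.asarray(a.values, dtype=float)
    xb = np.asarray(b.values, dtype=float)

    if np.var(xa) == 0.0 and np.var(xb) == 0.0 and xa[0] == xb[0]:
        # identical constant groups: no evidence of difference, by convention
        return TestResult("welch_t", 0.0, 1.0, gate_p=1.0, degenerate=True)

    _, gate_p = _f_variance_p(xa, xb)
    if gate_p < alpha_gate:
        u, p = _mann_whitney(xa, xb)
        return TestResult("mann_whitney", u, p, gate_p=gate_p)
    t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return TestResult("welch_t", float(t), float(p), gate_p=gate_p)


def chi_square_composition(
    observed_a: tuple[float, float, float],
    observed_b: tuple[float, float, float],
    labels: tuple[str, str, str] = ("red", "blue", "orange"),
) -> TestResult:
    """Pearson chi-square on two percentage compositions.

    The two triples (e.g. %fibrin / %collagen / %muscle of a scar section)
    are laid out as a 2x3 contingency table of percent units (each row
    totals 100) and compared with Pearson's chi-square on 2 degrees of
    freedom. A column whose expected count is zero makes the statistic
    undefined and raises.
    """
    oa = np.asarray(observed_a, dtype=float)
    ob = np.asarray(observed_b, dtype=float)
    for name, row in (("a", oa), ("b", ob)):
        if row.shape != (3,):
            raise ValueError(f"composition {name} must have 3 components")
        if np.any(row < 0):
            raise ValueError(f"composition {name} has negative components")
        if abs(row.sum() - 100.0) > 1e-6:
            raise ValueError(
                f"composition {name} sums to {row.sum()}, expected 100"
            )
    table = np.vstack([oa, ob])
    expected_cols = table.sum(axis=0)
    for j, tot in enumerate(expected_cols):
        if tot == 0.0:
            raise ValueError(
                f"expected count is zero in column {labels[j]!r}; "
                "chi-square undefined"
            )
    if np.allclose(oa, ob):
        return TestResult("chi_square", 0.0, 1.0)
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    assert dof == 2
    return TestResult("chi_square", float(chi2), float(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR).

    Order-preserving: output[i] corresponds to input[i]. Values are >= the
    raw p, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def write_test_results(results: dict[str, TestResult], path) -> None:
    """Write a mapping of comparison name -> TestResult as TSV."""
    import pandas as pd

    rows = [
        {
            "comparison": name,
            "test_name": r.test_name,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "gate_p": "" if r.gate_p is None else r.gate_p,
        }
        for name, r in results.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
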