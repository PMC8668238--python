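"""Mutual-information (G-test) independence tests for categorical data.

The marginal test statistic is G = 2*n*MI(X_i; X_j) with the plug-in mutual
information in nats, referred to an upper-tail chi-square with
(r_i - 1)(r_j - 1) degrees of freedom.  The conditional test stratifies on a
single conditioning variable: G = 2*n*CMI(X_i; X_k | X_cond) with
(r_i - 1)(r_k - 1) * r_cond degrees of freedom.  Degrees of freedom always
use the full nominal arities, even when some cells or strata are empty, so
results are deterministic functions of the declared variable domains.

No multiple-testing adjustment is applied; the screening stage uses a fixed
per-test significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .data_model import CategoricalDataset

__all__ = ["CITResult", "mi_test", "cmi_test", "g_statistic_from_table"]


@dataclass(frozen=True)
class CITResult:
    """A G statistic with its chi-square reference df and p-value."""

    statistic: float
    df: int
    p_value: float


def g_statistic_from_table(table: np.ndarray) -> float:
    """G = 2 * sum_ab N_ab * ln(N_ab * n / (N_a. * N_.b)); empty cells give 0."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        return 0.0
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / n
    nz = table > 0
    return float(2.0 * np.sum(table[nz] * np.log(table[nz] / expected[nz])))


def _contingency(data: CategoricalDataset, i: int, j: int) -> np.ndarray:
    ri, rj = int(data.arities[i]), int(data.arities[j])
    codes = data.values[:, i] * rj + data.values[:, j]
    return np.bincount(codes, minlength=ri * rj).reshape(ri, rj).astype(float)


def mi_test(data: CategoricalDataset, i: int, j: int) -> CITResult:
    """Marginal dependence test between variables i and j.

    Raises ValueError for i == j or for an arity-1 (degenerate) variable.
    """
    if i == j:
        raise ValueError("mi_test requires two distinct variables")
    ri, rj = int(data.arities[i]), int(data.arities[j])
    if ri < 2 or rj < 2:
        raise ValueError("mi_test requires both variables to have arity >= 2")
    g = g_statistic_from_table(_contingency(data, i, j))
    df = (ri - 1) * (rj - 1)
    return CITResult(g, df, float(chi2.sf(g, df)))


def cmi_test(data: CategoricalDataset, i: int, k: int, cond: int) -> CITResult:
    """Conditional dependence test of i vs k given a single variable ``cond``.

    The statistic is the sum over conditioning strata of the per-stratum G
    contribution (equivalently 2*n*CMI in nats); strata with no observations
    contribute 0 but still count toward the degrees of freedom.
    """
    if len({i, k, cond}) != 3:
        raise ValueError("cmi_test requires three pairwise-distinct variables")
    ri, rk = int(data.arities[i]), int(data.arities[k])
    rc = int(data.arities[cond])
    if ri < 2 or rk < 2:
        raise ValueError("cmi_test requires tested variables to have arity >= 2")
    vals = data.values
    codes = (vals[:, cond] * ri + vals[:, i]) * rk + vals[:, k]
    tables = (
        np.bincount(codes, minlength=rc * ri * rk).reshape(rc, ri, rk).astype(float)
    )
    g = sum(g_statistic_from_table(tables[c]) for c in range(rc))
    df = (ri - 1) * (rk - 1) * rc
    return CITResult(g, df, float(chi2.sf(g, df)))
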