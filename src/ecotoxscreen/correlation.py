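"""Spearman rank correlation tables for germination-index correlograms.

Germination indices are bounded, often tied percentages whose joint
distribution is rarely normal, so association between them is measured
by Spearman's rho: the Pearson correlation of midranks (ties receive
average ranks).  Significance uses the usual t approximation,
t = rho·sqrt((n − 2)/(1 − rho²)) on n − 2 df, matching standard
correlogram software; an exact permutation p-value is available for
very small samples (n <= 8).

Correlograms in this field are often labelled with R² values, so the
long-format output carries both rho and rho².
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

__all__ = ["CorrelationResult", "spearman_rho", "correlation_matrix"]

#: reported instead of 0.0 when |rho| = 1 makes the t statistic infinite
P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class CorrelationResult:
    var1: str
    var2: str
    rho: float
    p_value: float
    n_pairs: int

    @property
    def rho_squared(self) -> float:
        return self.rho**2


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be equal-length 1-D sequences")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def _midrank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise InvalidInputError("zero rank variance: a variable is constant")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_rho(
    x, y, *, var1: str = "x", var2: str = "y", method: str = "t"
) -> CorrelationResult:
    """Spearman correlation of two variables with pairwise deletion.

    ``method='t'`` (default) uses the t approximation for the p-value;
    ``method='exact'`` enumerates all permutations of one variable's
    ranks (only for n <= 8) and reports the two-sided tail probability
    of |rho| at least as large as observed.
    """
    xc, yc = _complete_pairs(x, y)
    n = len(xc)
    if n < 3:
        raise InvalidInputError(f"need >= 3 complete pairs, got {n}")
    rho = _midrank_rho(xc, yc)

    if method == "exact":
        if n > 8:
            raise InvalidInputError("exact permutation p only supported for n <= 8")
        ry = stats.rankdata(yc)
        rx = stats.rankdata(xc)
        observed = abs(rho)
        count = total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            total += 1
            if abs(r) >= observed - 1e-12:
                count += 1
        p = count / total
    elif method == "t":
        if abs(rho) >= 1.0 - 1e-15:
            p = P_FLOOR
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    return CorrelationResult(var1=var1, var2=var2, rho=rho, p_value=p, n_pairs=n)


def correlation_matrix(frame: pd.DataFrame, *, method: str = "t") -> pd.DataFrame:
    """All pairwise Spearman correlations of a replicate-by-index table.

    Rows are replicates, columns are variables (germination indices);
    missing entries are handled by pairwise deletion.  Returns a long
    table (var1, var2, rho, rho2, p_value, n) with one row per unordered
    pair, sorted by descending |rho|.  Diagonal entries are omitted
    (rho = 1 by construction).
    """
    cols = list(frame.columns)
    if len(cols) < 2:
        raise InvalidInputError("need at least 2 variables")
    if len(set(cols)) != len(cols):
        raise InvalidInputError("variable labels must be unique")
    rows = []
    for a, b in itertools.combinations(cols, 2):
        res = spearman_rho(frame[a], frame[b], var1=a, var2=b, method=method)
        rows.append(
            {
                "var1": a,
                "var2": b,
                "rho": res.rho,
                "rho2": res.rho_squared,
                "p_value": res.p_value,
                "n": res.n_pairs,
            }
        )
    out = pd.DataFrame(rows)
    return out.reindex(out["rho"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
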