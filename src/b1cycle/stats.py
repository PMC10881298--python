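"""Correlation screening of time series and biomass conversion.

Kendall's tau-b (tie-corrected) is screened over all variable pairs of a
small environmental/biological time-series table. Sample sizes here are
tiny (monthly sampling gives ~12 points), so for n <= 10 the two-sided
p-value is computed exactly by enumerating all n! permutations of one
series; larger n falls back to the usual normal approximation. No
multiple-testing correction is applied; the significance flag is simply
p < .05.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
EXACT_MAX_N = 10
_CHUNK = 40320  # permutations evaluated per vectorized block


def exact_kendall_pvalue(x, y) -> float:
    """Two-sided exact permutation p-value for Kendall's tau-b.

    Enumerates all n! orderings of ``y`` and counts those whose |tau| is
    at least the observed |tau|. The tau-b denominator depends only on
    the tie multisets, which permutation preserves, so comparing the
    concordance statistic S is equivalent and far cheaper.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("series lengths differ")
    if n > EXACT_MAX_N:
        raise ValueError(f"exact enumeration limited to n <= {EXACT_MAX_N}")
    ii, jj = np.triu_indices(n, 1)
    sx = np.sign(x[ii] - x[jj])
    s_obs = abs(float(np.sum(sx * np.sign(y[ii] - y[jj]))))
    count = total = 0
    perms = itertools.permutations(y)
    while True:
        chunk = list(itertools.islice(perms, _CHUNK))
        if not chunk:
            break
        arr = np.asarray(chunk)
        s = np.abs((sx[None, :] * np.sign(arr[:, ii] - arr[:, jj])).sum(axis=1))
        count += int(np.sum(s >= s_obs - 1e-9))
        total += len(chunk)
    return count / total


def kendall_tau(x, y, exact_max_n: int = EXACT_MAX_N) -> tuple[float, float, str]:
    """Tau-b and its p-value; returns ``(tau, p, method)``.

    ``method`` is ``"exact_permutation"`` for n <= ``exact_max_n`` and
    ``"normal_approx"`` otherwise. Constant series make tau undefined and
    return ``(nan, nan, "constant")``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan"), "constant"
    tau = float(sps.kendalltau(x, y, variant="b").statistic)
    if len(x) <= exact_max_n:
        return tau, exact_kendall_pvalue(x, y), "exact_permutation"
    p = float(sps.kendalltau(x, y, variant="b", method="asymptotic").pvalue)
    return tau, p, "normal_approx"


def kendall_screen(
    table: pd.DataFrame,
    alpha: float = ALPHA,
    min_pairs: int = 3,
    exact_max_n: int = EXACT_MAX_N,
) -> pd.DataFrame:
    """All-pairs Kendall correlation screen over a variables table.

    ``table`` has timepoints as rows and variables as columns; missing
    values are handled pairwise-complete. Pairs with fewer than
    ``min_pairs`` shared observations are reported with a
    ``too_few_pairs`` method and no statistic.

    Returns columns ``var_a, var_b, tau, p_value, n_pairs, significant,
    method`` with significance defined as exactly ``p < alpha``.
    """
    cols = list(table.columns)
    rows = []
    for a, b in itertools.combinations(cols, 2):
        pair = table[[a, b]].dropna()
        n = len(pair)
        if n < min_pairs:
            rows.append(
                {"var_a": a, "var_b": b, "tau": np.nan, "p_value": np.nan,
                 "n_pairs": n, "significant": False, "method": "too_few_pairs"}
            )
            continue
        tau, p, method = kendall_tau(pair[a], pair[b], exact_max_n=exact_max_n)
        rows.append(
            {"var_a": a, "var_b": b, "tau": tau, "p_value": p, "n_pairs": n,
             "significant": bool(p < alpha) if np.isfinite(p) else False,
             "method": method}
        )
    return pd.DataFrame(rows)


def bacterial_biomass(cells_per_ml, fg_c_per_cell: float = 20.0):
    """Convert flow-cytometry cell counts to biomass.

    ``cells_per_ml`` (scalar or array) x ``fg_c_per_cell`` -> µg C per
    litre: 1 ml⁻¹ = 1000 l⁻¹ and 1 fg = 1e-9 µg, so the net factor is
    ``fg_c_per_cell * 1e-6``.
    """
    counts = np.asarray(cells_per_ml, dtype=float)
    if (counts < 0).any():
        raise ValueError("cell counts must be >= 0")
    out = counts * fg_c_per_cell * 1e-6
    return float(out) if out.ndim == 0 else out
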