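"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written with plain Python loops and first-principles formulas,
sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def oracle_trim_fewest_missing(matrix: pd.DataFrame, groups: pd.Series) -> list[str]:
    """Row ids surviving the fewest-missing trim, by explicit counting."""
    counts = {rid: int(np.isnan(matrix.loc[rid].to_numpy()).sum()) for rid in matrix.index}
    keep = []
    for g in set(groups.loc[matrix.index]):
        members = [rid for rid in matrix.index if groups[rid] == g]
        best = min(counts[rid] for rid in members)
        keep.extend(rid for rid in members if counts[rid] == best)
    return [rid for rid in matrix.index if rid in keep]


def oracle_score(row: np.ndarray, method: str) -> float:
    obs = row[~np.isnan(row)]
    if method in ("MaxMean", "MinMean"):
        return float(obs.mean())
    if method in ("absMaxMean", "absMinMean"):
        return float(np.abs(obs).mean())
    if method == "maxRowVariance":
        if len(obs) < 2:
            return float("nan")
        mean = obs.mean()
        return float(sum((x - mean) ** 2 for x in obs) / (len(obs) - 1))
    raise ValueError(method)


def oracle_pick(rows: pd.DataFrame, method: str) -> str:
    """Arg-best row under a representative method (assumes no exact ties)."""
    sign = -1.0 if method in ("MinMean", "absMinMean") else 1.0
    scores = {}
    for rid in rows.index:
        s = oracle_score(rows.loc[rid].to_numpy(dtype=float), method)
        scores[rid] = -math.inf if math.isnan(s) else sign * s
    return max(rows.index, key=lambda rid: scores[rid])


def oracle_pairwise_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r over pairwise-complete positions, from the definition."""
    shared = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[shared], y[shared]
    mx, my = xs.mean(), ys.mean()
    num = float(((xs - mx) * (ys - my)).sum())
    den = math.sqrt(float(((xs - mx) ** 2).sum()) * float(((ys - my) ** 2).sum()))
    return num / den


def oracle_hub(rows: pd.DataFrame, beta: float = 1.0) -> str:
    """Most connected row via naive double-loop adjacency and row sums."""
    ids = list(rows.index)
    values = rows.to_numpy(dtype=float)
    n = len(ids)
    k = [0.0] * n
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = oracle_pairwise_pearson(values[i], values[j])
            k[i] += ((1.0 + r) / 2.0) ** beta
    best = max(k)
    for i in range(n):  # first row attaining the maximum
        if k[i] == best:
            return ids[i]
    raise AssertionError


def oracle_collapse_selection(
    matrix: pd.DataFrame,
    groups: pd.Series,
    method: str,
    connectivity_based: bool,
    beta: float = 1.0,
    select_fewest_missing: bool = True,
) -> dict[str, str]:
    """Group -> selected row id, replaying the documented dispatch rules."""
    keep = matrix.index
    if select_fewest_missing:
        keep = oracle_trim_fewest_missing(matrix, groups)
    sub = matrix.loc[keep]
    chosen = {}
    for g in sorted(set(groups.loc[sub.index])):
        members = [rid for rid in sub.index if groups[rid] == g]
        rows = sub.loc[members]
        if len(members) == 1:
            chosen[g] = members[0]
        elif connectivity_based and len(members) >= 3:
            chosen[g] = oracle_hub(rows, beta)
        else:
            chosen[g] = oracle_pick(rows, method)
    return chosen


def oracle_hypergeom_upper_tail(k: int, K: int, M: int, N: int) -> float:
    """P(X >= k) by direct combinatorial summation."""
    total = math.comb(N, K)
    acc = 0
    for j in range(k, min(K, M) + 1):
        acc += math.comb(M, j) * math.comb(N - M, K - j)
    return acc / total
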