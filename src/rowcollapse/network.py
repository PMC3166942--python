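"""Signed weighted correlation networks and node connectivity.

The adjacency between two variables (rows) x_i and x_j is the signed
soft-thresholded transform of their Pearson correlation,

    a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta,

so a correlation of -1 maps to adjacency 0, a correlation of +1 to adjacency
1, and the power beta preserves the continuous correlation information
instead of hard-thresholding it.  The connectivity (degree) of node i is the
sum of its adjacencies to every other node, k_i = sum_{j != i} a_ij — the
standard hub statistic of weighted co-expression networks.

The default soft power is beta = 1: groups being collapsed typically contain
few rows, so there is little need to threshold the correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_BETA = 1.0

#: Minimum shared non-missing samples for a pairwise correlation to be defined.
MIN_PAIR_OVERLAP = 3


class NetworkError(ValueError):
    """Raised when a correlation network cannot be formed."""


def _pairwise_pearson(values: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix over pairwise-complete columns.

    Raises if any pair shares fewer than ``MIN_PAIR_OVERLAP`` non-missing
    samples or if any row has zero variance on some shared support.
    """
    n = values.shape[0]
    mask = ~np.isnan(values)
    if not mask.any(axis=1).all():
        raise NetworkError("row with no observed values")
    if mask.all():
        if values.shape[1] < MIN_PAIR_OVERLAP:
            raise NetworkError(
                f"only {values.shape[1]} shared samples; need >= {MIN_PAIR_OVERLAP}"
            )
        sd = values.std(axis=1)
        if (sd == 0).any():
            bad = int(np.flatnonzero(sd == 0)[0])
            raise NetworkError(f"zero-variance row at position {bad}")
        corr = np.corrcoef(values)
        return np.clip(corr, -1.0, 1.0)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = mask[i] & mask[j]
            if shared.sum() < MIN_PAIR_OVERLAP:
                raise NetworkError(
                    f"rows {i} and {j} share only {int(shared.sum())} samples; "
                    f"need >= {MIN_PAIR_OVERLAP}"
                )
            xi, xj = values[i, shared], values[j, shared]
            if xi.std() == 0 or xj.std() == 0:
                raise NetworkError(f"zero-variance row in pair ({i}, {j})")
            corr[i, j] = corr[j, i] = np.clip(np.corrcoef(xi, xj)[0, 1], -1.0, 1.0)
    return corr


def adjacency_from_correlation(corr: float | np.ndarray, beta: float = DEFAULT_BETA) -> float | np.ndarray:
    """Signed soft-threshold transform: ((1 + r) / 2) ** beta."""
    if beta <= 0:
        raise ValueError(f"soft power beta must be positive, got {beta}")
    return ((1.0 + np.asarray(corr, dtype=float)) / 2.0) ** beta


def signed_adjacency(rows: pd.DataFrame, beta: float = DEFAULT_BETA) -> pd.DataFrame:
    """Signed weighted adjacency matrix among the rows of ``rows``.

    Correlations are Pearson on pairwise-complete samples; the result is a
    symmetric DataFrame with entries in [0, 1] and a unit diagonal (the
    diagonal is excluded from all connectivity sums).
    """
    if rows.shape[0] < 2:
        raise NetworkError("need at least 2 rows to form a network")
    corr = _pairwise_pearson(rows.to_numpy(dtype=float))
    adj = adjacency_from_correlation(corr, beta)
    return pd.DataFrame(adj, index=rows.index, columns=rows.index)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Connectivity k_i = sum of adjacencies of node i to all other nodes."""
    a = adj.to_numpy(dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    return pd.Series(k, index=adj.index, name="k")


def hub_row(rows: pd.DataFrame, beta: float = DEFAULT_BETA) -> str:
    """Identifier of the most highly connected row (the hub).

    If several rows attain the maximum connectivity, the first such row in
    input order is chosen.
    """
    k = connectivity(signed_adjacency(rows, beta)).to_numpy()
    return str(rows.index[int(np.argmax(k))])  # argmax returns first maximum


def whole_network_connectivity(
    matrix: pd.DataFrame, beta: float = DEFAULT_BETA, block_size: int = 512
) -> pd.Series:
    """Connectivity of every row against all other rows of the full matrix.

    Intended for collapsed (one row per gene) matrices with complete data:
    rows containing missing values or with zero variance are excluded with a
    warning, since their correlations are not defined network-wide.  The
    correlation matrix is accumulated in row blocks so memory stays bounded
    for matrices with thousands of rows.
    """
    complete = matrix.dropna(axis=0)
    values = complete.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all() or complete.shape[0] < matrix.shape[0]:
        import logging

        logging.getLogger(__name__).warning(
            "excluding %d row(s) with missing values or zero variance from "
            "whole-network connectivity",
            matrix.shape[0] - int(keep.sum()),
        )
    values = values[keep]
    index = complete.index[keep]
    n = values.shape[0]
    if n < 2:
        raise NetworkError("need at least 2 usable rows for whole-network connectivity")
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    unit = centred / norms[:, None]
    k = np.empty(n)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        corr_block = np.clip(unit[start:stop] @ unit.T, -1.0, 1.0)
        adj_block = adjacency_from_correlation(corr_block, beta)
        # subtract each node's self-adjacency (exactly 1) from its sum
        k[start:stop] = adj_block.sum(axis=1) - 1.0
    return pd.Series(k, index=index, name="k")
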