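"""Cross-dataset reproducibility of collapsing strategies.

Two independently collapsed datasets that measure the same biology should
agree on which genes are highly expressed and on which genes are network
hubs.  The framework quantifies this with two Spearman correlations over the
genes the datasets share: the correlation of ranked per-gene mean expression
and the correlation of ranked whole-network connectivity (computed per
dataset, after collapsing, in a signed weighted correlation network).  A
strategy is evaluated by its average correlations across all dataset pairs,
their standard errors, and the fraction of pairs on which it attains the
highest correlation among the strategies compared ("win" fraction, with ties
splitting the win equally).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .collapse import CollapseConfig, collapse
from .matrix_io import MatrixFormatError, intersect_on_groups
from .network import DEFAULT_BETA, whole_network_connectivity

logger = logging.getLogger(__name__)

#: Pseudo-strategy evaluating uncollapsed matrices intersected on row ids.
NO_COLLAPSE = "none"

MIN_SHARED_ROWS = 3


@dataclass
class StrategyComparison:
    """Aggregate reproducibility of one strategy across dataset pairs."""

    strategy: str
    mean_expression_correlation: float
    mean_connectivity_correlation: float
    se_expression: float
    se_connectivity: float
    win_fraction_expression: float
    win_fraction_connectivity: float
    n_pairs: int


def ranked_mean_expression_correlation(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Spearman correlation of per-row mean expression between two matrices
    already restricted to an identical row-label sequence."""
    _check_aligned(a, b)
    return float(stats.spearmanr(a.mean(axis=1), b.mean(axis=1)).statistic)


def ranked_connectivity_correlation(
    a: pd.DataFrame, b: pd.DataFrame, beta: float = DEFAULT_BETA
) -> float:
    """Spearman correlation of whole-network connectivity between two aligned
    matrices, each network built within its own dataset."""
    _check_aligned(a, b)
    ka = whole_network_connectivity(a, beta)
    kb = whole_network_connectivity(b, beta)
    shared = ka.index.intersection(kb.index)
    if len(shared) < MIN_SHARED_ROWS:
        raise MatrixFormatError(f"only {len(shared)} usable shared rows")
    return float(stats.spearmanr(ka.loc[shared], kb.loc[shared]).statistic)


def _check_aligned(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if list(a.index) != list(b.index):
        raise MatrixFormatError("matrices are not aligned on identical row labels")
    if a.shape[0] < MIN_SHARED_ROWS:
        raise MatrixFormatError(f"need >= {MIN_SHARED_ROWS} shared rows, got {a.shape[0]}")


def _pair_correlations(
    a: pd.DataFrame,
    ga: pd.Series | None,
    b: pd.DataFrame,
    gb: pd.Series | None,
    name: str,
    cfg: CollapseConfig | None,
    beta: float,
) -> tuple[float, float]:
    if name == NO_COLLAPSE:
        ca, cb = a, b
    else:
        ca = collapse(a, ga, cfg).matrix
        cb = collapse(b, gb, cfg).matrix
    ca, cb = intersect_on_groups(ca, cb)
    return (
        ranked_mean_expression_correlation(ca, cb),
        ranked_connectivity_correlation(ca, cb, beta),
    )


def compare_strategies(
    datasets: list[tuple[pd.DataFrame, pd.Series | None]],
    strategies: dict[str, CollapseConfig | None],
    beta: float = DEFAULT_BETA,
) -> list[StrategyComparison]:
    """Evaluate every strategy on every unordered dataset pair.

    ``datasets`` is a list of (matrix, group map) tuples; ``strategies``
    maps strategy names to configs (the value for the ``"none"`` baseline is
    ignored — uncollapsed matrices are intersected on row ids directly).
    Pairs on which any strategy fails (e.g. empty intersection) are skipped
    with a warning; per-pair correlations, means, standard errors and win
    fractions are aggregated over the remaining pairs.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    names = list(strategies)
    expr: dict[str, list[float]] = {n: [] for n in names}
    conn: dict[str, list[float]] = {n: [] for n in names}
    wins_e = {n: 0.0 for n in names}
    wins_k = {n: 0.0 for n in names}
    n_pairs = 0
    for (ia, ib) in itertools.combinations(range(len(datasets)), 2):
        (a, ga), (b, gb) = datasets[ia], datasets[ib]
        try:
            pair = {
                n: _pair_correlations(a, ga, b, gb, n, strategies[n], beta) for n in names
            }
        except MatrixFormatError as exc:
            logger.warning("skipping dataset pair (%d, %d): %s", ia, ib, exc)
            continue
        n_pairs += 1
        for n, (re_, rk) in pair.items():
            expr[n].append(re_)
            conn[n].append(rk)
        for wins, idx in ((wins_e, 0), (wins_k, 1)):
            top = max(v[idx] for v in pair.values())
            tied = [n for n in names if pair[n][idx] == top]
            for n in tied:  # ties split the win
                wins[n] += 1.0 / len(tied)
    if n_pairs == 0:
        raise MatrixFormatError("every dataset pair was skipped")

    def _se(xs: list[float]) -> float:
        return float(np.std(xs, ddof=1) / np.sqrt(len(xs))) if len(xs) > 1 else 0.0

    return [
        StrategyComparison(
            strategy=n,
            mean_expression_correlation=float(np.mean(expr[n])),
            mean_connectivity_correlation=float(np.mean(conn[n])),
            se_expression=_se(expr[n]),
            se_connectivity=_se(conn[n]),
            win_fraction_expression=wins_e[n] / n_pairs,
            win_fraction_connectivity=wins_k[n] / n_pairs,
            n_pairs=n_pairs,
        )
        for n in names
    ]


def comparison_table(comparisons: list[StrategyComparison]) -> pd.DataFrame:
    """Tabulate StrategyComparison records for reporting."""
    return pd.DataFrame([vars(c) for c in comparisons]).set_index("strategy")
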