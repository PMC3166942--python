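"""Marker-based estimation of relative cell-type abundance.

Expression of genes selectively expressed in one cell type tracks that
type's share of a mixed-tissue sample.  The procedure: (1) rank candidate
markers per cell type by fold-change enrichment in that type's pure
profiles against all other types pooled; (2) collapse the marker rows of
the mixture matrix, grouped by cell type, under any collapsing strategy —
the collapsed row is the abundance readout; (3) scale each cell type's row
to sum to one across samples.  The result estimates relative abundance only
up to a per-type constant (like converting between temperature scales), so
accuracy is scored by Pearson correlation with the known truth, pooled over
all (cell type, sample) points and per cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .collapse import CollapseConfig, collapse

logger = logging.getLogger(__name__)

#: Pseudocount guarding fold-change ratios against zero means (linear scale).
FOLD_CHANGE_PSEUDOCOUNT = 1.0


class DeconvolutionError(ValueError):
    pass


@dataclass
class MarkerPanel:
    """Per cell type, marker row ids ordered by descending fold change."""

    markers: dict[str, list[str]]
    fold_changes: dict[str, list[float]]

    def group_map(self) -> pd.Series:
        """Marker row id -> cell type, for use as a collapsing group map."""
        pairs = [(m, t) for t, ms in self.markers.items() for m in ms]
        return pd.Series(dict(pairs), name="cell_type")

    def __len__(self) -> int:
        return sum(len(ms) for ms in self.markers.values())


def select_markers(
    pure: pd.DataFrame,
    type_of_column: pd.Series,
    n: int,
    pseudocount: float = FOLD_CHANGE_PSEUDOCOUNT,
) -> MarkerPanel:
    """Top-``n`` marker genes per cell type by fold-change enrichment.

    Fold change of gene g for type t = (mean over t's pure columns + eps) /
    (mean over all other types' columns + eps), on linear-scale data (for
    log-scale input set ``pseudocount=0`` after exponentiating, or supply
    linearized values).  A gene enriched in several types is assigned only
    to the type where its fold change is highest, keeping panels disjoint.
    Types with fewer than ``n`` genes at fold change > 1 get a truncated,
    warned panel.
    """
    if n <= 0:
        raise DeconvolutionError(f"marker count must be positive, got {n}")
    types = sorted(type_of_column.unique())
    if len(types) < 2:
        raise DeconvolutionError("need at least 2 cell types")
    fc = pd.DataFrame(index=pure.index, columns=types, dtype=float)
    for t in types:
        in_cols = type_of_column.index[type_of_column == t]
        out_cols = type_of_column.index[type_of_column != t]
        fc[t] = (pure[in_cols].mean(axis=1) + pseudocount) / (
            pure[out_cols].mean(axis=1) + pseudocount
        )
    best_type = fc.idxmax(axis=1)  # each gene belongs to its best type only
    markers: dict[str, list[str]] = {}
    folds: dict[str, list[float]] = {}
    for t in types:
        candidates = fc.loc[best_type == t, t]
        candidates = candidates[candidates > 1.0]
        top = candidates.sort_values(ascending=False, kind="stable").head(n)
        if len(top) < n:
            logger.warning(
                "cell type %r: only %d marker(s) with fold change > 1 (requested %d)",
                t, len(top), n,
            )
        markers[t] = [str(g) for g in top.index]
        folds[t] = [float(x) for x in top.to_numpy()]
    return MarkerPanel(markers=markers, fold_changes=folds)


def scale_proportions(abundance: pd.DataFrame) -> pd.DataFrame:
    """Scale each cell type's row to sum to 1 across samples.

    This is the convention under which predicted and true proportions are
    compared; it absorbs the unknown per-type constant.  Composite methods
    (the eigengene in particular) can yield negative entries; the row sum is
    used as-is in that case and the result may contain negatives.
    """
    sums = abundance.sum(axis=1)
    if (sums == 0).any():
        bad = list(abundance.index[sums == 0])
        raise DeconvolutionError(f"zero row-sum for cell type(s) {bad}; cannot scale")
    return abundance.div(sums, axis=0)


def predict_proportions(
    mixtures: pd.DataFrame, panel: MarkerPanel, cfg: CollapseConfig | str = "3.kMax"
) -> pd.DataFrame:
    """Predict relative cell-type abundance across mixture samples.

    Collapses the panel's marker rows of ``mixtures`` grouped by cell type
    under ``cfg``, then applies the sum-to-one-across-samples scaling.
    Markers absent from the mixture matrix are dropped with a warning.
    Non-composite collapsed rows with non-positive sums (which make the
    scaling sign-flipping) are an error naming the type.
    """
    groups = panel.group_map()
    present = groups.index.intersection(mixtures.index)
    if len(present) < len(groups):
        logger.warning(
            "%d marker(s) absent from mixture matrix", len(groups) - len(present)
        )
    if len(present) == 0:
        raise DeconvolutionError("no panel markers present in mixture matrix")
    result = collapse(mixtures, groups.loc[present], cfg)
    abundance = result.matrix
    if result.config.method != "ME":
        bad = list(abundance.index[abundance.sum(axis=1) <= 0])
        if bad:
            raise DeconvolutionError(
                f"non-positive collapsed abundance for cell type(s) {bad}"
            )
    return scale_proportions(abundance)


@dataclass
class PredictionScore:
    """Pearson agreement between predicted and true relative proportions."""

    pooled_r: float
    per_type_r: dict[str, float]


def score_predictions(pred: pd.DataFrame, truth: pd.DataFrame) -> PredictionScore:
    """Correlate predictions with truth, pooled and per cell type.

    Truth is rescaled by the same sum-to-one convention so both sides share
    the scaling; shapes must match exactly.
    """
    if sorted(pred.index) != sorted(truth.index) or list(pred.columns) != list(truth.columns):
        raise DeconvolutionError("prediction and truth dimensions do not match")
    truth = scale_proportions(truth.loc[pred.index])
    pooled = float(
        stats.pearsonr(pred.to_numpy().ravel(), truth.to_numpy().ravel()).statistic
    )
    per_type = {
        str(t): float(stats.pearsonr(pred.loc[t], truth.loc[t]).statistic)
        for t in pred.index
    }
    return PredictionScore(pooled_r=pooled, per_type_r=per_type)


def marker_count_sweep(
    mixtures: pd.DataFrame,
    pure: pd.DataFrame,
    type_of_column: pd.Series,
    truth: pd.DataFrame,
    counts: list[int],
    strategies: dict[str, CollapseConfig | str],
) -> pd.DataFrame:
    """Pooled prediction accuracy as a function of markers-per-type count.

    One row per (marker count, strategy) cell, mirroring robustness analyses
    that vary the panel size.
    """
    records = []
    for n in counts:
        panel = select_markers(pure, type_of_column, n)
        for name, cfg in strategies.items():
            pred = predict_proportions(mixtures, panel, cfg)
            score = score_predictions(pred, truth)
            records.append(
                {"n_markers": n, "strategy": name, "pooled_r": score.pooled_r,
                 **{f"r_{t}": r for t, r in score.per_type_r.items()}}
            )
    return pd.DataFrame(records)
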