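"""Collapse grouped rows of a matrix into one representative or composite row.

Representative methods pick one existing row per group:

* ``MaxMean`` / ``MinMean`` — highest / lowest mean over non-missing entries
  (``MaxMean`` is the default);
* ``absMaxMean`` / ``absMinMean`` — the same on mean absolute values;
* ``maxRowVariance`` — highest sample variance across observations;
* connectivity-based collapsing — for groups of three or more rows, the row
  with the highest connectivity in the signed weighted correlation network
  among the group's rows (the intramodular hub); correlation networks are
  only meaningful from three variables up, so two-row groups fall back to
  the configured biostatistical method and singletons pass through.

Composite methods compute a new row per group: ``average`` (column-wise
mean), ``ME`` (the group's first principal component — the module eigengene
in co-expression applications) and ``function`` (a user-supplied aggregator).

Before collapsing, each group is by default trimmed to the rows with the
fewest missing values.  Score ties among representatives are broken by the
highest sample mean, and any remaining ties uniformly at random under a
recorded seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .matrix_io import align_to_groups
from .network import DEFAULT_BETA, hub_row

logger = logging.getLogger(__name__)

REPRESENTATIVE_METHODS = ("MaxMean", "MinMean", "absMaxMean", "absMinMean", "maxRowVariance")
COMPOSITE_METHODS = ("ME", "average", "function")

#: Sentinel row-id prefix used in provenance tables for composite methods.
COMPOSITE_SENTINEL = "<composite:{method}>"


class CollapseConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CollapseConfig:
    """Configuration of a single collapsing run.

    Parameters mirror the knobs of the aggregation engine: the scoring
    ``method``, whether groups of >= 3 rows are collapsed to their network
    hub (``connectivity_based``), the soft power ``connectivity_power``
    (beta) of the signed network, whether groups are first trimmed to the
    rows with fewest missing values, an optional custom aggregator (required
    iff ``method == "function"``), and the seed used for random tie-breaks.
    """

    method: str = "MaxMean"
    connectivity_based: bool = False
    connectivity_power: float = DEFAULT_BETA
    select_fewest_missing: bool = True
    custom_aggregator: Callable[[pd.DataFrame], np.ndarray] | None = None
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in REPRESENTATIVE_METHODS + COMPOSITE_METHODS:
            raise CollapseConfigError(f"unknown method {self.method!r}")
        if self.connectivity_power <= 0:
            raise CollapseConfigError("connectivity_power must be positive")
        if (self.method == "function") != (self.custom_aggregator is not None):
            raise CollapseConfigError(
                "custom_aggregator must be supplied exactly when method='function'"
            )


#: Named strategy presets used throughout the empirical evaluations.
STRATEGIES: dict[str, CollapseConfig] = {
    "1.max": CollapseConfig(method="MaxMean", connectivity_based=False),
    "2.var": CollapseConfig(method="maxRowVariance", connectivity_based=False),
    "3.kMax": CollapseConfig(method="MaxMean", connectivity_based=True),
    "4.kVar": CollapseConfig(method="maxRowVariance", connectivity_based=True),
    "5.ME": CollapseConfig(method="ME"),
    "6.Avg": CollapseConfig(method="average"),
}


def strategy(name: str, **overrides) -> CollapseConfig:
    """Look up a named strategy preset, optionally overriding fields."""
    try:
        cfg = STRATEGIES[name]
    except KeyError:
        raise CollapseConfigError(
            f"unknown strategy {name!r}; choose from {sorted(STRATEGIES)}"
        ) from None
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class CollapseResult:
    """One collapsed row per group plus per-group provenance."""

    matrix: pd.DataFrame
    group_to_row: dict[str, str]
    config: CollapseConfig = field(repr=False)

    def provenance(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": list(self.group_to_row), "selected_row": list(self.group_to_row.values())}
        ).set_index("group")


def trim_fewest_missing(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Keep, within each group, only the rows with that group's minimum
    missing-value count.  Complete data is the identity case; a group never
    vanishes since its minimum is always attained."""
    missing = matrix.isna().sum(axis=1)
    group_min = missing.groupby(groups.loc[matrix.index]).transform("min")
    return matrix.loc[missing == group_min]


def row_score(matrix: pd.DataFrame, method: str) -> pd.Series:
    """Per-row selection score for a representative method.

    Means are taken over non-missing entries; ``maxRowVariance`` uses the
    unbiased (n-1) sample variance and is undefined (NaN) for rows with
    fewer than two observed values — such rows lose all comparisons.
    """
    if method not in REPRESENTATIVE_METHODS:
        raise CollapseConfigError(f"{method!r} is not a representative method")
    if method in ("MaxMean", "MinMean"):
        return matrix.mean(axis=1)
    if method in ("absMaxMean", "absMinMean"):
        return matrix.abs().mean(axis=1)
    return matrix.var(axis=1, ddof=1)  # NaN when < 2 observed values


def _maximizing(method: str) -> bool:
    return method in ("MaxMean", "absMaxMean", "maxRowVariance")


def select_representative(
    rows: pd.DataFrame, method: str, rng: np.random.Generator | int | None = None
) -> str:
    """Pick the representative row id of one group under a scoring method.

    The arg-max (or arg-min) of the score wins; ties are broken by the
    highest sample mean, and remaining ties uniformly at random.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    score = row_score(rows, method).to_numpy(dtype=float)
    sign = 1.0 if _maximizing(method) else -1.0
    oriented = sign * score
    oriented[np.isnan(oriented)] = -np.inf  # undefined scores lose all ties
    best = oriented == oriented.max()
    if best.sum() > 1:  # break score ties by highest mean
        means = rows.mean(axis=1).to_numpy(dtype=float)
        means = np.where(best, means, -np.inf)
        best = means == means.max()
    candidates = np.flatnonzero(best)
    if len(candidates) > 1:
        logger.debug("random tie-break among %d rows", len(candidates))
        return str(rows.index[rng.choice(candidates)])
    return str(rows.index[candidates[0]])


def module_eigengene(rows: pd.DataFrame) -> np.ndarray:
    """First principal component of a group's rows over the sample dimension.

    Rows are standardized (missing cells imputed with the row mean first);
    the returned scores are the unit-norm first right-singular vector,
    sign-oriented so that its correlation with the group's column-wise mean
    row is non-negative.  A group whose rows are all constant has no
    principal direction: a zero vector is returned with a warning.
    """
    values = rows.to_numpy(dtype=float)
    if np.isnan(values).any():
        logger.warning("imputing missing values with row means for eigengene")
        row_means = np.nanmean(values, axis=1, keepdims=True)
        values = np.where(np.isnan(values), row_means, values)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    nonconstant = sd[:, 0] > 0
    if not nonconstant.any():
        logger.warning("all rows constant; eigengene undefined, returning zeros")
        return np.zeros(values.shape[1])
    z = (values[nonconstant] - values[nonconstant].mean(axis=1, keepdims=True)) / sd[nonconstant]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    mean_row = np.nanmean(rows.to_numpy(dtype=float), axis=0)
    orient = np.dot(pc, mean_row - mean_row.mean())
    if orient == 0:  # mean row uninformative (e.g. x and -x); fall back
        orient = np.dot(pc, z.mean(axis=0))
    if orient == 0:
        nz = np.flatnonzero(pc)
        orient = pc[nz[0]] if len(nz) else 1.0
    if orient < 0:
        pc = -pc
    return pc


def _composite_row(rows: pd.DataFrame, cfg: CollapseConfig, group: str) -> np.ndarray:
    if cfg.method == "average":
        return rows.mean(axis=0).to_numpy(dtype=float)
    if cfg.method == "ME":
        return module_eigengene(rows)
    out = np.asarray(cfg.custom_aggregator(rows), dtype=float).ravel()
    if out.shape != (rows.shape[1],):
        raise CollapseConfigError(
            f"custom aggregator returned length {out.size} for group {group!r}; "
            f"expected {rows.shape[1]}"
        )
    return out


def collapse(
    matrix: pd.DataFrame, groups: pd.Series, cfg: CollapseConfig | str = "MaxMean"
) -> CollapseResult:
    """Collapse a matrix to one row per group under ``cfg``.

    ``cfg`` may be a :class:`CollapseConfig`, a method name, or a strategy
    preset name (``"1.max"`` ... ``"6.Avg"``).  Rows without a usable group
    label are dropped first; if ``cfg.select_fewest_missing``, each group is
    then trimmed to its fewest-missing rows.  Output rows are labelled by
    group and emitted in sorted group order.
    """
    if isinstance(cfg, str):
        cfg = STRATEGIES.get(cfg) or CollapseConfig(method=cfg)
    sub, sub_groups = align_to_groups(matrix, groups)
    if cfg.select_fewest_missing:
        sub = trim_fewest_missing(sub, sub_groups)
        sub_groups = sub_groups.loc[sub.index]
    rng = np.random.default_rng(cfg.random_seed)

    collapsed_rows: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    for group in sorted(sub_groups.unique()):
        rows = sub.loc[sub_groups[sub_groups == group].index]
        if cfg.method in COMPOSITE_METHODS:
            collapsed_rows[group] = _composite_row(rows, cfg, group)
            provenance[group] = COMPOSITE_SENTINEL.format(method=cfg.method)
            continue
        if rows.shape[0] == 1:
            chosen = str(rows.index[0])
        elif cfg.connectivity_based and rows.shape[0] >= 3:
            chosen = hub_row(rows, cfg.connectivity_power)
        else:
            chosen = select_representative(rows, cfg.method, rng)
        collapsed_rows[group] = rows.loc[chosen].to_numpy(dtype=float)
        provenance[group] = chosen

    out = pd.DataFrame.from_dict(collapsed_rows, orient="index", columns=matrix.columns)
    out.index.name = groups.name or "group"
    return CollapseResult(matrix=out, group_to_row=provenance, config=cfg)
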