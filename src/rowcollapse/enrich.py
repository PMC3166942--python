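"""Hypergeometric enrichment of user gene lists against reference lists.

For a user list of size K and a reference list of size M drawn from a
common universe of N genes, the enrichment p-value is the upper tail
P(X >= k) of the hypergeometric distribution — the chance of sharing at
least the observed k genes by random draw.  All (user, reference) pairs are
tested and Bonferroni-corrected; the universe is an explicit parameter
because enrichment p-values are meaningless without a pinned background.

Gene symbols are uppercased and whitespace-trimmed before matching, since
symbol files are notoriously inconsistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


class EnrichmentError(ValueError):
    pass


def normalize_symbol(gene: str) -> str:
    return str(gene).strip().upper()


@dataclass
class GeneListCollection:
    """Named gene lists harmonized against a background universe."""

    lists: dict[str, set[str]]
    universe: set[str]

    @classmethod
    def from_lists(
        cls, lists: dict[str, set[str] | list[str]], universe: set[str] | list[str]
    ) -> "GeneListCollection":
        uni = {normalize_symbol(g) for g in universe}
        if not uni:
            raise EnrichmentError("empty universe")
        harmonized = {}
        for name, genes in lists.items():
            genes = {normalize_symbol(g) for g in genes}
            outside = genes - uni
            if outside:
                logger.warning(
                    "list %r: dropping %d gene(s) outside the universe", name, len(outside)
                )
            harmonized[name] = genes & uni
        return cls(lists=harmonized, universe=uni)


def read_list_collection(path: str | Path, universe: set[str] | list[str]) -> GeneListCollection:
    """Read a two-column (gene, list name) TSV into a collection."""
    table = pd.read_csv(
        path, sep="\t", header=None, names=["gene", "list"], dtype=str,
        keep_default_na=False,
    )
    lists: dict[str, set[str]] = {}
    for name, block in table.groupby("list"):
        lists[str(name)] = set(block["gene"])
    return GeneListCollection.from_lists(lists, universe)


def hypergeometric_p(k: int, K: int, M: int, N: int) -> float:
    """Upper-tail P(X >= k): X ~ Hypergeometric(population N, successes M,
    draws K).  k = 0 gives exactly 1."""
    if not (0 <= k <= min(K, M) and max(K, M) <= N):
        raise EnrichmentError(
            f"invalid counts: k={k}, K={K}, M={M}, N={N} (need 0 <= k <= min(K, M) <= N)"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, M, K))


@dataclass
class EnrichmentRecord:
    user_list: str
    reference_list: str
    overlap: int
    user_size: int
    reference_size: int
    universe_size: int
    p_value: float
    corrected_p: float
    significant: bool
    overlapping_genes: tuple[str, ...]


def enrich(
    user: GeneListCollection,
    reference: GeneListCollection,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentRecord]:
    """Test every (user list, reference list) pair for overlap enrichment.

    Both collections are intersected onto a shared universe; p-values are
    Bonferroni-corrected across all pairs tested, and records with
    corrected p < alpha are flagged significant.
    """
    universe = user.universe & reference.universe
    if not universe:
        raise EnrichmentError("user and reference universes do not intersect")
    n_tests = len(user.lists) * len(reference.lists)
    records = []
    for uname, ugenes in user.lists.items():
        ug = ugenes & universe
        for rname, rgenes in reference.lists.items():
            rg = rgenes & universe
            shared = ug & rg
            p = hypergeometric_p(len(shared), len(ug), len(rg), len(universe))
            corrected = min(1.0, p * n_tests)
            records.append(
                EnrichmentRecord(
                    user_list=uname,
                    reference_list=rname,
                    overlap=len(shared),
                    user_size=len(ug),
                    reference_size=len(rg),
                    universe_size=len(universe),
                    p_value=p,
                    corrected_p=corrected,
                    significant=corrected < alpha,
                    overlapping_genes=tuple(sorted(shared)),
                )
            )
    return records


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = vars(r).copy()
        d["overlapping_genes"] = "|".join(d["overlapping_genes"])
        rows.append(d)
    return pd.DataFrame(rows)


def write_enrichment(
    records: list[EnrichmentRecord],
    path: str | Path,
    significant_path: str | Path | None = None,
) -> None:
    """Write the full table and, optionally, the significant-only table."""
    table = enrichment_table(records)
    table.to_csv(path, sep="\t", index=False)
    if significant_path is not None:
        table[table["significant"]].to_csv(significant_path, sep="\t", index=False)
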