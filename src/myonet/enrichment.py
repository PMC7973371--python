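"""One-sided Fisher's exact (hypergeometric) gene-set enrichment.

Each temporal gene group is tested against each pathway gene set over a
stated gene universe; the p-value is the hypergeometric upper tail
P(X ≥ overlap).  Odds ratios come from the 2×2 table with a
Haldane–Anscombe 0.5 correction when any cell is zero, with a Woolf
log-OR ± 1.96·SE confidence interval.  Benjamini–Hochberg adjustment is
applied within each pathway category by default (configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene-set ids")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def categories(self) -> list[str]:
        return sorted({s.category for s in self.sets})


def fisher_enrich(
    group_genes: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
) -> dict:
    """One-sided (enrichment) Fisher's exact test of a gene group
    against one gene set within a universe.

    Both sets are intersected with the universe first.  Returns a dict
    with overlap/size fields, the upper-tail hypergeometric p-value,
    and the odds ratio with its 95% Woolf interval.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    group = set(group_genes) & universe
    gset = set(gene_set) & universe
    overlap = len(group & gset)
    m = len(universe)
    k_set = len(gset)
    n_group = len(group)
    # upper tail P(X >= overlap) for X ~ Hypergeom(M=m, K=k_set, n=n_group)
    p = float(stats.hypergeom.sf(overlap - 1, m, k_set, n_group))
    p = min(max(p, 0.0), 1.0)

    a = overlap
    b = n_group - overlap
    c = k_set - overlap
    d = m - k_set - n_group + overlap
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = float(a), float(b), float(c), float(d)
    oddsratio = (a2 * d2) / (b2 * c2)
    se_log_or = math.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    ci_low = math.exp(math.log(oddsratio) - 1.96 * se_log_or)
    ci_high = math.exp(math.log(oddsratio) + 1.96 * se_log_or)
    return {
        "overlap": overlap,
        "group_size": n_group,
        "set_size": k_set,
        "universe_size": m,
        "odds_ratio": oddsratio,
        "or_ci_low": ci_low,
        "or_ci_high": ci_high,
        "p": p,
    }


def enrich_all(
    groups: Mapping[str, str] | pd.Series,
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    adjust_scope: str = "category",
) -> pd.DataFrame:
    """Enrichment of every (gene group, gene set) pair.

    ``groups`` maps gene -> group label.  BH adjustment runs within each
    pathway category across all tests in that category
    (``adjust_scope="category"``, the default) or across every test
    jointly (``adjust_scope="global"``).  Rows are flagged significant
    at adjusted p < alpha.
    """
    if adjust_scope not in ("category", "global"):
        raise ValueError(f"unknown adjust_scope {adjust_scope!r}")
    universe = set(universe)
    groups = pd.Series(groups)
    by_label: dict[str, set[str]] = {}
    for gene, label in groups.items():
        by_label.setdefault(label, set()).add(gene)

    rows = []
    for label in sorted(by_label):
        for gset in sorted(collection, key=lambda s: s.set_id):
            res = fisher_enrich(by_label[label], gset.genes, universe)
            rows.append(
                {
                    "group": label,
                    "set_id": gset.set_id,
                    "set_name": gset.name,
                    "category": gset.category,
                    **res,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        table["adj_p"] = []
        table["significant"] = []
        return table
    table["adj_p"] = np.nan
    if adjust_scope == "global":
        table["adj_p"] = adjust_bh(table["p"].to_numpy())
    else:
        for cat in table["category"].unique():
            mask = table["category"] == cat
            table.loc[mask, "adj_p"] = adjust_bh(table.loc[mask, "p"].to_numpy())
    table["significant"] = table["adj_p"] < alpha
    return table
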