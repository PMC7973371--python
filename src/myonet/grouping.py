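"""Temporal gene groups from per-timepoint differential-expression calls.

Genes significant at one or more timepoints are classified by onset,
persistence and direction of differential expression across the three
sampling days (early/mid/late).  The seven groups are:

====== =====================================================
label  per-timepoint call pattern (early, mid, late)
====== =====================================================
EPi    (induced,  induced,  induced)   early onset, persists
MPi    (ns,       induced,  induced)   mid onset, persists
MPr    (ns,       repressed, repressed)
MTi    (ns,       induced,  ns)        mid transient
MTr    (ns,       repressed, ns)
LTi    (ns,       ns,       induced)   late transient
LTr    (ns,       ns,       repressed)
====== =====================================================

Any other pattern with at least one significant call (sign reversals,
early-only, early+late without mid) is ``unclassified``; genes with no
significant call anywhere are excluded from the output entirely.  The
rules are configurable, so additional categories can be defined.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

GROUP_LABELS = ("EPi", "MPi", "MPr", "MTi", "MTr", "LTi", "LTr")
UNCLASSIFIED = "unclassified"
VALID_CALLS = ("induced", "repressed", "ns")

#: default onset × persistence × direction membership rules
DEFAULT_RULES: dict[tuple[str, str, str], str] = {
    ("induced", "induced", "induced"): "EPi",
    ("ns", "induced", "induced"): "MPi",
    ("ns", "repressed", "repressed"): "MPr",
    ("ns", "induced", "ns"): "MTi",
    ("ns", "repressed", "ns"): "MTr",
    ("ns", "ns", "induced"): "LTi",
    ("ns", "ns", "repressed"): "LTr",
}


def call_patterns(de_tables: Mapping[object, pd.DataFrame]) -> pd.DataFrame:
    """Per-gene call triple across the (sorted) timepoints.

    Genes absent from a timepoint's table are treated as ``ns`` there.
    """
    tps = sorted(de_tables.keys())
    if len(tps) != 3:
        raise ValueError(f"expected 3 timepoints, got {tps}")
    genes = sorted(set().union(*(set(t["gene"]) for t in de_tables.values())))
    frame = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for tp in tps:
        table = de_tables[tp]
        calls = pd.Series(
            table["call"].to_numpy(), index=table["gene"].to_numpy()
        )
        frame[f"call_{tp}"] = calls.reindex(genes, fill_value="ns")
    return frame


def assign_groups(
    patterns: pd.DataFrame,
    rules: Mapping[tuple[str, str, str], str] | None = None,
) -> pd.Series:
    """Map each gene's call pattern to a temporal group label.

    ``patterns`` has one row per gene and three call columns in temporal
    order (as produced by :func:`call_patterns`).  Genes that are not
    significant at any timepoint are excluded from the result; patterns
    not covered by the rules are labelled ``unclassified``.
    """
    if rules is None:
        rules = DEFAULT_RULES
    cols = list(patterns.columns)
    if len(cols) != 3:
        raise ValueError(f"expected 3 call columns, got {cols}")
    labels = {}
    for gene, row in patterns.iterrows():
        triple = tuple(row[c] for c in cols)
        for call in triple:
            if call not in VALID_CALLS:
                raise ValueError(f"unknown call symbol {call!r} for gene {gene!r}")
        if all(c == "ns" for c in triple):
            continue
        labels[gene] = rules.get(triple, UNCLASSIFIED)
    return pd.Series(labels, name="group", dtype=object)


def intersection_counts(
    patterns: pd.DataFrame,
    rules: Mapping[tuple[str, str, str], str] | None = None,
) -> pd.DataFrame:
    """Gene counts per non-null call pattern, with group totals.

    Covers all 3³−1 = 26 patterns having at least one significant call;
    each row carries the pattern triple, its gene count, and the group
    label the pattern maps to (or ``unclassified``).  Group totals equal
    the sums of their constituent pattern counts by construction.
    """
    if rules is None:
        rules = DEFAULT_RULES
    cols = list(patterns.columns)
    if len(cols) != 3:
        raise ValueError(f"expected 3 call columns, got {cols}")
    tallies: dict[tuple[str, str, str], int] = {}
    for _, row in patterns.iterrows():
        triple = tuple(row[c] for c in cols)
        for call in triple:
            if call not in VALID_CALLS:
                raise ValueError(f"unknown call symbol {call!r}")
        if all(c == "ns" for c in triple):
            continue
        tallies[triple] = tallies.get(triple, 0) + 1
    rows = []
    for c1 in VALID_CALLS:
        for c2 in VALID_CALLS:
            for c3 in VALID_CALLS:
                triple = (c1, c2, c3)
                if triple == ("ns", "ns", "ns"):
                    continue
                rows.append(
                    {
                        "pattern": "|".join(triple),
                        "count": tallies.get(triple, 0),
                        "group": rules.get(triple, UNCLASSIFIED),
                    }
                )
    return pd.DataFrame(rows)


def group_totals(counts: pd.DataFrame) -> pd.Series:
    """Total genes per group label from an intersection-count table."""
    return counts.groupby("group")["count"].sum()


def load_rules(path) -> dict[tuple[str, str, str], str]:
    """Read membership rules from a YAML mapping of 'c1|c2|c3' -> label."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = {}
    for key, label in raw.items():
        triple = tuple(part.strip() for part in str(key).split("|"))
        if len(triple) != 3 or any(c not in VALID_CALLS for c in triple):
            raise ValueError(f"malformed rule pattern {key!r}")
        rules[triple] = str(label)
    return rules
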