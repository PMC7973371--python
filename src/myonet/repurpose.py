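"""Drug-repurposing target prioritization over a disease subnetwork.

A ChEMBL-style drug-target table is filtered to non-withdrawn,
mechanism-of-action-supported, non-promiscuous records keeping only the
maximum clinical phase per (gene, indication); the surviving targets are
mapped onto the (mouse) subnetwork genes through a mouse→human homology
map; enrichment of approved and phased (phase II/III) target sets in the
subnetwork is tested with the one-sided Fisher's exact test; and the
combinatorial attack search can be restricted to druggable nodes,
optionally conditioned on a fixed base set (e.g. the targets of
established therapy).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from . import attack as attack_mod
from .diffexpr import adjust_bh
from .enrichment import fisher_enrich

REQUIRED_COLUMNS = (
    "drug_id", "drug_name", "gene", "max_phase", "indication",
    "has_moa", "withdrawn",
)

#: a drug targeting more than this many distinct genes is "promiscuous"
DEFAULT_MAX_TARGETS_PER_DRUG = 5

PHASE_CLASS = {4: "approved", 3: "phase III", 2: "phase II"}


def _validate_drug_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"drug table lacks columns: {missing}")
    phases = pd.to_numeric(records["max_phase"], errors="coerce")
    bad = records.loc[phases.isna() | ~phases.isin([1, 2, 3, 4])]
    if len(bad):
        raise ValueError(
            f"malformed max_phase values: {bad['max_phase'].tolist()}"
        )
    records = records.copy()
    records["max_phase"] = phases.astype(int)
    return records


def filter_drug_table(
    records: pd.DataFrame,
    max_targets_per_drug: int = DEFAULT_MAX_TARGETS_PER_DRUG,
) -> pd.DataFrame:
    """Apply the repurposing filters to a drug-target table.

    Drops withdrawn rows, rows without a defined mechanism of action,
    and promiscuous drugs (more than ``max_targets_per_drug`` distinct
    target genes); within each (gene, indication) pair only rows at the
    maximum phase are retained.  The operation is idempotent.
    """
    if records.empty:
        return records.copy()
    records = _validate_drug_table(records)
    kept = records.loc[~records["withdrawn"].astype(bool)]
    kept = kept.loc[kept["has_moa"].astype(bool)]
    if kept.empty:
        return kept.reset_index(drop=True)
    promiscuity = kept.groupby("drug_id")["gene"].nunique()
    ok_drugs = promiscuity.index[promiscuity <= max_targets_per_drug]
    kept = kept.loc[kept["drug_id"].isin(ok_drugs)]
    if kept.empty:
        return kept.reset_index(drop=True)
    max_phase = kept.groupby(["gene", "indication"])["max_phase"].transform("max")
    kept = kept.loc[kept["max_phase"] == max_phase]
    return kept.sort_values(["gene", "indication", "drug_id"]).reset_index(drop=True)


def default_homology(mouse_genes: Iterable[str]) -> dict[str, str]:
    """Uppercase-symbol identity homology map (mouse Btk -> human BTK)."""
    return {g: g.upper() for g in mouse_genes}


def validate_homology(homology: Mapping[str, str]) -> dict[str, str]:
    """Check that no mouse symbol maps to two human symbols."""
    out: dict[str, str] = {}
    for mouse, human in homology.items():
        if mouse in out and out[mouse] != human:
            raise ValueError(f"mouse symbol {mouse!r} maps to multiple human symbols")
        out[mouse] = human
    return out


def map_targets(
    subnetwork_genes: Iterable[str],
    drugs: pd.DataFrame,
    homology: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Map filtered drug records onto subnetwork genes via homology.

    One output row per (subnetwork mouse gene, drug record) whose human
    homolog equals the drug's target gene.  Rows carry the phase class
    (approved / phase III / phase II); phase-1-only records carry no
    class and are excluded from the target-set partition.
    """
    genes = sorted(set(subnetwork_genes))
    if homology is None:
        homology = default_homology(genes)
    else:
        homology = validate_homology(homology)
    rows = []
    if not drugs.empty:
        drugs = _validate_drug_table(drugs)
        by_target: dict[str, pd.DataFrame] = {
            t: sub for t, sub in drugs.groupby("gene")
        }
        for mouse in genes:
            human = homology.get(mouse)
            if human is None or human not in by_target:
                continue
            for _, rec in by_target[human].sort_values("drug_id").iterrows():
                rows.append(
                    {
                        "mouse_gene": mouse,
                        "human_gene": human,
                        "drug_id": rec["drug_id"],
                        "drug_name": rec["drug_name"],
                        "max_phase": int(rec["max_phase"]),
                        "indication": rec["indication"],
                        "phase_class": PHASE_CLASS.get(int(rec["max_phase"]), "NA"),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "mouse_gene", "human_gene", "drug_id", "drug_name",
            "max_phase", "indication", "phase_class",
        ],
    )


def partition_targets(mapped: pd.DataFrame) -> dict[str, set[str]]:
    """Split mapped subnetwork genes into approved-drug targets and
    phased (phase II/III) targets; a gene with any approved drug is
    counted as approved only."""
    approved = set(mapped.loc[mapped["max_phase"] == 4, "mouse_gene"])
    phased = (
        set(mapped.loc[mapped["max_phase"].isin([2, 3]), "mouse_gene"]) - approved
    )
    return {"approved": approved, "phased": phased}


def target_set_enrichment(
    subnetwork_genes: Iterable[str],
    target_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Fisher enrichment of each target set among subnetwork genes,
    BH-adjusted across the target sets."""
    sub = set(subnetwork_genes)
    rows = []
    for name in sorted(target_sets):
        res = fisher_enrich(sub, set(target_sets[name]), universe)
        rows.append({"target_set": name, **res})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["adj_p"] = adjust_bh(table["p"].to_numpy())
    return table


def constrained_attack(
    network: nx.Graph,
    druggable: Iterable[str],
    k: int,
    base_set: Iterable[str] = (),
    top_m: int = 10,
    convention: str = "count-removed",
) -> list[attack_mod.AttackRecord]:
    """Combinatorial attack restricted to druggable candidate nodes."""
    druggable = set(druggable) - set(base_set)
    missing = [v for v in druggable if v not in network]
    if missing:
        raise ValueError(f"druggable nodes absent from network: {sorted(missing)}")
    return attack_mod.combinatorial_attack(
        network,
        k=k,
        candidates=druggable,
        base_set=base_set,
        top_m=top_m,
        convention=convention,
    )
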