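"""File formats, configuration, and the end-to-end pipeline orchestrator.

All tabular outputs are TSV with header rows and ``NA`` for missing
values; gene identifiers are opaque case-sensitive strings.  Gene sets
use the standard GMT dialect (set id, description, member genes,
tab-separated); networks are exchanged as two/three-column edge lists or
GraphML with node-level score/fold-change/FDR attributes and edge
provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import attack as attack_mod
from . import diffexpr, enrichment, grouping, netbuild, repurpose
from .diffexpr import CountsTable
from .enrichment import GeneSet, GeneSetCollection
from .netbuild import SubnetworkResult

logger = logging.getLogger(__name__)

NA = "NA"


# ---------------------------------------------------------------------------
# counts and sample sheets

def read_counts(counts_path, sample_sheet_path) -> CountsTable:
    """Read a gene × sample count TSV plus its sample sheet."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {counts_path}: {dupes}")
    arr = counts.to_numpy()
    if arr.size:
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError(f"non-numeric counts in {counts_path}")
        if np.any(arr != np.floor(arr)):
            gi, sj = np.argwhere(arr != np.floor(arr))[0]
            raise ValueError(
                f"non-integer count at gene {counts.index[gi]!r}, "
                f"sample {counts.columns[sj]!r}"
            )
        if arr.min() < 0:
            gi, sj = np.unravel_index(arr.argmin(), arr.shape)
            raise ValueError(
                f"negative count at gene {counts.index[gi]!r}, "
                f"sample {counts.columns[sj]!r}"
            )
    counts = counts.astype(np.int64)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    if "sample_id" not in sheet.columns:
        raise ValueError(f"sample sheet {sample_sheet_path} lacks 'sample_id'")
    sheet = sheet.set_index("sample_id")
    missing = [s for s in counts.columns if s not in sheet.index]
    if missing:
        raise ValueError(f"samples missing from sample sheet: {missing}")
    return CountsTable(counts, sheet)


def write_counts(table: CountsTable, counts_path, sample_sheet_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="gene")
    table.samples.to_csv(sample_sheet_path, sep="\t", index_label="sample_id",
                         na_rep=NA)


# ---------------------------------------------------------------------------
# differential-expression tables

DE_COLUMNS = ["gene", "log2fc", "p", "fdr", "call"]


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=NA,
                 columns=[c for c in ["gene", "timepoint", *DE_COLUMNS[1:]]
                          if c in table.columns])


def read_de_table(path, timepoint=None, alpha=diffexpr.DEFAULT_ALPHA,
                  lfc_min=diffexpr.DEFAULT_LFC_MIN) -> pd.DataFrame:
    """Read a per-timepoint DE TSV (gene, log2fc, p, fdr[, call]).

    Accepts externally produced tables; when the ``call`` column is
    absent, calls are derived from the stated thresholds.
    """
    table = pd.read_csv(path, sep="\t", na_values=[NA])
    missing = [c for c in ("gene", "log2fc", "p", "fdr") if c not in table.columns]
    if missing:
        raise ValueError(f"DE table {path} lacks columns: {missing}")
    if timepoint is not None and "timepoint" not in table.columns:
        table["timepoint"] = timepoint
    if "call" not in table.columns:
        table["call"] = diffexpr.assign_calls(table, alpha=alpha, lfc_min=lfc_min)
    return table


# ---------------------------------------------------------------------------
# gene sets, edge lists, drug tables, homology, truth labels

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file; the description field doubles as the category tag
    when it is nonempty."""
    sets = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{line_no}: GMT line has {len(fields)} fields, need ≥3"
                )
            set_id, description, *genes = fields
            genes = [g for g in genes if g]
            sets.append(
                GeneSet(set_id, set_id, description or "uncategorized",
                        frozenset(genes))
            )
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gset in sorted(collection, key=lambda s: s.set_id):
            fh.write(
                "\t".join([gset.set_id, gset.category, *sorted(gset.genes)]) + "\n"
            )


def read_edge_lists(paths) -> dict[str, list[tuple[str, str]]]:
    """Read per-pathway edge-list TSVs into {pathway id: [(a, b), ...]}.

    Files may have two columns (pathway id taken from the file stem) or
    three (gene_a, gene_b, pathway_id).  A header row whose first two
    fields look like column names (gene_a/gene_b) is skipped.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    edge_lists: dict[str, list[tuple[str, str]]] = {}
    for path in paths:
        stem = Path(path).stem
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) not in (2, 3):
                    raise ValueError(
                        f"{path}:{line_no}: edge row has {len(fields)} fields"
                    )
                if line_no == 1 and fields[0].lower() in ("gene_a", "source", "from"):
                    continue
                a, b = fields[0], fields[1]
                if not a or not b:
                    raise ValueError(f"{path}:{line_no}: empty gene symbol")
                pid = fields[2] if len(fields) == 3 else stem
                edge_lists.setdefault(pid, []).append((a, b))
    return edge_lists


def write_edge_list(graph: nx.Graph, path, pathway_attr: str = "pathways") -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tpathways\n")
        for u, v in sorted((min(u, v), max(u, v)) for u, v in graph.edges()):
            prov = graph.edges[u, v].get(pathway_attr, ())
            fh.write(f"{u}\t{v}\t{','.join(prov) if prov else NA}\n")


def read_drug_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=[NA])
    for col in ("has_moa", "withdrawn"):
        if col in table.columns and table[col].dtype == object:
            table[col] = table[col].map(
                {"True": True, "False": False, "true": True, "false": False}
            ).fillna(table[col])
    return table


def write_drug_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_homology(path) -> dict[str, str]:
    """Two-column mouse→human symbol TSV; must be one-to-one per mouse
    symbol."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValueError(f"homology map {path} needs two columns")
    mouse_col, human_col = table.columns[:2]
    mapping: dict[str, str] = {}
    for mouse, human in zip(table[mouse_col], table[human_col]):
        mouse, human = str(mouse), str(human)
        if mouse in mapping and mapping[mouse] != human:
            raise ValueError(f"mouse symbol {mouse!r} maps to multiple human symbols")
        mapping[mouse] = human
    return mapping


def write_truth_labels(truth, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlabel\n")
        for gene in sorted(truth.labels):
            fh.write(f"{gene}\t{truth.labels[gene]}\n")


def read_truth_labels(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table["gene"].astype(str), table["label"].astype(str)))


# ---------------------------------------------------------------------------
# GraphML

def write_graphml(subnetwork: SubnetworkResult | nx.Graph, path) -> None:
    """Write a subnetwork (or bare graph) as GraphML, flattening edge
    provenance tuples to comma-joined strings."""
    graph = subnetwork.graph if isinstance(subnetwork, SubnetworkResult) else subnetwork
    out = nx.Graph()
    out.add_nodes_from((v, dict(d)) for v, d in graph.nodes(data=True))
    for u, v, d in graph.edges(data=True):
        d = dict(d)
        if "pathways" in d:
            d["pathways"] = ",".join(d["pathways"])
        out.add_edge(u, v, **d)
    nx.write_graphml(out, path)


def read_graphml(path) -> nx.Graph:
    graph = nx.read_graphml(path)
    for u, v, d in graph.edges(data=True):
        if "pathways" in d and isinstance(d["pathways"], str):
            d["pathways"] = tuple(d["pathways"].split(","))
    return nx.relabel_nodes(graph, str)


# ---------------------------------------------------------------------------
# configuration and pipeline

@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    counts: str = ""
    sample_sheet: str = ""
    gmt: str = ""
    edge_lists: list[str] = field(default_factory=list)
    drug_table: str = ""
    homology: str = ""
    truth_module: str = ""  # optional planted-module gene list (one per line)
    de_tables: dict = field(default_factory=dict)  # timepoint -> path (optional)
    outdir: str = "myonet_out"
    fdr_alpha: float = 0.01
    lfc_min: float = 1.0
    enrichment_alpha: float = 0.05
    subnetwork_size_range: tuple[int, int] = (30, 60)
    attack_k: int = 4
    attack_top_m: int = 10
    convention: str = "count-removed"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1 or not 0 < self.enrichment_alpha < 1:
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be ≥ 0")
        n_min, n_max = self.subnetwork_size_range
        if not 1 <= n_min <= n_max:
            raise ValueError("invalid subnetwork size range")
        if not 1 <= self.attack_k <= attack_mod.MAX_K:
            raise ValueError(f"attack_k must be in 1–{attack_mod.MAX_K}")
        if self.convention not in attack_mod.CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "subnetwork_size_range" in raw:
            raw["subnetwork_size_range"] = tuple(raw["subnetwork_size_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subnetwork_size_range"] = list(d["subnetwork_size_range"])
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run differential expression → grouping → enrichment → subnetwork →
    attack → repurposing, writing every intermediate artifact and a JSON
    manifest (config, seed, input checksums, stage summaries).

    Reruns on identical inputs are bit-identical.  A stage failure
    aborts the run; the manifest records the failing stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = [config.counts, config.sample_sheet, config.gmt,
              config.drug_table, *config.edge_lists]
    if config.homology:
        inputs.append(config.homology)
    if config.truth_module:
        inputs.append(config.truth_module)
    inputs.extend(str(p) for p in config.de_tables.values())
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {str(p): _sha256(p) for p in inputs
                   if p and Path(p).exists()},
        "stages": {},
    }
    manifest_path = outdir / "manifest.json"
    current_stage = "setup"
    try:
        # --- differential expression -------------------------------------
        current_stage = "diffexpr"
        counts = read_counts(config.counts, config.sample_sheet)
        filtered = diffexpr.filter_low_counts(counts)
        if config.de_tables:
            de_tables = {
                tp: read_de_table(path, timepoint=tp, alpha=config.fdr_alpha,
                                  lfc_min=config.lfc_min)
                for tp, path in config.de_tables.items()
            }
        else:
            de_tables = diffexpr.run_differential(
                filtered, alpha=config.fdr_alpha, lfc_min=config.lfc_min
            )
        for tp, table in de_tables.items():
            write_de_table(table, outdir / f"de_d{tp}.tsv")
        manifest["stages"]["diffexpr"] = {
            "genes_tested": int(len(filtered.genes)),
            "genes_called": {
                str(tp): int((t["call"] != "ns").sum()) for tp, t in de_tables.items()
            },
        }

        # --- temporal grouping -------------------------------------------
        current_stage = "grouping"
        patterns = grouping.call_patterns(de_tables)
        groups = grouping.assign_groups(patterns)
        counts_table = grouping.intersection_counts(patterns)
        groups.rename_axis("gene").reset_index().to_csv(
            outdir / "groups.tsv", sep="\t", index=False)
        counts_table.to_csv(outdir / "intersection_counts.tsv", sep="\t",
                            index=False)
        manifest["stages"]["grouping"] = {
            "genes_grouped": int(len(groups)),
            "totals": {
                k: int(v) for k, v in groups.value_counts().sort_index().items()
            },
        }

        # --- enrichment -----------------------------------------------------
        current_stage = "enrichment"
        collection = read_gmt(config.gmt)
        annotated = set().union(*(set(s.genes) for s in collection)) if len(collection) else set()
        universe = set(filtered.genes) & annotated
        enr = enrichment.enrich_all(
            groups[groups != grouping.UNCLASSIFIED], collection, universe,
            alpha=config.enrichment_alpha,
        )
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, na_rep=NA)
        manifest["stages"]["enrichment"] = {
            "tests": int(len(enr)),
            "significant": int(enr["significant"].sum()) if len(enr) else 0,
        }

        # --- subnetwork ------------------------------------------------------
        current_stage = "netbuild"
        edge_lists = read_edge_lists(config.edge_lists)
        parent = netbuild.merge_pathway_networks(edge_lists)
        scores = netbuild.combine_scores(de_tables)
        subnet = netbuild.find_subnetwork(
            parent, scores, size_range=config.subnetwork_size_range
        )
        netbuild.annotate_subnetwork(subnet, de_tables)
        scores.rename_axis("gene").reset_index().to_csv(
            outdir / "scores.tsv", sep="\t", index=False)
        write_edge_list(subnet.graph, outdir / "subnetwork_edges.tsv")
        write_graphml(subnet, outdir / "subnetwork.graphml")
        manifest["stages"]["netbuild"] = {
            "parent_nodes": parent.number_of_nodes(),
            "parent_edges": parent.number_of_edges(),
            "subnetwork_nodes": len(subnet),
            "subnetwork_edges": subnet.graph.number_of_edges(),
            "threshold": float(subnet.threshold),
            "net_weight": float(subnet.net_weight),
            "size_in_range": bool(subnet.size_in_range),
        }
        if config.truth_module:
            with open(config.truth_module) as fh:
                planted = {line.strip() for line in fh if line.strip()}
            recovered = set(subnet.nodes)
            union = recovered | planted
            manifest["stages"]["netbuild"]["jaccard_vs_truth"] = (
                len(recovered & planted) / len(union) if union else 1.0
            )

        # --- attack ---------------------------------------------------------
        current_stage = "attack"
        if len(subnet) == 0:
            raise ValueError("empty subnetwork; cannot run the attack stage")
        profile = attack_mod.attackness_profile(subnet.graph, config.convention)
        _write_attack_records(profile, outdir / "attack_profile.tsv")
        combos = attack_mod.combinatorial_attack(
            subnet.graph, k=min(config.attack_k, len(subnet) - 1),
            top_m=config.attack_top_m, convention=config.convention,
        )
        _write_attack_records(combos, outdir / "attack_combinations.tsv")
        manifest["stages"]["attack"] = {
            "top_single": {"nodes": list(profile[0].removed),
                           "attackness": profile[0].attackness},
            "top_combination": {"nodes": list(combos[0].removed),
                                "attackness": combos[0].attackness},
        }

        # --- repurposing ------------------------------------------------------
        current_stage = "repurpose"
        drug_table = read_drug_table(config.drug_table)
        filtered_drugs = repurpose.filter_drug_table(drug_table)
        homology = read_homology(config.homology) if config.homology else None
        mapped = repurpose.map_targets(subnet.nodes, filtered_drugs, homology)
        mapped.to_csv(outdir / "mapped_targets.tsv", sep="\t", index=False,
                      na_rep=NA)
        targets = repurpose.partition_targets(mapped)
        tse = repurpose.target_set_enrichment(
            subnet.nodes, targets, universe=set(parent.nodes())
        )
        tse.to_csv(outdir / "target_enrichment.tsv", sep="\t", index=False,
                   na_rep=NA)
        druggable = sorted(targets["approved"] | targets["phased"])
        if druggable:
            k = min(config.attack_k, len(druggable))
            constrained = repurpose.constrained_attack(
                subnet.graph, druggable, k=k, top_m=config.attack_top_m,
                convention=config.convention,
            )
            _write_attack_records(constrained, outdir / "constrained_attack.tsv")
            top_constrained = {"nodes": list(constrained[0].removed),
                               "attackness": constrained[0].attackness}
        else:
            top_constrained = None
        manifest["stages"]["repurpose"] = {
            "drug_rows_kept": int(len(filtered_drugs)),
            "mapped_rows": int(len(mapped)),
            "approved_targets": sorted(targets["approved"]),
            "phased_targets": sorted(targets["phased"]),
            "top_constrained": top_constrained,
        }
    except Exception as exc:
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, manifest_path)
        raise

    manifest["completed_stages"] = list(manifest["stages"])
    _write_manifest(manifest, manifest_path)
    logger.info("pipeline complete: %d stages, seed=%d, outdir=%s",
                len(manifest["stages"]), config.seed, outdir)
    return manifest


def _write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_attack_records(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("removed\tattackness\tn_nodes\tgiant_before\tgiant_after\tconvention\n")
        for r in records:
            fh.write(
                f"{','.join(r.removed)}\t{r.attackness:.6g}\t{r.n_nodes}\t"
                f"{r.giant_before}\t{r.giant_after}\t{r.convention}\n"
            )


def read_attack_records(path) -> list[attack_mod.AttackRecord]:
    table = pd.read_csv(path, sep="\t")
    return [
        attack_mod.AttackRecord(
            tuple(str(row.removed).split(",")), float(row.attackness),
            int(row.n_nodes), int(row.giant_before), int(row.giant_after),
            str(row.convention),
        )
        for row in table.itertuples()
    ]
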