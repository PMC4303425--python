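"""Drug -> PTM-enzyme -> disease-gene -> disease network assembly.

Disease genes whose mutations are enriched in PTM regions (hotspot-model
significant) often carry mutated sites with experimentally annotated
upstream enzymes; where an approved drug targets such an enzyme, the chain
drug -> enzyme -> gene -> disease is a candidate repurposing interaction.
Paths are enumerated by relational join over the link tables and exported
as path and node/edge tables; a (drug, disease) pair summary counts the
supporting paths.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

PATH_COLUMNS = ["drug", "enzyme", "gene", "disease", "site_position", "record_ids"]


def assemble(
    pad_genes: set[str],
    significant_regions: pd.DataFrame,
    site_enzymes: pd.DataFrame,
    drug_targets: pd.DataFrame,
    disease_annotations: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enumerate satisfiable drug-enzyme-gene-disease paths.

    Inputs: *pad_genes* — hotspot-significant genes; *significant_regions*
    (protein, start, end) — their significantly mutated PTM regions;
    *site_enzymes* (protein, position, enzyme) — experimentally annotated
    upstream enzymes per modified site; *drug_targets* (drug, enzyme);
    *disease_annotations* (protein, residue_index, disease[, record_id]).
    A path requires the enzyme-bound site to lie in a significant region of
    a significant gene and the disease annotation to hit that region.
    Returns (paths, dangling) where dangling reports identifiers that could
    not be joined (not fatal).
    """
    dangling = []
    if not pad_genes or significant_regions.empty:
        return pd.DataFrame(columns=PATH_COLUMNS), pd.DataFrame(dangling)
    regions = significant_regions[significant_regions["protein"].isin(pad_genes)]
    # sites on non-significant proteins are expected, not dangling; enzymes
    # without any targeting drug are reported below
    se = site_enzymes[site_enzymes["protein"].isin(set(regions["protein"]))]
    sited = se.merge(regions, on="protein")
    sited = sited[(sited["position"] >= sited["start"]) & (sited["position"] <= sited["end"])]
    missing_drug = set(sited["enzyme"]) - set(drug_targets["enzyme"])
    for e in sorted(missing_drug):
        dangling.append({"kind": "enzyme-without-drug", "identifier": e})
    with_drug = sited.merge(drug_targets, on="enzyme")
    ann = disease_annotations.rename(columns={"residue_index": "mutated_position"})
    joined = with_drug.merge(ann, on="protein")
    joined = joined[
        (joined["mutated_position"] >= joined["start"]) & (joined["mutated_position"] <= joined["end"])
    ]
    if joined.empty:
        return pd.DataFrame(columns=PATH_COLUMNS), pd.DataFrame(dangling)
    rec_col = "record_id" if "record_id" in joined.columns else None
    grouped = (
        joined.groupby(["drug", "enzyme", "protein", "disease", "position"])
        .agg(record_ids=(rec_col, lambda s: ";".join(map(str, sorted(set(s)))))
             if rec_col else ("mutated_position", "size"))
        .reset_index()
        .rename(columns={"protein": "gene", "position": "site_position"})
    )
    if rec_col is None:
        grouped = grouped.rename(columns={grouped.columns[-1]: "record_ids"})
    paths = grouped[PATH_COLUMNS].drop_duplicates(subset=PATH_COLUMNS[:5]).reset_index(drop=True)
    return paths, pd.DataFrame(dangling)


def pair_summary(paths: pd.DataFrame) -> pd.DataFrame:
    """Distinct (drug, disease) pairs with supporting path counts."""
    if paths.empty:
        return pd.DataFrame(columns=["drug", "disease", "n_paths"])
    out = (
        paths.groupby(["drug", "disease"]).size().reset_index(name="n_paths")
        .sort_values(["drug", "disease"], kind="stable").reset_index(drop=True)
    )
    return out


def to_graph(paths: pd.DataFrame) -> nx.DiGraph:
    """Directed network: drug -> enzyme -> gene -> disease."""
    g = nx.DiGraph()
    for rec in paths.itertuples(index=False):
        nodes = [
            (f"drug::{rec.drug}", "drug", rec.drug),
            (f"enzyme::{rec.enzyme}", "enzyme", rec.enzyme),
            (f"gene::{rec.gene}", "gene", rec.gene),
            (f"disease::{rec.disease}", "disease", rec.disease),
        ]
        for node, kind, name in nodes:
            g.add_node(node, kind=kind, name=name)
        for (a, _, _), (b, _, _) in zip(nodes, nodes[1:]):
            g.add_edge(a, b)
    return g


def graph_tables(g: nx.DiGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    nodes = pd.DataFrame(
        [{"node": n, "kind": d["kind"], "name": d["name"]} for n, d in g.nodes(data=True)]
    )
    edges = pd.DataFrame([{"source": a, "target": b} for a, b in g.edges()])
    return nodes, edges


def literature_query_list(pairs: pd.DataFrame) -> pd.DataFrame:
    """(drug, disease) query strings for external literature screening."""
    out = pairs[["drug", "disease"]].drop_duplicates().copy()
    out["query"] = out["drug"] + " AND " + out["disease"]
    return out.reset_index(drop=True)
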