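"""Pathway coverage: the fraction of a pathway's members present in a gene list.

Coverage is a similarity readout: a higher coverage of a liver pathway by the
non-DEGs of a cell model means the model preserves more of that pathway's
expression program. The denominator always counts pathway members (genes or
protein nodes), never the query list size.

Two modes exist because pathway mapping tools frequently map more than one
gene to a protein node: in node mode a node counts as covered when any of its
member genes is in the list. As a consequence, node-mode coverages of a DEG
list and its complementary non-DEG list can sum to more than 100% — coverage
of one list is not the inverse of the other.
"""

from __future__ import annotations

import pandas as pd

from .data_model import GeneSet, GeneSetCollection

__all__ = ["compute_coverage", "coverage_matrix"]


def compute_coverage(gene_list: set, pathway: GeneSet, mode: str = "gene") -> float:
    """Coverage percentage of one pathway by one gene list.

    gene mode: 100 * |list ∩ pathway| / |pathway genes|.
    node mode: 100 * (nodes with >= 1 member in the list) / (number of nodes);
    a pathway without node groupings treats each gene as a singleton node.
    """
    genes = set(gene_list)
    if mode == "gene":
        return 100.0 * len(genes & pathway.genes) / len(pathway.genes)
    if mode == "node":
        nodes = pathway.nodes
        if nodes is None:
            nodes = tuple(frozenset({g}) for g in sorted(pathway.genes))
        hit = sum(1 for node in nodes if node & genes)
        return 100.0 * hit / len(nodes)
    raise ValueError(f"unknown coverage mode {mode!r}")


def coverage_matrix(
    gene_lists: dict,
    collection: GeneSetCollection,
    mode: str = "gene",
) -> pd.DataFrame:
    """Pathways x comparisons coverage table, deterministically ordered.

    Rows are pathway ids and columns comparison ids, both sorted. Values are
    percentages in [0, 100]; an empty gene list gives a zero column. Genes
    absent from every pathway contribute nothing.
    """
    if len(gene_lists) == 0:
        raise ValueError("need at least one gene list")
    if len(collection) == 0:
        raise ValueError("need at least one pathway")
    pathway_ids = sorted(p.pathway_id for p in collection)
    comparison_ids = sorted(gene_lists)
    data = {
        comp: [compute_coverage(gene_lists[comp], collection.get(pid), mode) for pid in pathway_ids]
        for comp in comparison_ids
    }
    return pd.DataFrame(data, index=pathway_ids)
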