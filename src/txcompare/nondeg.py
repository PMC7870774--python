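"""Non-DEG / DEG call sets, set overlaps across models, and bootstrap replicate selection.

The similarity metric of the workflow is the number of non-differentially
expressed genes (non-DEGs): genes with adjusted p strictly above 0.05 and
baseMean strictly above 10 when a model is compared against the reference
group. DEGs mirror the definition (padj strictly below 0.05, baseMean strictly
above 10); the +-1 log2-fold-change lines are a direction annotation, not part
of DEG membership. Boundary genes (padj exactly at alpha, baseMean exactly at
the floor) belong to neither set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .data_model import GeneCountMatrix, SampleTable
from .de import DEResult, run_de

__all__ = [
    "GeneCallSet",
    "BootstrapResult",
    "extract_non_degs",
    "extract_degs",
    "make_call_set",
    "overlap_sets",
    "bootstrap_select_replicates",
]

DEFAULT_ALPHA = 0.05
DEFAULT_BASEMEAN_MIN = 10.0
DEFAULT_LFC_FLAG = 1.0


@dataclass
class GeneCallSet:
    """Partition of tested genes into non-DEGs and DEGs for one comparison."""

    comparison_id: str
    non_degs: set
    degs: set
    directions: dict = field(default_factory=dict)  # gene -> up | down | small_effect

    def __post_init__(self) -> None:
        if self.non_degs & self.degs:
            raise ValueError("non-DEG and DEG sets must be disjoint")


def extract_non_degs(
    result: DEResult,
    alpha: float = DEFAULT_ALPHA,
    basemean_min: float = DEFAULT_BASEMEAN_MIN,
) -> set:
    """Genes with padj strictly > alpha AND baseMean strictly > basemean_min.

    Genes with undefined padj (excluded from testing) are never non-DEGs.
    """
    frame = result.frame
    keep = frame["padj"].gt(alpha) & frame["baseMean"].gt(basemean_min) & frame["padj"].notna()
    return set(frame.index[keep])


def extract_degs(
    result: DEResult,
    alpha: float = DEFAULT_ALPHA,
    count_min: float = DEFAULT_BASEMEAN_MIN,
    lfc_flag: float = DEFAULT_LFC_FLAG,
) -> tuple[set, dict]:
    """DEGs (padj < alpha AND baseMean > count_min) with direction flags.

    The flag is "up"/"down" when |log2FC| exceeds ``lfc_flag``, otherwise
    "small_effect" (significant but below the display threshold).
    """
    frame = result.frame
    is_deg = frame["padj"].lt(alpha) & frame["baseMean"].gt(count_min) & frame["padj"].notna()
    degs = set(frame.index[is_deg])
    directions: dict = {}
    for gene in degs:
        lfc = frame.at[gene, "log2FoldChange"]
        if lfc > lfc_flag:
            directions[gene] = "up"
        elif lfc < -lfc_flag:
            directions[gene] = "down"
        else:
            directions[gene] = "small_effect"
    return degs, directions


def make_call_set(
    result: DEResult,
    comparison_id: str,
    alpha: float = DEFAULT_ALPHA,
    basemean_min: float = DEFAULT_BASEMEAN_MIN,
    lfc_flag: float = DEFAULT_LFC_FLAG,
) -> GeneCallSet:
    non_degs = extract_non_degs(result, alpha, basemean_min)
    degs, directions = extract_degs(result, alpha, basemean_min, lfc_flag)
    return GeneCallSet(comparison_id, non_degs, degs, directions)


def overlap_sets(sets: dict, top_n: int = 50) -> pd.DataFrame:
    """Exclusive-intersection (UpSet-style) counts over named gene sets.

    Each gene is counted in exactly one combination cell — the cell of the
    full membership pattern it satisfies. Rows are sorted by descending count
    (ties: lexicographic member tuple) and truncated to ``top_n``; cell counts
    therefore sum to the size of the union before truncation.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets to overlap")
    names = sorted(sets)
    cells: dict[tuple, int] = {}
    universe = set().union(*sets.values())
    for gene in universe:
        members = tuple(n for n in names if gene in sets[n])
        cells[members] = cells.get(members, 0) + 1
    rows = sorted(cells.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return pd.DataFrame(
        {
            "members": ["&".join(members) for members, _ in rows],
            "degree": [len(members) for members, _ in rows],
            "count": [count for _, count in rows],
        }
    )


@dataclass
class BootstrapResult:
    """Per-combination non-DEG/DEG counts and the selected replicate subset."""

    model_label: str
    time_point_h: int
    combinations: pd.DataFrame  # columns: replicates, n_non_degs, n_degs
    selected: tuple

    def write(self, path) -> None:
        out = self.combinations.copy()
        out["selected"] = out["replicates"] == "+".join(self.selected)
        out.to_csv(path, sep="\t", index=False)


def bootstrap_select_replicates(
    matrix: GeneCountMatrix,
    control_ids: list,
    test_replicates: list,
    k: int = 3,
    allow_fewer: bool = False,
    alpha: float = DEFAULT_ALPHA,
    basemean_min: float = DEFAULT_BASEMEAN_MIN,
    model_label: str = "",
    time_point_h: int = 0,
) -> BootstrapResult:
    """Exhaustively evaluate all k-subsets of a model's replicates against the
    full reference group and keep the subset with the most non-DEGs.

    Every combination is a fresh comparison: size factors and dispersions are
    re-estimated on (control union subset). Ties are broken by the
    lexicographically smallest replicate-id tuple; combined with the sorted
    enumeration this makes the selection invariant to the input order of
    ``test_replicates``. When fewer than k replicates exist, ``allow_fewer``
    permits proceeding with k-1 (one model in the study kept 2 of 3 replicates
    after a sequencing-depth filter); otherwise it is an error.
    """
    replicates = sorted(set(test_replicates))
    if len(replicates) < k:
        if allow_fewer and len(replicates) == k - 1:
            k = len(replicates)
        else:
            raise ValueError(
                f"{len(replicates)} replicates available but k={k}; "
                "set allow_fewer=True to proceed with k-1"
            )

    sheet_rows = []
    for s in control_ids:
        sheet_rows.append((s, "control", "reference", 0, s))

    records = []
    best: tuple | None = None
    best_counts: tuple[int, int] | None = None
    for combo in itertools.combinations(replicates, k):
        rows = list(sheet_rows) + [(s, "test", model_label or "model", time_point_h, s) for s in combo]
        samples = SampleTable(
            pd.DataFrame(rows, columns=["sample_id", "group", "model_label", "time_point_h", "replicate_id"])
        )
        result = run_de(matrix.subset_samples(list(control_ids) + list(combo)), samples)
        n_non = len(extract_non_degs(result, alpha, basemean_min))
        n_deg = len(extract_degs(result, alpha, basemean_min)[0])
        records.append({"replicates": "+".join(combo), "n_non_degs": n_non, "n_degs": n_deg})
        if best_counts is None or n_non > best_counts[0] or (n_non == best_counts[0] and combo < best):
            best, best_counts = combo, (n_non, n_deg)

    table = pd.DataFrame(records)
    return BootstrapResult(model_label, time_point_h, table, best)
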