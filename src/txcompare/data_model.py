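"""Domain types and readers/writers for quantification tables, sample sheets and gene sets.

The in-memory containers wrap :class:`pandas.DataFrame` objects and validate the
structural invariants the downstream statistics rely on: unique sample ids, a
two-group (control/test) design, non-negative counts, a single parent gene per
isoform, and per-gene isoform usage percentages that sum to 100.

All on-disk formats are plain tab-delimited UTF-8 text with a header row:
RSEM-style ``.genes.results`` / ``.isoforms.results`` column subsets, plain
count matrices, a sample sheet, and GMT gene-set files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleTable",
    "GeneCountMatrix",
    "IsoformTable",
    "GeneSet",
    "GeneSetCollection",
    "read_sample_table",
    "read_gene_counts",
    "read_isoform_quant",
    "compute_isoform_percentages",
    "read_gene_sets",
    "write_gene_counts",
    "write_isoform_table",
]

#: accepted spellings for the two design groups
GROUP_ALIASES: Mapping[str, str] = {
    "control": "control",
    "ctrl": "control",
    "reference": "control",
    "in_vivo": "control",
    "in vivo": "control",
    "vivo": "control",
    "test": "test",
    "in_vitro": "test",
    "in vitro": "test",
    "vitro": "test",
    "treatment": "test",
}

_VERSION_RE = re.compile(r"\.\d+$")

USAGE_SUM_TOL = 1e-6


def strip_version(identifier: str) -> str:
    """Drop a trailing Ensembl-style ``.N`` version suffix from an id."""
    return _VERSION_RE.sub("", identifier)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ("sample_id", "group", "model_label", "time_point_h", "replicate_id")


@dataclass
class SampleTable:
    """Sample sheet: which samples exist, and which group/model/time they belong to."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample sheet is missing required columns: {missing}")
        if len(self.frame) == 0:
            raise ValueError("no samples in sample sheet")
        ids = self.frame["sample_id"].astype(str)
        dup = ids[ids.duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate sample_id: {sorted(set(dup))}")
        frame = self.frame.copy()
        frame["sample_id"] = ids
        groups = []
        for _, row in frame.iterrows():
            raw = str(row["group"]).strip().lower()
            if raw not in GROUP_ALIASES:
                raise ValueError(
                    f"unknown group label {row['group']!r} for sample {row['sample_id']!r}"
                )
            groups.append(GROUP_ALIASES[raw])
        frame["group"] = groups
        tp = pd.to_numeric(frame["time_point_h"], errors="raise")
        if (tp < 0).any():
            raise ValueError("time_point_h must be non-negative")
        frame["time_point_h"] = tp.astype(int)
        frame = frame.reset_index(drop=True)
        object.__setattr__(self, "frame", frame)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def control_ids(self) -> list[str]:
        return self.frame.loc[self.frame["group"] == "control", "sample_id"].tolist()

    @property
    def test_ids(self) -> list[str]:
        return self.frame.loc[self.frame["group"] == "test", "sample_id"].tolist()

    def group_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["group"].iloc[0])

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        keep = self.frame[self.frame["sample_id"].isin(list(sample_ids))]
        return SampleTable(keep.copy())

    def require_two_groups(self, min_per_group: int = 2) -> None:
        n_control, n_test = len(self.control_ids), len(self.test_ids)
        if n_control < min_per_group or n_test < min_per_group:
            raise ValueError(
                f"need at least {min_per_group} samples per group "
                f"(control={n_control}, test={n_test})"
            )

    def __len__(self) -> int:
        return len(self.frame)


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a tab-delimited sample sheet and validate it.

    Raises on duplicate sample ids, unknown group labels (naming the offending
    row) and empty files.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no samples: {path} is empty") from None
    if len(frame) == 0:
        raise ValueError(f"no samples in {path}")
    return SampleTable(frame)


# ---------------------------------------------------------------------------
# gene counts
# ---------------------------------------------------------------------------


@dataclass
class GeneCountMatrix:
    """Genes x samples expected counts plus per-sample library sizes.

    Expected counts may be fractional (the quantifier emits posterior expected
    counts); they are never rounded before statistics.
    """

    counts: pd.DataFrame  # genes x samples
    library_size: pd.Series | None = None

    def __post_init__(self) -> None:
        counts = self.counts.astype(float)
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {sorted(set(dup))}")
        neg = counts.lt(0)
        if neg.any().any():
            g = counts.index[neg.any(axis=1)][0]
            s = counts.columns[neg.loc[g]][0]
            raise ValueError(f"negative count at gene={g!r}, sample={s!r}")
        if self.library_size is None:
            lib = counts.sum(axis=0)
        else:
            lib = self.library_size.astype(float).reindex(counts.columns)
            if lib.isna().any():
                missing = lib.index[lib.isna()].tolist()
                raise ValueError(f"library_size missing for samples: {missing}")
        if (lib <= 0).any():
            bad = lib.index[lib <= 0].tolist()
            raise ValueError(f"library_size must be > 0, offending samples: {bad}")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "library_size", lib)

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    def subset_samples(self, sample_ids: Sequence[str]) -> "GeneCountMatrix":
        cols = list(sample_ids)
        missing = [s for s in cols if s not in self.counts.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return GeneCountMatrix(self.counts[cols].copy(), self.library_size[cols].copy())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_counts(
    path: str | Path | Sequence[str | Path],
    dialect: str = "matrix",
    sample_table: SampleTable | None = None,
    strip_id_version: bool = False,
) -> GeneCountMatrix:
    """Read gene-level expected counts.

    ``matrix`` dialect: one TSV with a ``gene_id`` column followed by one column
    per sample. ``rsem_genes`` dialect: one ``<sample>.genes.results``-style file
    per sample with at least ``gene_id`` and ``expected_count`` columns; the
    sample id is the file stem with ``.genes.results`` / ``.genes`` removed.

    Gene id universes must be identical across samples; a mismatch is an error
    listing the symmetric difference (silent intersection would change
    downstream non-DEG counts).
    """
    if dialect == "matrix":
        frame = _read_tsv(Path(path))  # type: ignore[arg-type]
        if "gene_id" not in frame.columns:
            raise ValueError("matrix dialect requires a 'gene_id' column")
        frame = frame.set_index("gene_id")
        frame.index = frame.index.astype(str)
        if strip_id_version:
            frame.index = frame.index.map(strip_version)
        matrix = GeneCountMatrix(frame)
    elif dialect == "rsem_genes":
        paths = [Path(p) for p in path]  # type: ignore[union-attr]
        if not paths:
            raise ValueError("no rsem_genes files given")
        columns: dict[str, pd.Series] = {}
        gene_sets: dict[str, set[str]] = {}
        for p in paths:
            sample_id = p.name
            for suffix in (".genes.results", ".genes", ".results", ".tsv"):
                if sample_id.endswith(suffix):
                    sample_id = sample_id[: -len(suffix)]
                    break
            frame = _read_tsv(p)
            for col in ("gene_id", "expected_count"):
                if col not in frame.columns:
                    raise ValueError(f"{p}: missing column {col!r}")
            ids = frame["gene_id"].astype(str)
            if strip_id_version:
                ids = ids.map(strip_version)
            series = pd.Series(frame["expected_count"].to_numpy(float), index=ids)
            columns[sample_id] = series
            gene_sets[sample_id] = set(ids)
        universes = list(gene_sets.values())
        reference = universes[0]
        for sample_id, universe in gene_sets.items():
            if universe != reference:
                diff = sorted(universe ^ reference)
                raise ValueError(
                    f"gene id universes differ across samples (sample {sample_id!r}); "
                    f"symmetric difference: {diff}"
                )
        order = columns[next(iter(columns))].index
        matrix = GeneCountMatrix(pd.DataFrame({s: col.reindex(order) for s, col in columns.items()}))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if sample_table is not None:
        unknown = [s for s in matrix.sample_ids if s not in sample_table.sample_ids]
        if unknown:
            raise ValueError(f"samples present in counts but absent from sample sheet: {unknown}")
    return matrix


def write_gene_counts(matrix: GeneCountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# isoform table
# ---------------------------------------------------------------------------


@dataclass
class IsoformTable:
    """Isoform counts, parent-gene mapping and per-sample usage percentages.

    For each gene and sample the usage percentages over its isoforms sum to
    100 (+- 1e-6), or are all zero when the gene total count is zero.
    """

    counts: pd.DataFrame  # isoforms x samples
    parent_gene: pd.Series  # isoform_id -> gene_id
    usage_pct: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        counts = self.counts.astype(float)
        if counts.index.has_duplicates:
            dup = sorted(set(counts.index[counts.index.duplicated()]))
            raise ValueError(f"duplicate isoform ids: {dup}")
        if counts.lt(0).any().any():
            raise ValueError("negative isoform counts")
        parent = self.parent_gene.astype(str).reindex(counts.index)
        if parent.isna().any():
            missing = parent.index[parent.isna()].tolist()
            raise ValueError(f"isoforms without a parent gene: {missing}")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "parent_gene", parent)
        if self.usage_pct is not None:
            usage = self.usage_pct.astype(float).reindex(index=counts.index, columns=counts.columns)
            if usage.isna().any().any():
                raise ValueError("usage_pct does not cover every isoform/sample")
            if (usage.lt(-USAGE_SUM_TOL) | usage.gt(100 + USAGE_SUM_TOL)).any().any():
                raise ValueError("usage_pct outside [0, 100]")
            sums = usage.groupby(parent).sum()
            ok = sums.sub(100).abs().le(1e-4) | sums.abs().le(USAGE_SUM_TOL)
            if not ok.all().all():
                gene = ok.index[~ok.all(axis=1)][0]
                raise ValueError(f"usage percentages of gene {gene!r} do not sum to 100 (or all-zero)")
            object.__setattr__(self, "usage_pct", usage)

    @property
    def isoform_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.parent_gene:
            seen.setdefault(g, None)
        return list(seen)

    def gene_totals(self) -> pd.DataFrame:
        """Per-gene total counts (genes x samples)."""
        return self.counts.groupby(self.parent_gene).sum()

    def subset_isoforms(self, isoform_ids: Iterable[str]) -> "IsoformTable":
        keep = [i for i in self.counts.index if i in set(isoform_ids)]
        usage = None if self.usage_pct is None else self.usage_pct.loc[keep].copy()
        # subsetting breaks the 100% sum on purpose (filters never renormalize),
        # so bypass usage re-validation
        table = IsoformTable.__new__(IsoformTable)
        object.__setattr__(table, "counts", self.counts.loc[keep].copy())
        object.__setattr__(table, "parent_gene", self.parent_gene.loc[keep].copy())
        object.__setattr__(table, "usage_pct", usage)
        return table

    def subset_samples(self, sample_ids: Sequence[str]) -> "IsoformTable":
        cols = list(sample_ids)
        table = IsoformTable.__new__(IsoformTable)
        object.__setattr__(table, "counts", self.counts[cols].copy())
        object.__setattr__(table, "parent_gene", self.parent_gene.copy())
        usage = None if self.usage_pct is None else self.usage_pct[cols].copy()
        object.__setattr__(table, "usage_pct", usage)
        return table


def compute_isoform_percentages(iso: IsoformTable) -> IsoformTable:
    """Fill ``usage_pct`` as 100 x isoform count / parent-gene total, per sample.

    A gene-sample with zero total count gets all-zero usage (RSEM IsoPct
    convention). Idempotent and invariant to rescaling a gene-sample's counts.
    """
    totals = iso.gene_totals()
    denom = totals.reindex(iso.parent_gene.to_numpy()).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * iso.counts.to_numpy() / denom
    pct = np.where(denom > 0, pct, 0.0)
    usage = pd.DataFrame(pct, index=iso.counts.index, columns=iso.counts.columns)
    return IsoformTable(iso.counts, iso.parent_gene, usage)


def read_isoform_quant(
    paths: str | Path | Sequence[str | Path],
    dialect: str = "rsem_isoforms",
    pct_path: str | Path | None = None,
    strip_id_version: bool = False,
) -> IsoformTable:
    """Read isoform-level quantification.

    ``rsem_isoforms``: one ``.isoforms.results``-style file per sample with
    ``transcript_id``, ``gene_id``, ``expected_count`` and optionally ``IsoPct``
    columns. ``matrix_pair``: a counts TSV with ``isoform_id``, ``gene_id`` and
    sample columns, plus an optional usage TSV of the same shape (``pct_path``).

    Missing usage percentages are derived from counts. An isoform mapped to two
    different genes across files is a hard error naming the isoform.
    """
    if dialect == "rsem_isoforms":
        file_list = [Path(p) for p in paths]  # type: ignore[union-attr]
        if not file_list:
            raise ValueError("no rsem_isoforms files given")
        count_cols: dict[str, pd.Series] = {}
        pct_cols: dict[str, pd.Series] = {}
        parent: dict[str, str] = {}
        have_pct = True
        for p in file_list:
            sample_id = p.name
            for suffix in (".isoforms.results", ".isoforms", ".results", ".tsv"):
                if sample_id.endswith(suffix):
                    sample_id = sample_id[: -len(suffix)]
                    break
            frame = _read_tsv(p)
            for col in ("transcript_id", "gene_id", "expected_count"):
                if col not in frame.columns:
                    raise ValueError(f"{p}: missing column {col!r}")
            tids = frame["transcript_id"].astype(str)
            gids = frame["gene_id"].astype(str)
            if strip_id_version:
                tids = tids.map(strip_version)
                gids = gids.map(strip_version)
            for tid, gid in zip(tids, gids):
                if tid in parent and parent[tid] != gid:
                    raise ValueError(
                        f"isoform {tid!r} mapped to two different genes: "
                        f"{parent[tid]!r} and {gid!r}"
                    )
                parent[tid] = gid
            count_cols[sample_id] = pd.Series(frame["expected_count"].to_numpy(float), index=tids)
            if "IsoPct" in frame.columns:
                pct_cols[sample_id] = pd.Series(frame["IsoPct"].to_numpy(float), index=tids)
            else:
                have_pct = False
        order = count_cols[next(iter(count_cols))].index
        counts = pd.DataFrame({s: c.reindex(order) for s, c in count_cols.items()})
        parent_series = pd.Series(parent).reindex(order)
        if have_pct:
            usage = pd.DataFrame({s: c.reindex(order) for s, c in pct_cols.items()})
            return IsoformTable(counts, parent_series, usage)
        return compute_isoform_percentages(IsoformTable(counts, parent_series))
    if dialect == "matrix_pair":
        frame = _read_tsv(Path(paths))  # type: ignore[arg-type]
        for col in ("isoform_id", "gene_id"):
            if col not in frame.columns:
                raise ValueError(f"matrix_pair counts file requires column {col!r}")
        frame["isoform_id"] = frame["isoform_id"].astype(str)
        if strip_id_version:
            frame["isoform_id"] = frame["isoform_id"].map(strip_version)
            frame["gene_id"] = frame["gene_id"].astype(str).map(strip_version)
        frame = frame.set_index("isoform_id")
        parent_series = frame.pop("gene_id").astype(str)
        counts = frame
        if pct_path is not None:
            pframe = _read_tsv(Path(pct_path)).set_index("isoform_id")
            pframe.index = pframe.index.astype(str)
            if "gene_id" in pframe.columns:
                pframe = pframe.drop(columns="gene_id")
            return IsoformTable(counts, parent_series, pframe)
        return compute_isoform_percentages(IsoformTable(counts, parent_series))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_isoform_table(iso: IsoformTable, counts_path: str | Path, pct_path: str | Path | None = None) -> None:
    out = iso.counts.copy()
    out.insert(0, "gene_id", iso.parent_gene)
    out.index.name = "isoform_id"
    out.to_csv(counts_path, sep="\t")
    if pct_path is not None and iso.usage_pct is not None:
        pout = iso.usage_pct.copy()
        pout.insert(0, "gene_id", iso.parent_gene)
        pout.index.name = "isoform_id"
        pout.to_csv(pct_path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    pathway_id: str
    name: str
    genes: frozenset
    nodes: tuple | None = None  # tuple of frozensets, union == genes

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id!r} has no genes")
        if self.nodes is not None:
            union = frozenset().union(*self.nodes) if self.nodes else frozenset()
            if union != self.genes:
                raise ValueError(
                    f"pathway {self.pathway_id!r}: union of node gene sets must equal the pathway gene set"
                )


@dataclass
class GeneSetCollection:
    pathways: list

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pathway ids")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def get(self, pathway_id: str) -> GeneSet:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)


def read_gene_sets(path: str | Path, node_map: str | Path | None = None) -> GeneSetCollection:
    """Read a GMT file (id, description, tab-separated genes), one pathway per line.

    ``node_map`` is an optional TSV (pathway_id, node_id, gene_id) grouping member
    genes into protein nodes; genes not named by the map become singleton nodes.
    A pathway with zero genes, or a node-map gene outside its pathway, is a hard
    error.
    """
    node_groups: dict[str, dict[str, set]] = {}
    if node_map is not None:
        nm = pd.read_csv(node_map, sep="\t", dtype=str)
        for col in ("pathway_id", "node_id", "gene_id"):
            if col not in nm.columns:
                raise ValueError(f"node map requires column {col!r}")
        for _, row in nm.iterrows():
            node_groups.setdefault(row["pathway_id"], {}).setdefault(row["node_id"], set()).add(
                row["gene_id"]
            )

    pathways: list[GeneSet] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            pathway_id, name = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ValueError(f"pathway {pathway_id!r} has no genes")
            nodes = None
            if pathway_id in node_groups:
                grouped: list[frozenset] = []
                covered: set = set()
                for node_id in sorted(node_groups[pathway_id]):
                    members = node_groups[pathway_id][node_id]
                    outside = members - genes
                    if outside:
                        raise ValueError(
                            f"node map for pathway {pathway_id!r} references genes "
                            f"outside the pathway: {sorted(outside)}"
                        )
                    grouped.append(frozenset(members))
                    covered |= members
                # ungrouped members complete as singleton nodes
                for g in sorted(genes - covered):
                    grouped.append(frozenset({g}))
                nodes = tuple(grouped)
            pathways.append(GeneSet(pathway_id, name, genes, nodes))
    return GeneSetCollection(pathways)
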