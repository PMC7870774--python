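"""Differential-transcript-usage cascade.

A gene shows differential transcript usage (DTU) when the proportional
contribution of its isoforms to the gene total changes between conditions,
even if the total is unchanged. The cascade:

1. low-expression filter on (normalized) isoform counts: drop isoforms whose
   group-mean CPM is below 1 in either group — below noise at this depth;
2. similar-usage filter on percentages: drop isoforms whose control and test
   mean usage differ by at most 10 percentage points;
3. detection filter on percentages: drop isoforms undetected in more than 20%
   of the samples of either group; a group with fewer than 5 samples must
   detect the isoform in every sample;
4. synchronize the count and percentage views (union of removals) and prune
   genes left with a single isoform;
5. classical one-way two-level ANOVA on the usage percentages of the survivors
   (percentages are linear, unlike counts);
6. a gene is called DTU when its control-dominant isoform (highest mean control
   usage) has ANOVA p below 0.01 — a stricter raw threshold because isoform
   quantification has a higher error rate; no multiplicity adjustment.

Removing the DTU genes from the non-DEG set yields the non-DEG^DTU- list:
genes similar at the gene level *and* with stable isoform composition.

Usage percentages are never renormalized after a removal: the ANOVA runs on
the original percentages, so the similar-usage filter's semantics are
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GeneCountMatrix, IsoformTable, SampleTable
from .de import estimate_size_factors, normalize_counts

__all__ = [
    "FilterTrace",
    "DTUCallSet",
    "filter_low_expression",
    "filter_similar_usage",
    "filter_detection",
    "synchronize_and_prune",
    "run_filter_cascade",
    "anova_isoform_usage",
    "call_dtu_genes",
    "derive_nondeg_dtu_minus",
    "run_dtu",
]

DEFAULT_CPM_FLOOR = 1.0
DEFAULT_DELTA_PCT = 10.0
DEFAULT_MAX_MISSING_FRAC = 0.2
DEFAULT_SMALL_N = 5
DEFAULT_ALPHA_DTU = 0.01


@dataclass
class FilterTrace:
    """Audit trail of the cascade: ordered removal steps with disjoint sets."""

    initial: frozenset
    steps: list = field(default_factory=list)  # (step_name, removed frozenset, reason dict)

    def add_step(self, name: str, removed: set, reasons: dict | None = None) -> None:
        already = self.removed_total()
        removed = frozenset(removed) - already
        self.steps.append((name, removed, reasons or {}))

    def removed_total(self) -> frozenset:
        out: set = set()
        for _, removed, _ in self.steps:
            out |= removed
        return frozenset(out)

    def survivors(self) -> frozenset:
        return self.initial - self.removed_total()

    def survivors_after(self, step_name: str) -> frozenset:
        out = set(self.initial)
        for name, removed, _ in self.steps:
            out -= removed
            if name == step_name:
                break
        return frozenset(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, removed, reasons in self.steps:
            for iso in sorted(removed):
                rows.append({"step": name, "isoform_id": iso, "reason": reasons.get(iso, name)})
        return pd.DataFrame(rows, columns=["step", "isoform_id", "reason"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class DTUCallSet:
    """Per-gene DTU summary over cascade survivors."""

    table: pd.DataFrame
    # index gene_id; columns dominant_isoform, control_mean_pct, test_mean_pct,
    # anova_p, is_dtu, dominant_switched
    alpha: float = DEFAULT_ALPHA_DTU

    @property
    def dtu_genes(self) -> set:
        if self.table.empty:
            return set()
        return set(self.table.index[self.table["is_dtu"]])

    @property
    def dominant(self) -> dict:
        return self.table["dominant_isoform"].to_dict()

    def write(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# the three filters
# ---------------------------------------------------------------------------


def _group_columns(iso: IsoformTable, samples: SampleTable) -> tuple[list, list]:
    cols = list(iso.counts.columns)
    ctrl = [s for s in samples.control_ids if s in cols]
    test = [s for s in samples.test_ids if s in cols]
    if len(ctrl) < 2 or len(test) < 2:
        raise ValueError("both groups need at least 2 samples present in the isoform table")
    return ctrl, test


def filter_low_expression(
    iso: IsoformTable,
    samples: SampleTable,
    cpm_floor: float = DEFAULT_CPM_FLOOR,
    counts: pd.DataFrame | None = None,
) -> tuple[set, dict]:
    """Remove isoforms expressed below ``cpm_floor`` counts-per-million in either group.

    CPM is computed per sample against the sample's total isoform counts
    (one-in-a-million reads), then averaged within each group. Operates on the
    count view; pass ``counts`` to use normalized counts.
    """
    ctrl, test = _group_columns(iso, samples)
    values = iso.counts if counts is None else counts
    lib = values.sum(axis=0)
    cpm = values.div(lib, axis=1) * 1e6
    mean_ctrl = cpm[ctrl].mean(axis=1)
    mean_test = cpm[test].mean(axis=1)
    low = mean_ctrl.lt(cpm_floor) | mean_test.lt(cpm_floor)
    removed = set(values.index[low])
    reasons = {
        iso_id: (
            f"mean CPM control={mean_ctrl[iso_id]:.4g}, test={mean_test[iso_id]:.4g} < {cpm_floor:g}"
        )
        for iso_id in removed
    }
    return removed, reasons


def filter_similar_usage(
    iso: IsoformTable,
    samples: SampleTable,
    delta_pct: float = DEFAULT_DELTA_PCT,
) -> tuple[set, dict]:
    """Remove isoforms whose control and test mean usage differ by <= ``delta_pct`` points.

    Inclusive boundary: a difference of exactly ``delta_pct`` is removed.
    Operates on the percentage view.
    """
    if iso.usage_pct is None:
        raise ValueError("usage_pct not populated")
    ctrl, test = _group_columns(iso, samples)
    mean_ctrl = iso.usage_pct[ctrl].mean(axis=1)
    mean_test = iso.usage_pct[test].mean(axis=1)
    delta = (mean_ctrl - mean_test).abs()
    similar = delta.le(delta_pct)
    removed = set(iso.usage_pct.index[similar])
    reasons = {iso_id: f"|delta usage| = {delta[iso_id]:.4g} <= {delta_pct:g}" for iso_id in removed}
    return removed, reasons


def filter_detection(
    iso: IsoformTable,
    samples: SampleTable,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
    small_n: int = DEFAULT_SMALL_N,
) -> tuple[set, dict]:
    """Remove isoforms undetected in more than ``max_missing_frac`` of either group's samples.

    Detection means usage_pct > 0 (equivalently count > 0). A group with fewer
    than ``small_n`` samples must detect the isoform in all of them. Operates on
    the percentage view.
    """
    if iso.usage_pct is None:
        raise ValueError("usage_pct not populated")
    ctrl, test = _group_columns(iso, samples)
    removed: set = set()
    reasons: dict = {}
    for label, cols in (("control", ctrl), ("test", test)):
        n = len(cols)
        missing = iso.usage_pct[cols].le(0).sum(axis=1)
        if n < small_n:
            bad = missing.gt(0)
            rule = "all-samples rule (n < small_n)"
        else:
            bad = (missing / n).gt(max_missing_frac)
            rule = f"missing fraction > {max_missing_frac:g}"
        for iso_id in iso.usage_pct.index[bad]:
            if iso_id not in removed:
                removed.add(iso_id)
                reasons[iso_id] = f"{label}: undetected in {missing[iso_id]}/{n} samples ({rule})"
    return removed, reasons


# ---------------------------------------------------------------------------
# synchronization and pruning
# ---------------------------------------------------------------------------


def synchronize_and_prune(
    iso: IsoformTable,
    count_removals: set,
    pct_removals: set,
) -> tuple[IsoformTable, set]:
    """Union the removals of the count and percentage views, then prune genes
    left with a single surviving isoform (the lone isoform is removed too).

    Returns the surviving table (percentages NOT renormalized) and the set of
    isoforms removed by the single-isoform prune.
    """
    removed = set(count_removals) | set(pct_removals)
    survivors = [i for i in iso.isoform_ids if i not in removed]
    sub = iso.subset_isoforms(survivors)
    sizes = sub.parent_gene.groupby(sub.parent_gene).size()
    lonely_genes = set(sizes.index[sizes < 2])
    pruned = {i for i in sub.isoform_ids if sub.parent_gene[i] in lonely_genes}
    final = sub.subset_isoforms([i for i in sub.isoform_ids if i not in pruned])
    return final, pruned


def run_filter_cascade(
    iso: IsoformTable,
    samples: SampleTable,
    cpm_floor: float = DEFAULT_CPM_FLOOR,
    delta_pct: float = DEFAULT_DELTA_PCT,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
    small_n: int = DEFAULT_SMALL_N,
    normalized_counts: pd.DataFrame | None = None,
) -> tuple[IsoformTable, FilterTrace]:
    """Apply the full cascade in its fixed order and return survivors plus trace.

    Order: low-expression (counts) -> similar-usage (percentages) -> detection
    (percentages) -> synchronize -> prune single-isoform genes. Each filter is
    evaluated on the full table; an isoform failing several filters is
    attributed to the first step in the order, keeping trace sets disjoint.
    """
    if iso.usage_pct is None:
        raise ValueError("usage_pct not populated; call compute_isoform_percentages first")
    trace = FilterTrace(frozenset(iso.isoform_ids))

    low, low_reasons = filter_low_expression(iso, samples, cpm_floor, counts=normalized_counts)
    trace.add_step("low_expression", low, low_reasons)

    similar, similar_reasons = filter_similar_usage(iso, samples, delta_pct)
    trace.add_step("similar_usage", similar, similar_reasons)

    detect, detect_reasons = filter_detection(iso, samples, max_missing_frac, small_n)
    trace.add_step("detection", detect, detect_reasons)

    final, pruned = synchronize_and_prune(iso, low, similar | detect)
    trace.add_step("single_isoform_prune", pruned, {i: "gene left with one isoform" for i in pruned})
    return final, trace


# ---------------------------------------------------------------------------
# ANOVA and DTU calling
# ---------------------------------------------------------------------------


def anova_isoform_usage(iso: IsoformTable, samples: SampleTable) -> pd.Series:
    """One-way fixed-effects ANOVA of usage percentage on group (two levels), per isoform.

    Classical equal-variance F test; with two levels F equals the squared
    pooled-variance t statistic. Degenerate rows (zero within-group variance
    everywhere) take the limit convention: p = 1 for equal group means, p = 0
    otherwise.
    """
    if iso.usage_pct is None:
        raise ValueError("usage_pct not populated")
    ctrl, test = _group_columns(iso, samples)
    xc = iso.usage_pct[ctrl].to_numpy(float)
    xt = iso.usage_pct[test].to_numpy(float)
    nc, nt = xc.shape[1], xt.shape[1]
    n = nc + nt
    mc = xc.mean(axis=1)
    mt = xt.mean(axis=1)
    grand = (nc * mc + nt * mt) / n
    ssb = nc * (mc - grand) ** 2 + nt * (mt - grand) ** 2
    ssw = ((xc - mc[:, None]) ** 2).sum(axis=1) + ((xt - mt[:, None]) ** 2).sum(axis=1)
    df_within = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / 1.0) / (ssw / df_within)
    p = stats.f.sf(f, 1, df_within)
    degenerate = ssw <= 0
    p = np.where(degenerate & (ssb <= 1e-24), 1.0, p)
    p = np.where(degenerate & (ssb > 1e-24), 0.0, p)
    return pd.Series(p, index=iso.usage_pct.index, name="anova_p")


def call_dtu_genes(
    iso: IsoformTable,
    pvalues: pd.Series,
    samples: SampleTable,
    alpha: float = DEFAULT_ALPHA_DTU,
) -> DTUCallSet:
    """Call DTU genes by the control-dominant-isoform rule.

    For each surviving gene the dominant isoform is the argmax of mean control
    usage (ties: lexicographically smallest isoform id); the gene is DTU iff
    that isoform's ANOVA p is strictly below ``alpha``. A ``dominant_switched``
    column flags genes whose test-dominant isoform differs from the control's,
    for inspection only — it never enters the call.
    """
    if iso.usage_pct is None:
        raise ValueError("usage_pct not populated")
    rows = []
    if len(iso.isoform_ids) > 0:
        ctrl, test = _group_columns(iso, samples)
        mean_ctrl = iso.usage_pct[ctrl].mean(axis=1)
        mean_test = iso.usage_pct[test].mean(axis=1)
        for gene, members in iso.parent_gene.groupby(iso.parent_gene).groups.items():
            members = sorted(members)
            best_val = max(mean_ctrl[i] for i in members)
            # ties resolved by the lexicographically smallest isoform id
            dominant = min(i for i in members if mean_ctrl[i] == best_val)
            test_dominant = min([i for i in members if mean_test[i] == mean_test[members].max()])
            p = float(pvalues[dominant])
            rows.append(
                {
                    "gene_id": gene,
                    "dominant_isoform": dominant,
                    "control_mean_pct": float(best_val),
                    "test_mean_pct": float(mean_test[dominant]),
                    "anova_p": p,
                    "is_dtu": p < alpha,
                    "dominant_switched": test_dominant != dominant,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "dominant_isoform",
            "control_mean_pct",
            "test_mean_pct",
            "anova_p",
            "is_dtu",
            "dominant_switched",
        ],
    ).set_index("gene_id")
    return DTUCallSet(table, alpha)


def derive_nondeg_dtu_minus(non_degs: set, dtu: DTUCallSet) -> set:
    """non-DEG^DTU- = non-DEGs minus DTU genes (always a subset of non-DEGs)."""
    return set(non_degs) - dtu.dtu_genes


def run_dtu(
    iso: IsoformTable,
    samples: SampleTable,
    cpm_floor: float = DEFAULT_CPM_FLOOR,
    delta_pct: float = DEFAULT_DELTA_PCT,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
    small_n: int = DEFAULT_SMALL_N,
    alpha: float = DEFAULT_ALPHA_DTU,
    normalize: bool = True,
) -> tuple[DTUCallSet, FilterTrace]:
    """Full DTU path for one comparison.

    Isoform counts are normalized with median-of-ratios size factors (as for
    gene counts) before the CPM filter when ``normalize`` is on; the CPM ratio
    itself is invariant to per-sample scaling, so this mirrors the stated
    procedure without changing which isoforms pass. An empty survivor set
    yields an empty call set.
    """
    sub = iso.subset_samples([s for s in samples.sample_ids if s in iso.counts.columns])
    norm_counts = None
    if normalize:
        sf = estimate_size_factors(sub.counts)
        norm_counts = sub.counts.div(sf, axis=1)
    survivors, trace = run_filter_cascade(
        sub,
        samples,
        cpm_floor=cpm_floor,
        delta_pct=delta_pct,
        max_missing_frac=max_missing_frac,
        small_n=small_n,
        normalized_counts=norm_counts,
    )
    if len(survivors.isoform_ids) == 0:
        empty = pd.DataFrame(
            columns=[
                "gene_id",
                "dominant_isoform",
                "control_mean_pct",
                "test_mean_pct",
                "anova_p",
                "is_dtu",
                "dominant_switched",
            ]
        ).set_index("gene_id")
        return DTUCallSet(empty, alpha), trace
    pvalues = anova_isoform_usage(survivors, samples)
    calls = call_dtu_genes(survivors, pvalues, samples, alpha)
    return calls, trace
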