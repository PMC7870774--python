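"""Negative-binomial differential-expression engine for two-group comparisons.

This is a deliberately simplified re-implementation of the standard bulk
RNA-seq workflow: median-of-ratios size factors, method-of-moments gene-wise
dispersions shrunk toward a parametric mean-dispersion trend, a per-gene NB
GLM Wald test of the group coefficient (log link, size-factor offsets), and
Benjamini-Hochberg adjustment. There is no Cox-Reid adjustment, no outlier
refitting and no independent filtering: the decision logic downstream operates
only on (padj, baseMean) thresholds, which this engine reproduces.

Everything is vectorized across genes, so a full comparison (thousands of
genes, dozens of samples) runs in milliseconds — which makes the exhaustive
bootstrap over replicate combinations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GeneCountMatrix, SampleTable

__all__ = [
    "DEResult",
    "estimate_size_factors",
    "normalize_counts",
    "estimate_dispersions",
    "wald_test",
    "adjust_bh",
    "run_de",
]

MIN_DISPERSION = 1e-8
MAX_DISPERSION = 20.0
#: log-space weight of the fitted trend when shrinking gene-wise dispersions
TREND_SHRINK_WEIGHT = 0.6
#: pseudo-count added to group means for fold-change reporting only
LFC_PSEUDOCOUNT = 0.5


@dataclass
class DEResult:
    """Per-gene DE summary: baseMean, log2FoldChange (test over control), Wald p, BH padj."""

    frame: pd.DataFrame  # index gene_id; columns baseMean, log2FoldChange, pvalue, padj

    @property
    def gene_ids(self) -> list[str]:
        return self.frame.index.tolist()

    def write(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "DEResult":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def estimate_size_factors(counts: pd.DataFrame | GeneCountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to unit geometric mean.

    factor_j = median over genes (with a positive geometric mean across all
    samples) of count_gj / geometric_mean_g, divided by the geometric mean of
    the per-sample medians. The rescaling pins the overall scale so that
    re-estimating on normalized counts returns exactly unit factors (the
    normalization is a fixed point). Invariant to gene order.
    """
    if isinstance(counts, GeneCountMatrix):
        counts = counts.counts
    if counts.shape[1] < 2:
        raise ValueError("size-factor estimation needs at least 2 samples")
    values = counts.to_numpy(float)
    with np.errstate(divide="ignore"):
        log_values = np.log(values)
    log_geomean = log_values.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError(
            "no gene has positive counts in every sample; cannot apply median-of-ratios "
            "(consider library-size scaling as a fallback)"
        )
    ratios = np.exp(log_values[usable] - log_geomean[usable, None])
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(matrix: GeneCountMatrix, size_factors: pd.Series) -> GeneCountMatrix:
    """Divide each sample column by its size factor; library sizes are recomputed."""
    sf = size_factors.reindex(matrix.counts.columns)
    if sf.isna().any():
        missing = sf.index[sf.isna()].tolist()
        raise ValueError(f"size factors missing for samples: {missing}")
    return GeneCountMatrix(matrix.counts.div(sf, axis=1))


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------


def _fit_dispersion_trend(base_mean: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Fit the parametric trend alpha(mu) = a0 + a1/mu by iterated weighted least squares.

    Gamma-family-style weights (1/prediction^2); coefficients clipped to be
    non-negative. Falls back to the median moment estimate when too few genes
    are informative.
    """
    use = np.isfinite(alpha_mom) & (alpha_mom > 1e-7) & (base_mean > 0)
    if use.sum() < 10:
        med = float(np.nanmedian(np.where(alpha_mom > 0, alpha_mom, np.nan)))
        if not np.isfinite(med) or med <= 0:
            med = 0.1
        return med, 0.0
    x = 1.0 / base_mean[use]
    y = alpha_mom[use]
    a0, a1 = max(float(np.median(y)), 1e-6), 0.0
    design = np.column_stack([np.ones_like(x), x])
    for _ in range(6):
        pred = np.clip(a0 + a1 * x, 1e-6, None)
        w = 1.0 / pred**2
        lhs = design.T @ (design * w[:, None])
        rhs = design.T @ (w * y)
        try:
            coef = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            break
        a0 = float(max(coef[0], 1e-9))
        a1 = float(max(coef[1], 0.0))
    return a0, a1


def estimate_dispersions(
    matrix: GeneCountMatrix,
    size_factors: pd.Series,
    samples: SampleTable,
) -> pd.Series:
    """Per-gene NB dispersions: method of moments within groups, shrunk to a trend.

    On normalized counts x = y/s, Var(x) = q * mean(1/s) + alpha * q^2 within a
    group with common mean q, so the moment estimate pools
    (variance - q * mean(1/s)) / q^2 across the two groups, weighted by their
    degrees of freedom. Gene-wise estimates are then shrunk toward the fitted
    trend alpha(mu) = a0 + a1/mu in log space. Genes with zero counts everywhere
    get NaN (excluded from testing).
    """
    samples.require_two_groups()
    sf = size_factors.reindex(matrix.counts.columns).to_numpy(float)
    y = matrix.counts.to_numpy(float)
    x = y / sf[None, :]

    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    base_mean = x.mean(axis=1)
    for ids in (samples.control_ids, samples.test_ids):
        cols = [matrix.counts.columns.get_loc(s) for s in ids]
        xg = x[:, cols]
        n = len(cols)
        if n < 2:
            raise ValueError("need at least 2 samples per group to estimate dispersions")
        m = xg.mean(axis=1)
        v = xg.var(axis=1, ddof=1)
        inv_s = float(np.mean(1.0 / sf[cols]))
        num += (n - 1) * (v - m * inv_s)
        den += (n - 1) * m**2

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = num / den
    alpha_mom = np.where(den > 0, np.clip(alpha_mom, MIN_DISPERSION, MAX_DISPERSION), np.nan)

    a0, a1 = _fit_dispersion_trend(base_mean, alpha_mom)
    with np.errstate(divide="ignore"):
        alpha_trend = np.clip(a0 + a1 / np.where(base_mean > 0, base_mean, np.nan), MIN_DISPERSION, MAX_DISPERSION)
    w = TREND_SHRINK_WEIGHT
    log_shrunk = w * np.log(alpha_trend) + (1 - w) * np.log(alpha_mom)
    alpha = np.exp(log_shrunk)
    alpha = np.where(np.isnan(alpha_mom) | np.isnan(alpha_trend), np.nan, alpha)
    return pd.Series(alpha, index=matrix.counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------


def _fit_group_mean(
    y: np.ndarray, sf: np.ndarray, alpha: np.ndarray, n_iter: int = 60, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """MLE of the per-gene group mean q (on the normalized scale) for NB counts
    with known dispersion and per-sample offsets sf; Newton iterations on log q.

    Returns (q_hat, fisher_info) where fisher_info is the observed information
    for theta = log q: sum_j mu_j / (1 + alpha * mu_j). Groups with all-zero
    counts return q_hat = 0 and info 0 (handled by the caller).
    """
    totals = y.sum(axis=1)
    s_sum = sf.sum()
    q0 = totals / s_sum
    positive = q0 > 0
    theta = np.where(positive, np.log(np.where(positive, q0, 1.0)), 0.0)
    for _ in range(n_iter):
        mu = np.exp(theta)[:, None] * sf[None, :]
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        curvature = -(mu * (1.0 + alpha[:, None] * y) / denom**2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(curvature < 0, score / curvature, 0.0)
        step = np.clip(step, -3.0, 3.0)
        theta = np.where(positive, theta - step, theta)
        if np.nanmax(np.abs(np.where(positive, step, 0.0))) < tol:
            break
    q = np.where(positive, np.exp(theta), 0.0)
    mu = q[:, None] * sf[None, :]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return q, info


def wald_test(
    matrix: GeneCountMatrix,
    size_factors: pd.Series,
    samples: SampleTable,
    dispersions: pd.Series,
) -> DEResult:
    """Per-gene NB Wald test of test-vs-control, with BH-adjusted p-values.

    For each gene the group means are fitted by maximum likelihood with known
    dispersion and size-factor offsets; the Wald statistic is
    z = (log q_test - log q_control) / sqrt(1/I_control + 1/I_test).
    A group with all-zero counts is replaced by the pseudo-mean 0.5/sum(s) so
    the statistic stays finite in the degenerate direction. The reported
    log2FoldChange adds a 0.5 pseudo-count to both group means (reporting only,
    never the test statistic). baseMean is the mean of normalized counts over
    all samples of the comparison. Deterministic given inputs.
    """
    samples.require_two_groups()
    cols = matrix.counts.columns
    sf = size_factors.reindex(cols).to_numpy(float)
    y = matrix.counts.to_numpy(float)
    alpha = dispersions.reindex(matrix.counts.index).to_numpy(float)

    tested = np.isfinite(alpha)
    alpha_safe = np.where(tested, alpha, 0.1)

    ctrl_cols = [cols.get_loc(s) for s in samples.control_ids]
    test_cols = [cols.get_loc(s) for s in samples.test_ids]

    q_c, info_c = _fit_group_mean(y[:, ctrl_cols], sf[ctrl_cols], alpha_safe)
    q_t, info_t = _fit_group_mean(y[:, test_cols], sf[test_cols], alpha_safe)

    # degenerate all-zero groups: pseudo-mean keeps the contrast finite
    def _regularize(q: np.ndarray, info: np.ndarray, group_cols: list[int]) -> tuple[np.ndarray, np.ndarray]:
        s_sum = sf[group_cols].sum()
        q_floor = LFC_PSEUDOCOUNT / s_sum
        zero = q <= 0
        if zero.any():
            q = np.where(zero, q_floor, q)
            mu = q[:, None] * sf[None, group_cols]
            info_floor = (mu / (1.0 + alpha_safe[:, None] * mu)).sum(axis=1)
            info = np.where(zero, info_floor, info)
        return q, info

    q_c, info_c = _regularize(q_c, info_c, ctrl_cols)
    q_t, info_t = _regularize(q_t, info_t, test_cols)

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / info_c + 1.0 / info_t)
        z = (np.log(q_t) - np.log(q_c)) / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.where(tested & np.isfinite(pvalue), pvalue, np.nan)

    base_mean = (y / sf[None, :]).mean(axis=1)
    lfc = np.log2((q_t + LFC_PSEUDOCOUNT) / (q_c + LFC_PSEUDOCOUNT))

    padj = np.full_like(pvalue, np.nan)
    defined = np.isfinite(pvalue)
    if defined.any():
        padj[defined] = adjust_bh(pvalue[defined])

    frame = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=matrix.counts.index,
    )
    return DEResult(frame)


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    padj_(i) = min over j >= i of (m * p_(j) / j), capped at 1; tied p-values
    share the max-rank adjusted value by construction of the running minimum.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d p-value vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# convenience driver
# ---------------------------------------------------------------------------


def run_de(matrix: GeneCountMatrix, samples: SampleTable) -> DEResult:
    """Full two-group DE path: size factors -> dispersions -> Wald test -> BH.

    Size factors are computed jointly on the comparison (control union test),
    matching a per-comparison normalization of the reference against one model
    and time point at a time.
    """
    sub = matrix.subset_samples(samples.sample_ids)
    sf = estimate_size_factors(sub.counts)
    disp = estimate_dispersions(sub, sf, samples)
    return wald_test(sub, sf, samples, disp)
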