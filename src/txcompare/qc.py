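"""Global similarity diagnostics: pairwise Spearman correlation and variation coefficients.

These reproduce the first-pass QC view of a multi-model comparison: rank
correlation of normalized counts between every pair of samples, and a
per-model coefficient of variation summarizing how consistently a model's
replicates correlate with the reference samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GeneCountMatrix, SampleTable

__all__ = ["spearman_matrix", "variation_coefficient"]


def spearman_matrix(matrix: GeneCountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlation of the sample columns.

    Average ranks for ties; the result is symmetric with a unit diagonal.
    Pairs involving a constant column are undefined and reported as NaN.
    """
    counts = matrix.counts if isinstance(matrix, GeneCountMatrix) else matrix
    values = counts.to_numpy(float)
    n = values.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    constant = values.std(axis=0) == 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.asarray(corr, dtype=float).reshape(n, n)
    corr = (corr + corr.T) / 2  # enforce exact symmetry against rounding
    for j in np.flatnonzero(constant):
        corr[j, :] = np.nan
        corr[:, j] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=counts.columns, columns=counts.columns)


def variation_coefficient(
    corr: pd.DataFrame,
    samples: SampleTable,
    model_label: str,
    basis: str = "cross",
) -> float:
    """Coefficient of variation (percent) of a model's correlation coefficients.

    ``cross`` basis (default): the correlations between the model's replicates
    and all control samples — CV = 100 * sd / mean with the sample (n-1)
    standard deviation. ``intra`` basis: the correlations among the model's own
    replicate pairs. A model with fewer than 2 replicates is undefined (NaN).
    """
    frame = samples.frame
    model_ids = frame.loc[frame["model_label"] == model_label, "sample_id"].tolist()
    model_ids = [s for s in model_ids if s in corr.index]
    if len(model_ids) < 2:
        return float("nan")
    if basis == "cross":
        control_ids = [s for s in samples.control_ids if s in corr.columns and s not in model_ids]
        if not control_ids:
            return float("nan")
        values = corr.loc[model_ids, control_ids].to_numpy(float).ravel()
    elif basis == "intra":
        sub = corr.loc[model_ids, model_ids].to_numpy(float)
        iu = np.triu_indices(len(model_ids), k=1)
        values = sub[iu]
    else:
        raise ValueError(f"unknown basis {basis!r}")
    values = values[np.isfinite(values)]
    if values.size < 2:
        return float("nan")
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * values.std(ddof=1) / mean)
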