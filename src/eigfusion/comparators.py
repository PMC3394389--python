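"""Benchmark outlier statistics: COPA, OS, ORT, GTI and the two-sample KS.

All four robust statistics work per gene on median/MAD-standardized profiles
(COPA and OS standardize by the whole-profile median, ORT centers on the normal
group), share the linear-interpolation quantile convention, and rank descending
with stable tie-breaking. They flag genes over-expressed in a subset of cancer
samples but, unlike the spectral score, pay no attention to how the *rest* of
the cancer group behaves — which is why they mistake all-cancer biomarkers for
outlier genes (exercised in the test suite).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .io import ExpressionMatrix, SampleLabels

#: method registry used by :func:`score_matrix` and the CLI
METHODS = ("eigfusion", "copa", "os", "ort", "gti", "ks")


def _result(gene_ids: list[str], scores: np.ndarray, method: str) -> pd.DataFrame:
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(scores.size, dtype=int)
    ranks[order] = np.arange(1, scores.size + 1)
    table = pd.DataFrame({"gene": gene_ids, "score": scores, "rank": ranks})
    table.attrs["method"] = method
    return table.sort_values("rank", ignore_index=True)


def _standardized(matrix: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """(x - overall median) / MAD per gene; zero-MAD genes are dropped."""
    values = matrix.values
    med = np.median(values, axis=1)
    mad = np.median(np.abs(values - med[:, None]), axis=1)
    keep = mad > 0
    if not keep.any():
        raise ValueError("no scorable genes: every gene has zero MAD")
    z = (values[keep] - med[keep, None]) / mad[keep, None]
    gene_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return z, gene_ids


def _masks(matrix: ExpressionMatrix, labels: SampleLabels):
    labels.validate_against(matrix)
    return labels.masks(matrix.sample_ids)


def copa_scores(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    percentile: float = 80.0,
) -> pd.DataFrame:
    """Cancer outlier profile analysis: the given percentile (default 80th) of
    the standardized values over the cancer group."""
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    s1_mask, _ = _masks(matrix, labels)
    z, gene_ids = _standardized(matrix)
    scores = np.percentile(z[:, s1_mask], percentile, axis=1)
    return _result(gene_ids, scores, "copa")


def os_scores(matrix: ExpressionMatrix, labels: SampleLabels,
              fence_multiplier: float = 1.0) -> pd.DataFrame:
    """Outlier sum: the sum of standardized cancer-group values strictly above
    the Tukey fence q75 + f*IQR of the standardized whole profile; 0 when no
    value exceeds the fence."""
    s1_mask, _ = _masks(matrix, labels)
    z, gene_ids = _standardized(matrix)
    q75 = np.quantile(z, 0.75, axis=1)
    q25 = np.quantile(z, 0.25, axis=1)
    fence = q75 + fence_multiplier * (q75 - q25)
    z1 = z[:, s1_mask]
    scores = np.where(z1 > fence[:, None], z1, 0.0).sum(axis=1)
    return _result(gene_ids, scores, "os")


def ort_scores(matrix: ExpressionMatrix, labels: SampleLabels,
               fence_multiplier: float = 1.0) -> pd.DataFrame:
    """Outlier robust t-statistic: center on the *normal*-group median, scale by
    the median absolute deviation about the two group medians, and sum the
    scaled cancer values above the fence of the scaled normal group."""
    s1_mask, s2_mask = _masks(matrix, labels)
    if s2_mask.sum() < 2:
        raise ValueError("ORT needs at least 2 normal samples")
    values = matrix.values
    s1 = values[:, s1_mask]
    s2 = values[:, s2_mask]
    med1 = np.median(s1, axis=1)
    med2 = np.median(s2, axis=1)
    scale = np.median(
        np.hstack([np.abs(s1 - med1[:, None]), np.abs(s2 - med2[:, None])]), axis=1
    )
    keep = scale > 0
    if not keep.any():
        raise ValueError("no scorable genes: every gene has zero ORT scale")
    gene_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    u1 = (s1[keep] - med2[keep, None]) / scale[keep, None]
    u2 = (s2[keep] - med2[keep, None]) / scale[keep, None]
    q75 = np.quantile(u2, 0.75, axis=1)
    q25 = np.quantile(u2, 0.25, axis=1)
    fence = q75 + fence_multiplier * (q75 - q25)
    scores = np.where(u1 > fence[:, None], u1, 0.0).sum(axis=1)
    return _result(gene_ids, scores, "ort")


def gti_scores(matrix: ExpressionMatrix, labels: SampleLabels,
               fence_multiplier: float = 1.0) -> pd.DataFrame:
    """Gene tissue index: the outlier proportion in the cancer group weighted by
    how far the outliers sit above the group's upper quartile.

    Outliers are standardized S1 values above q75(S1) + f*IQR(S1); the statistic
    is (n_out/|S1|) * (mean(outliers) - q75(S1)) / max(|median|, MAD), evaluated
    on the standardized profile (where the denominator equals 1, making the
    statistic location/scale invariant like its peers); 0 with no outliers.
    """
    s1_mask, _ = _masks(matrix, labels)
    z, gene_ids = _standardized(matrix)
    z1 = z[:, s1_mask]
    n1 = z1.shape[1]
    q75 = np.quantile(z1, 0.75, axis=1)
    q25 = np.quantile(z1, 0.25, axis=1)
    fence = q75 + fence_multiplier * (q75 - q25)
    is_out = z1 > fence[:, None]
    n_out = is_out.sum(axis=1)
    sum_out = np.where(is_out, z1, 0.0).sum(axis=1)
    mean_out = np.divide(sum_out, n_out, out=np.zeros_like(sum_out),
                         where=n_out > 0)
    med_z = np.median(z, axis=1)
    mad_z = np.median(np.abs(z - med_z[:, None]), axis=1)
    robust_scale = np.maximum(np.abs(med_z), mad_z)
    scores = np.where(n_out > 0, (n_out / n1) * (mean_out - q75) / robust_scale, 0.0)
    return _result(gene_ids, scores, "gti")


def ks_scores(matrix: ExpressionMatrix, labels: SampleLabels) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov D statistic between the cancer and normal
    empirical distributions of each gene (a whole-distribution shift detector,
    included as the naive differential-expression baseline)."""
    s1_mask, s2_mask = _masks(matrix, labels)
    values = matrix.values
    scores = np.array(
        [
            stats.ks_2samp(row[s1_mask], row[s2_mask], method="asymp").statistic
            for row in values
        ]
    )
    return _result(list(matrix.gene_ids), scores, "ks")


def score_matrix(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    method: str,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Dispatch a method name from :data:`METHODS` to its scoring function."""
    from .core import eigfusion_scores

    config = config or RunConfig()
    if method == "eigfusion":
        return eigfusion_scores(matrix, labels, config)
    if method == "copa":
        return copa_scores(matrix, labels, config.copa_percentile)
    if method == "os":
        return os_scores(matrix, labels, config.fence_multiplier)
    if method == "ort":
        return ort_scores(matrix, labels, config.fence_multiplier)
    if method == "gti":
        return gti_scores(matrix, labels, config.fence_multiplier)
    if method == "ks":
        return ks_scores(matrix, labels)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
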