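"""Binary rearrangement vectors and Hamming-distance clinical association.

A scored gene's outlier-sample set (the cancer samples beyond the Tukey fence
of its transformed profile) defines a 0/1 vector over the cancer group: bit 1
marks a sample called as harbouring the putative rearrangement. Comparing such
vectors against binary clinical vectors (death / aggressiveness) by normalized
Hamming distance measures how well the rearrangement tracks outcome. Because a
small Hamming distance only means high concordance when the two vectors have
similar support, the conditional rate P(clinical = 1 | rearranged) is reported
alongside the distance rather than conflated with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .core import eigfusion_scores
from .io import ExpressionMatrix, SampleLabels


@dataclass
class BinaryVector:
    """0/1 vector over an ordered set of sample IDs."""

    sample_ids: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=int)
        if self.bits.ndim != 1 or self.bits.size != len(self.sample_ids):
            raise ValueError("bits must be one 0/1 value per sample")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0 or 1")


def rearrangement_vector(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    gene_id: str,
    config: RunConfig | None = None,
    scores: pd.DataFrame | None = None,
) -> BinaryVector:
    """Binary vector over the cancer samples: 1 where the gene's transformed
    value lies beyond the Tukey fence (the gene's outlier-sample set).

    Restricted to S1 because clinical outcomes attach to tumours. Pass a
    precomputed ``scores`` table (from :func:`eigfusion_scores`) to avoid
    rescoring per gene.
    """
    if scores is None:
        scores = eigfusion_scores(matrix, labels, config)
    row = scores.loc[scores["gene"] == gene_id]
    if row.empty:
        dropped = dict(scores.attrs.get("dropped_genes", []))
        if gene_id in dropped:
            raise ValueError(f"gene {gene_id!r} was dropped: {dropped[gene_id]}")
        raise KeyError(f"unknown gene {gene_id!r}")
    outliers = set(row["outlier_samples"].iloc[0])
    bits = np.array([1 if s in outliers else 0 for s in labels.s1])
    return BinaryVector(list(labels.s1), bits)


def hamming_association(
    v: BinaryVector, clinical: BinaryVector
) -> tuple[float, float]:
    """Normalized Hamming distance and conditional concordance.

    Returns ``(distance, rate)`` where distance is the fraction of mismatching
    positions after aligning ``clinical`` to ``v``'s sample order, and rate is
    P(clinical = 1 | v = 1) — NaN when the gene has no rearranged samples. The
    two sample sets must be identical.
    """
    if set(v.sample_ids) != set(clinical.sample_ids):
        raise ValueError("sample sets differ between vectors")
    clin_by_id = dict(zip(clinical.sample_ids, clinical.bits))
    aligned = np.array([clin_by_id[s] for s in v.sample_ids])
    distance = float(np.mean(v.bits != aligned))
    n_rearranged = int(v.bits.sum())
    if n_rearranged == 0:
        rate = float("nan")
    else:
        rate = float(aligned[v.bits == 1].sum() / n_rearranged)
    return distance, rate


def read_clinical(path: str | Path, sample_ids: list[str] | None = None) -> BinaryVector:
    """Read a two-column (sample_id, 0/1) clinical vector file.

    When ``sample_ids`` is given the vector is restricted to (and must cover)
    those samples, in that order.
    """
    table = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                        comment="#")
    if table.shape[1] < 2:
        raise ValueError("clinical file must have two columns (sample_id, 0/1)")
    first = str(table.iloc[0, 0]).lower()
    if first in {"sample", "sample_id", "id"}:
        table = table.iloc[1:]
    bits_by_id = {}
    for _, row in table.iterrows():
        token = str(row.iloc[1]).strip()
        if token not in {"0", "1"}:
            raise ValueError(
                f"clinical value {row.iloc[1]!r} for sample {row.iloc[0]!r} "
                "is not 0/1"
            )
        bits_by_id[str(row.iloc[0])] = int(token)
    if sample_ids is None:
        ids = list(bits_by_id)
    else:
        missing = [s for s in sample_ids if s not in bits_by_id]
        if missing:
            raise ValueError(f"clinical file missing samples: {missing}")
        ids = list(sample_ids)
    return BinaryVector(ids, np.array([bits_by_id[s] for s in ids]))


def associate(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    clinical: BinaryVector,
    gene_ids: list[str] | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Hamming association of every (or selected) scored gene with a clinical
    vector; one row per gene with distance, conditional rate and the number of
    rearranged samples."""
    scores = eigfusion_scores(matrix, labels, config)
    if gene_ids is None:
        gene_ids = list(scores["gene"])
    rows = []
    for gid in gene_ids:
        v = rearrangement_vector(matrix, labels, gid, config, scores=scores)
        distance, rate = hamming_association(v, clinical)
        rows.append(
            {
                "gene": gid,
                "hamming_distance": distance,
                "conditional_rate": rate,
                "n_rearranged": int(v.bits.sum()),
            }
        )
    return pd.DataFrame(rows)
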