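"""Synthetic spike-in benchmark: Gaussian background plus embedded test genes.

The benchmark emulates a two-group expression study: 1000 background genes over
200 samples drawn i.i.d. from N(mu, sigma^2) with additive Gaussian noise, the
first ``cancer_size`` samples labelled cancer (S1). For each requested outlier
count k, one test gene (``test_k``) is appended whose first k cancer samples
have the constant u — the maximum value observed in the background matrix —
added (amplification) or subtracted (deletion) on top of fresh background draws.
A test gene affected in fewer than half the cancer samples is a genuine outlier
gene ("positive"); one affected in *all* cancer samples is indistinguishable
from an ordinary biomarker and is a deliberate negative control; intermediate
counts are labelled ambiguous and excluded from confusion counting. The cancer
group size is swept over {20, 50, 100, 120, 150, 180} to probe sensitivity to
the cancer/normal ratio.

Test genes can equally be embedded into a user-supplied real matrix (the same
protocol, with u taken as that matrix's maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ExpressionMatrix, SampleLabels

DEFAULT_TEST_KS = (2, 5, 10, 20, 50, 80, 100, 120, 150)
DEFAULT_CANCER_SIZES = (20, 50, 100, 120, 150, 180)


@dataclass
class SimulationSpec:
    """Generator settings; the defaults are the benchmark's study conditions."""

    n_genes: int = 1000
    n_samples: int = 200
    mu: float = 0.0
    sigma: float = 1.0
    noise_sd: float = 1.0
    cancer_size: int = 100
    test_ks: tuple[int, ...] = DEFAULT_TEST_KS
    direction: str = "amplify"
    random_affected: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cancer_size >= self.n_samples:
            raise ValueError("cancer_size must be smaller than n_samples")
        if self.cancer_size < 2 or self.n_samples - self.cancer_size < 2:
            raise ValueError("both groups need at least 2 samples")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.direction not in ("amplify", "delete"):
            raise ValueError("direction must be 'amplify' or 'delete'")

    @property
    def retained_ks(self) -> tuple[int, ...]:
        """Outlier counts embeddable in this scenario (k <= cancer_size)."""
        return tuple(k for k in self.test_ks if 0 < k <= self.cancer_size)


@dataclass
class TestGene:
    gene_id: str
    k: int
    affected_samples: list[str]
    label: str  # positive | biomarker | ambiguous


@dataclass
class TruthSet:
    """Ground truth for the embedded test genes of one simulated dataset."""

    entries: list[TestGene] = field(default_factory=list)

    def by_label(self, label: str) -> list[TestGene]:
        return [e for e in self.entries if e.label == label]

    @property
    def positives(self) -> list[TestGene]:
        return self.by_label("positive")

    @property
    def biomarkers(self) -> list[TestGene]:
        return self.by_label("biomarker")

    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]


@dataclass
class SimulatedDataset:
    matrix: ExpressionMatrix
    labels: SampleLabels
    truth: TruthSet
    spec: SimulationSpec


def _truth_label(k: int, cancer_size: int) -> str:
    if k == cancer_size:
        return "biomarker"
    if k < cancer_size / 2:
        return "positive"
    return "ambiguous"


def generate_background(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, SampleLabels]:
    """Draw the background matrix and label the first ``cancer_size`` samples S1.

    Each value is an independent N(mu, sigma^2) draw plus N(0, noise_sd^2)
    noise; identical seeds give identical matrices.
    """
    rng = np.random.default_rng(spec.seed)
    values = rng.normal(spec.mu, spec.sigma, (spec.n_genes, spec.n_samples))
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd,
                                     (spec.n_genes, spec.n_samples))
    gene_ids = [f"gene_{i + 1}" for i in range(spec.n_genes)]
    sample_ids = [f"sample_{j + 1}" for j in range(spec.n_samples)]
    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    labels = SampleLabels(sample_ids[: spec.cancer_size],
                          sample_ids[spec.cancer_size:])
    return matrix, labels


def embed_test_genes(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, TruthSet]:
    """Append one ``test_k`` gene per retained k to ``matrix``.

    u is the maximum of the supplied matrix (before any embedding). Each test
    gene is a fresh background draw whose affected cancer samples get +u
    (amplify) or -u (delete) added; by default the affected samples are the
    first k S1 samples for reproducibility (``random_affected`` draws them
    instead). Works on simulated or user-supplied (real) matrices alike.
    """
    if rng is None:
        # offset keeps these draws distinct from generate_background's stream
        rng = np.random.default_rng(spec.seed + 1_000_003)
    u = float(matrix.values.max())
    sign = 1.0 if spec.direction == "amplify" else -1.0
    s1_ids = list(labels.s1)
    rows = []
    truth = TruthSet()
    gene_ids = list(matrix.gene_ids)
    for k in spec.retained_ks:
        row = rng.normal(spec.mu, spec.sigma, matrix.n_samples)
        if spec.noise_sd > 0:
            row = row + rng.normal(0.0, spec.noise_sd, matrix.n_samples)
        if spec.random_affected:
            affected = sorted(rng.choice(len(s1_ids), size=k, replace=False))
        else:
            affected = list(range(k))
        affected_ids = [s1_ids[i] for i in affected]
        col_index = {s: j for j, s in enumerate(matrix.sample_ids)}
        for sid in affected_ids:
            row[col_index[sid]] += sign * u
        gid = f"test_{k}"
        rows.append(row)
        gene_ids.append(gid)
        truth.entries.append(
            TestGene(gid, k, affected_ids, _truth_label(k, len(s1_ids)))
        )
    values = np.vstack([matrix.values] + [r[None, :] for r in rows])
    return ExpressionMatrix(gene_ids, list(matrix.sample_ids), values), truth


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Background plus embedded test genes in one call."""
    background, labels = generate_background(spec)
    matrix, truth = embed_test_genes(background, labels, spec)
    return SimulatedDataset(matrix, labels, truth, spec)


def scenario_sweep(
    base_spec: SimulationSpec,
    cancer_sizes: tuple[int, ...] = DEFAULT_CANCER_SIZES,
) -> list[SimulatedDataset]:
    """One dataset per cancer-group size, seeds derived as base seed + index."""
    datasets = []
    for i, size in enumerate(cancer_sizes):
        spec = replace(base_spec, cancer_size=size, seed=base_spec.seed + i)
        datasets.append(simulate_dataset(spec))
    return datasets
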