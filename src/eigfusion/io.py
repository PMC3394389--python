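"""Expression-matrix, label-file and score-table input/output.

File conventions
----------------
* Expression matrix: delimited text (tab or comma, auto-detected), first row holds
  sample identifiers, first column holds gene identifiers. Genes are rows.
* Labels: two columns (sample_id, group). Group tokens are matched case-insensitively
  against configurable alias sets ({S1, cancer, tumor} and {S2, normal, benign}).
* Score table: tab-separated with the fixed header
  ``gene score rank p_value direction n_outlier_samples outlier_samples``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: group tokens accepted by :func:`read_labels`, lower-cased
DEFAULT_S1_ALIASES = ("s1", "cancer", "tumor")
DEFAULT_S2_ALIASES = ("s2", "normal", "benign")

SCORE_COLUMNS = [
    "gene",
    "score",
    "rank",
    "p_value",
    "direction",
    "n_outlier_samples",
    "outlier_samples",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued matrix with unique row/column identifiers.

    Values are used exactly as supplied (log-scale or raw); the package applies no
    normalization of its own. All values must be finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if m != len(self.gene_ids) or n != len(self.sample_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value for gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleLabels:
    """Partition of a matrix's samples into cancer (s1) and normal (s2) groups."""

    s1: list[str]
    s2: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.s1) & set(self.s2)
        if overlap:
            raise ValueError(f"samples in both groups: {sorted(overlap)}")
        if len(self.s1) < 2 or len(self.s2) < 2:
            raise ValueError("each group needs at least 2 samples")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        labelled = set(self.s1) | set(self.s2)
        in_matrix = set(matrix.sample_ids)
        missing = sorted(in_matrix - labelled)
        if missing:
            raise ValueError(f"matrix samples missing from labels: {missing}")
        extra = sorted(labelled - in_matrix)
        if extra:
            raise ValueError(f"labelled samples absent from matrix: {extra}")

    def masks(self, sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks over ``sample_ids`` for (s1, s2)."""
        s1 = set(self.s1)
        s2 = set(self.s2)
        m1 = np.array([s in s1 for s in sample_ids])
        m2 = np.array([s in s2 for s in sample_ids])
        return m1, m2


def _check_unique(ids: list[str], kind: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(i for i, c in seen.items() if c > 1)
    if dups:
        raise ValueError(f"duplicate {kind} IDs: {dups}")


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    # prefer tab; a single-column header with commas means CSV
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return "\t"


def read_expression(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from delimited text.

    The delimiter is auto-detected from {tab, comma} when not given. Duplicate gene
    or sample IDs, and any non-numeric or non-finite cell, are load errors that name
    the offending gene and sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter or _detect_delimiter(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    gene_ids = [str(g) for g in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        try:
            # python float() is correctly rounded, unlike pandas' fast parser
            values[:, j] = raw[col].to_numpy(dtype=float)
        except (ValueError, TypeError):
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = np.flatnonzero(converted.isna().to_numpy())
            cell = raw[col].iloc[bad[0]] if bad.size else raw[col].iloc[0]
            row = gene_ids[bad[0]] if bad.size else "?"
            raise ValueError(
                f"non-numeric expression value {cell!r} for gene "
                f"{row!r}, sample {sample_ids[j]!r}"
            ) from None
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a matrix so that :func:`read_expression` round-trips it.

    Values are printed with 17 significant digits (exact float round-trip).
    """
    with open(path, "w") as fh:
        fh.write(delimiter.join([""] + matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(delimiter.join([gid] + [f"{v:.17g}" for v in row]) + "\n")


def read_labels(
    path: str | Path,
    matrix: ExpressionMatrix,
    s1_aliases: tuple[str, ...] = DEFAULT_S1_ALIASES,
    s2_aliases: tuple[str, ...] = DEFAULT_S2_ALIASES,
) -> SampleLabels:
    """Read a two-column (sample_id, group) label file and validate it.

    Every matrix sample must be labelled exactly once, and every labelled sample
    must exist in the matrix. Unrecognized group tokens are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                        comment="#")
    if table.shape[1] < 2:
        raise ValueError(f"label file {path} must have two columns (sample_id, group)")
    # tolerate an optional header line
    first = str(table.iloc[0, 0]).lower()
    if first in {"sample", "sample_id", "id"}:
        table = table.iloc[1:]
    s1_set = {a.lower() for a in s1_aliases}
    s2_set = {a.lower() for a in s2_aliases}
    s1: list[str] = []
    s2: list[str] = []
    for _, row in table.iterrows():
        sid, group = str(row.iloc[0]), str(row.iloc[1]).strip().lower()
        if group in s1_set:
            s1.append(sid)
        elif group in s2_set:
            s2.append(sid)
        else:
            raise ValueError(
                f"unrecognized group token {row.iloc[1]!r} for sample {sid!r}; "
                f"known aliases: {sorted(s1_set)} -> S1, {sorted(s2_set)} -> S2"
            )
    labels = SampleLabels(s1, s2)
    labels.validate_against(matrix)
    return labels


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in labels.s1:
            fh.write(f"{sid}\tS1\n")
        for sid in labels.s2:
            fh.write(f"{sid}\tS2\n")


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    """Write a gene score table as TSV with the canonical column layout.

    ``outlier_samples`` (a list of sample IDs per gene) is comma-joined; an empty
    set becomes the empty string. Missing p-values are written as empty fields.
    Scores are printed with 15 significant digits so a re-read reproduces them to
    (at least) 12 significant digits.
    """
    if table.empty:
        raise ValueError("refusing to write an empty score table")
    out = pd.DataFrame(index=table.index)
    out["gene"] = table["gene"]
    out["score"] = [f"{v:.15g}" for v in table["score"]]
    out["rank"] = table["rank"].astype(int)
    if "p_value" in table and table["p_value"].notna().any():
        out["p_value"] = [
            "" if pd.isna(v) else f"{v:.15g}" for v in table["p_value"]
        ]
    else:
        out["p_value"] = ""
    out["direction"] = table.get("direction", pd.Series("", index=table.index)).fillna("")
    if "outlier_samples" in table:
        joined = [
            ",".join(v) if isinstance(v, (list, tuple)) else ""
            for v in table["outlier_samples"]
        ]
    else:
        joined = [""] * len(table)
    out["n_outlier_samples"] = [len(v.split(",")) if v else 0 for v in joined]
    out["outlier_samples"] = joined
    out.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a score table written by :func:`write_scores`."""
    table = pd.read_csv(path, sep="\t", dtype={"gene": str, "outlier_samples": str})
    table["outlier_samples"] = [
        v.split(",") if isinstance(v, str) and v else []
        for v in table["outlier_samples"]
    ]
    table["direction"] = table["direction"].fillna("")
    return table
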