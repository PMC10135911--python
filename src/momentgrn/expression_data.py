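"""Expression matrices: I/O, gene-ID standardization, TPM/FPKM normalization.

The pipeline starts from a gene × sample matrix of raw counts (RNA-seq) or
intensities (microarray).  Raw counts are normalized within each sample to
transcripts-per-kilobase-million (TPM) or fragments-per-kilobase-million
(FPKM) using annotated gene lengths; both divide counts by gene length and
sequencing depth and differ only in the order of the two normalizations.
Gene identifiers can be rewritten to a canonical naming scheme (e.g. yeast
ordered-locus names) through an alias → canonical mapping table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NormalizationTag = Literal["raw_counts", "tpm", "fpkm", "microarray", "zscored"]

NORMALIZATION_TAGS: tuple[str, ...] = (
    "raw_counts",
    "tpm",
    "fpkm",
    "microarray",
    "zscored",
)


class ExpressionDataError(ValueError):
    """Invalid expression-matrix content or incompatible inputs."""


@dataclass
class ExpressionMatrix:
    """A gene × sample expression matrix with a normalization tag.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows).
    sample_ids
        Ordered, unique sample identifiers (columns).
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``.
        Non-negative unless ``normalization == "zscored"``.
    normalization
        One of ``raw_counts``, ``tpm``, ``fpkm``, ``microarray``, ``zscored``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    normalization: str = "raw_counts"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.normalization not in NORMALIZATION_TAGS:
            raise ExpressionDataError(
                f"unknown normalization tag {self.normalization!r}; "
                f"expected one of {NORMALIZATION_TAGS}"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ExpressionDataError(f"duplicate gene id {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ExpressionDataError(f"duplicate sample id {dup!r}")
        expected = (len(self.gene_ids), len(self.sample_ids))
        if self.values.shape != expected:
            raise ExpressionDataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ExpressionDataError("values contain non-finite entries")
        if self.normalization == "raw_counts" and np.any(self.values < 0):
            raise ExpressionDataError("raw counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index()[gene_id]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        """Write as delimited text: header row of sample ids, first column gene ids."""
        frame = self.to_frame()
        frame.index.name = "gene_id"
        frame.to_csv(path, sep=delimiter, float_format="%.17g")


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


def read_expression_matrix(
    path: str | Path,
    delimiter: str = "\t",
    normalization: str = "raw_counts",
) -> ExpressionMatrix:
    """Read a delimited gene × sample matrix.

    The file must have a header row of sample ids and gene ids in the first
    column.  The normalization tag is supplied by the caller; the file itself
    carries no metadata.

    Raises
    ------
    ExpressionDataError
        On duplicate gene ids (naming the id) or non-numeric cells (naming
        the row and column).
    """
    frame = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    gene_ids = [str(g) for g in frame.index]
    dup = _first_duplicate(gene_ids)
    if dup is not None:
        raise ExpressionDataError(f"duplicate gene id {dup!r} in {path}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(parsed.isna().to_numpy() & frame[col].notna().to_numpy())
        if bad.size or parsed.isna().any():
            i = bad[0] if bad.size else int(np.flatnonzero(parsed.isna())[0])
            raise ExpressionDataError(
                f"non-numeric cell at gene {gene_ids[i]!r}, sample {col!r} in {path}"
            )
        values[:, j] = parsed.to_numpy()
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[str(s) for s in frame.columns],
        values=values,
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# Gene lengths and gene-ID maps
# ---------------------------------------------------------------------------

def read_gene_lengths(path: str | Path, delimiter: str = "\t") -> dict[str, int]:
    """Read a two-column table (gene_id, length_bp) into a mapping."""
    frame = pd.read_csv(path, sep=delimiter)
    if frame.shape[1] < 2:
        raise ExpressionDataError(f"gene-length table {path} needs two columns")
    lengths: dict[str, int] = {}
    for gene, length in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        lengths[str(gene)] = int(length)
    _validate_lengths(lengths)
    return lengths


def _validate_lengths(lengths: Mapping[str, int]) -> None:
    for gene, length in lengths.items():
        if length <= 0:
            raise ExpressionDataError(
                f"gene {gene!r} has non-positive length {length}"
            )


def read_gene_id_map(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column alias → canonical-id table into a mapping.

    Each alias must map to exactly one canonical name.
    """
    frame = pd.read_csv(path, sep=delimiter)
    if frame.shape[1] < 2:
        raise ExpressionDataError(f"gene-id map {path} needs two columns")
    mapping: dict[str, str] = {}
    for alias, canonical in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        alias, canonical = str(alias), str(canonical)
        if alias in mapping and mapping[alias] != canonical:
            raise ExpressionDataError(
                f"alias {alias!r} maps to both {mapping[alias]!r} and {canonical!r}"
            )
        mapping[alias] = canonical
    return mapping


def apply_gene_id_map(
    matrix: ExpressionMatrix,
    id_map: Mapping[str, str],
    on_missing: Literal["keep", "drop", "fail"] = "keep",
) -> ExpressionMatrix:
    """Rename genes to canonical identifiers.

    ``on_missing`` controls genes absent from the map: ``keep`` them under
    their current id, ``drop`` their rows, or ``fail``.

    Raises
    ------
    ExpressionDataError
        If renaming would collide two rows onto one canonical id, or
        ``on_missing="fail"`` and an unmapped gene exists.
    """
    if on_missing not in ("keep", "drop", "fail"):
        raise ExpressionDataError(f"unknown on_missing policy {on_missing!r}")
    new_ids: list[str] = []
    keep_rows: list[int] = []
    for i, gene in enumerate(matrix.gene_ids):
        if gene in id_map:
            new_ids.append(str(id_map[gene]))
            keep_rows.append(i)
        elif on_missing == "keep":
            new_ids.append(gene)
            keep_rows.append(i)
        elif on_missing == "fail":
            raise ExpressionDataError(f"gene {gene!r} missing from id map")
        # drop: skip the row
    dup = _first_duplicate(new_ids)
    if dup is not None:
        raise ExpressionDataError(
            f"id-map collision: two rows map onto canonical id {dup!r}"
        )
    return ExpressionMatrix(
        gene_ids=new_ids,
        sample_ids=list(matrix.sample_ids),
        values=matrix.values[keep_rows],
        normalization=matrix.normalization,
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _check_lengths_cover(
    counts: ExpressionMatrix, lengths: Mapping[str, int]
) -> np.ndarray:
    _validate_lengths(lengths)
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise ExpressionDataError(
            f"{len(missing)} gene(s) missing from length table, "
            f"first: {missing[0]!r}"
        )
    return np.array([lengths[g] for g in counts.gene_ids], dtype=float)


def _require_raw_counts(counts: ExpressionMatrix) -> None:
    if counts.normalization != "raw_counts":
        raise ExpressionDataError(
            f"normalization expects raw counts, got {counts.normalization!r}"
        )


def tpm_normalize(
    counts: ExpressionMatrix,
    lengths: Mapping[str, int],
    on_zero_sample: Literal["error", "zero"] = "error",
) -> ExpressionMatrix:
    """Transcripts-per-kilobase-million.

    Per sample: ``rate_g = count_g / (length_g / 1000)``; then
    ``tpm_g = rate_g / Σ_g rate_g × 10⁶``.  Every column of the result sums
    to 10⁶ unless the sample had zero total counts (``on_zero_sample``
    selects an error, the default, or an all-zero output column).
    """
    _require_raw_counts(counts)
    length_bp = _check_lengths_cover(counts, lengths)
    rates = counts.values / (length_bp[:, None] / 1000.0)
    totals = rates.sum(axis=0)
    zero_cols = totals == 0
    if np.any(zero_cols):
        if on_zero_sample == "error":
            bad = counts.sample_ids[int(np.flatnonzero(zero_cols)[0])]
            raise ExpressionDataError(f"sample {bad!r} has zero total counts")
        totals = np.where(zero_cols, 1.0, totals)
    tpm = rates / totals * 1e6
    _flag_zero_rows(counts)
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=tpm,
        normalization="tpm",
    )


def fpkm_normalize(
    counts: ExpressionMatrix,
    lengths: Mapping[str, int],
    on_zero_sample: Literal["error", "zero"] = "error",
) -> ExpressionMatrix:
    """Fragments-per-kilobase-million.

    Per sample with total mapped fragments ``T = Σ_g count_g``:
    ``fpkm_g = count_g × 10⁹ / (length_g × T)``.  The per-million denominator
    is the column sum of the count matrix, which is the only depth
    information available when starting from a count matrix.
    """
    _require_raw_counts(counts)
    length_bp = _check_lengths_cover(counts, lengths)
    totals = counts.values.sum(axis=0)
    zero_cols = totals == 0
    if np.any(zero_cols):
        if on_zero_sample == "error":
            bad = counts.sample_ids[int(np.flatnonzero(zero_cols)[0])]
            raise ExpressionDataError(f"sample {bad!r} has zero total counts")
        totals = np.where(zero_cols, 1.0, totals)
    fpkm = counts.values * 1e9 / (length_bp[:, None] * totals)
    _flag_zero_rows(counts)
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=fpkm,
        normalization="fpkm",
    )


def _flag_zero_rows(counts: ExpressionMatrix) -> list[str]:
    zero_rows = [
        g
        for g, row in zip(counts.gene_ids, counts.values)
        if not np.any(row)
    ]
    if zero_rows:
        # retained through normalization; they fall out later at z-scoring
        logger.warning(
            "%d all-zero gene row(s) retained through normalization (first: %s)",
            len(zero_rows),
            zero_rows[0],
        )
    return zero_rows


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """log2-transform positive expression values (for intensity-scale data).

    Intensity-like data (microarray, or the simulator's exponentiated
    output) is usually analysed on the log scale, where dependence between
    regulator and target is closer to the polynomial forms the moment
    features detect.  Off by default in the pipeline; enable per run.
    """
    shifted = matrix.values + pseudocount
    if np.any(shifted <= 0):
        raise ExpressionDataError(
            "log transform requires strictly positive values "
            f"(pseudocount={pseudocount})"
        )
    return replace(matrix, values=np.log2(shifted))
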