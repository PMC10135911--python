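"""Joint-moment features for gene pairs, with standardization and PCA.

Each unordered gene pair (a, b) is described by the grid of joint moments
m_{n,m} = E[xⁿ yᵐ] with n, m ∈ {1..7} (49 features), where x and y are the
two genes' expression profiles after per-gene z-scoring.  On z-scored rows
the (1,1) moment is exactly the (population) Pearson correlation, and the
higher entries capture nonlinear dependence that correlation misses — e.g.
a quadratic regulator → target link shows up in E[x²y] with E[xy] ≈ 0.
Moment columns are standardized across pairs and reduced to 36 principal
components before classification.

Pairs are canonicalized so that x is always the lexicographically smaller
gene id; moments are orientation-dependent, so this fixes a deterministic
orientation (an optional symmetrized variant averages both orientations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .expression_data import ExpressionMatrix

logger = logging.getLogger(__name__)


class FeatureError(ValueError):
    """Invalid feature-computation input."""


@dataclass(frozen=True)
class MomentSpec:
    """Which joint moments to compute: all (n, m) with 1 ≤ n, m ≤ max_order.

    The default grid {1..7}² gives 49 features per pair, in row-major order
    (1,1), (1,2), ..., (7,7); index 0 is the correlation moment.
    """

    max_order: int = 7

    def __post_init__(self) -> None:
        if self.max_order < 1:
            raise FeatureError("max_order must be >= 1")

    @property
    def n_features(self) -> int:
        return self.max_order**2

    @property
    def orders(self) -> list[tuple[int, int]]:
        r = range(1, self.max_order + 1)
        return [(n, m) for n in r for m in r]

    def column_of(self, n: int, m: int) -> int:
        if not (1 <= n <= self.max_order and 1 <= m <= self.max_order):
            raise FeatureError(f"moment ({n},{m}) outside grid 1..{self.max_order}")
        return (n - 1) * self.max_order + (m - 1)


@dataclass
class PairList:
    """Canonical unordered pairs over a sorted gene-id vocabulary.

    Pairs are stored as index arrays into ``gene_ids`` (which is
    lexicographically sorted), with ``left < right``; hence the pair
    (gene_ids[left], gene_ids[right]) always has the smaller id first.
    """

    gene_ids: np.ndarray  # sorted unique ids, dtype=str
    left: np.ndarray  # int indices, left < right
    right: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids)
        self.left = np.asarray(self.left, dtype=np.int64)
        self.right = np.asarray(self.right, dtype=np.int64)
        if self.left.shape != self.right.shape:
            raise FeatureError("left/right index arrays differ in length")
        if self.left.size and not np.all(self.left < self.right):
            raise FeatureError("pair indices must satisfy left < right")

    def __len__(self) -> int:
        return int(self.left.size)

    def pair_ids(self) -> np.ndarray:
        """(n_pairs, 2) array of gene-id pairs, smaller id first."""
        return np.stack(
            [self.gene_ids[self.left], self.gene_ids[self.right]], axis=1
        )

    def index_of(self) -> dict[tuple[str, str], int]:
        ids = self.pair_ids()
        return {(str(a), str(b)): i for i, (a, b) in enumerate(ids)}

    def subset(self, rows: np.ndarray) -> "PairList":
        return PairList(self.gene_ids, self.left[rows], self.right[rows])


def enumerate_pairs(gene_ids: list[str] | np.ndarray) -> PairList:
    """All unordered pairs of distinct genes, canonically ordered.

    The id list is sorted lexicographically and the G(G−1)/2 index pairs
    are generated with ``left < right``, so pair i is (a, b) with a < b and
    the whole list is in lexicographic pair order.
    """
    ids = np.asarray([str(g) for g in gene_ids])
    if np.unique(ids).size != ids.size:
        raise FeatureError("duplicate gene ids in pair enumeration")
    ids = np.sort(ids)
    left, right = np.triu_indices(ids.size, k=1)
    return PairList(gene_ids=ids, left=left, right=right)


@dataclass
class PairFeatureTable:
    """Joint-moment features for a list of canonical pairs.

    ``raw_moments`` is (n_pairs × spec.n_features); ``reduced`` holds the
    PCA projection once computed.  ``moment_means``/``moment_sds`` record
    the across-pair standardization if one has been applied.
    """

    pairs: PairList
    spec: MomentSpec
    raw_moments: np.ndarray
    reduced: np.ndarray | None = None
    moment_means: np.ndarray | None = None
    moment_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw_moments = np.asarray(self.raw_moments, dtype=float)
        if self.raw_moments.shape != (len(self.pairs), self.spec.n_features):
            raise FeatureError(
                f"moment matrix shape {self.raw_moments.shape} does not match "
                f"{len(self.pairs)} pairs × {self.spec.n_features} features"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def moment(self, n: int, m: int) -> np.ndarray:
        """Column of the (n, m) moment across all pairs."""
        return self.raw_moments[:, self.spec.column_of(n, m)]

    @property
    def correlation(self) -> np.ndarray:
        """The (1,1) moment: population Pearson correlation on z-scored rows."""
        return self.moment(1, 1)

    def subset(self, rows: np.ndarray) -> "PairFeatureTable":
        return PairFeatureTable(
            pairs=self.pairs.subset(rows),
            spec=self.spec,
            raw_moments=self.raw_moments[rows],
            reduced=None if self.reduced is None else self.reduced[rows],
            moment_means=self.moment_means,
            moment_sds=self.moment_sds,
        )

    def to_frame(self, reduced: bool = False) -> pd.DataFrame:
        ids = self.pairs.pair_ids()
        if reduced:
            if self.reduced is None:
                raise FeatureError("no reduced features computed")
            cols = [f"pc{j + 1}" for j in range(self.reduced.shape[1])]
            data = self.reduced
        else:
            cols = [f"m{n}_{m}" for n, m in self.spec.orders]
            data = self.raw_moments
        frame = pd.DataFrame(data, columns=cols)
        frame.insert(0, "pair_b", ids[:, 1])
        frame.insert(0, "pair_a", ids[:, 0])
        return frame

    def write(self, path: str | Path, reduced: bool = False) -> None:
        self.to_frame(reduced=reduced).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Z-scoring
# ---------------------------------------------------------------------------

def zscore_genes(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, list[str]]:
    """Standardize every gene row to mean 0, variance 1 (population SD).

    Zero-variance genes cannot be standardized; they are dropped and
    returned in the exclusion list.  Population (ddof=0) convention so that
    the (1,1) joint moment of two z-scored rows is exactly their Pearson
    correlation.
    """
    if matrix.n_samples < 2:
        raise FeatureError("z-scoring needs at least 2 samples")
    means = matrix.values.mean(axis=1, keepdims=True)
    sds = matrix.values.std(axis=1, keepdims=True)  # ddof=0
    keep = sds[:, 0] > 0
    excluded = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    if excluded:
        logger.warning(
            "dropping %d zero-variance gene(s) at z-scoring (first: %s)",
            len(excluded),
            excluded[0],
        )
    z = (matrix.values[keep] - means[keep]) / sds[keep]
    out = ExpressionMatrix(
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        sample_ids=list(matrix.sample_ids),
        values=z,
        normalization="zscored",
    )
    return out, excluded


# ---------------------------------------------------------------------------
# Moment computation
# ---------------------------------------------------------------------------

def compute_moments(
    z: ExpressionMatrix,
    pairs: PairList,
    spec: MomentSpec = MomentSpec(),
    chunk_size: int = 8192,
    symmetrize: bool = False,
) -> PairFeatureTable:
    """Joint moments m_{n,m} = (1/S) Σ_s x_sⁿ y_sᵐ for every pair.

    x is the lexicographically smaller gene of each pair.  Work proceeds in
    pair chunks against a precomputed gene × order × sample power tensor,
    so memory stays bounded for large pair lists.  With ``symmetrize`` the
    two orientations are averaged, removing the orientation dependence of
    the raw grid.
    """
    if z.normalization != "zscored":
        raise FeatureError(
            f"moments are defined on z-scored data, got {z.normalization!r}"
        )
    gene_index = z.gene_index()
    missing = [g for g in pairs.gene_ids if g not in gene_index]
    if missing:
        raise FeatureError(f"pair member {missing[0]!r} absent from matrix")

    # map pair-list vocabulary indices -> matrix rows
    vocab_rows = np.array([gene_index[str(g)] for g in pairs.gene_ids])
    S = z.n_samples
    K = spec.max_order
    # powers[g, k, s] = z[g, s] ** (k+1)
    powers = np.empty((z.n_genes, K, S))
    powers[:, 0, :] = z.values
    for k in range(1, K):
        powers[:, k, :] = powers[:, k - 1, :] * z.values

    n_pairs = len(pairs)
    out = np.empty((n_pairs, spec.n_features))
    left_rows = vocab_rows[pairs.left]
    right_rows = vocab_rows[pairs.right]
    for start in range(0, n_pairs, chunk_size):
        stop = min(start + chunk_size, n_pairs)
        a = powers[left_rows[start:stop]]
        b = powers[right_rows[start:stop]]
        m = np.einsum("cns,cms->cnm", a, b) / S
        if symmetrize:
            m = 0.5 * (m + np.swapaxes(m, 1, 2))
        out[start:stop] = m.reshape(stop - start, spec.n_features)
    return PairFeatureTable(pairs=pairs, spec=spec, raw_moments=out)


def standardize_moments(
    table: PairFeatureTable,
) -> tuple[PairFeatureTable, np.ndarray, np.ndarray]:
    """Scale every moment column to mean 0, SD 1 (population) across pairs.

    Zero-variance columns are set to zero (with a warning) and their SD
    recorded as 1 so the transform stays invertible in the others.
    Standardizing an already-standardized table is the identity.
    """
    if table.n_pairs < 2:
        raise FeatureError("standardization needs at least 2 pairs")
    means = table.raw_moments.mean(axis=0)
    sds = table.raw_moments.std(axis=0)
    flat = sds == 0
    if np.any(flat):
        logger.warning("%d constant moment column(s) zeroed", int(flat.sum()))
        sds = np.where(flat, 1.0, sds)
    standardized = (table.raw_moments - means) / sds
    out = replace(
        table,
        raw_moments=standardized,
        moment_means=means,
        moment_sds=sds,
        reduced=table.reduced,
    )
    return out, means, sds


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Standardization parameters plus orthonormal PCA loadings.

    ``loadings`` is (n_features × n_components) with orthonormal columns;
    ``explained_variance`` is non-increasing.  ``feature_means``/``sds``
    are the across-pair moment standardization folded into the model so it
    can be applied directly to raw moment tables.
    """

    feature_means: np.ndarray
    feature_sds: np.ndarray
    loadings: np.ndarray
    n_components: int
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise FeatureError("PCA loadings are not orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise FeatureError("explained variance must be non-increasing")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# momentgrn PCA model\n")
            for name, arr in (
                ("means", self.feature_means),
                ("sds", self.feature_sds),
                ("explained_variance", self.explained_variance),
            ):
                fh.write(f">{name}\t" + "\t".join(f"{v:.17g}" for v in arr) + "\n")
            fh.write(">loadings\n")
            for row in self.loadings:
                fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "PCAModel":
        vectors: dict[str, np.ndarray] = {}
        rows: list[list[float]] = []
        section = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                if line.startswith(">"):
                    parts = line[1:].split("\t")
                    section = parts[0]
                    if section != "loadings":
                        vectors[section] = np.array([float(v) for v in parts[1:]])
                elif section == "loadings":
                    rows.append([float(v) for v in line.split("\t")])
        loadings = np.array(rows)
        return cls(
            feature_means=vectors["means"],
            feature_sds=vectors["sds"],
            loadings=loadings,
            n_components=loadings.shape[1],
            explained_variance=vectors["explained_variance"],
        )


def fit_pca(table: PairFeatureTable, n_components: int = 36) -> PCAModel:
    """Fit PCA loadings on a standardized moment table.

    The loadings are the leading eigenvectors of the empirical covariance
    of the standardized moments (computed via SVD).  Requires the table to
    carry standardization parameters (see :func:`standardize_moments`); the
    model folds them in so it can later be applied to raw tables.
    """
    if n_components > table.spec.n_features:
        raise FeatureError(
            f"n_components={n_components} exceeds {table.spec.n_features} features"
        )
    if table.moment_means is None or table.moment_sds is None:
        raise FeatureError("fit_pca expects a standardized table")
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    pca.fit(table.raw_moments)
    return PCAModel(
        feature_means=table.moment_means.copy(),
        feature_sds=table.moment_sds.copy(),
        loadings=pca.components_.T.copy(),
        n_components=n_components,
        explained_variance=pca.explained_variance_.copy(),
    )


def transform_pca(model: PCAModel, table: PairFeatureTable) -> PairFeatureTable:
    """Project a moment table onto the PCA components.

    Standardization is re-applied from the model parameters unless the
    table already carries identical ones, so both raw and standardized
    tables are accepted.
    """
    if table.spec.n_features != model.loadings.shape[0]:
        raise FeatureError(
            f"table has {table.spec.n_features} features but model expects "
            f"{model.loadings.shape[0]}"
        )
    if table.moment_means is None:
        standardized = (table.raw_moments - model.feature_means) / model.feature_sds
    else:
        standardized = table.raw_moments
    reduced = standardized @ model.loadings
    return replace(table, reduced=reduced)
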