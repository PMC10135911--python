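"""Training-set construction: gold-standard positives, low-correlation negatives.

Positive pairs are those whose unordered form appears in a curated
regulator → target edge list.  True negatives are unknowable, so the
negative class is built from the pairs with the smallest |m₁,₁| (absolute
correlation on z-scored genes) — the "least correlated pairs are unrelated"
heuristic.  The assembled training matrix is balanced (equal ones and
zeros), by default 10,000 of each over the reduced features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pair_features import PairFeatureTable
from .synthetic_grn import GoldStandard

logger = logging.getLogger(__name__)


class LabelingError(ValueError):
    """Invalid labeling input or insufficient supply of labeled pairs."""


@dataclass(frozen=True)
class NegativeSelectionConfig:
    """How many lowest-|correlation| pairs form the negative class."""

    k: int = 10_000
    exclude_gold: bool = True

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise LabelingError("k must be positive")


@dataclass
class LabeledTrainingSet:
    """Aligned features, 0/1 labels, pair ids, and per-row provenance."""

    features: np.ndarray
    labels: np.ndarray
    pair_ids: np.ndarray  # (n, 2) canonical pairs
    provenance: np.ndarray  # per-row tag: gold source or "low-correlation"
    table_rows: np.ndarray | None = None  # row indices into the source table

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.pair_ids) == len(self.provenance) == n):
            raise LabelingError("training-set fields are misaligned")
        if self.table_rows is not None and len(self.table_rows) != n:
            raise LabelingError("training-set fields are misaligned")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise LabelingError("labels must be 0/1")
        keys = {tuple(p) for p in self.pair_ids}
        if len(keys) != n:
            raise LabelingError("a pair appears twice in the training set")

    @property
    def n_rows(self) -> int:
        return int(self.features.shape[0])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.features,
            columns=[f"f{j + 1}" for j in range(self.features.shape[1])],
        )
        frame.insert(0, "provenance", self.provenance)
        frame.insert(0, "label", self.labels)
        frame.insert(0, "pair_b", self.pair_ids[:, 1])
        frame.insert(0, "pair_a", self.pair_ids[:, 0])
        return frame

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_gold_edges(
    path: str | Path,
    delimiter: str = "\t",
    id_map: dict[str, str] | None = None,
    on_self_edge: str = "warn",
    source_tag: str | None = None,
) -> GoldStandard:
    """Parse a two-column (regulator, target) edge list.

    Gene ids pass through ``id_map`` when supplied.  Self-edges are dropped
    with a warning (``on_self_edge="warn"``) or rejected (``"error"``);
    duplicate rows are deduplicated with the count logged.
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        header_skipped = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(delimiter)
            if len(parts) < 2 or any(not p.strip() for p in parts[:2]):
                raise LabelingError(
                    f"malformed edge row at line {lineno} of {path}: {line!r}"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if not header_skipped and {a.lower(), b.lower()} & {
                "regulator",
                "target",
                "tf",
                "source",
            }:
                header_skipped = True
                continue
            if id_map:
                a, b = id_map.get(a, a), id_map.get(b, b)
            if a == b:
                if on_self_edge == "error":
                    raise LabelingError(f"self-edge {a!r} at line {lineno}")
                logger.warning("dropping self-edge %r at line %d", a, lineno)
                continue
            edges.append((a, b))
    unique = frozenset(edges)
    if len(unique) < len(edges):
        logger.info(
            "deduplicated %d duplicate edge row(s)", len(edges) - len(unique)
        )
    return GoldStandard(edges=unique, source_tag=source_tag or str(path))


def build_positive_set(
    table: PairFeatureTable, gold: GoldStandard
) -> tuple[np.ndarray, int]:
    """Rows of the feature table whose pair matches a gold edge (undirected).

    Directed edges are collapsed to unordered pairs, so A→B and B→A yield
    one positive.  Gold pairs absent from the table (e.g. genes not in the
    expression matrix) are skipped; their count is returned.

    Returns (sorted row indices, number of gold pairs skipped).
    """
    index = table.pairs.index_of()
    rows: set[int] = set()
    skipped = 0
    for a, b in gold.undirected_pairs():
        i = index.get((a, b))
        if i is None:
            skipped += 1
        else:
            rows.add(i)
    if not rows:
        raise LabelingError(
            "no gold pair matches the feature table; nothing to train on"
        )
    if skipped:
        logger.info("%d gold pair(s) absent from the feature table", skipped)
    return np.array(sorted(rows), dtype=np.int64), skipped


def select_negatives(
    table: PairFeatureTable,
    gold: GoldStandard,
    config: NegativeSelectionConfig = NegativeSelectionConfig(),
) -> np.ndarray:
    """The k pairs with the smallest |m₁,₁|, as row indices.

    Eligible pairs (all pairs, minus gold pairs when ``exclude_gold``) are
    ranked by |m₁,₁| ascending with a stable tie-break on canonical pair id
    (the table's lexicographic pair order), and the first k are taken.
    """
    abs_corr = np.abs(table.correlation)
    eligible = np.ones(table.n_pairs, dtype=bool)
    if config.exclude_gold:
        index = table.pairs.index_of()
        for a, b in gold.undirected_pairs():
            i = index.get((a, b))
            if i is not None:
                eligible[i] = False
    n_eligible = int(eligible.sum())
    if config.k > n_eligible:
        raise LabelingError(
            f"k={config.k} negatives requested but only {n_eligible} "
            "eligible pairs"
        )
    candidates = np.flatnonzero(eligible)
    # stable sort on |m11|; candidates are already in canonical pair order
    order = candidates[np.argsort(abs_corr[candidates], kind="stable")]
    return np.sort(order[: config.k])


def correlation_histogram(
    table: PairFeatureTable, n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of |m₁,₁| over all pairs: (bin_edges, counts)."""
    abs_corr = np.abs(table.correlation)
    counts, edges = np.histogram(abs_corr, bins=n_bins, range=(0.0, max(1.0, abs_corr.max())))
    return edges, counts


def density_overlap(
    table: PairFeatureTable,
    positives: np.ndarray,
    n_bins: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Binned densities of m₁,₁ for positive vs remaining pairs.

    Returns (bin_edges, density_positive, density_rest, overlap) where the
    overlap coefficient ∈ [0, 1] is the integral of the pointwise minimum
    of the two densities.  A value near 1 means correlation alone cannot
    separate linked from unlinked pairs.
    """
    if len(positives) == 0:
        raise LabelingError("positive set is empty")
    corr = table.correlation
    mask = np.zeros(table.n_pairs, dtype=bool)
    mask[positives] = True
    lo, hi = float(corr.min()), float(corr.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    dens_pos, _ = np.histogram(corr[mask], bins=edges, density=True)
    rest = corr[~mask]
    if rest.size:
        dens_rest, _ = np.histogram(rest, bins=edges, density=True)
    else:
        dens_rest = np.zeros_like(dens_pos)
    width = np.diff(edges)
    overlap = float(np.sum(np.minimum(dens_pos, dens_rest) * width))
    return edges, dens_pos, dens_rest, min(overlap, 1.0)


def assemble_training_set(
    positives: np.ndarray,
    negatives: np.ndarray,
    table: PairFeatureTable,
    n_pos: int = 10_000,
    n_neg: int = 10_000,
    seed: int = 0,
) -> LabeledTrainingSet:
    """Balanced labeled matrix over the reduced features.

    When supply exceeds demand, rows are sampled uniformly without
    replacement with the given seed; exact supply is taken whole.  The
    positive and negative index sets must be disjoint.
    """
    if table.reduced is None:
        raise LabelingError("feature table has no reduced features")
    if set(positives.tolist()) & set(negatives.tolist()):
        raise LabelingError("positive and negative sets overlap")
    if len(positives) < n_pos:
        raise LabelingError(
            f"need {n_pos} positives but only {len(positives)} available "
            f"(shortfall {n_pos - len(positives)})"
        )
    if len(negatives) < n_neg:
        raise LabelingError(
            f"need {n_neg} negatives but only {len(negatives)} available "
            f"(shortfall {n_neg - len(negatives)})"
        )
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(positives, size=n_pos, replace=False))
    neg = np.sort(rng.choice(negatives, size=n_neg, replace=False))
    rows = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    ids = table.pairs.pair_ids()[rows]
    provenance = np.concatenate(
        [np.full(n_pos, "gold"), np.full(n_neg, "low-correlation")]
    )
    return LabeledTrainingSet(
        features=table.reduced[rows],
        labels=labels,
        pair_ids=ids,
        provenance=provenance,
        table_rows=rows,
    )
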