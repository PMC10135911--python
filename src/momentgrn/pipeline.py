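"""End-to-end orchestration: simulate/load → features → label → train → evaluate.

A run is driven by a :class:`RunConfig` (loadable from YAML).  All
randomness flows from the single config seed through named sub-seeds, so a
rerun with the same config reproduces every artifact byte-for-byte.  Each
stage's output is written to the run directory and checksummed into a
manifest.

The held-out evaluation has two parts:

* a balanced test split of the labeled set (class accuracies, recall,
  precision, ROC/PR with bootstrap error bars), and
* a network-recovery ranking: held-out gold pairs against randomly drawn
  non-gold candidate pairs, scored by each classifier and by the
  |correlation|-only baseline.  This is the comparison that shows what the
  higher moments add over plain correlation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .classifiers import (
    OneClassConfig,
    REWKLRConfig,
    SVMConfig,
    bootstrap_tune,
    make_grid,
    predict_ocsvm,
    predict_rewklr,
    predict_svm,
    train_ocsvm,
    train_rewklr,
    train_svm,
)
from .evaluation import evaluate_classifier
from .expression_data import (
    ExpressionMatrix,
    fpkm_normalize,
    log_transform,
    read_expression_matrix,
    read_gene_id_map,
    read_gene_lengths,
    tpm_normalize,
)
from .labeling import (
    NegativeSelectionConfig,
    assemble_training_set,
    build_positive_set,
    density_overlap,
    load_gold_edges,
    select_negatives,
)
from .pair_features import (
    MomentSpec,
    compute_moments,
    enumerate_pairs,
    fit_pca,
    standardize_moments,
    transform_pca,
    zscore_genes,
)
from .synthetic_grn import GoldStandard, SimulationConfig, simulate_expression, simulate_network

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_GRIDS: dict[str, dict[str, list[float]]] = {
    # smoother kernels first: grid order breaks ties toward them
    "rewklr": {"sigma": [20.0, 10.0, 5.0, 2.0], "lam": [0.01, 0.1, 1.0]},
    "svm": {"gamma": [0.001, 0.01, 0.1, 1.0], "C": [1.0, 10.0, 30.0]},
    "ocsvm": {"gamma": [0.001, 0.01, 0.1], "nu": [0.03, 0.1, 0.2]},
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Either ``simulate`` (study conditions for the synthetic generator) or
    ``input_paths`` (matrix/gold, optional lengths/id-map files) must be
    given.  ``normalization`` applies TPM/FPKM to raw counts;
    ``log_transform`` moves intensity-scale data to log2 before z-scoring.
    """

    output_dir: str = "runs/run"
    seed: int = 0
    simulate: dict[str, Any] | None = None
    input_paths: dict[str, str] | None = None
    normalization: str = "none"  # tpm | fpkm | none
    log_transform: bool = False
    max_order: int = 7
    n_components: int = 36
    chunk_size: int = 8192
    negatives_k: int = 10_000
    exclude_gold: bool = True
    n_pos: int | None = None  # default: balanced min(10_000, supply)
    n_neg: int | None = None
    train_fraction: float = 0.5
    classifiers: list[str] = field(default_factory=lambda: ["rewklr", "svm", "ocsvm"])
    grids: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    n_boot: int = 10
    # "sample": unweighted (default — with balanced 1:1 training the
    # prevalence correction collapses the effective positive sample);
    # "gold_prevalence": τ = fraction of candidate pairs that are gold;
    # or an explicit population prevalence in (0,1)
    rewklr_tau: float | str = "sample"
    n_thresholds: int = 101
    n_resamples: int = 500
    n_eval_negatives: int = 1000
    write_features: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _spawn_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name attached."""

    class _Guard:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Guard()


def _load_inputs(cfg: RunConfig) -> tuple[ExpressionMatrix, GoldStandard, dict | None]:
    if cfg.simulate is not None:
        sim = SimulationConfig(seed=cfg.seed, **cfg.simulate)
        gold = simulate_network(sim)
        matrix = simulate_expression(gold, sim)
        return matrix, gold, None
    paths = cfg.input_paths or {}
    for key in ("matrix", "gold"):
        if key not in paths:
            raise PipelineError(f"input_paths must provide {key!r}")
        if not Path(paths[key]).exists():
            raise PipelineError(f"missing input file: {paths[key]}")
    for key in ("lengths", "id_map"):
        if key in paths and not Path(paths[key]).exists():
            raise PipelineError(f"missing input file: {paths[key]}")
    tag = "raw_counts" if cfg.normalization in ("tpm", "fpkm") else "microarray"
    matrix = read_expression_matrix(paths["matrix"], normalization=tag)
    id_map = read_gene_id_map(paths["id_map"]) if "id_map" in paths else None
    if id_map:
        from .expression_data import apply_gene_id_map

        matrix = apply_gene_id_map(matrix, id_map, on_missing="keep")
    gold = load_gold_edges(paths["gold"], id_map=id_map)
    lengths = read_gene_lengths(paths["lengths"]) if "lengths" in paths else None
    return matrix, gold, lengths


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written to disk)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(
        cfg.seed, ["sample", "split", "tune", "eval", "eval_negatives"]
    )
    cfg.to_yaml(out / "config.yaml")
    artifacts: list[Path] = [out / "config.yaml"]
    report: dict[str, Any] = {"seed": cfg.seed, "sub_seeds": seeds}

    with _stage("inputs"):
        matrix, gold, lengths = _load_inputs(cfg)
        gold.write(out / "gold_standard.tsv")
        artifacts.append(out / "gold_standard.tsv")
        report["n_genes_input"] = matrix.n_genes
        report["n_samples"] = matrix.n_samples
        report["n_gold_edges"] = gold.n_edges

    with _stage("normalize"):
        if cfg.normalization == "tpm":
            matrix = tpm_normalize(matrix, lengths or {})
        elif cfg.normalization == "fpkm":
            matrix = fpkm_normalize(matrix, lengths or {})
        elif cfg.normalization != "none":
            raise PipelineError(f"unknown normalization {cfg.normalization!r}")
        if cfg.log_transform:
            matrix = log_transform(matrix)
        report["normalization"] = cfg.normalization
        report["log_transform"] = cfg.log_transform

    with _stage("features"):
        z, excluded = zscore_genes(matrix)
        pairs = enumerate_pairs(z.gene_ids)
        spec = MomentSpec(max_order=cfg.max_order)
        table = compute_moments(z, pairs, spec, chunk_size=cfg.chunk_size)
        table, means, sds = standardize_moments(table)
        pca = fit_pca(table, n_components=cfg.n_components)
        table = transform_pca(pca, table)
        pca.write(out / "pca_model.tsv")
        artifacts.append(out / "pca_model.tsv")
        if cfg.write_features:
            table.write(out / "pair_features.tsv", reduced=True)
            artifacts.append(out / "pair_features.tsv")
        report["n_genes_retained"] = z.n_genes
        report["n_genes_excluded"] = len(excluded)
        report["n_pairs"] = table.n_pairs
        report["n_moment_features"] = spec.n_features
        report["n_reduced_features"] = cfg.n_components

    with _stage("label"):
        positives, skipped = build_positive_set(table, gold)
        neg_cfg = NegativeSelectionConfig(
            k=min(cfg.negatives_k, table.n_pairs - len(positives) - 1),
            exclude_gold=cfg.exclude_gold,
        )
        negatives = select_negatives(table, gold, neg_cfg)
        n_pos = cfg.n_pos or min(10_000, len(positives))
        n_neg = cfg.n_neg or min(n_pos, len(negatives))
        training = assemble_training_set(
            positives, negatives, table, n_pos=n_pos, n_neg=n_neg, seed=seeds["sample"]
        )
        training.write(out / "training_set.tsv")
        artifacts.append(out / "training_set.tsv")
        _, _, _, overlap = density_overlap(table, positives)
        report["n_positives_available"] = len(positives)
        report["n_gold_pairs_skipped"] = skipped
        report["negatives_k"] = neg_cfg.k
        report["training_rows"] = training.n_rows
        report["training_features"] = int(training.features.shape[1])
        report["correlation_density_overlap"] = overlap

    with _stage("split"):
        rng = np.random.default_rng(seeds["split"])
        train_idx, test_idx = _stratified_split(
            training.labels, cfg.train_fraction, rng
        )
        report["n_train"] = len(train_idx)
        report["n_test"] = len(test_idx)

    X_tr, y_tr = training.features[train_idx], training.labels[train_idx]
    X_te, y_te = training.features[test_idx], training.labels[test_idx]

    if cfg.rewklr_tau == "gold_prevalence":
        rewklr_tau: float | str = len(positives) / table.n_pairs
    else:
        rewklr_tau = cfg.rewklr_tau
    report["rewklr_tau"] = rewklr_tau

    with _stage("train"):
        models, tuning = _train_all(cfg, X_tr, y_tr, seeds["tune"], rewklr_tau)
        for tag, frame in tuning.items():
            frame.to_csv(out / f"tuning_{tag}.tsv", sep="\t", index=False)
            artifacts.append(out / f"tuning_{tag}.tsv")
        report["tuned_parameters"] = {
            tag: params for tag, (params, _) in models.items()
        }

    with _stage("evaluate"):
        report["test_metrics"] = {}
        for tag, (params, model) in models.items():
            scores, predictions = _score(tag, model, X_te)
            rep = evaluate_classifier(
                y_te,
                scores,
                predictions,
                n_thresholds=cfg.n_thresholds,
                n_resamples=cfg.n_resamples,
                seed=seeds["eval"],
                one_class=(tag == "ocsvm"),
                dataset_tag=cfg.normalization,
                classifier_tag=tag,
            )
            report["test_metrics"][tag] = rep.summary()
            if rep.roc is not None:
                rep.roc.to_frame("fpr", "tpr").to_csv(
                    out / f"roc_{tag}.tsv", sep="\t", index=False
                )
                artifacts.append(out / f"roc_{tag}.tsv")
            if rep.pr is not None:
                rep.pr.to_frame("recall", "precision").to_csv(
                    out / f"pr_{tag}.tsv", sep="\t", index=False
                )
                artifacts.append(out / f"pr_{tag}.tsv")

        report["ranking"] = _ranking_evaluation(
            cfg, table, gold, training, test_idx, models, seeds["eval_negatives"]
        )

    with _stage("report"):
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        artifacts.append(out / "report.json")
        manifest = {str(p.relative_to(out)): _sha256(p) for p in artifacts}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return report


def _jsonable(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_parts, test_parts = [], []
    for cls in (0, 1):
        rows = np.flatnonzero(labels == cls)
        perm = rng.permutation(rows)
        n_train = int(round(train_fraction * len(rows)))
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def _train_all(
    cfg: RunConfig,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    tune_seed: int,
    rewklr_tau: float | str = "sample",
) -> tuple[dict, dict]:
    models: dict[str, tuple[dict, Any]] = {}
    tuning: dict[str, Any] = {}
    for tag in cfg.classifiers:
        grid_axes = cfg.grids.get(tag, DEFAULT_GRIDS[tag])
        grid = make_grid(**grid_axes)
        params, tune_table = bootstrap_tune(
            (X_tr, y_tr), tag, grid, n_boot=cfg.n_boot, seed=tune_seed
        )
        tuning[tag] = tune_table
        if tag == "rewklr":
            model = train_rewklr(
                (X_tr, y_tr),
                REWKLRConfig(
                    lam=params["lam"], sigma=params["sigma"], tau=rewklr_tau
                ),
            )
        elif tag == "svm":
            model = train_svm(
                (X_tr, y_tr), SVMConfig(C=params["C"], gamma=params["gamma"])
            )
        elif tag == "ocsvm":
            model = train_ocsvm(
                X_tr[y_tr == 1],
                OneClassConfig(nu=params["nu"], gamma=params["gamma"]),
            )
        else:
            raise PipelineError(f"unknown classifier tag {tag!r}")
        models[tag] = (params, model)
    return models, tuning


def _score(tag: str, model: Any, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if tag == "rewklr":
        prob, labels = predict_rewklr(model, X)
        return prob, labels
    if tag == "svm":
        return predict_svm(model, X)
    if tag == "ocsvm":
        return predict_ocsvm(model, X)
    raise PipelineError(f"unknown classifier tag {tag!r}")


def _ranking_evaluation(
    cfg: RunConfig,
    table,
    gold: GoldStandard,
    training,
    test_idx: np.ndarray,
    models: dict,
    seed: int,
) -> dict:
    """Held-out gold pairs vs random non-gold pairs, ranked by each classifier.

    The |m₁,₁| baseline ranks the same pairs by absolute correlation; the
    margin of the moment classifiers over this baseline quantifies what the
    higher-order moments contribute.
    """
    index = table.pairs.index_of()
    gold_rows = {
        index[p] for p in gold.undirected_pairs() if p in index
    }
    held_out_pos = np.array(
        sorted(
            set(training.table_rows[test_idx][training.labels[test_idx] == 1])
        ),
        dtype=np.int64,
    )
    if held_out_pos.size == 0:
        return {}
    used = set(training.table_rows.tolist())
    candidates = np.array(
        sorted(set(range(table.n_pairs)) - gold_rows - used), dtype=np.int64
    )
    rng = np.random.default_rng(seed)
    n_neg = min(cfg.n_eval_negatives, len(candidates))
    eval_neg = np.sort(rng.choice(candidates, size=n_neg, replace=False))
    rows = np.concatenate([held_out_pos, eval_neg])
    labels = np.concatenate(
        [np.ones(held_out_pos.size, int), np.zeros(eval_neg.size, int)]
    )
    out: dict[str, Any] = {
        "n_heldout_positives": int(held_out_pos.size),
        "n_random_negatives": int(eval_neg.size),
    }
    baseline = np.abs(table.correlation[rows])
    out["correlation_only_auc"] = _rank_auc(labels, baseline)
    for tag, (_, model) in models.items():
        if tag == "ocsvm":
            scores, _ = predict_ocsvm(model, table.reduced[rows])
        else:
            scores, _ = _score(tag, model, table.reduced[rows])
        out[f"{tag}_auc"] = _rank_auc(labels, scores)
    return out


def _rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Exact Mann–Whitney AUC (ties counted half)."""
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
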