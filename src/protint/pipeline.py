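"""End-to-end orchestration: dataset → grid search → model → scan → report.

One :class:`RunConfig` (loadable from YAML) drives the whole protocol:

1. redundancy-reduce the positive partners (identity > threshold removed);
2. sample constraint-satisfying negatives from the background proteome;
3. optionally upsample positives and enlarge the negative sample to match;
4. encode everything in a frozen feature space and grid-search
   (C, γ, n_features) by stratified 5-fold cross-validation;
5. train the final calibrated model at the optimum and derive the
   probability call threshold from the training set;
6. scan the proteome (training proteins excluded) and, when a category map
   is supplied, tabulate GOslim molecular-function profiles of known vs
   newly predicted partners.

Every artifact is written under ``output_dir``; the machine-readable
``report.json`` is byte-identical across reruns with the same config and
seeds (stage wall-times go to the log, never into the report).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from protint import dataset as ds
from protint import model as md
from protint import scan as sc
from protint.features import build_space, f_score_rank
from protint.redundancy import IdentityConfig, dedupe_within
from protint.seqdata import (
    Proteome,
    attach_domains,
    read_accession_list,
    read_domain_table,
    read_fasta,
    write_fasta,
)

logger = logging.getLogger(__name__)


def derived_seed(master: int, *key: int) -> int:
    """Deterministic child seed (< 2^31) from a master seed and a counter key.

    Any single repeat of a multi-run experiment is re-runnable in isolation
    by reconstructing its seed from the master seed and its counter.
    """
    return int(np.random.SeedSequence([master, *key]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    proteome_fasta: str
    domain_tsv: str
    positives_list: str
    output_dir: str
    goslim_tsv: str | None = None
    sampling: ds.SamplingConfig = field(default_factory=ds.SamplingConfig)
    grid: md.GridSpec = field(default_factory=md.GridSpec)
    k: int = 5
    seed: int = 0
    leaky_upsampling: bool = False
    global_selection: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sampling" in raw:
            raw["sampling"] = ds.SamplingConfig(**raw["sampling"])
        if "grid" in raw:
            grid = raw["grid"]
            if "feature_count_candidates" in grid and grid["feature_count_candidates"]:
                grid["feature_count_candidates"] = tuple(grid["feature_count_candidates"])
            raw["grid"] = md.GridSpec(**grid)
        return cls(**raw)

    def validate_paths(self) -> None:
        missing = [
            p
            for p in (self.proteome_fasta, self.domain_tsv, self.positives_list,
                      self.goslim_tsv)
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    n_positives_input: int
    n_positives_nonredundant: int
    upsample_factor: int
    n_positive_examples: int
    n_negative_examples: int
    feature_dimension: int
    best_C: float
    best_gamma: float
    best_n_features: int
    cv_sensitivity: float
    cv_specificity: float
    cv_accuracy: float
    cv_confusion: dict
    cv_auc: float
    threshold: float
    n_correct_training: int
    n_scanned: int
    n_candidates: int
    seed: int
    k: int
    leaky_upsampling: bool
    global_selection: bool

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2) + "\n"


class _Stage:
    """Log wall time per pipeline stage; abort messages carry the stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is not None:
            logger.error("stage %s: failed after %.2fs: %s", self.name, dt, exc)
            return False
        logger.info("stage %s: done in %.2fs", self.name, dt)
        return False


def _load_inputs(config: RunConfig) -> tuple[Proteome, list[str]]:
    proteome = read_fasta(config.proteome_fasta)
    annotations = read_domain_table(config.domain_tsv)
    proteome = attach_domains(proteome, annotations)
    positives = read_accession_list(config.positives_list)
    missing = [a for a in positives if a not in proteome]
    if missing:
        raise ValueError(f"positive accessions not in proteome: {missing[:5]}")
    return proteome, positives


def _build_training_set(
    config: RunConfig,
    proteome: Proteome,
    positives_nr,
    sample_seed: int,
    upsample_factor: int | None = None,
):
    factor = config.sampling.upsample_factor if upsample_factor is None else upsample_factor
    pos_up = ds.upsample_positives(positives_nr, factor)
    n_neg = (
        config.sampling.n_negatives
        if config.sampling.n_negatives is not None
        else len(pos_up)
    )
    sampling = dataclasses.replace(
        config.sampling, n_negatives=n_neg, seed=sample_seed
    )
    negatives = ds.sample_negatives(proteome, positives_nr, sampling)
    space = build_space(list(positives_nr) + list(negatives))
    return ds.assemble(pos_up, negatives, space, seed=sample_seed), negatives


def run(config: RunConfig) -> RunReport:
    """Execute the full protocol and write all artifacts to ``output_dir``.

    Fully reproducible given the config and seeds: reports are byte-identical
    across reruns.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _Stage("load"):
        proteome, positive_accessions = _load_inputs(config)

    with _Stage("dedupe"):
        id_config = IdentityConfig(threshold=config.sampling.identity_threshold)
        positives_nr = dedupe_within(proteome.subset(positive_accessions), id_config)
        write_fasta(positives_nr, out / "positives_nonredundant.fasta")

    with _Stage("sample-negatives"):
        dataset, negatives = _build_training_set(
            config, proteome, positives_nr, sample_seed=config.seed
        )
        (out / "negatives.txt").write_text(
            "".join(r.accession + "\n" for r in negatives)
        )
        dataset.save(out / "dataset")

    with _Stage("grid-search"):
        gs = md.grid_search(
            dataset, config.grid, k=config.k, seed=config.seed,
            global_selection=config.global_selection, leaky=config.leaky_upsampling,
        )
        gs.surface.to_csv(out / "grid_surface.tsv", sep="\t", index=False)
        gs.best_cv.roc.to_frame().to_csv(out / "roc.tsv", sep="\t", index=False)

    with _Stage("final-train"):
        final = md.train(dataset, gs.best_config, seed=config.seed, probability=True)
        final.save(out / "model.joblib")
        thr = sc.derive_threshold(final, dataset)

    with _Stage("scan"):
        exclude = set(positive_accessions) | {r.accession for r in negatives}
        predictions = sc.scan_proteome(final, proteome, exclude, thr.threshold)
        sc.predictions_to_frame(predictions).to_csv(
            out / "predictions.tsv", sep="\t", index=False
        )
        candidates = [p.accession for p in predictions if p.call]

    if config.goslim_tsv is not None:
        with _Stage("goslim"):
            category_map = read_domain_table(config.goslim_tsv)
            table = sc.goslim_side_by_side(positive_accessions, candidates, category_map)
            table.to_csv(out / "goslim.tsv", sep="\t", index=False)

    report = RunReport(
        n_positives_input=len(positive_accessions),
        n_positives_nonredundant=len(positives_nr),
        upsample_factor=config.sampling.upsample_factor,
        n_positive_examples=dataset.n_positives,
        n_negative_examples=dataset.n_negatives,
        feature_dimension=dataset.space.dimension,
        best_C=float(gs.best_config.C),
        best_gamma=float(gs.best_config.gamma),
        best_n_features=int(gs.best_config.n_features),
        cv_sensitivity=float(gs.best_cv.metrics.sensitivity),
        cv_specificity=float(gs.best_cv.metrics.specificity),
        cv_accuracy=float(gs.best_cv.metrics.accuracy),
        cv_confusion={
            "TP": gs.best_cv.metrics.confusion.TP,
            "FP": gs.best_cv.metrics.confusion.FP,
            "TN": gs.best_cv.metrics.confusion.TN,
            "FN": gs.best_cv.metrics.confusion.FN,
        },
        cv_auc=float(gs.best_cv.roc.auc),
        threshold=float(thr.threshold),
        n_correct_training=int(thr.n_correct),
        n_scanned=len(predictions),
        n_candidates=len(candidates),
        seed=config.seed,
        k=config.k,
        leaky_upsampling=config.leaky_upsampling,
        global_selection=config.global_selection,
    )
    (out / "report.json").write_text(report.to_json())
    return report


@dataclass
class RepeatSummary:
    """Accuracy distribution over repeated negative-set selections."""

    accuracies: list[float]
    model_config: md.ModelConfig

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def min(self) -> float:
        return float(np.min(self.accuracies))

    @property
    def max(self) -> float:
        return float(np.max(self.accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


def repeat_negatives(
    config: RunConfig,
    n_repeats: int,
    model_config: md.ModelConfig,
) -> RepeatSummary:
    """Robustness to random negative selection at fixed (C, γ, n_features).

    Re-samples the negative set ``n_repeats`` times with seeds derived from
    the master seed by counter, re-runs cross-validation, and summarizes the
    accuracy distribution (mean/min/max/std).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    config.validate_paths()
    proteome, positive_accessions = _load_inputs(config)
    id_config = IdentityConfig(threshold=config.sampling.identity_threshold)
    positives_nr = dedupe_within(proteome.subset(positive_accessions), id_config)
    accuracies = []
    for i in range(n_repeats):
        seed_i = derived_seed(config.seed, i)
        dataset, _ = _build_training_set(config, proteome, positives_nr, sample_seed=seed_i)
        cv = md.cross_validate(
            dataset, model_config, k=config.k, seed=seed_i,
            global_selection=config.global_selection, leaky=config.leaky_upsampling,
        )
        accuracies.append(float(cv.metrics.accuracy))
    return RepeatSummary(accuracies=accuracies, model_config=model_config)


def upsample_sweep(
    config: RunConfig,
    model_config: md.ModelConfig,
    factors: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_selections: int = 10,
) -> pd.DataFrame:
    """Accuracy vs upsampling factor, negatives re-selected per factor.

    For each factor the negative set (matched in size to the upsampled
    positives) is re-sampled ``n_selections`` times; returns a frame with
    per-factor mean and standard deviation of CV accuracy.
    """
    config.validate_paths()
    proteome, positive_accessions = _load_inputs(config)
    id_config = IdentityConfig(threshold=config.sampling.identity_threshold)
    positives_nr = dedupe_within(proteome.subset(positive_accessions), id_config)
    rows = []
    for factor in factors:
        accs = []
        for j in range(n_selections):
            seed_j = derived_seed(config.seed, factor, j)
            dataset, _ = _build_training_set(
                config, proteome, positives_nr, sample_seed=seed_j,
                upsample_factor=factor,
            )
            cv = md.cross_validate(
                dataset, model_config, k=config.k, seed=seed_j,
                global_selection=config.global_selection,
                leaky=config.leaky_upsampling,
            )
            accs.append(float(cv.metrics.accuracy))
        rows.append(
            {
                "factor": factor,
                "mean_accuracy": float(np.mean(accs)),
                "std_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "n_selections": len(accs),
            }
        )
    return pd.DataFrame(rows)


def rank_features(dataset: ds.LabeledDataset) -> pd.DataFrame:
    """Convenience: F-score ranking as a frame with human-readable names."""
    names = dataset.space.feature_names()
    scores = f_score_rank(dataset)
    return pd.DataFrame(
        [
            {"rank": s.rank, "feature": names[s.feature_index],
             "feature_index": s.feature_index, "f_score": s.f_score}
            for s in scores
        ]
    )
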