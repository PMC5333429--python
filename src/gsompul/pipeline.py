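"""Staged pipeline tying the method together over an output directory.

Stages (each persists its artifacts so CLI subcommands can run them
independently): featurize -> cluster -> profile -> train -> predict ->
annotate -> evaluate.  ``run_pipeline`` executes them in order and writes
a manifest (config echo, seeds, package version) sufficient to reproduce
every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import __version__
from .classification import (
    build_balanced_sets,
    ensemble_predict,
    train_svm,
)
from .cyp_annotation import CYP_INDEPENDENT, CYPLabel, annotate_predictions, label_map_cyp
from .evaluation import compute_metrics, confusion_from_labels, kfold_cv
from .gsom import GSOMConfig, GSOMMap, train_gsom
from .io import (
    read_cyp_annotations,
    read_feature_matrix,
    read_negative_set,
    read_pair_feature_table,
    read_pair_labels,
    write_negative_set,
    write_node_profiles,
    write_pair_feature_table,
)
from .pul_profiling import (
    ambiguous_unlabeled_pairs,
    consensus_negatives,
    infer_negatives,
    profile_nodes,
)
from .similarity import (
    POSITIVE,
    UNLABELED,
    build_pair_feature_table,
    fit_variance_projection,
    project_table,
)

logger = logging.getLogger("gsompul")

REPRESENTATIONS = ("SFR1", "SFR2-projected")


@dataclass(frozen=True)
class PipelineConfig:
    """Paths plus per-stage settings; defaults mirror the method's standard run."""

    matrix_paths: tuple[str, ...] = ()
    positives_path: str = ""
    cyp_path: str | None = None
    output_dir: str = "gsompul_out"
    spread_factor_sfr1: float = 0.1
    spread_factor_sfr2: float = 1e-15
    variance_fraction: float = 0.90
    min_node_size: int = 2
    n_balanced_sets: int = 10
    kernel_degree: int = 2
    c_sfr1: float = 1e-2
    c_sfr2: float = 1e-3
    threshold: float = 0.5
    balanced_set_cap: int | None = None
    cv_folds: int = 5
    master_seed: int = 0
    gsom: GSOMConfig = field(default_factory=GSOMConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gsom = GSOMConfig(**raw.pop("gsom", {}))
        raw["matrix_paths"] = tuple(raw.get("matrix_paths", ()))
        return cls(gsom=gsom, **raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["matrix_paths"] = list(data["matrix_paths"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def rep_settings(self, representation: str) -> tuple[float, float]:
        """(spread_factor, C) for a representation."""
        if representation == "SFR1":
            return self.spread_factor_sfr1, self.c_sfr1
        return self.spread_factor_sfr2, self.c_sfr2


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _rep_slug(rep: str) -> str:
    return rep.lower().replace("-", "_")


def stage_featurize(config: PipelineConfig) -> dict[str, object]:
    """Read matrices + positive pairs, build SFR1 and projected SFR2 tables."""
    out = _outdir(config)
    matrices = [read_feature_matrix(p) for p in config.matrix_paths]
    common = set(matrices[0].drug_ids)
    for m in matrices[1:]:
        common &= set(m.drug_ids)
    dropped = set().union(*(m.drug_ids for m in matrices)) - common
    if dropped:
        logger.warning("dropping %d drugs absent from some source", len(dropped))
    labels = read_pair_labels(config.positives_path, known_drugs=common)

    sfr1 = build_pair_feature_table(matrices, "SFR1").with_labels(labels)
    sfr2 = build_pair_feature_table(matrices, "SFR2").with_labels(labels)
    projection = fit_variance_projection(sfr2, config.variance_fraction)
    sfr2p = project_table(sfr2, projection)

    write_pair_feature_table(sfr1, out / "sfr1.tsv", out / "sfr1.meta.json")
    write_pair_feature_table(sfr2p, out / "sfr2_projected.tsv", out / "sfr2_projected.meta.json")
    with open(out / "projection.json", "w") as fh:
        json.dump(
            {
                "n_components": projection.n_components,
                "retained_variance_fraction": projection.retained_variance_fraction,
            },
            fh,
            indent=1,
        )
    logger.info(
        "featurize: %d pairs, %d positives, %d projected components",
        len(sfr1.pairs), sum(l == POSITIVE for l in sfr1.labels), projection.n_components,
    )
    return {"SFR1": sfr1, "SFR2-projected": sfr2p}


def _load_tables(config: PipelineConfig) -> dict[str, object]:
    out = _outdir(config)
    return {
        "SFR1": read_pair_feature_table(out / "sfr1.tsv", out / "sfr1.meta.json"),
        "SFR2-projected": read_pair_feature_table(
            out / "sfr2_projected.tsv", out / "sfr2_projected.meta.json"
        ),
    }


def stage_cluster(config: PipelineConfig, tables=None) -> dict[str, GSOMMap]:
    """Train one GSOM per representation (seeds derived from the master seed)."""
    out = _outdir(config)
    tables = tables or _load_tables(config)
    maps = {}
    for i, rep in enumerate(REPRESENTATIONS):
        sf, _ = config.rep_settings(rep)
        cfg = replace(
            config.gsom,
            spread_factor=sf,
            random_seed=(config.master_seed * 1000003 + i) % (2**31),
        )
        m = train_gsom(tables[rep].vectors, cfg, sample_ids=list(tables[rep].pairs))
        m.save(out / f"map_{_rep_slug(rep)}.json")
        logger.info("cluster[%s]: %d nodes", rep, m.n_nodes)
        maps[rep] = m
    return maps


def stage_profile(config: PipelineConfig, tables=None, maps=None):
    """Profile nodes, infer per-map negatives and the consensus set."""
    out = _outdir(config)
    tables = tables or _load_tables(config)
    if maps is None:
        maps = {
            rep: GSOMMap.load(out / f"map_{_rep_slug(rep)}.json")
            for rep in REPRESENTATIONS
        }
    labels = tables["SFR1"].label_map()
    profiles, negs = {}, {}
    for rep in REPRESENTATIONS:
        prof = profile_nodes(maps[rep], labels, min_node_size=config.min_node_size)
        write_node_profiles(prof, out / f"profiles_{_rep_slug(rep)}.tsv")
        negs[rep] = infer_negatives(prof, provenance=rep)
        write_negative_set(negs[rep], out / f"negatives_{_rep_slug(rep)}.tsv")
        profiles[rep] = prof
        logger.info("profile[%s]: %d inferred negatives", rep, len(negs[rep]))
    consensus = consensus_negatives(negs["SFR1"], negs["SFR2-projected"])
    write_negative_set(consensus, out / "negatives_consensus.tsv")
    logger.info("profile: %d consensus negatives", len(consensus))
    return profiles, negs, consensus


def stage_train(config: PipelineConfig, tables=None, consensus=None):
    """Balanced-set ensemble training; models pickled with a JSON manifest."""
    out = _outdir(config)
    tables = tables or _load_tables(config)
    if consensus is None:
        consensus = read_negative_set(out / "negatives_consensus.tsv")
    labels = tables["SFR1"].label_map()
    positives = {p for p, l in labels.items() if l == POSITIVE}
    sets = build_balanced_sets(
        positives,
        consensus.pairs,
        n_sets=config.n_balanced_sets,
        seed=config.master_seed,
        max_per_class=config.balanced_set_cap,
    )
    models, manifest = [], []
    for rep in REPRESENTATIONS:
        _, C = config.rep_settings(rep)
        for i, ts in enumerate(sets):
            model = train_svm(
                ts,
                tables[rep],
                kernel_degree=config.kernel_degree,
                C=C,
                seed=(config.master_seed * 97 + i) % (2**31),
                training_set_id=i,
            )
            models.append(model)
            manifest.append(
                {
                    "representation": rep,
                    "training_set_id": i,
                    "seed": ts.seed,
                    "C": C,
                    "degree": config.kernel_degree,
                    "platt_A": model.calibration.A,
                    "platt_B": model.calibration.B,
                }
            )
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    with open(model_dir / "models.pkl", "wb") as fh:
        pickle.dump(models, fh)
    with open(model_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("train: %d models (%d sets x %d representations)",
                len(models), len(sets), len(REPRESENTATIONS))
    return models


def stage_predict(config: PipelineConfig, tables=None, models=None, profiles=None):
    """Score the prediction universe (unlabeled members of ambiguous nodes)."""
    out = _outdir(config)
    tables = tables or _load_tables(config)
    if models is None:
        with open(out / "models" / "models.pkl", "rb") as fh:
            models = pickle.load(fh)
    labels = tables["SFR1"].label_map()
    if profiles is None:
        maps = {
            rep: GSOMMap.load(out / f"map_{_rep_slug(rep)}.json")
            for rep in REPRESENTATIONS
        }
        profiles = {
            rep: profile_nodes(maps[rep], labels, min_node_size=config.min_node_size)
            for rep in REPRESENTATIONS
        }
    consensus = read_negative_set(out / "negatives_consensus.tsv")
    universe = set()
    for rep in REPRESENTATIONS:
        universe |= ambiguous_unlabeled_pairs(profiles[rep], labels)
    universe -= consensus.pairs
    predictions = ensemble_predict(models, tables, universe, threshold=config.threshold)
    import pandas as pd

    df = pd.DataFrame(
        {
            "drug_a": [p.pair[0] for p in predictions],
            "drug_b": [p.pair[1] for p in predictions],
            "mean_posterior": [p.mean_posterior for p in predictions],
            "decision": [p.decision for p in predictions],
        }
    )
    for m in range(len(models)):
        df[f"posterior_m{m}"] = [p.per_model_posteriors[m] for p in predictions]
    df.to_csv(out / "predictions.tsv", sep="\t", index=False)
    logger.info("predict: %d pairs scored, %d called",
                len(predictions), sum(p.decision == "predicted_DDI" for p in predictions))
    return predictions


def stage_annotate(config: PipelineConfig, tables=None, predictions=None, profiles=None):
    """Attach CYP dependence/isoforms to predictions from both maps' nodes."""
    if config.cyp_path is None:
        logger.info("annotate: no CYP annotation file configured, skipping")
        return None
    out = _outdir(config)
    tables = tables or _load_tables(config)
    labels = tables["SFR1"].label_map()
    known_cyp = read_cyp_annotations(config.cyp_path)
    if profiles is None:
        maps = {
            rep: GSOMMap.load(out / f"map_{_rep_slug(rep)}.json")
            for rep in REPRESENTATIONS
        }
        profiles = {
            rep: profile_nodes(maps[rep], labels, min_node_size=config.min_node_size)
            for rep in REPRESENTATIONS
        }
    if predictions is None:
        predictions = stage_predict(config, tables=tables, profiles=profiles)
    per_map_labels = []
    for rep in REPRESENTATIONS:
        lab = label_map_cyp(profiles[rep], known_cyp, labels)
        # pairs in excluded/positive nodes of this map get no node label;
        # treat them as carrying no CYP evidence from this map
        for pred in predictions:
            lab.setdefault(pred.pair, CYPLabel(dependence=CYP_INDEPENDENT))
        per_map_labels.append(lab)
    df = annotate_predictions(predictions, per_map_labels)
    df.to_csv(Path(config.output_dir) / "predictions_annotated.tsv", sep="\t", index=False)
    logger.info("annotate: %d CYP-dependent of %d predictions",
                int((df["cyp_dependence"] == "CYP-Dependent").sum()), len(df))
    return df


def stage_evaluate(config: PipelineConfig, tables=None):
    """Cross-validated metrics of the ensemble's base configuration.

    Mirrors the headline comparison layout: per representation, mean
    precision/recall/F1 over ``cv_folds`` stratified folds of the complete
    balanced training set (all positives used in balanced sets + consensus
    negatives).
    """
    from sklearn.svm import SVC
    import pandas as pd

    out = _outdir(config)
    tables = tables or _load_tables(config)
    consensus = read_negative_set(out / "negatives_consensus.tsv")
    labels = tables["SFR1"].label_map()
    positives = sorted(p for p, l in labels.items() if l == POSITIVE)
    negatives = sorted(consensus.pairs)
    m = min(len(positives), len(negatives))
    if config.balanced_set_cap:
        m = min(m, config.balanced_set_cap)
    rng = np.random.default_rng(config.master_seed)
    pos = [positives[i] for i in sorted(rng.choice(len(positives), m, replace=False))] \
        if len(positives) > m else positives
    neg = [negatives[i] for i in sorted(rng.choice(len(negatives), m, replace=False))] \
        if len(negatives) > m else negatives
    pairs = pos + neg
    y = np.array([1] * len(pos) + [0] * len(neg))
    rows = []
    for rep in REPRESENTATIONS:
        _, C = config.rep_settings(rep)
        X = tables[rep].matrix_for(pairs)

        def trainer(Xtr, ytr, C=C):
            svc = SVC(kernel="poly", degree=config.kernel_degree, C=C,
                      gamma="scale", coef0=1.0)
            svc.fit(Xtr, ytr)
            return svc

        mean, _ = kfold_cv(X, y, config.cv_folds, trainer, seed=config.master_seed)
        rows.append(
            {"representation": rep, "precision": mean.precision,
             "recall": mean.recall, "f1": mean.f1}
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "metrics.tsv", sep="\t", index=False)
    logger.info("evaluate:\n%s", df.to_string(index=False))
    return df


def _config_hash(config: PipelineConfig) -> str:
    data = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(data.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order; returns the output directory."""
    out = _outdir(config)
    tables = stage_featurize(config)
    maps = stage_cluster(config, tables=tables)
    profiles, _negs, consensus = stage_profile(config, tables=tables, maps=maps)
    models = stage_train(config, tables=tables, consensus=consensus)
    predictions = stage_predict(config, tables=tables, models=models, profiles=profiles)
    stage_annotate(config, tables=tables, predictions=predictions, profiles=profiles)
    stage_evaluate(config, tables=tables)
    manifest = {
        "gsompul_version": __version__,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "config_hash": _config_hash(config),
        "master_seed": config.master_seed,
        "stages": [
            "featurize", "cluster", "profile", "train",
            "predict", "annotate", "evaluate",
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
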