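"""High-level workflows: simulate, train, predict, evaluate.

These functions wire the library modules into the standard
train/predict/evaluate cycle and are the programmatic equivalent of a
command-line front end: each run writes its outputs plus a JSON
provenance record (configuration, seeds, package version, stage counts)
beside them, so any run is reproducible from the record alone.

Configuration files are JSON with the documented keys::

    {
      "encoder": "ONEHOT2",          # AMNF|ADNF|DPCP|TPCP|ONEHOT1|ONEHOT2|FUSED
      "folds": 5,
      "seed": 0,
      "vote_threshold": 3,
      "validation_fraction": 0.2,    # 0 disables the internal validation split
      "grids": {"RF": {"n_estimators": [100, 300]}, ...}   # optional
    }
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from methylvote.encoders import get_encoder
from methylvote.ensemble import (
    default_specs,
    load_model,
    save_model,
    train_ensemble,
)
from methylvote.evaluation import evaluate_predictions
from methylvote.sequence_io import (
    LabeledDataset,
    SplitSpec,
    clean_datasets,
    read_fasta,
    split_dataset,
    write_fasta,
)
from methylvote.synthetic import SyntheticSpec, default_profile, generate_pair

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "encoder": "ONEHOT2",
    "folds": 5,
    "seed": 0,
    "vote_threshold": 3,
    "validation_fraction": 0.2,
    "grids": None,
}


def load_config(path) -> dict:
    """Read a JSON run configuration, filling in documented defaults."""
    with open(path) as fh:
        user = json.load(fh)
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def _write_provenance(out_dir: Path, stage: str, payload: dict) -> None:
    from methylvote import __version__

    record = {"stage": stage, "package_version": __version__, **payload}
    with open(out_dir / f"{stage}_provenance.json", "w") as fh:
        json.dump(record, fh, indent=2, default=str)


def simulate(out_dir, n_pos: int = 1000, n_neg: int = 1000,
             strength: float = 0.5, seed: int = 0,
             window_length: int = 41, n_rate: float = 0.0) -> dict:
    """Write positives.fasta / negatives.fasta plus a JSON sidecar.

    Returns the paths written. The sidecar records the full generating
    spec so the dataset can be regenerated exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profile = default_profile(strength=strength, window_length=window_length,
                              n_rate=n_rate)
    spec = SyntheticSpec(n_pos=n_pos, n_neg=n_neg, profile=profile, seed=seed)
    pos, neg = generate_pair(spec)
    pos_path, neg_path = out_dir / "positives.fasta", out_dir / "negatives.fasta"
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
    sidecar = {
        "n_pos": n_pos, "n_neg": n_neg, "seed": seed,
        "window_length": window_length, "strength": strength,
        "n_rate": n_rate,
        "enriched": [list(e) for e in profile.enriched],
    }
    with open(out_dir / "simulation.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    _write_provenance(out_dir, "simulate", sidecar)
    logger.info("simulated %d positives + %d negatives into %s",
                n_pos, n_neg, out_dir)
    return {"positives": pos_path, "negatives": neg_path,
            "sidecar": out_dir / "simulation.json"}


def train(pos_fasta, neg_fasta, out_dir, config: dict | None = None,
          window_length: int = 41) -> dict:
    """Clean, optionally split, encode, fit the 5-learner ensemble, save.

    Stages (each logged): read FASTA -> clean -> optional internal
    validation split -> encode with the configured encoder -> optional
    per-algorithm grid search -> fit all five base learners -> save the
    model archive. Writes ``model.joblib``, ``cleaning_report.json``,
    validation metrics (if a validation split was requested) and a
    provenance record into ``out_dir``.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage read: loading %s and %s", pos_fasta, neg_fasta)
    positives = read_fasta(pos_fasta, label=1)
    negatives = read_fasta(neg_fasta, label=0)

    logger.info("stage clean: %d positives, %d negatives in",
                len(positives), len(negatives))
    pos, neg, report = clean_datasets(positives, negatives, max_len=window_length)
    (out_dir / "cleaning_report.json").write_text(report.to_json())

    data = pos.concat(neg, name=f"{pos_fasta}+{neg_fasta}")
    val_metrics = None
    val_frac = float(cfg["validation_fraction"] or 0.0)
    if val_frac > 0:
        logger.info("stage split: holding out %.0f%% for validation",
                    100 * val_frac)
        train_set, val_set = split_dataset(
            data, SplitSpec(train_fraction=1.0 - val_frac, seed=cfg["seed"])
        )
    else:
        train_set, val_set = data, None

    encoder = get_encoder(cfg["encoder"])
    logger.info("stage train: fitting ensemble on %d windows with %s",
                len(train_set), encoder.name)
    model = train_ensemble(
        train_set, encoder,
        specs=default_specs(cfg["seed"]),
        grids=cfg["grids"],
        folds=cfg["folds"],
        seed=cfg["seed"],
        vote_threshold=cfg["vote_threshold"],
        window_length=window_length,
    )
    model_path = out_dir / "model.joblib"
    save_model(model, model_path)

    if val_set is not None:
        logger.info("stage validate: scoring %d held-out windows", len(val_set))
        rep = evaluate_predictions(val_set.label_array(), model.predict(val_set),
                                   metadata={"split": "validation"})
        val_metrics = rep.as_dict()
        with open(out_dir / "validation_metrics.json", "w") as fh:
            json.dump(val_metrics, fh, indent=2)

    _write_provenance(out_dir, "train", {
        "config": cfg, "window_length": window_length,
        "inputs": {"positives": str(pos_fasta), "negatives": str(neg_fasta)},
        "cleaning": {"positive": report.positive, "negative": report.negative},
        "n_train": len(train_set),
        "validation_metrics": val_metrics,
    })
    return {"model": model_path, "validation_metrics": val_metrics,
            "cleaning_report": report}


def predict(model_path, query_fasta, out_tsv, skip_invalid: bool = False):
    """Predict every query window; write a TSV of labels and base votes.

    Output columns: ``id``, ``ensemble_label``, then one ``vote_<alg>``
    column per base learner. Invalid windows (wrong length or non-A
    center) abort the run with their ids listed unless ``skip_invalid``.
    """
    model = load_model(model_path)
    queries = read_fasta(query_fasta, label=0)
    windows = list(queries.windows)
    if skip_invalid:
        valid = [w for w in windows if w.is_model_ready(model.window_length)]
        n_dropped = len(windows) - len(valid)
        if n_dropped:
            logger.warning("skipping %d invalid query windows", n_dropped)
        if not valid:
            raise ValueError("no valid query windows remain after filtering")
        windows = valid
    table = model.predict_table(windows)
    table.to_csv(out_tsv, sep="\t", index=False)
    logger.info("wrote %d predictions to %s", len(table), out_tsv)
    return table


def evaluate(model_path, pos_fasta, neg_fasta, out_dir):
    """Score a model on a labeled FASTA pair; write TSV + JSON reports.

    Writes per-sample predictions (``predictions.tsv``), the metrics as
    both ``metrics.json`` and ``metrics.tsv``, and a provenance record.
    Returns the :class:`~methylvote.evaluation.MetricsReport`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = load_model(model_path)
    pos = read_fasta(pos_fasta, label=1)
    neg = read_fasta(neg_fasta, label=0)
    data = pos.concat(neg, name=f"{pos_fasta}+{neg_fasta}")

    table = model.predict_table(data)
    table["true_label"] = data.labels
    table.to_csv(out_dir / "predictions.tsv", sep="\t", index=False)

    rep = evaluate_predictions(data.label_array(),
                               table["ensemble_label"].to_numpy(),
                               metadata={"model": str(model_path)})
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(rep.as_dict(), fh, indent=2)
    with open(out_dir / "metrics.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in rep.as_dict().items():
            fh.write(f"{k}\t{v:.3f}\n")
    _write_provenance(out_dir, "evaluate", {
        "model": str(model_path),
        "inputs": {"positives": str(pos_fasta), "negatives": str(neg_fasta)},
        "n_evaluated": len(data),
        "metrics": rep.as_dict(),
    })
    logger.info("evaluation: %s", rep)
    return rep
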