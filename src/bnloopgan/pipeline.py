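"""End-to-end pipelines shared by the CLI and the test suite."""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np

from . import augmentation, evaluation, gan_core, io, loop_learning
from .config import RunConfig, substream_seed
from .gan_core import Network, build_classifier
from .synthetic_data import generate_connectomes

logger = logging.getLogger(__name__)


def prepare_samples(cfg: RunConfig, manifest=None):
    """Load or synthesize, then optionally scale and augment."""
    if manifest is not None:
        samples = io.load_samples(manifest)
    else:
        samples = generate_connectomes(cfg.synth)
    if cfg.scale:
        samples = [augmentation.scale_sample(s) for s in samples]
    if cfg.augment:
        out = []
        for s in samples:
            out.extend(augmentation.augment(s).all_samples())
        samples = out
    return samples


def metrics_from_scores(labels: np.ndarray, scores: np.ndarray,
                        seed: int) -> dict:
    preds = (scores > 0).astype(int)
    acc, sen, spe = evaluation.acc_sen_spe(evaluation.confusion(labels, preds))
    return {"ACC": round(acc, 6), "SEN": round(sen, 6), "SPE": round(spe, 6),
            "AUC": round(evaluation.auc_from_scores(scores, labels), 6),
            "n": int(labels.size), "seed": int(seed),
            "positive_class": "AB=1"}


def write_metrics(out_dir, metrics: dict) -> Path:
    path = Path(out_dir) / "metrics.json"
    path.write_text(json.dumps(metrics, sort_keys=True, indent=1) + "\n")
    return path


def run_training(cfg: RunConfig, manifest=None, out_dir=None) -> dict:
    """synthesize/load -> split -> pre-train GAN -> multi-loop -> metrics.

    Writes history.csv, ledger.jsonl, metrics.json, checkpoint.npz and
    the resolved-config sidecar into ``out_dir`` (when given) and
    returns the metrics dict.
    """
    cfg.resolve_seeds()
    samples = prepare_samples(cfg, manifest)
    train, test = augmentation.split_dataset(
        samples, cfg.split_fraction, cfg.split_mode,
        seed=substream_seed(cfg.seed, "split"))

    first = samples[0]
    cfg.gan.n_modalities = first.n_channels
    cfg.gan.image_size = first.n_regions

    gan = gan_core.pretrain_gan(train, cfg.gan)
    cls_rng = np.random.default_rng(substream_seed(cfg.seed, "classifier-init"))
    classifier = Network(build_classifier(cfg.gan.n_modalities,
                                          cfg.gan.image_size,
                                          width=cfg.gan.width), cls_rng)
    result = loop_learning.run_multiloop(train, gan, classifier, cfg.loop, test)

    tx = np.stack([s.tensor.transpose(2, 0, 1) for s in test])
    ty = np.array([s.label for s in test])
    scores = loop_learning.classifier_scores(result.classifier, tx)
    metrics = metrics_from_scores(ty, scores, cfg.seed)
    metrics["converged"] = bool(result.converged)
    metrics["n_loops"] = len(result.history)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.write_sidecar(out)
        write_metrics(out, metrics)
        with open(out / "history.csv", "w", newline="") as f:
            w = csv.DictWriter(f, fieldnames=["loop", "n_selected",
                                              "acc", "sen", "spe"])
            w.writeheader()
            w.writerows(result.history)
        with open(out / "ledger.jsonl", "w") as f:
            for rec in result.ledger:
                f.write(json.dumps(rec, sort_keys=True) + "\n")
        io.save_checkpoint(out / "checkpoint.npz",
                           {"generator": gan.generator, "critic": gan.critic,
                            "classifier": result.classifier},
                           {"config": cfg.to_dict()})
    return metrics


def run_evaluation(checkpoint, manifest, out_dir=None) -> dict:
    """Score a saved classifier on a manifest's samples."""
    arrays, meta = io.load_checkpoint(checkpoint)
    cfg = RunConfig.from_dict(meta["config"])
    samples = prepare_samples(cfg, manifest)
    classifier = Network(build_classifier(cfg.gan.n_modalities,
                                          cfg.gan.image_size,
                                          width=cfg.gan.width),
                         np.random.default_rng(0))
    io.restore_network(classifier, arrays, "classifier")
    x = np.stack([s.tensor.transpose(2, 0, 1) for s in samples])
    y = np.array([s.label for s in samples])
    scores = loop_learning.classifier_scores(classifier, x)
    metrics = metrics_from_scores(y, scores, cfg.seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_metrics(out, metrics)
        curve = evaluation.roc_curve(scores, y)
        with open(out / "roc.csv", "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["fpr", "tpr", "threshold"])
            w.writerows(zip(curve.fpr, curve.tpr, curve.thresholds))
    return metrics
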